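"""Sequence and annotation input/output.

Reads protein and CDS FASTA, translates in-frame coding sequences, and
derives per-gene exon statistics from a GFF3 subset or a tabular gene-order
file.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "CdsRecord",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "read_gene_order",
    "read_gff3_gene_models",
    "exon_stats",
]

_CODON_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with a unique identifier.

    ``sequence`` is uppercase over the 20 standard letters plus X/B/Z/U/*.
    """

    id: str
    sequence: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """An in-frame coding sequence over {A,C,G,T,N}; frame is always 1."""

    id: str
    sequence: str
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """One gene locus with its primary-transcript exon count."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_count: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")


def read_fasta(path: str | Path, kind: str = "protein") -> list:
    """Read a FASTA file into :class:`ProteinRecord` or :class:`CdsRecord`.

    The record ID is the first whitespace-delimited token of the header;
    sequences are uppercased.  Duplicate IDs raise ``ValueError``; an empty
    file returns an empty list with a warning.
    """
    path = Path(path)
    if kind not in ("protein", "cds"):
        raise ValueError(f"unknown kind {kind!r}")
    text_head = ""
    with open(path) as handle:
        for line in handle:
            if line.strip():
                text_head = line
                break
    if not text_head:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    if not text_head.startswith(">"):
        raise ValueError(f"{path}: sequence data before first FASTA header")

    cls = ProteinRecord if kind == "protein" else CdsRecord
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicated record ID {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() or None
        records.append(cls(id=rec.id, sequence=str(rec.seq), description=desc))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    seqrecords = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=r.description or "",
        )
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def translate_cds(cds: CdsRecord) -> ProteinRecord:
    """Translate an in-frame CDS with the standard genetic code.

    A terminal stop codon is dropped; an internal stop raises ``ValueError``
    naming the 1-based codon index.  Codons containing a base outside
    {A,C,G,T} translate to ``X``.
    """
    seq = cds.sequence
    if len(seq) % 3 != 0:
        raise ValueError(
            f"{cds.id}: CDS length {len(seq)} not divisible by 3"
        )
    n_codons = len(seq) // 3
    residues: list[str] = []
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        if any(b not in "ACGT" for b in codon):
            residues.append("X")
        elif codon in _STOP_CODONS:
            if i == n_codons - 1:
                break  # terminal stop dropped
            raise ValueError(
                f"{cds.id}: internal stop codon {codon} at codon {i + 1}"
            )
        else:
            residues.append(_CODON_TABLE.forward_table[codon])
    if not residues:
        raise ValueError(f"{cds.id}: CDS encodes no residues")
    return ProteinRecord(id=cds.id, sequence="".join(residues),
                         description=cds.description)


def read_gene_order(path: str | Path) -> list[GeneModel]:
    """Read a tabular gene-order TSV.

    Columns: gene_id, chromosome, start, end, strand and optionally
    exon_count (defaults to 1).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chromosome", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicated gene ID {dup!r}")
    has_exons = "exon_count" in df.columns
    return [
        GeneModel(
            gene_id=str(row.gene_id),
            chromosome=str(row.chromosome),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            exon_count=int(row.exon_count) if has_exons else 1,
        )
        for row in df.itertuples(index=False)
    ]


def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 subset (gene/mRNA/exon rows only).

    The exon count is taken from the primary transcript, defined as the
    first mRNA listed for the gene; a gene with no mRNA children gets
    exon_count 1.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    # file order of mRNA features, for the "first listed" rule
    mrna_order: dict[str, int] = {}
    for i, feat in enumerate(db.all_features()):
        if feat.featuretype == "mRNA":
            mrna_order[feat.id] = i

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = sorted(
            db.children(gene, featuretype="mRNA"),
            key=lambda m: mrna_order.get(m.id, 0),
        )
        if mrnas:
            exon_count = sum(
                1 for _ in db.children(mrnas[0], featuretype="exon")
            )
            exon_count = max(exon_count, 1)
        else:
            exon_count = 1
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exon_count=exon_count,
            )
        )
    return models


def exon_stats(models: Iterable[GeneModel]) -> tuple[dict[int, int], int]:
    """Histogram of exon counts and the number of intronless genes.

    Returns ``(histogram, intronless)`` where ``histogram`` maps
    exon_count -> gene count and intronless genes are those with a single
    exon.
    """
    hist: dict[int, int] = {}
    for m in models:
        hist[m.exon_count] = hist.get(m.exon_count, 0) + 1
    return dict(sorted(hist.items())), hist.get(1, 0)
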