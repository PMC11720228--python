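"""RING-domain detection by metal-ligand grammar matching.

A RING zinc-finger coordinates two zinc ions through eight metal-ligand
(ml) residues in a cross-brace arrangement: ml1-ml2 and ml5-ml6 bind one
ion, ml3-ml4 and ml7-ml8 the other.  Each RING type is described by a
small grammar: an allowed residue set at each of the eight ml positions
and a bounded range (or finite set) of spacer lengths between consecutive
ml residues.  The scanner enumerates every position 8-tuple satisfying a
type's constraints, so detection is exhaustive by construction.

The default grammar encodes the eight cotton RING type specifications
(RING-H2, RING-HCa, RING-HCb, RING-v, RING-C2, RING-S/T, RING-D, RING-G).
One deliberate deviation from the published consensus table: the
RING-HCb ml7-ml8 spacer is fixed at 4 residues, following the observation
that all RING-HCb domains carry a four-residue spacer there; with a
two-residue spacer the HCb row would be a strict subset of HCa.  The
grammar is user-overridable via JSON for anyone preferring the printed
table.

RING-D is encoded exactly as its consensus row prints (no aspartate
appears in the row): it is a fixed-gap special case lying inside
RING-HCa's ranges, separated from HCa purely by precedence
(most-constrained types are checked first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seqio import ProteinRecord

__all__ = [
    "RingTypeSpec",
    "RingGrammar",
    "RingDomainHit",
    "default_grammar",
    "enumerate_matches",
    "resolve_hits",
    "classify_proteins",
    "hits_to_frame",
    "frame_to_hits",
]

#: letters that may appear in an ml residue set
LIGAND_LETTERS = frozenset("CHSTG")

#: 1-letter codes that never satisfy an ml constraint but are legal spacers
NONSTANDARD = frozenset("XBZU*")


@dataclass(frozen=True)
class RingTypeSpec:
    """Grammar for one RING type.

    ``residues`` holds 8 allowed-residue sets (ml1..ml8); ``gaps`` holds
    7 finite sets of allowed spacer lengths between consecutive ml
    residues.  ``precedence`` ranks the type for tie-breaking when several
    types match the same positions (lower = checked first).
    """

    name: str
    residues: tuple[frozenset[str], ...]
    gaps: tuple[frozenset[int], ...]
    precedence: int

    def __post_init__(self) -> None:
        if len(self.residues) != 8:
            raise ValueError(f"{self.name}: need 8 residue sets")
        if len(self.gaps) != 7:
            raise ValueError(f"{self.name}: need 7 gap sets")
        for rset in self.residues:
            if not rset or not rset <= LIGAND_LETTERS:
                raise ValueError(
                    f"{self.name}: residue sets must be non-empty subsets "
                    f"of {sorted(LIGAND_LETTERS)}"
                )
        for gset in self.gaps:
            if not gset or min(gset) < 0:
                raise ValueError(f"{self.name}: invalid gap set {gset}")

    @property
    def min_span(self) -> int:
        return 8 + sum(min(g) for g in self.gaps)


def _spec(name: str, residues: Sequence[str], gaps: Sequence, rank: int
          ) -> RingTypeSpec:
    gsets = []
    for g in gaps:
        if isinstance(g, int):
            gsets.append(frozenset({g}))
        elif isinstance(g, tuple):
            gsets.append(frozenset(range(g[0], g[1] + 1)))
        else:
            gsets.append(frozenset(g))
    return RingTypeSpec(
        name=name,
        residues=tuple(frozenset(r) for r in residues),
        gaps=tuple(gsets),
        precedence=rank,
    )


@dataclass(frozen=True)
class RingGrammar:
    """An ordered collection of :class:`RingTypeSpec` (by precedence)."""

    specs: tuple[RingTypeSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate type names in grammar")
        object.__setattr__(
            self, "specs", tuple(sorted(self.specs, key=lambda s: s.precedence))
        )

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def spec(self, name: str) -> RingTypeSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def type_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": s.name,
                "residues": ["".join(sorted(r)) for r in s.residues],
                "gaps": [sorted(g) for g in s.gaps],
                "precedence": s.precedence,
            }
            for s in self.specs
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RingGrammar":
        payload = json.loads(Path(path).read_text())
        return cls(
            specs=tuple(
                RingTypeSpec(
                    name=item["name"],
                    residues=tuple(frozenset(r) for r in item["residues"]),
                    gaps=tuple(frozenset(g) for g in item["gaps"]),
                    precedence=int(item["precedence"]),
                )
                for item in payload
            )
        )


def default_grammar() -> RingGrammar:
    """The eight-type cotton RING grammar.

    Precedence is specific-before-general: fixed-gap and rare-residue
    types first, broadest ranges last, so the RING-HCa spec cannot absorb
    the special cases it contains.
    """
    specs = (
        _spec("RING-G", ["C", "C", "C", "H", "G", "C", "C", "C"],
              [2, 16, 1, 2, 2, 13, 2], 0),
        _spec("RING-D", ["C", "C", "C", "H", "C", "C", "C", "C"],
              [2, 12, 1, 2, 2, 10, 2], 1),
        _spec("RING-S/T", ["C", "ST", "C", "H", "C", "CS", "C", "C"],
              [2, (10, 14), 1, {2, 3}, 2, {6, 13}, 2], 2),
        _spec("RING-C2", ["C", "C", "C", "C", "C", "C", "C", "C"],
              [2, (13, 15), 1, 4, 2, (10, 36), 2], 3),
        _spec("RING-v", ["C", "C", "C", "C", "H", "C", "C", "C"],
              [2, (11, 27), 1, 7, 2, (12, 15), 4], 4),
        _spec("RING-HCb", ["C", "C", "C", "H", "C", "C", "C", "C"],
              [2, (11, 13), 1, 2, 2, (11, 18), 4], 5),
        _spec("RING-H2", ["C", "C", "C", "H", "H", "C", "C", "C"],
              [2, (11, 28), 1, 2, 2, (7, 45), 2], 6),
        _spec("RING-HCa", ["C", "C", "C", "H", "C", "C", "C", "C"],
              [2, (9, 20), 1, {2, 3}, 2, (6, 29), {1, 2}], 7),
    )
    return RingGrammar(specs=specs)


@dataclass(frozen=True)
class RingDomainHit:
    """One detected RING domain.

    ``ml_positions`` are the 1-based indices of the eight metal-ligand
    residues; ``spacers`` are the seven intervening amino-acid counts.
    """

    protein_id: str
    type_name: str
    ml_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ml_positions) != 8:
            raise ValueError("need 8 ml positions")
        if any(b <= a for a, b in zip(self.ml_positions, self.ml_positions[1:])):
            raise ValueError("ml positions must be strictly increasing")

    @property
    def spacers(self) -> tuple[int, ...]:
        p = self.ml_positions
        return tuple(p[i + 1] - p[i] - 1 for i in range(7))

    @property
    def start(self) -> int:
        return self.ml_positions[0]

    @property
    def end(self) -> int:
        return self.ml_positions[7]

    def overlaps(self, other: "RingDomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


def enumerate_matches(
    record: ProteinRecord, grammar: RingGrammar | None = None
) -> list[RingDomainHit]:
    """All (type, ml-tuple) matches in one protein, exhaustively.

    Equivalent to brute-force enumeration of every strictly increasing
    8-tuple of positions against each type's residue and gap constraints;
    implemented as a depth-first walk over candidate ligand positions.
    Spacer residues are unconstrained.  Hits are returned in ascending
    start order (then end, then type precedence).
    """
    if grammar is None:
        grammar = default_grammar()
    seq = record.sequence.upper()
    n = len(seq)
    # candidate position lists per ligand letter, 0-based
    positions: dict[str, list[int]] = {c: [] for c in LIGAND_LETTERS}
    for i, aa in enumerate(seq):
        if aa in positions:
            positions[aa].append(i)

    hits: list[RingDomainHit] = []
    for spec in grammar:
        if n < spec.min_span:
            continue
        starts = sorted(
            {i for aa in spec.residues[0] for i in positions[aa]}
        )
        # iterative DFS over (slot, position) partial matches
        for start in starts:
            stack = [(1, (start,))]
            while stack:
                slot, tup = stack.pop()
                if slot == 8:
                    hits.append(
                        RingDomainHit(
                            protein_id=record.id,
                            type_name=spec.name,
                            ml_positions=tuple(p + 1 for p in tup),
                        )
                    )
                    continue
                prev = tup[-1]
                allowed = spec.residues[slot]
                for gap in spec.gaps[slot - 1]:
                    j = prev + gap + 1
                    if j < n and seq[j] in allowed:
                        stack.append((slot + 1, tup + (j,)))

    rank = {s.name: s.precedence for s in grammar}
    hits.sort(key=lambda h: (h.start, h.end, rank[h.type_name], h.ml_positions))
    return hits


def resolve_hits(
    hits: Iterable[RingDomainHit],
    grammar: RingGrammar | None = None,
    policy: str = "resolved",
) -> list[RingDomainHit]:
    """Reduce overlapping hits of one protein to disjoint domains.

    Default policy partitions the hits into overlap clusters (transitive
    sharing of any sequence position) and keeps one hit per cluster,
    preferring highest-precedence type, then leftmost ml1, then smallest
    span.  Policy ``"all"`` returns the input unchanged.
    """
    hits = list(hits)
    if policy == "all":
        return hits
    if policy != "resolved":
        raise ValueError(f"unknown policy {policy!r}")
    if not hits:
        return []
    if len({h.protein_id for h in hits}) > 1:
        raise ValueError("resolve_hits expects hits from a single protein")
    if grammar is None:
        grammar = default_grammar()
    rank = {s.name: s.precedence for s in grammar}

    ordered = sorted(hits, key=lambda h: (h.start, h.end))
    clusters: list[list[RingDomainHit]] = []
    cluster_end = -1
    for h in ordered:
        if clusters and h.start <= cluster_end:
            clusters[-1].append(h)
            cluster_end = max(cluster_end, h.end)
        else:
            clusters.append([h])
            cluster_end = h.end
    return [
        min(c, key=lambda h: (rank[h.type_name], h.start, h.end - h.start))
        for c in clusters
    ]


def classify_proteins(
    records: Iterable[ProteinRecord],
    grammar: RingGrammar | None = None,
    policy: str = "resolved",
) -> tuple[pd.DataFrame, pd.Series, list[RingDomainHit]]:
    """Scan a protein cohort and summarize it.

    Returns ``(per_protein, per_type, hits)``: a per-protein table
    (protein_id, n_domains, types) restricted to proteins with at least
    one domain, per-type domain totals, and the flat hit list.
    """
    if grammar is None:
        grammar = default_grammar()
    rows = []
    all_hits: list[RingDomainHit] = []
    type_totals = {name: 0 for name in grammar.type_names}
    for rec in records:
        hits = resolve_hits(enumerate_matches(rec, grammar), grammar, policy)
        if not hits:
            continue
        all_hits.extend(hits)
        for h in hits:
            type_totals[h.type_name] += 1
        rows.append(
            {
                "protein_id": rec.id,
                "n_domains": len(hits),
                "types": ",".join(h.type_name for h in hits),
            }
        )
    per_protein = pd.DataFrame(rows, columns=["protein_id", "n_domains", "types"])
    per_type = pd.Series(type_totals, name="n_domains")
    return per_protein, per_type, all_hits


def hits_to_frame(hits: Iterable[RingDomainHit]) -> pd.DataFrame:
    """Flatten hits to a table (one row per domain)."""
    rows = []
    for h in hits:
        row = {"protein_id": h.protein_id, "type": h.type_name,
               "start": h.start, "end": h.end}
        for i, p in enumerate(h.ml_positions, 1):
            row[f"ml{i}"] = p
        for i, g in enumerate(h.spacers, 1):
            row[f"g{i}"] = g
        rows.append(row)
    cols = (["protein_id", "type", "start", "end"]
            + [f"ml{i}" for i in range(1, 9)] + [f"g{i}" for i in range(1, 8)])
    return pd.DataFrame(rows, columns=cols)


def frame_to_hits(df: pd.DataFrame) -> list[RingDomainHit]:
    return [
        RingDomainHit(
            protein_id=str(row["protein_id"]),
            type_name=str(row["type"]),
            ml_positions=tuple(int(row[f"ml{i}"]) for i in range(1, 9)),
        )
        for _, row in df.iterrows()
    ]
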