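"""Synthetic fixtures with known ground truth.

Three generators emulate the data structures of a RING gene-family study:

* protein cohorts with planted RING domains of each grammar type (in the
  default "non-ligand" mode, spacer and flank residues avoid C/H/S/T/G so
  the planted domains are provably the only grammar matches);
* codon-aligned CDS pairs evolved from a common ancestor at a specified
  dN/dS (nonsynonymous proposals accepted with probability min(1, omega),
  synonymous with min(1, 1/omega); stop-creating changes are rejected and
  redrawn);
* long-format expression tables over salt-stress time points with planted
  per-time-point DEG counts, all-time-point up/down genes and
  concordant/discordant duplicate pairs.

Each generator takes a single integer seed driving one private
``numpy.random.default_rng`` stream, so equal seeds give byte-identical
output.  Ground truth is returned alongside the data, never re-derived.

The generators emulate structure, not realism: amino-acid composition is
uniform over the chosen alphabet, codon usage is uniform over sense
codons, and expression values are drawn directly in (log2FC, adjusted p)
space rather than from a count model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .grammar import RingGrammar, default_grammar
from .seqio import CdsRecord, ProteinRecord

__all__ = [
    "NONLIGAND_ALPHABET",
    "PlantedCohortSpec",
    "OmegaSimSpec",
    "make_protein_cohort",
    "simulate_codon_pairs",
    "make_expression_fixture",
    "make_duplicate_fixture",
]

#: standard residues that can never satisfy an ml constraint
NONLIGAND_ALPHABET: str = "AVLIPFWMDENQKRY"
FULL_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_STOPS = frozenset(_TABLE.stop_codons)
_SENSE_CODONS = sorted(
    c for c in ("".join(p) for p in product("ACGT", repeat=3))
    if c not in _STOPS
)
_AA = {c: _TABLE.forward_table.get(c, "*") for c in
       ("".join(p) for p in product("ACGT", repeat=3))}


# --------------------------------------------------------------------------
# planted RING-domain cohorts
# --------------------------------------------------------------------------

@dataclass
class PlantedCohortSpec:
    """Recipe for a protein cohort with planted RING domains.

    ``counts`` maps type name -> number of planted domains.  Domains are
    packed onto proteins: ``n_three_domain`` proteins carry three domains
    and ``n_two_domain`` carry two; the rest carry one each.  Spacer
    lengths default to uniform draws from each type's grammar range;
    ``spacer_lengths`` may pin them per type.  ``alphabet`` selects the
    spacer/flank residue pool ("non-ligand" or "full").
    """

    counts: dict[str, int]
    n_two_domain: int = 0
    n_three_domain: int = 0
    flank_length: tuple[int, int] = (10, 40)
    alphabet: str = "non-ligand"
    spacer_lengths: dict[str, Sequence[int]] | None = None
    seed: int = 0
    grammar: RingGrammar | None = None

    def __post_init__(self) -> None:
        if self.alphabet not in ("non-ligand", "full"):
            raise ValueError(f"unknown alphabet mode {self.alphabet!r}")
        grammar = self.grammar or default_grammar()
        for name, n in self.counts.items():
            grammar.spec(name)  # KeyError on unknown type
            if n < 0:
                raise ValueError(f"negative count for {name}")
        if self.spacer_lengths:
            for name, lengths in self.spacer_lengths.items():
                spec = grammar.spec(name)
                if len(lengths) != 7:
                    raise ValueError(f"{name}: need 7 spacer lengths")
                for gi, (length, gset) in enumerate(
                    zip(lengths, spec.gaps), 1
                ):
                    if length not in gset:
                        raise ValueError(
                            f"{name}: spacer g{gi}={length} outside grammar "
                            f"range {sorted(gset)}"
                        )
        total = sum(self.counts.values())
        needed = 2 * self.n_two_domain + 3 * self.n_three_domain
        if needed > total:
            raise ValueError(
                f"multi-domain layout needs {needed} domains, only "
                f"{total} requested"
            )


def _build_domain(
    spec,
    rng: np.random.Generator,
    pinned: Sequence[int] | None,
    shadowing_specs: Sequence = (),
) -> tuple[list[str], list[int]]:
    """Draw ml residues and spacer lengths for one planted domain.

    When spacer lengths are drawn (not pinned), draws that would also
    satisfy a higher-precedence type on the same positions are rejected
    and redrawn, so the planted domain is classified as its own type.
    """
    residues = [
        sorted(rset)[rng.integers(len(rset))] for rset in spec.residues
    ]
    if pinned is not None:
        return residues, list(pinned)
    for _ in range(1000):
        gaps = [sorted(g)[rng.integers(len(g))] for g in spec.gaps]
        shadowed = any(
            all(r in other.residues[i] for i, r in enumerate(residues))
            and all(g in other.gaps[i] for i, g in enumerate(gaps))
            for other in shadowing_specs
        )
        if not shadowed:
            return residues, gaps
    raise ValueError(
        f"{spec.name}: every spacer draw collides with a higher-precedence "
        "type"
    )


def make_protein_cohort(
    spec: PlantedCohortSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a protein cohort and its ground-truth hit table.

    Returns ``(records, truth)`` where ``truth`` has one row per planted
    domain: protein_id, type, start, end and ml1..ml8 (1-based).
    """
    rng = np.random.default_rng(spec.seed)
    grammar = spec.grammar or default_grammar()
    letters = NONLIGAND_ALPHABET if spec.alphabet == "non-ligand" else FULL_ALPHABET
    letters = np.array(list(letters))

    def random_run(length: int) -> str:
        if length == 0:
            return ""
        return "".join(rng.choice(letters, size=length))

    pool: list[str] = []
    for name in sorted(spec.counts):
        pool.extend([name] * spec.counts[name])
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    layout: list[int] = (
        [3] * spec.n_three_domain + [2] * spec.n_two_domain
    )
    layout += [1] * (len(pool) - sum(layout))

    # inter-domain linkers longer than the widest grammar gap, so no
    # chimeric match can bridge two planted domains
    max_gap = max(max(g) for s in grammar for g in s.gaps)

    records: list[ProteinRecord] = []
    truth_rows = []
    cursor = 0
    lo, hi = spec.flank_length
    for p_idx, n_domains in enumerate(layout):
        if n_domains == 0:
            continue
        pid = f"synth{p_idx + 1:04d}"
        parts: list[str] = []
        pos = 0
        for d in range(n_domains):
            type_name = pool[cursor]
            cursor += 1
            tspec = grammar.spec(type_name)
            if d == 0:
                flank = random_run(int(rng.integers(lo, hi + 1)))
            else:
                flank = random_run(
                    int(rng.integers(max_gap + 1, max_gap + 41))
                )
            parts.append(flank)
            pos += len(flank)
            pinned = (
                spec.spacer_lengths.get(type_name)
                if spec.spacer_lengths else None
            )
            shadowing = [
                s for s in grammar if s.precedence < tspec.precedence
            ]
            residues, gaps = _build_domain(tspec, rng, pinned, shadowing)
            ml_offsets = [0]
            for g in gaps:
                ml_offsets.append(ml_offsets[-1] + g + 1)
            domain_chars = [""] * (ml_offsets[-1] + 1)
            for off, res in zip(ml_offsets, residues):
                domain_chars[off] = res
            for i, ch in enumerate(domain_chars):
                if not ch:
                    domain_chars[i] = str(rng.choice(letters))
            domain = "".join(domain_chars)
            ml_abs = [pos + off + 1 for off in ml_offsets]  # 1-based
            row = {"protein_id": pid, "type": type_name,
                   "start": ml_abs[0], "end": ml_abs[-1]}
            for i, p in enumerate(ml_abs, 1):
                row[f"ml{i}"] = p
            truth_rows.append(row)
            parts.append(domain)
            pos += len(domain)
        tail = random_run(int(rng.integers(lo, hi + 1)))
        parts.append(tail)
        records.append(ProteinRecord(id=pid, sequence="".join(parts)))

    cols = (["protein_id", "type", "start", "end"]
            + [f"ml{i}" for i in range(1, 9)])
    truth = pd.DataFrame(truth_rows, columns=cols)
    return records, truth


# --------------------------------------------------------------------------
# codon-pair evolution at a target omega
# --------------------------------------------------------------------------

@dataclass
class OmegaSimSpec:
    """Recipe for codon-aligned pairs evolved at a fixed dN/dS."""

    n_pairs: int
    n_codons: int
    p_substitution: float
    omega: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_substitution < 0.1:
            raise ValueError(
                "per-site substitution probability must be in [0, 0.1) "
                "(low-divergence regime)"
            )
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.n_pairs < 0 or self.n_codons <= 0:
            raise ValueError("invalid cohort dimensions")


def _mutate_lineage(
    codons: list[str], p: float, omega: float, rng: np.random.Generator
) -> list[str]:
    """One descendant: per-site mutation with selection on amino acids.

    Nonsynonymous proposals are accepted with probability min(1, omega)
    and synonymous proposals with min(1, 1/omega), so the realized
    nonsynonymous/synonymous rate ratio equals omega on both sides of 1
    (for omega <= 1 synonymous changes are always accepted).
    """
    n_sites = 3 * len(codons)
    hit = np.flatnonzero(rng.random(n_sites) < p)
    accept_nonsyn = min(1.0, omega)
    accept_syn = min(1.0, 1.0 / omega)
    out = list(codons)
    for site in hit:
        k, j = divmod(int(site), 3)
        codon = out[k]
        current = codon[j]
        candidates = [b for b in "ACGT" if b != current]
        order = rng.permutation(3)
        new_codon = None
        for idx in order:
            cand = codon[:j] + candidates[idx] + codon[j + 1:]
            if cand not in _STOPS:
                new_codon = cand
                break
        if new_codon is None:
            continue  # every alternative creates a stop (cannot happen)
        accept = (
            accept_nonsyn if _AA[new_codon] != _AA[codon] else accept_syn
        )
        if accept < 1.0 and rng.random() >= accept:
            continue
        out[k] = new_codon
    return out


def simulate_codon_pairs(
    spec: OmegaSimSpec,
) -> tuple[list[tuple[CdsRecord, CdsRecord]], pd.DataFrame]:
    """Evolve CDS pairs from uniform-sense-codon ancestors.

    Each of the two descendants mutates independently: every nucleotide
    site mutates with probability ``p_substitution``; a proposed change is
    redrawn if it creates a stop codon, accepted with probability
    min(1, omega) if nonsynonymous and min(1, 1/omega) if synonymous.
    Returns the pair list and a truth table (pair_id, omega).
    """
    rng = np.random.default_rng(spec.seed)
    sense = np.array(_SENSE_CODONS)
    pairs: list[tuple[CdsRecord, CdsRecord]] = []
    truth_rows = []
    for i in range(spec.n_pairs):
        ancestor = list(rng.choice(sense, size=spec.n_codons))
        d1 = _mutate_lineage(ancestor, spec.p_substitution, spec.omega, rng)
        d2 = _mutate_lineage(ancestor, spec.p_substitution, spec.omega, rng)
        pair_id = f"pair{i + 1:04d}"
        pairs.append(
            (
                CdsRecord(id=f"{pair_id}_a", sequence="".join(d1)),
                CdsRecord(id=f"{pair_id}_b", sequence="".join(d2)),
            )
        )
        truth_rows.append((pair_id, spec.omega))
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "omega"])
    return pairs, truth


# --------------------------------------------------------------------------
# expression tables with planted DEG structure
# --------------------------------------------------------------------------

def make_expression_fixture(
    n_genes: int = 914,
    per_timepoint_degs: Sequence[int] = (107, 153, 273, 90),
    timepoints: Sequence[int] = (1, 3, 12, 48),
    n_total_degs: int = 393,
    n_min2: int = 144,
    n_all: int = 13,
    n_all_up: int = 10,
    n_concordant_pairs: int = 45,
    n_discordant_pairs: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Long-format expression table with fully planted DEG structure.

    The defaults emulate the shape of a four-time-point salt-stress
    screen of a 914-member gene family: 393 DEGs overall with
    107/153/273/90 per time point, 144 genes differential at two or more
    time points, 13 of them at all four (10 up, 3 down), and 45 duplicate
    pairs with direction-concordant expression.

    Planted DEG cells receive |log2FC| in [1.5, 4] and adjusted p below
    0.05; every other cell violates at least one threshold.  Duplicate
    pair members share identical DEG time-point sets so concordance is
    non-vacuous.  Returns ``(table, truth)``; ``truth`` holds the planted
    per-time-point counts, membership sets, pair table and per-cell DEG
    labels.
    """
    rng = np.random.default_rng(seed)
    T = len(timepoints)
    per_tp = list(per_timepoint_degs)
    if len(per_tp) != T:
        raise ValueError("per_timepoint_degs length must match timepoints")
    if not (n_all <= n_min2 <= n_total_degs <= n_genes):
        raise ValueError("need n_all <= n_min2 <= n_total_degs <= n_genes")
    if n_all_up > n_all:
        raise ValueError("n_all_up exceeds n_all")
    if any(c < n_all for c in per_tp):
        raise ValueError("per-timepoint counts must cover all-timepoint genes")

    events_total = sum(per_tp)
    n_single = n_total_degs - n_min2
    n_multi = n_min2 - n_all  # DE at 2..T-1 timepoints
    multi_events = events_total - n_all * T - n_single
    if not (2 * n_multi <= multi_events <= max(T - 1, 2) * n_multi):
        raise ValueError(
            f"infeasible: {n_multi} multi genes cannot produce "
            f"{multi_events} DEG events with 2..{T - 1} timepoints each"
        )
    n_k3 = multi_events - 2 * n_multi  # genes DE at 3 timepoints (T=4)
    if T == 3:
        n_k3 = 0
        if multi_events != 2 * n_multi:
            raise ValueError("with 3 timepoints multi genes must have k=2")

    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    shuffled = [genes[i] for i in rng.permutation(n_genes)]
    it = iter(shuffled)
    all_up = [next(it) for _ in range(n_all_up)]
    all_down = [next(it) for _ in range(n_all - n_all_up)]
    multi_k = [3] * n_k3 + [2] * (n_multi - n_k3)
    multi_genes = [next(it) for _ in range(n_multi)]
    single_genes = [next(it) for _ in range(n_single)]

    # pair multi genes of equal k so pair members share a timepoint set
    n_pairs = n_concordant_pairs + n_discordant_pairs
    k3_genes = multi_genes[:n_k3]
    k2_genes = multi_genes[n_k3:]
    avail_pairs = len(k3_genes) // 2 + len(k2_genes) // 2
    if n_pairs > avail_pairs:
        raise ValueError(
            f"cannot form {n_pairs} pairs from {n_multi} multi-timepoint "
            f"genes of equal k (max {avail_pairs})"
        )
    pair_units: list[tuple[str, str, int]] = []  # (gene_a, gene_b, k)
    paired: set[str] = set()
    for glist, k in ((k3_genes, 3), (k2_genes, 2)):
        for i in range(0, len(glist) - 1, 2):
            if len(pair_units) == n_pairs:
                break
            pair_units.append((glist[i], glist[i + 1], k))
            paired.update(glist[i : i + 2])
    unpaired_multi = [
        (g, k) for g, k in zip(multi_genes, multi_k) if g not in paired
    ]

    # capacity-greedy timepoint assignment
    capacity = np.array([c - n_all for c in per_tp], dtype=int)
    assignment: dict[str, list[int]] = {}

    def assign(unit_genes: list[str], k: int, weight: int) -> None:
        order = np.argsort(-capacity, kind="stable")[:k]
        chosen = sorted(int(t) for t in order)
        if capacity[chosen].min() < weight:
            raise ValueError("timepoint capacities exhausted; "
                             "planted counts are infeasible")
        for t in chosen:
            capacity[t] -= weight
        for g in unit_genes:
            assignment[g] = chosen

    for a, b, k in pair_units:
        assign([a, b], k, 2)
    for g, k in sorted(unpaired_multi, key=lambda x: -x[1]):
        assign([g], k, 1)
    for g in single_genes:
        assign([g], 1, 1)
    if capacity.sum() != 0 or capacity.min() < 0:
        raise ValueError("timepoint capacities not exactly consumed")

    # directions
    direction: dict[tuple[str, int], str] = {}
    for g in all_up:
        for t in range(T):
            direction[(g, t)] = "up"
    for g in all_down:
        for t in range(T):
            direction[(g, t)] = "down"
    for a, b, _k in pair_units:
        for t in assignment[a]:
            d = "up" if rng.random() < 0.5 else "down"
            direction[(a, t)] = d
            direction[(b, t)] = d
    for i, (a, b, _k) in enumerate(pair_units):
        if i >= n_concordant_pairs:  # make discordant: flip one timepoint
            t_flip = assignment[a][int(rng.integers(len(assignment[a])))]
            direction[(b, t_flip)] = (
                "down" if direction[(a, t_flip)] == "up" else "up"
            )
    for g, _k in unpaired_multi:
        for t in assignment[g]:
            direction[(g, t)] = "up" if rng.random() < 0.5 else "down"
    for g in single_genes:
        for t in assignment[g]:
            direction[(g, t)] = "up" if rng.random() < 0.5 else "down"

    deg_cells = set(direction)

    rows = []
    for g in genes:
        for t in range(T):
            if (g, t) in deg_cells:
                sign = 1.0 if direction[(g, t)] == "up" else -1.0
                lfc = sign * rng.uniform(1.5, 4.0)
                padj = rng.uniform(1e-6, 0.04)
            elif rng.random() < 0.5:
                lfc = rng.uniform(-0.9, 0.9)
                padj = rng.uniform(0.0, 1.0)
            else:
                lfc = rng.uniform(-3.0, 3.0)
                padj = rng.uniform(0.08, 1.0)
            rows.append((g, timepoints[t], lfc, padj))
    table = pd.DataFrame(
        rows, columns=["gene_id", "timepoint", "log2fc", "padj"]
    )

    truth_counts = pd.Series(
        per_tp, index=list(timepoints), name="n_degs"
    )
    pair_rows = [
        (a, b, i < n_concordant_pairs)
        for i, (a, b, _k) in enumerate(pair_units)
    ]
    deg_truth = pd.DataFrame(
        [
            (g, timepoints[t], direction[(g, t)])
            for (g, t) in sorted(deg_cells)
        ],
        columns=["gene_id", "timepoint", "deg"],
    )
    truth = {
        "per_timepoint": truth_counts,
        "any": {g for g, _t in deg_cells},
        "min2": set(multi_genes) | set(all_up) | set(all_down),
        "all_up": set(all_up),
        "all_down": set(all_down),
        "pairs": pd.DataFrame(
            pair_rows, columns=["gene_a", "gene_b", "concordant"]
        ),
        "deg_cells": deg_truth,
    }
    return table, truth


# --------------------------------------------------------------------------
# gene order with planted tandem pairs
# --------------------------------------------------------------------------

def make_duplicate_fixture(
    n_genes: int = 60,
    n_chromosomes: int = 3,
    n_tandem: int = 5,
    n_nontandem: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-order table plus duplicate pairs with known tandem status.

    Tandem pairs are adjacent in gene rank on one chromosome; nontandem
    pairs are either separated by at least three intervening genes or on
    different chromosomes.  Returns ``(gene_order, pairs)`` with a true
    ``mode`` column in ``pairs``.
    """
    rng = np.random.default_rng(seed)
    per_chrom = n_genes // n_chromosomes
    if per_chrom < 8:
        raise ValueError("need at least 8 genes per chromosome")
    rows = []
    gid = 0
    for c in range(n_chromosomes):
        pos = 1
        for _ in range(per_chrom):
            gid += 1
            length = int(rng.integers(500, 5000))
            rows.append(
                (f"G{gid:04d}", f"chr{c + 1}", pos, pos + length,
                 "+" if rng.random() < 0.5 else "-")
            )
            pos += length + int(rng.integers(200, 2000))
    order = pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand"]
    )

    by_chrom = {
        c: order[order["chromosome"] == c]["gene_id"].tolist()
        for c in order["chromosome"].unique()
    }
    chroms = list(by_chrom)
    pair_rows = []
    used: set[str] = set()
    for i in range(n_tandem):
        c = chroms[i % len(chroms)]
        genes = [g for g in by_chrom[c] if g not in used]
        for j in range(len(genes) - 1):
            a, b = genes[j], genes[j + 1]
            if by_chrom[c].index(b) - by_chrom[c].index(a) == 1:
                pair_rows.append((a, b, "tandem"))
                used.update((a, b))
                break
        else:
            raise ValueError("could not place tandem pair")
    for i in range(n_nontandem):
        if i % 2 == 0 and len(chroms) > 1:  # cross-chromosome
            a_pool = [g for g in by_chrom[chroms[0]] if g not in used]
            b_pool = [g for g in by_chrom[chroms[1]] if g not in used]
            a, b = a_pool[0], b_pool[0]
        else:  # same chromosome, >= 3 genes apart
            c = chroms[i % len(chroms)]
            free = [g for g in by_chrom[c] if g not in used]
            cand = [
                (a, b) for a in free for b in free
                if by_chrom[c].index(b) - by_chrom[c].index(a) >= 4
            ]
            if not cand:
                raise ValueError("could not place nontandem pair")
            a, b = cand[0]
        pair_rows.append((a, b, "nontandem"))
        used.update((a, b))
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "mode"])
    return order, pairs
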