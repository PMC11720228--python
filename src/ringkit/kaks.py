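"""Nei-Gojobori (1986) Ka/Ks estimation for codon-aligned CDS pairs.

Synonymous (S) and nonsynonymous (N) site counts are computed per codon as
the fraction of the three possible single-nucleotide changes at each
position that are synonymous; changes to stop codons are excluded from the
denominator, so S + N = 3 for every sense codon.  For codons differing at
several positions, the synonymous/nonsynonymous difference counts are
averaged over all orderings of the single-step mutational pathways, with
pathways passing through a stop codon excluded (if every pathway is
blocked, the average falls back to all pathways).  Proportions
ps = Sd/S and pn = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).

The ratio ka/ks < 1 is read as purifying selection, > 1 as positive
selection; ks = 0 with ka > 0 yields an infinite ratio (positive), and a
fully identical pair is "undefined".  Sites are averaged over the two
sequences; codons containing an ambiguous base, a gap, or a stop in either
sequence are skipped pairwise and reported.

This is the equal-weight NG86 counting method; model-averaged estimators
(as produced by KaKs_Calculator and maximum-likelihood tools) will give
different values on the same pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .seqio import CdsRecord

__all__ = [
    "KaKsResult",
    "count_sites",
    "pathway_diffs",
    "kaks_pair",
    "classify_selection",
]

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_STOPS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}
_AA = {c: _TABLE.forward_table.get(c, "*") for c in _CODONS}


def count_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Per position, the synonymous fraction is the share of non-stop
    single-base changes that preserve the amino acid; the two fractions
    sum to 3 over the codon.  Stop codons raise ``ValueError``.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = _AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt in _STOPS:
                continue
            n_valid += 1
            if _AA[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def pathway_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    Averages the per-step synonymous/nonsynonymous classification over all
    orderings of the differing positions, skipping orderings whose
    intermediate codons are stops.  Both codons must be sense codons.
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    for c in (codon1, codon2):
        if c in _STOPS or any(b not in _BASES for b in c):
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = codon1
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                return None
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    valid = [r for r in map(walk, permutations(diff_positions)) if r is not None]
    if not valid:
        # all pathways blocked by stops: average over all orderings,
        # classifying each step by amino-acid change
        valid = []
        for order in permutations(diff_positions):
            sd = nd = 0.0
            cur = codon1
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
                if _AA[cur] == _AA[nxt] and nxt not in _STOPS and cur not in _STOPS:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((sd, nd))
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


# --- lazily built lookup tables for fast pair scoring ------------------------

_SITE_TAB: np.ndarray | None = None      # (64, 2) S,N per codon; NaN for stops
_DIFF_TAB: np.ndarray | None = None      # (64, 64, 2) Sd,Nd per codon pair


def _tables() -> tuple[np.ndarray, np.ndarray]:
    global _SITE_TAB, _DIFF_TAB
    if _SITE_TAB is None:
        site = np.full((64, 2), np.nan)
        for i, c in enumerate(_CODONS):
            if c not in _STOPS:
                site[i] = count_sites(c)
        diff = np.full((64, 64, 2), np.nan)
        for i, c1 in enumerate(_CODONS):
            if c1 in _STOPS:
                continue
            for j, c2 in enumerate(_CODONS):
                if c2 in _STOPS:
                    continue
                diff[i, j] = pathway_diffs(c1, c2)
        _SITE_TAB, _DIFF_TAB = site, diff
    return _SITE_TAB, _DIFF_TAB


def _codon_indices(seq: str) -> np.ndarray:
    """Codon index array; -1 marks codons with non-ACGT characters."""
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(out)):
        codon = seq[3 * k : 3 * k + 3]
        out[k] = _CODON_INDEX.get(codon, -1)
    return out


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one codon-aligned pair."""

    pair_id: str
    n_codons: int          # codons compared (after skipping)
    n_skipped: int         # codons dropped (ambiguity, gap or stop)
    syn_sites: float       # S
    nonsyn_sites: float    # N
    syn_diffs: float       # Sd
    nonsyn_diffs: float    # Nd
    ps: float
    pn: float
    ks: float
    ka: float
    ratio: float           # ka/ks; inf when ks=0<ka; nan when both 0
    selection: str         # purifying | neutral | positive | undefined


def _jukes_cantor(p: float, label: str) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        raise ValueError(
            f"{label} proportion {p:.4f} >= 3/4: Jukes-Cantor saturation"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_pair(
    cds1: CdsRecord | str, cds2: CdsRecord | str, pair_id: str | None = None
) -> KaKsResult:
    """Ka, Ks and selection class for one codon-aligned CDS pair.

    Sequences must be equal length and a multiple of 3; gaps (``-``) and
    ambiguous bases cause pairwise codon skipping.
    """
    s1 = cds1.sequence if isinstance(cds1, CdsRecord) else str(cds1).upper()
    s2 = cds2.sequence if isinstance(cds2, CdsRecord) else str(cds2).upper()
    if pair_id is None:
        id1 = cds1.id if isinstance(cds1, CdsRecord) else "seq1"
        id2 = cds2.id if isinstance(cds2, CdsRecord) else "seq2"
        pair_id = f"{id1}|{id2}"
    if len(s1) != len(s2):
        raise ValueError(f"{pair_id}: unequal lengths {len(s1)} vs {len(s2)}")
    if len(s1) % 3 != 0:
        raise ValueError(f"{pair_id}: length {len(s1)} not divisible by 3")

    site, diff = _tables()
    idx1 = _codon_indices(s1)
    idx2 = _codon_indices(s2)
    stop_idx = np.array([_CODON_INDEX[c] for c in _STOPS])
    ok = (idx1 >= 0) & (idx2 >= 0)
    ok &= ~np.isin(idx1, stop_idx) & ~np.isin(idx2, stop_idx)
    n_skipped = int((~ok).sum())
    i1, i2 = idx1[ok], idx2[ok]
    n_codons = int(len(i1))

    if n_codons == 0:
        raise ValueError(f"{pair_id}: no comparable codons")

    # sites averaged over the two sequences
    s_total = float((site[i1, 0].sum() + site[i2, 0].sum()) / 2.0)
    n_total = float((site[i1, 1].sum() + site[i2, 1].sum()) / 2.0)
    sd = float(diff[i1, i2, 0].sum())
    nd = float(diff[i1, i2, 1].sum())

    ps = sd / s_total if s_total > 0 else 0.0
    pn = nd / n_total if n_total > 0 else 0.0
    ks = _jukes_cantor(ps, f"{pair_id}: synonymous")
    ka = _jukes_cantor(pn, f"{pair_id}: nonsynonymous")

    if ks > 0:
        ratio = ka / ks
    elif ka > 0:
        ratio = math.inf
    else:
        ratio = math.nan

    if math.isnan(ratio):
        selection = "undefined"
    elif abs(ratio - 1.0) <= 1e-12:
        selection = "neutral"
    elif ratio < 1.0:
        selection = "purifying"
    else:
        selection = "positive"

    return KaKsResult(
        pair_id=pair_id, n_codons=n_codons, n_skipped=n_skipped,
        syn_sites=s_total, nonsyn_sites=n_total, syn_diffs=sd,
        nonsyn_diffs=nd, ps=ps, pn=pn, ks=ks, ka=ka,
        ratio=ratio, selection=selection,
    )


def classify_selection(results: Iterable[KaKsResult]) -> pd.DataFrame:
    """Counts and fractions of selection classes over a result set."""
    results = list(results)
    classes = ["purifying", "neutral", "positive", "undefined"]
    counts = {c: 0 for c in classes}
    for r in results:
        counts[r.selection] += 1
    total = len(results)
    return pd.DataFrame(
        {
            "selection": classes,
            "count": [counts[c] for c in classes],
            "fraction": [counts[c] / total if total else 0.0 for c in classes],
        }
    )


def results_to_frame(results: Iterable[KaKsResult]) -> pd.DataFrame:
    rows = [
        (r.pair_id, r.n_codons, r.n_skipped, r.syn_sites, r.nonsyn_sites,
         r.syn_diffs, r.nonsyn_diffs, r.ka, r.ks, r.ratio, r.selection)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["pair_id", "n_codons", "n_skipped", "S", "N", "Sd", "Nd",
                 "ka", "ks", "ratio", "selection"],
    )
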