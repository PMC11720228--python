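"""Independent reference implementations used only by the test suite.

These deliberately avoid the production code paths: the domain oracle
enumerates candidate position tuples from per-slot residue lists, and the
BH oracle is a literal transcription of the step-up procedure.
"""

from __future__ import annotations

import numpy as np


def brute_force_matches(seq: str, grammar) -> set[tuple[str, tuple[int, ...]]]:
    """All (type, 1-based ml 8-tuple) matches by exhaustive tuple search.

    For each type, every strictly increasing 8-tuple drawn from the
    per-slot allowed-residue position lists is tested against the gap
    constraints (tuples whose next gap already exceeds the slot maximum
    are abandoned, which discards only tuples that cannot match).
    """
    seq = seq.upper()
    found: set[tuple[str, tuple[int, ...]]] = set()
    for spec in grammar:
        cands = [
            [i for i, aa in enumerate(seq) if aa in spec.residues[k]]
            for k in range(8)
        ]
        if any(not c for c in cands):
            continue
        gap_max = [max(g) for g in spec.gaps]

        def extend(slot: int, tup: tuple[int, ...]) -> None:
            if slot == 8:
                found.add((spec.name, tuple(p + 1 for p in tup)))
                return
            prev = tup[-1]
            for j in cands[slot]:
                if j <= prev:
                    continue
                gap = j - prev - 1
                if gap > gap_max[slot - 1]:
                    break
                if gap in spec.gaps[slot - 1]:
                    extend(slot + 1, tup + (j,))

        for start in cands[0]:
            extend(1, (start,))
    return found


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg by the textbook recipe: sort, scale by n/i,
    cumulative minimum from the largest rank, cap at 1."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
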