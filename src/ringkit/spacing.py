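"""Spacer-length distributions between metal-ligand pairs.

Profiles how many residues separate consecutive ml residues across a set
of detected RING domains, per type and overall.  The short spacers
(ml1-ml2, ml3-ml4, ml5-ml6) are structurally pinned by the cross-brace
zinc coordination; the ml2-ml3 and ml6-ml7 loops are the variable ones.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .grammar import RingDomainHit

__all__ = ["spacing_profile", "modal_spacing"]

#: stratum label aggregating all types
ALL = "ALL"


def spacing_profile(hits: Iterable[RingDomainHit]) -> pd.DataFrame:
    """Count spacer lengths per (type, gap index) stratum and overall.

    Returns a long-format table with columns ``type`` (a type name or
    ``"ALL"``), ``gap_index`` (1-7), ``spacer_length``, ``count`` and
    ``fraction``.  Fractions are relative to the number of hits in the
    stratum, so they sum to 1 within each (type, gap_index).
    """
    hits = list(hits)
    cols = ["type", "gap_index", "spacer_length", "count", "fraction"]
    if not hits:
        return pd.DataFrame(columns=cols)
    rows = []
    for h in hits:
        for gi, length in enumerate(h.spacers, 1):
            rows.append((h.type_name, gi, length))
            rows.append((ALL, gi, length))
    df = pd.DataFrame(rows, columns=["type", "gap_index", "spacer_length"])
    out = (
        df.groupby(["type", "gap_index", "spacer_length"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = out.groupby(["type", "gap_index"])["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out.sort_values(
        ["type", "gap_index", "spacer_length"], ignore_index=True
    )


def modal_spacing(
    table: pd.DataFrame, type_name: str, gap_index: int
) -> tuple[int, int]:
    """Most frequent spacer length in a stratum, with its count.

    Ties are broken toward the smaller length (deterministic convention).
    Raises ``ValueError`` on an empty stratum.
    """
    stratum = table[
        (table["type"] == type_name) & (table["gap_index"] == gap_index)
    ]
    if stratum.empty:
        raise ValueError(
            f"empty stratum (type={type_name!r}, gap_index={gap_index})"
        )
    best = stratum.sort_values(
        ["count", "spacer_length"], ascending=[False, True]
    ).iloc[0]
    return int(best["spacer_length"]), int(best["count"])
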