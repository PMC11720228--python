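"""Duplicate-pair classification and salt-stress expression logic.

Covers: tandem-vs-nontandem calling for duplicate gene pairs by adjacency
in chromosomal gene rank; Benjamini-Hochberg adjustment; differential
expression calling at an inclusive |log2FC| >= 1, adjusted p <= 0.05
cutoff; multi-time-point DEG set construction; direction concordance of
duplicated pairs; and the Livak 2^-ddCt transform for qPCR.

The expression table convention is long format: one row per
(gene_id, timepoint) with ``log2fc`` and ``padj`` columns.  Time points
default to 1, 3, 12 and 48 h of salt treatment.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "classify_tandem",
    "bh_adjust",
    "call_degs",
    "multi_timepoint_sets",
    "pair_concordance",
    "livak",
]

DEFAULT_TIMEPOINTS: tuple[int, ...] = (1, 3, 12, 48)


def _gene_ranks(gene_order: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chromosome", "start"}
    missing = required - set(gene_order.columns)
    if missing:
        raise ValueError(f"gene order table missing columns {sorted(missing)}")
    order = gene_order.sort_values(["chromosome", "start"], kind="stable").copy()
    order["rank"] = order.groupby("chromosome").cumcount()
    return order.set_index("gene_id")


def classify_tandem(
    pairs: pd.DataFrame, gene_order: pd.DataFrame, max_gap: int = 0
) -> pd.DataFrame:
    """Label duplicate pairs as ``tandem`` or ``nontandem``.

    A pair is tandem when both genes sit on the same chromosome and their
    gene ranks differ by at most ``max_gap + 1`` (default: adjacent).
    All other pairs are nontandem (segmental-duplication candidates; true
    segmental assignment needs collinearity blocks supplied externally).
    A gene absent from the order table raises ``KeyError`` naming it.
    """
    ranks = _gene_ranks(gene_order)
    out = pairs.copy()
    modes = []
    for a, b in zip(out["gene_a"], out["gene_b"]):
        if a == b:
            raise ValueError(f"self pair {a!r}")
        for g in (a, b):
            if g not in ranks.index:
                raise KeyError(f"gene {g!r} missing from gene order table")
        ra, rb = ranks.loc[a], ranks.loc[b]
        same_chrom = ra["chromosome"] == rb["chromosome"]
        close = abs(int(ra["rank"]) - int(rb["rank"])) <= max_gap + 1
        modes.append("tandem" if same_chrom and close else "nontandem")
    out["mode"] = modes
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    records: pd.DataFrame, lfc: float = 1.0, padj: float = 0.05
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Flag differentially expressed gene/time-point records.

    A record is ``up`` when log2fc >= lfc and padj <= the cutoff, ``down``
    when log2fc <= -lfc and padj <= the cutoff (thresholds inclusive),
    else ``none``.  Records with missing log2fc or padj are dropped and
    counted.  Returns ``(flagged records, per-timepoint DEG counts,
    n_excluded)``.
    """
    required = {"gene_id", "timepoint", "log2fc", "padj"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    df = records.copy()
    bad = df["log2fc"].isna() | df["padj"].isna()
    n_excluded = int(bad.sum())
    df = df[~bad].copy()
    sig = df["padj"] <= padj
    df["deg"] = np.select(
        [sig & (df["log2fc"] >= lfc), sig & (df["log2fc"] <= -lfc)],
        ["up", "down"],
        default="none",
    )
    is_deg = df["deg"] != "none"
    counts = (
        df[is_deg].groupby("timepoint")["gene_id"].nunique()
        .reindex(sorted(df["timepoint"].unique()), fill_value=0)
    )
    counts.name = "n_degs"
    return df, counts, n_excluded


def multi_timepoint_sets(
    records: pd.DataFrame,
    timepoints: Sequence | None = None,
    min_timepoints: int = 2,
) -> dict[str, set]:
    """DEG membership sets across time points.

    Returns sets keyed ``"any"`` (DE at >= 1 time point), ``"min_k"``
    (DE at >= ``min_timepoints`` time points, in either direction),
    ``"all_up"`` and ``"all_down"`` (the same direction at every
    configured time point; mixed-direction genes belong to neither).
    """
    if "deg" not in records.columns:
        raise ValueError("records need a 'deg' column (run call_degs first)")
    if timepoints is None:
        timepoints = sorted(records["timepoint"].unique())
    timepoints = list(timepoints)
    df = records[records["timepoint"].isin(timepoints)]
    de = df[df["deg"] != "none"]
    per_gene = de.groupby("gene_id")["timepoint"].nunique()
    any_set = set(per_gene.index)
    min_k = set(per_gene[per_gene >= min_timepoints].index)

    n_t = len(timepoints)
    updf = df[df["deg"] == "up"].groupby("gene_id")["timepoint"].nunique()
    downdf = df[df["deg"] == "down"].groupby("gene_id")["timepoint"].nunique()
    all_up = set(updf[updf == n_t].index)
    all_down = set(downdf[downdf == n_t].index)
    return {"any": any_set, "min_k": min_k, "all_up": all_up,
            "all_down": all_down}


def pair_concordance(
    pairs: pd.DataFrame, records: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Direction concordance of duplicated pairs across time points.

    A pair is ``discordant`` when at some time point both genes are DEGs
    with opposite directions; ``concordant`` when the directions match at
    every shared DEG time point and at least one such time point exists;
    ``untested`` when the genes are never DEGs at the same time point
    (vacuously concordant).  Pairs with a gene absent from the expression
    table are skipped and returned separately.
    """
    if "deg" not in records.columns:
        raise ValueError("records need a 'deg' column (run call_degs first)")
    deg_map: dict[tuple[str, object], str] = {
        (r.gene_id, r.timepoint): r.deg
        for r in records.itertuples(index=False)
        if r.deg != "none"
    }
    present = set(records["gene_id"])
    timepoints = sorted(records["timepoint"].unique())

    rows = []
    skipped: list[tuple[str, str]] = []
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        if a not in present or b not in present:
            skipped.append((a, b))
            continue
        shared = 0
        discord = False
        for t in timepoints:
            da, db = deg_map.get((a, t)), deg_map.get((b, t))
            if da is not None and db is not None:
                shared += 1
                if da != db:
                    discord = True
        if discord:
            status = "discordant"
        elif shared > 0:
            status = "concordant"
        else:
            status = "untested"
        rows.append((a, b, shared, status))
    result = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "shared_deg_timepoints", "status"]
    )
    return result, skipped


def livak(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control).
    """
    for v in (ct_target_treated, ct_ref_treated,
              ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct))
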