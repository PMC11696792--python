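"""Scalar quantifications: qPCR isoform fractions and AP-MS partner filtering.

Isoform abundance relative to a total-transcript amplicon is the standard
2^-ΔCt, with ΔCt = Ct(isoform amplicon) - Ct(total amplicon) in the same
sample.  Partner specificity from a tandem-affinity-purification LFQ table
follows the detection rules: a protein is a specific partner when it is
detected (LFQ intensity > 0) in at least 2 of 3 bait replicates, in none
of the control replicates, and is supported by at least 2 razor/unique
peptides.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "isoform_fraction",
    "isoform_fractions_table",
    "proportion_shares",
    "partner_filter",
]


def isoform_fraction(ct_isoform: float, ct_total: float) -> float:
    """Fraction of total transcript for one isoform amplicon: 2^-(ΔCt).

    ΔCt = Ct(isoform) - Ct(total), both measured in the same sample;
    replicate Cts should be averaged before calling.
    """
    if ct_isoform is None or ct_total is None or np.isnan(ct_isoform) or np.isnan(ct_total):
        raise ValueError("missing Ct value")
    if ct_isoform <= 0 or ct_total <= 0:
        raise ValueError("Ct values must be positive")
    return float(2.0 ** -(ct_isoform - ct_total))


def isoform_fractions_table(ct_table: pd.DataFrame, total_target: str = "total") -> pd.DataFrame:
    """Per-sample isoform fractions from a long Ct table (sample,target,ct).

    Replicate rows (same sample and target) are averaged by mean Ct before
    the ΔCt; the ``total_target`` row of each sample is the reference.
    """
    required = {"sample", "target", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    agg = ct_table.groupby(["sample", "target"], sort=True)["ct"].mean().reset_index()
    rows = []
    for sample, g in agg.groupby("sample"):
        ref = g.loc[g["target"] == total_target, "ct"]
        if ref.empty:
            raise ValueError(f"sample {sample!r}: no {total_target!r} amplicon")
        ct_tot = float(ref.iloc[0])
        for _, r in g[g["target"] != total_target].iterrows():
            rows.append(
                {
                    "sample": sample,
                    "target": r["target"],
                    "delta_ct": r["ct"] - ct_tot,
                    "fraction": isoform_fraction(float(r["ct"]), ct_tot),
                }
            )
    return pd.DataFrame(rows)


def proportion_shares(fractions: pd.Series | dict) -> pd.Series:
    """Renormalise per-amplicon fractions to shares summing to 1.

    Overlapping amplicons do not partition the transcript pool, so raw
    2^-ΔCt fractions need not sum to 1; this helper produces the
    "respective abundance"-style proportions.
    """
    s = pd.Series(fractions, dtype=float)
    total = s.sum()
    if total <= 0:
        raise ValueError("fractions must sum to a positive value")
    return s / total


def partner_filter(
    table: pd.DataFrame,
    min_reps: int = 2,
    min_peptides: int = 2,
    bait_cols: Sequence[str] | None = None,
    ctrl_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Specific partners from an LFQ intensity table.

    Keeps proteins detected (intensity > 0) in at least ``min_reps`` bait
    replicates, not detected in any control replicate, and supported by at
    least ``min_peptides`` razor/unique peptides.  Output is sorted by mean
    bait LFQ intensity, descending.  Bait/control replicate columns default
    to those named ``bait_*`` / ``ctrl_*``.
    """
    if bait_cols is None:
        bait_cols = [c for c in table.columns if c.startswith("bait_")]
    if ctrl_cols is None:
        ctrl_cols = [c for c in table.columns if c.startswith("ctrl_")]
    if not bait_cols or not ctrl_cols:
        raise ValueError("missing bait/control replicate columns")
    if "protein_id" not in table.columns or "peptides" not in table.columns:
        raise ValueError("table needs protein_id and peptides columns")

    bait = table[list(bait_cols)].to_numpy(float)
    ctrl = table[list(ctrl_cols)].to_numpy(float)
    detected_bait = (bait > 0).sum(axis=1)
    detected_ctrl = (ctrl > 0).sum(axis=1)
    keep = (
        (detected_bait >= min_reps)
        & (detected_ctrl == 0)
        & (table["peptides"].to_numpy(int) >= min_peptides)
    )
    out = table.loc[keep].copy()
    out["n_bait_detected"] = detected_bait[keep]
    out["mean_bait_lfq"] = np.where(
        detected_bait[keep] > 0,
        bait[keep].sum(axis=1) / np.maximum(detected_bait[keep], 1),
        0.0,
    )
    return out.sort_values(
        ["mean_bait_lfq", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
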