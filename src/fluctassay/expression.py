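"""Relative expression by the ddCq (delta-delta quantification cycle) method.

For each biological replicate, the target amplicon's Cq is referenced to a
second amplicon measured from the same cDNA (dCq = Cq_target - Cq_ref,
technical replicates averaged on the Cq scale first), then to a calibrator
condition:

    fold change = 2 ** -(dCq_sample - dCq_calibrator)

Base 2 assumes 100% amplification efficiency per cycle; no efficiency
(Pfaffl) correction is applied. Biological replicates are summarised on the
fold scale (mean and sd of per-replicate fold changes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CQ_COLUMNS",
    "delta_cq",
    "ddcq_fold_change",
    "delta_cq_table",
    "fold_change_table",
]

CQ_COLUMNS = [
    "sample_id",
    "role",
    "biological_rep",
    "technical_rep",
    "cq_target",
    "cq_reference",
]


def delta_cq(cq_target, cq_reference) -> float:
    """dCq = mean(Cq_target) - mean(Cq_reference).

    Scalars or arrays of technical replicates are accepted; technical
    replicates are averaged on the Cq scale before subtraction.
    """
    t = np.asarray(cq_target, dtype=float)
    r = np.asarray(cq_reference, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("Cq values must be finite")
    return float(t.mean() - r.mean())


def ddcq_fold_change(dcq_sample: float, dcq_calibrator: float) -> float:
    """Fold change 2^-(ddCq) of a sample relative to the calibrator."""
    if not (np.isfinite(dcq_sample) and np.isfinite(dcq_calibrator)):
        raise ValueError("dCq values must be finite")
    return float(2.0 ** -(dcq_sample - dcq_calibrator))


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if not np.all(np.isfinite(table[["cq_target", "cq_reference"]].to_numpy(float))):
        raise ValueError("Cq values must be finite")


def delta_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, biological replicate) dCq from a CqMeasurement table."""
    _check_table(table)
    grouped = (
        table.groupby(["sample_id", "role", "biological_rep"], sort=True)[
            ["cq_target", "cq_reference"]
        ]
        .mean()
        .reset_index()
    )
    grouped["dcq"] = grouped["cq_target"] - grouped["cq_reference"]
    return grouped


def fold_change_table(table: pd.DataFrame, calibrator: str | None = None) -> pd.DataFrame:
    """Per-sample fold changes relative to the calibrator condition.

    The calibrator is the set of rows with ``role == "calibrator"`` (or the
    rows of ``sample_id == calibrator`` if given); its dCq is averaged over
    biological replicates on the Cq scale. Every other sample gets one fold
    change per biological replicate plus a mean/sd summary row.

    Returns a frame with columns ``sample_id, biological_rep, fold`` and the
    per-sample aggregate columns ``mean_fold, sd_fold`` merged on.
    """
    dcq = delta_cq_table(table)
    if calibrator is None:
        cal = dcq.loc[dcq["role"] == "calibrator"]
    else:
        cal = dcq.loc[dcq["sample_id"] == calibrator]
    if cal.empty:
        raise ValueError("no calibrator rows found")
    dcq_cal = float(cal["dcq"].mean())
    samples = dcq.loc[~dcq.index.isin(cal.index)].copy()
    if samples.empty:
        raise ValueError("no sample rows found")
    samples["fold"] = [
        ddcq_fold_change(d, dcq_cal) for d in samples["dcq"].to_numpy(float)
    ]
    agg = (
        samples.groupby("sample_id")["fold"]
        .agg(mean_fold="mean", sd_fold="std")
        .reset_index()
    )
    return samples.merge(agg, on="sample_id")[
        ["sample_id", "biological_rep", "dcq", "fold", "mean_fold", "sd_fold"]
    ]
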