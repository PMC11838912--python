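"""Selection coefficients from two-marker competition assays.

Per-generation selection coefficient of a focal strain against a reference:

    s = ln( R(t) / R(0) ) / t,    R = focal / reference event counts

with fluorophore-swap correction: the fitness cost of the fluorescent
markers enters s with opposite sign in the two marker orientations, so the
mean over a balanced swap design cancels it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionObservation",
    "FitnessSummary",
    "COMPETITION_COLUMNS",
    "selection_coefficient",
    "generations_elapsed",
    "swap_corrected_fitness",
]

COMPETITION_COLUMNS = [
    "replicate_id",
    "marker_orientation",
    "counts_focal_t0",
    "counts_ref_t0",
    "counts_focal_t",
    "counts_ref_t",
    "generations",
]

ORIENTATIONS = ("focal_gfp", "focal_scarlet")


@dataclass
class CompetitionObservation:
    """Event counts for one competition replicate at two time points."""

    counts_focal_t0: float
    counts_ref_t0: float
    counts_focal_t: float
    counts_ref_t: float
    generations: float
    marker_orientation: str = "focal_gfp"
    replicate_id: str = "rep1"

    def validate(self) -> None:
        counts = (
            self.counts_focal_t0,
            self.counts_ref_t0,
            self.counts_focal_t,
            self.counts_ref_t,
        )
        if any(c < 0 for c in counts):
            raise ValueError("event counts must be nonnegative")
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.marker_orientation not in ORIENTATIONS:
            raise ValueError(f"unknown marker orientation {self.marker_orientation!r}")


@dataclass
class FitnessSummary:
    """Swap-corrected selection-coefficient summary across replicates."""

    mean_s: float
    sd_s: float
    orientation_means: dict
    per_replicate: pd.DataFrame
    n_used: int
    n_excluded: int
    single_orientation: bool


def selection_coefficient(obs: CompetitionObservation) -> float:
    """Per-generation selection coefficient of one competition replicate.

    Returns NaN (the "flagged undefined" sentinel) when any of the four
    counts is zero — at sampling depths of >= 20,000 events a zero count is
    diagnostic of assay failure, so such replicates are excluded rather than
    pseudocounted.
    """
    obs.validate()
    counts = (
        obs.counts_focal_t0,
        obs.counts_ref_t0,
        obs.counts_focal_t,
        obs.counts_ref_t,
    )
    if any(c == 0 for c in counts):
        return math.nan
    r0 = obs.counts_focal_t0 / obs.counts_ref_t0
    rt = obs.counts_focal_t / obs.counts_ref_t
    return math.log(rt / r0) / obs.generations


def generations_elapsed(n_initial: float, n_final: float) -> float:
    """Generations of growth between two population sizes, log2(Nf/N0)."""
    if n_initial <= 0 or n_final <= 0:
        raise ValueError("population sizes must be positive")
    if n_final < n_initial:
        raise ValueError("n_final must be >= n_initial")
    return math.log2(n_final / n_initial)


def swap_corrected_fitness(
    observations: list[CompetitionObservation],
) -> FitnessSummary:
    """Mean selection coefficient with fluorophore-swap correction.

    Computes s per replicate first, then averages across replicates pooled
    over the two marker orientations (the marker cost cancels in
    expectation under a balanced design). Replicates with a zero count are
    excluded with a flag; a single-orientation input is averaged uncorrected
    with a warning.
    """
    if not observations:
        raise ValueError("no observations")
    rows = []
    for obs in observations:
        rows.append(
            {
                "replicate_id": obs.replicate_id,
                "marker_orientation": obs.marker_orientation,
                "s": selection_coefficient(obs),
            }
        )
    per_rep = pd.DataFrame(rows)
    per_rep["excluded"] = per_rep["s"].isna()
    used = per_rep.loc[~per_rep["excluded"]]
    if used.empty:
        raise ValueError("all replicates excluded (zero counts)")
    orientations = sorted(used["marker_orientation"].unique())
    single = len(orientations) < 2
    if single:
        warnings.warn(
            "only one marker orientation present; mean is not corrected for "
            "fluorophore cost",
            stacklevel=2,
        )
    orientation_means = {
        o: float(used.loc[used["marker_orientation"] == o, "s"].mean())
        for o in orientations
    }
    s_values = used["s"].to_numpy(dtype=float)
    return FitnessSummary(
        mean_s=float(s_values.mean()),
        sd_s=float(s_values.std(ddof=1)) if len(s_values) > 1 else math.nan,
        orientation_means=orientation_means,
        per_replicate=per_rep,
        n_used=int(len(used)),
        n_excluded=int(per_rep["excluded"].sum()),
        single_orientation=single,
    )


def observations_from_frame(table: pd.DataFrame) -> list[CompetitionObservation]:
    """Build observations from a table in the competition CSV schema."""
    missing = [c for c in COMPETITION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return [
        CompetitionObservation(
            counts_focal_t0=row.counts_focal_t0,
            counts_ref_t0=row.counts_ref_t0,
            counts_focal_t=row.counts_focal_t,
            counts_ref_t=row.counts_ref_t,
            generations=row.generations,
            marker_orientation=row.marker_orientation,
            replicate_id=str(row.replicate_id),
        )
        for row in table.itertuples(index=False)
    ]


def observations_to_frame(observations: list[CompetitionObservation]) -> pd.DataFrame:
    """Tabulate observations in the competition CSV schema."""
    return pd.DataFrame(
        [
            {
                "replicate_id": o.replicate_id,
                "marker_orientation": o.marker_orientation,
                "counts_focal_t0": o.counts_focal_t0,
                "counts_ref_t0": o.counts_ref_t0,
                "counts_focal_t": o.counts_focal_t,
                "counts_ref_t": o.counts_ref_t,
                "generations": o.generations,
            }
            for o in observations
        ],
        columns=COMPETITION_COLUMNS,
    )
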