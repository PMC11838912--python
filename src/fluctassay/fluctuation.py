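"""Mutation-rate estimation from fluctuation assays by MSS maximum likelihood.

Implements the Ma-Sandri-Sarkar (MSS) recursion for the Luria-Delbrück
mutant-count distribution, maximum-likelihood estimation of ``m`` (the
expected number of mutation events per culture), Stewart and
profile-likelihood confidence intervals, sequencing-confirmation correction
of candidate colony counts, plating-fraction handling, and conversion of
``m`` to a mutation rate per base pair per replication.

The mutant-count model is the classical Lea-Coulson one: mutations arise at
random during exponential growth of a culture from ``N0`` to ``Nt`` cells,
each founding a neutrally expanding clone, which produces the heavy-tailed
("jackpot") distribution whose pmf the MSS recursion computes exactly:

    p_0 = exp(-m)
    p_k = (m/k) * sum_{i=0}^{k-1} p_i / (k - i + 1)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

__all__ = [
    "FluctuationDataset",
    "MutationRateEstimate",
    "CorrectedCounts",
    "FLUCTUATION_COLUMNS",
    "DEFAULT_K_CAP",
    "mss_pmf",
    "mss_log_likelihood",
    "estimate_m",
    "confidence_interval",
    "correct_candidate_counts",
    "apply_plating_fraction",
    "mutation_rate",
    "fold_difference",
    "mutant_frequency",
]

#: Columns of the tabular fluctuation-assay schema (one row per culture).
FLUCTUATION_COLUMNS = [
    "culture_id",
    "genotype",
    "n_initial",
    "n_final",
    "plated_fraction_selective",
    "candidate_colonies",
    "n_sequenced",
    "n_confirmed_target",
    "n_confirmed_other",
]

#: Hard ceiling on the pmf recursion; observed counts above it are pooled
#: into a tail class so jackpot cultures cannot make the O(k^2) recursion
#: intractable.
DEFAULT_K_CAP = 5000

# Stewart's large-sample coefficients for the sd of ln(m_hat) from a single
# culture; scaled by 1/sqrt(C) for C parallel cultures.
_STEWART_COEF = 1.225
_STEWART_EXP = -0.315


@dataclass
class FluctuationDataset:
    """Per-culture fluctuation-assay data for one genotype.

    ``table`` holds one row per culture with columns ``FLUCTUATION_COLUMNS``.
    ``ground_truth`` optionally records the generating parameters when the
    dataset is simulated.
    """

    genotype: str
    table: pd.DataFrame
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    def validate(self) -> None:
        """Raise ``ValueError`` on any schema-invariant violation."""
        t = self.table
        missing = [c for c in FLUCTUATION_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(t) == 0:
            raise ValueError("dataset has no cultures")
        if (t["n_final"] <= 0).any():
            raise ValueError("n_final must be positive for every culture")
        eps = t["plated_fraction_selective"]
        if ((eps <= 0) | (eps > 1)).any():
            raise ValueError("plated_fraction_selective must lie in (0, 1]")
        confirmed = t["n_confirmed_target"] + t["n_confirmed_other"]
        if (confirmed > t["n_sequenced"]).any():
            raise ValueError("confirmed colonies exceed sequenced colonies")
        nonzero = t["candidate_colonies"] > 0
        if (t.loc[nonzero, "n_sequenced"] > t.loc[nonzero, "candidate_colonies"]).any():
            raise ValueError("n_sequenced exceeds candidate_colonies")
        if (t["candidate_colonies"] < 0).any():
            raise ValueError("negative candidate colony count")

    @property
    def counts(self) -> np.ndarray:
        """Raw candidate colony counts, one per culture."""
        return self.table["candidate_colonies"].to_numpy(dtype=np.int64)

    @property
    def n_cultures(self) -> int:
        return len(self.table)


@dataclass
class MutationRateEstimate:
    """Result of the fluctuation-assay estimation chain.

    ``m_hat`` is on the per-culture event scale; ``mu_hat`` on the per-site
    per-replication scale. CI bounds accompany each scale; ``boundary`` flags
    an all-zero dataset whose MLE sits on the m = 0 boundary.
    """

    m_hat: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    mu_hat: float = math.nan
    mu_ci_low: float = math.nan
    mu_ci_high: float = math.nan
    ci_method: str = ""
    n_cultures: int = 0
    mean_frequency: float = math.nan
    boundary: bool = False
    denominator_mode: str = ""
    genotype: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CorrectedCounts:
    """Candidate counts scaled by the sequencing-confirmed mutant fraction."""

    counts: np.ndarray
    fraction_pooled: float
    fractions: np.ndarray
    fallback: np.ndarray  # True where per-culture mode fell back to pooled
    mode: str


def _check_m(m: float) -> float:
    m = float(m)
    if not math.isfinite(m) or m < 0:
        raise ValueError(f"m must be a finite nonnegative number, got {m}")
    return m


def mss_pmf(m: float, k_max: int) -> np.ndarray:
    """Exact Luria-Delbrück mutant-count pmf ``p_0 .. p_{k_max}``.

    Evaluates the MSS recursion for expected mutation number ``m`` per
    culture under the Lea-Coulson model (neutral clone expansion, whole
    culture plated).
    """
    m = _check_m(m)
    k_max = int(k_max)
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m)
    if m == 0.0 or k_max == 0:
        return p
    # inv[j-1] = 1/(j+1): weight of the clone-size-j term in the recursion
    inv = 1.0 / np.arange(2.0, k_max + 2.0)
    for k in range(1, k_max + 1):
        p[k] = (m / k) * np.dot(p[k - 1 :: -1], inv[:k])
    return p


def _as_counts(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("counts must contain at least one culture")
    if not np.issubdtype(c.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    return np.asarray(np.rint(c), dtype=np.int64)


def _resolve_k_cap(counts: np.ndarray, k_cap: int | None) -> int:
    if k_cap is None:
        k_cap = min(int(counts.max(initial=0)), DEFAULT_K_CAP)
    return max(int(k_cap), 0)


def mss_log_likelihood(
    m: float,
    counts: Sequence[int] | np.ndarray,
    k_cap: int | None = None,
) -> float:
    """Log-likelihood of ``m`` given per-culture mutant counts.

    Counts above ``k_cap`` (default: the maximum observed count, hard-capped
    at ``DEFAULT_K_CAP``) are pooled into a tail class of probability
    ``1 - sum_{k <= k_cap} p_k``, which keeps the likelihood proper in the
    presence of jackpot cultures.
    """
    m = _check_m(m)
    counts = _as_counts(counts)
    if m == 0.0:
        return 0.0 if counts.max(initial=0) == 0 else -math.inf
    k_cap = _resolve_k_cap(counts, k_cap)
    p = mss_pmf(m, k_cap)
    ll = 0.0
    in_body = counts <= k_cap
    body = counts[in_body]
    if body.size:
        pk = p[body]
        if np.any(pk <= 0.0):
            return -math.inf
        ll += float(np.log(pk).sum())
    n_tail = int((~in_body).sum())
    if n_tail:
        tail = max(1.0 - float(p.sum()), 0.0)
        if tail <= 0.0:
            return -math.inf
        ll += n_tail * math.log(tail)
    return ll


# Coarse log-spaced grid bracketing the MLE before Brent refinement; the
# likelihood is unimodal in m so a one-bracket refinement suffices.
_M_GRID = np.concatenate(([0.0], np.logspace(-4, math.log10(500.0), 60)))


def estimate_m(
    counts: Sequence[int] | np.ndarray,
    k_cap: int | None = None,
    tol: float = 1e-7,
) -> MutationRateEstimate:
    """Maximum-likelihood estimate of ``m`` from per-culture mutant counts.

    Maximizes :func:`mss_log_likelihood` over ``m >= 0`` by a coarse grid
    scan followed by bounded Brent refinement (absolute tolerance ``tol`` on
    m). An all-zero dataset returns ``m_hat = 0`` with ``boundary=True``.
    """
    counts = _as_counts(counts)
    n = counts.size
    if counts.max(initial=0) == 0:
        return MutationRateEstimate(m_hat=0.0, boundary=True, n_cultures=n)
    k_cap = _resolve_k_cap(counts, k_cap)
    if counts.min() > k_cap:
        # every culture in the pooled tail: the likelihood carries no
        # information below the cap and the MLE diverges
        raise ValueError(
            "all counts exceed k_cap; increase k_cap or check the plating "
            "fraction (counts this large are outside the estimator's regime)"
        )

    lls = np.array([mss_log_likelihood(g, counts, k_cap) for g in _M_GRID])
    i = int(np.nanargmax(lls))
    lo = _M_GRID[max(i - 1, 0)] if i > 0 else 1e-9
    hi = _M_GRID[min(i + 1, len(_M_GRID) - 1)]
    if i == len(_M_GRID) - 1:  # expand upward until the likelihood turns over
        hi = _M_GRID[-1]
        while mss_log_likelihood(hi * 2, counts, k_cap) > mss_log_likelihood(
            hi, counts, k_cap
        ):
            hi *= 2
        hi *= 2
    res = optimize.minimize_scalar(
        lambda mm: -mss_log_likelihood(mm, counts, k_cap),
        bounds=(max(lo, 1e-12), hi),
        method="bounded",
        options={"xatol": tol},
    )
    return MutationRateEstimate(m_hat=float(res.x), boundary=False, n_cultures=n)


def confidence_interval(
    m_hat: float,
    counts: Sequence[int] | np.ndarray,
    method: str = "stewart",
    level: float = 0.95,
    k_cap: int | None = None,
) -> tuple[float, float]:
    """Confidence interval for ``m`` at the given level.

    ``stewart``: normal interval on ln(m) using Stewart's large-sample
    standard deviation ``1.225 * m^-0.315 / sqrt(C)`` for ``C`` cultures,
    exponentiated back (the interval FALCOR-style MSS-MLE analyses report).

    ``profile_likelihood``: the set of ``m`` whose log-likelihood lies within
    ``chi2_{1,level}/2`` of the maximum.

    At the ``m_hat = 0`` boundary both methods return the degenerate interval
    ``(0, upper)`` where the upper bound comes from the likelihood drop-off
    of the all-zero data (``exp(-C m)``).
    """
    counts = _as_counts(counts)
    n = counts.size
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    delta = chi2.ppf(level, 1) / 2.0
    if m_hat <= 0.0:
        return (0.0, delta / n)
    if method == "stewart":
        z = norm.ppf(0.5 + level / 2.0)
        sigma = _STEWART_COEF * m_hat**_STEWART_EXP / math.sqrt(n)
        return (m_hat * math.exp(-z * sigma), m_hat * math.exp(z * sigma))
    if method == "profile_likelihood":
        k_cap = _resolve_k_cap(counts, k_cap)
        ll_max = mss_log_likelihood(m_hat, counts, k_cap)
        cutoff = ll_max - delta

        def drop(mm: float) -> float:
            return mss_log_likelihood(mm, counts, k_cap) - cutoff

        lo_b = m_hat
        while drop(lo_b) > 0 and lo_b > 1e-12:
            lo_b /= 4.0
        low = 0.0 if lo_b <= 1e-12 else optimize.brentq(drop, lo_b, m_hat, xtol=1e-10)
        hi_b = m_hat * 2.0
        while drop(hi_b) > 0:
            hi_b *= 2.0
        high = optimize.brentq(drop, m_hat, hi_b, xtol=1e-10)
        return (float(low), float(high))
    raise ValueError(f"unknown CI method {method!r}")


def correct_candidate_counts(
    candidates: Sequence[int] | np.ndarray | int,
    n_confirmed_target: Sequence[int] | np.ndarray | int,
    n_sequenced: Sequence[int] | np.ndarray | int,
    mode: str = "pooled",
) -> CorrectedCounts:
    """Scale candidate colony counts by the sequencing-confirmed fraction.

    The fraction of sequenced colonies confirmed to carry the target mutation
    multiplies each culture's candidate count; ``pooled`` computes one
    fraction over the whole genotype, ``per_culture`` uses each culture's own
    fraction and falls back to the pooled one (with a flag) where no colonies
    were sequenced. Corrected counts are rounded to the nearest integer,
    ties half up, since the likelihood takes integer counts.
    """
    cand = np.atleast_1d(np.asarray(candidates, dtype=float))
    conf = np.atleast_1d(np.asarray(n_confirmed_target, dtype=float))
    seq = np.atleast_1d(np.asarray(n_sequenced, dtype=float))
    if np.any(cand < 0):
        raise ValueError("candidate counts must be nonnegative")
    if np.any(conf > seq):
        raise ValueError("confirmed count exceeds sequenced count")
    if mode not in ("pooled", "per_culture"):
        raise ValueError(f"unknown correction mode {mode!r}")
    seq_total = seq.sum()
    pooled = float(conf.sum() / seq_total) if seq_total > 0 else 1.0
    if mode == "pooled":
        fractions = np.full_like(cand, pooled)
        fallback = np.zeros(cand.shape, dtype=bool)
    else:
        fallback = seq == 0
        if fallback.any():
            warnings.warn(
                "per-culture correction fell back to the pooled fraction for "
                f"{int(fallback.sum())} culture(s) with no sequenced colonies",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            fractions = np.where(fallback, pooled, conf / np.where(seq == 0, 1, seq))
    corrected = np.floor(cand * fractions + 0.5).astype(np.int64)
    return CorrectedCounts(
        counts=corrected,
        fraction_pooled=pooled,
        fractions=fractions,
        fallback=fallback,
        mode=mode,
    )


def apply_plating_fraction(m_observed: float, epsilon: float) -> float:
    """Rescale a plate-level ``m`` to the whole culture.

    Uses the expected-count scaling ``m_whole = m_observed / epsilon``. This
    is a documented approximation: partial plating strictly changes the shape
    of the count law, not only its mean, so the linear rule carries a bias
    that grows as epsilon shrinks.
    """
    if not 0 < epsilon <= 1:
        raise ValueError("plating fraction must lie in (0, 1]")
    if m_observed < 0:
        raise ValueError("m_observed must be nonnegative")
    return m_observed / epsilon


def mutation_rate(
    m_hat: float,
    population_size: float,
    denominator_mode: str = "final_n",
    n_initial: float = 0.0,
) -> float:
    """Convert ``m`` to a rate per site per replication.

    ``final_n`` divides by the final population size ``Nt`` (the default;
    the number of replications in a culture grown from a tiny inoculum is
    Nt - N0 ~ Nt); ``net_growth`` divides by ``Nt - N0`` exactly.
    """
    if population_size <= 0:
        raise ValueError("population size must be positive")
    if denominator_mode == "final_n":
        denom = population_size
    elif denominator_mode == "net_growth":
        denom = population_size - n_initial
        if denom <= 0:
            raise ValueError("net growth Nt - N0 must be positive")
    else:
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    return m_hat / denom


def fold_difference(rate_a: float, rate_b: float, rounding: str | None = None) -> float:
    """Ratio ``rate_a / rate_b`` with an optional display rounding mode.

    ``rounding`` may be ``None`` (exact ratio), ``"nearest_ten"`` or
    ``"one_sig_fig"`` — the modes used when reporting fold differences such
    as "~60-fold".
    """
    if rate_b == 0:
        raise ZeroDivisionError("reference rate is zero")
    ratio = rate_a / rate_b
    if rounding is None:
        return ratio
    if rounding == "nearest_ten":
        return float(round(ratio / 10.0) * 10.0)
    if rounding == "one_sig_fig":
        if ratio == 0:
            return 0.0
        exp = math.floor(math.log10(abs(ratio)))
        return float(round(ratio / 10**exp) * 10**exp)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def mutant_frequency(
    dataset: FluctuationDataset,
    correction_mode: str = "pooled",
) -> tuple[np.ndarray, float, float]:
    """Mutant frequency (mutants per cell) per culture and its mean.

    Candidate counts are confirmation-corrected, scaled to the whole culture
    by the per-culture plated fraction, and divided by the final population
    size. Returns ``(per_culture, mean, reciprocal)`` where ``reciprocal``
    is the "one in N cells" report of the mean.
    """
    t = dataset.table
    corrected = correct_candidate_counts(
        t["candidate_colonies"],
        t["n_confirmed_target"],
        t["n_sequenced"],
        mode=correction_mode,
    )
    eps = t["plated_fraction_selective"].to_numpy(dtype=float)
    n_final = t["n_final"].to_numpy(dtype=float)
    per_culture = corrected.counts / eps / n_final
    mean = float(per_culture.mean())
    reciprocal = math.inf if mean == 0 else 1.0 / mean
    return per_culture, mean, reciprocal
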