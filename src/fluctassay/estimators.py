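"""Estimator classes (scikit-learn style) over the analysis stages.

Each stage of the analysis — mutation-rate estimation from fluctuation
data, competition fitness, relative expression — is exposed as a
``fit``-shaped estimator with ``get_params``/``set_params`` so it composes
with sklearn model-selection tooling; the underlying numerics live in the
corresponding function modules.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import fluctuation as fc
from .expression import fold_change_table
from .fitness import observations_from_frame, swap_corrected_fitness

__all__ = ["MutationRateMLE", "CompetitionFitness", "RelativeExpression"]


class MutationRateMLE(BaseEstimator):
    """MSS maximum-likelihood mutation-rate estimator for fluctuation data.

    Chains sequencing-confirmation correction of candidate colony counts,
    MSS maximum-likelihood estimation of the expected mutation number m per
    culture, a confidence interval, plating-fraction rescaling, and
    conversion to a rate per site per replication.

    Parameters
    ----------
    ci_method : {"stewart", "profile_likelihood"}
        Confidence-interval construction; Stewart's large-sample interval
        on ln m is the default (the interval FALCOR-style analyses report).
    level : float
        Confidence level.
    denominator_mode : {"final_n", "net_growth"}
        Population-size denominator converting m to a rate: the mean final
        population size Nt across cultures, or the mean net growth Nt - N0.
    correction_mode : {"pooled", "per_culture"}
        How the confirmed-mutant fraction is computed (pooled over the
        genotype by default: eight sequenced colonies per culture are too
        few for stable per-culture fractions).
    k_cap : int or None
        Cap of the pmf recursion; counts beyond it pool into a tail class.
        None means the maximum observed count (hard-capped internally).

    Attributes
    ----------
    m_plate_ : float
        MLE of m on the plated-sample scale.
    m_ : float
        m rescaled to the whole culture by the mean plated fraction.
    ci_low_, ci_high_ : float
        Confidence interval for whole-culture m.
    mu_ : float
        Mutation rate per site per replication.
    mu_ci_low_, mu_ci_high_ : float
        CI for the rate (same division as the point estimate).
    mean_frequency_, frequency_reciprocal_ : float
        Mean mutant frequency (mutants per cell) and its "one in N" form.
    boundary_ : bool
        True when all corrected counts were zero (MLE on the m=0 boundary).
    """

    def __init__(
        self,
        ci_method: str = "stewart",
        level: float = 0.95,
        denominator_mode: str = "final_n",
        correction_mode: str = "pooled",
        k_cap: int | None = None,
    ):
        self.ci_method = ci_method
        self.level = level
        self.denominator_mode = denominator_mode
        self.correction_mode = correction_mode
        self.k_cap = k_cap

    def _as_dataset(self, X) -> fc.FluctuationDataset:
        if isinstance(X, fc.FluctuationDataset):
            return X
        if isinstance(X, pd.DataFrame):
            genotype = str(X["genotype"].iloc[0]) if "genotype" in X else ""
            return fc.FluctuationDataset(genotype=genotype, table=X)
        raise TypeError("X must be a FluctuationDataset or a DataFrame")

    def fit(self, X, y=None):
        """Run the estimation chain on a fluctuation dataset."""
        ds = self._as_dataset(X)
        ds.validate()
        t = ds.table
        corrected = fc.correct_candidate_counts(
            t["candidate_colonies"],
            t["n_confirmed_target"],
            t["n_sequenced"],
            mode=self.correction_mode,
        )
        self.corrected_counts_ = corrected.counts
        self.confirmation_fraction_ = corrected.fraction_pooled

        est = fc.estimate_m(corrected.counts, k_cap=self.k_cap)
        ci = fc.confidence_interval(
            est.m_hat,
            corrected.counts,
            method=self.ci_method,
            level=self.level,
            k_cap=self.k_cap,
        )
        self.m_plate_ = est.m_hat
        self.boundary_ = est.boundary
        self.n_cultures_ = est.n_cultures

        # single scalar plated fraction for the m rescaling (schema allows
        # per-culture epsilon; the mean is used and recorded)
        self.epsilon_ = float(t["plated_fraction_selective"].mean())
        self.m_ = fc.apply_plating_fraction(self.m_plate_, self.epsilon_)
        self.ci_low_ = fc.apply_plating_fraction(ci[0], self.epsilon_)
        self.ci_high_ = fc.apply_plating_fraction(ci[1], self.epsilon_)

        n_final_mean = float(t["n_final"].mean())
        n_initial_mean = float(t["n_initial"].mean())
        self.denominator_ = (
            n_final_mean
            if self.denominator_mode == "final_n"
            else n_final_mean - n_initial_mean
        )
        self.mu_ = fc.mutation_rate(
            self.m_, n_final_mean, self.denominator_mode, n_initial_mean
        )
        self.mu_ci_low_ = fc.mutation_rate(
            self.ci_low_, n_final_mean, self.denominator_mode, n_initial_mean
        )
        self.mu_ci_high_ = fc.mutation_rate(
            self.ci_high_, n_final_mean, self.denominator_mode, n_initial_mean
        )

        _, self.mean_frequency_, self.frequency_reciprocal_ = fc.mutant_frequency(
            ds, correction_mode=self.correction_mode
        )
        self.genotype_ = ds.genotype
        return self

    def estimate_(self) -> fc.MutationRateEstimate:
        """Fitted results packed as a :class:`MutationRateEstimate`."""
        self._check_fitted()
        return fc.MutationRateEstimate(
            m_hat=self.m_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            mu_hat=self.mu_,
            mu_ci_low=self.mu_ci_low_,
            mu_ci_high=self.mu_ci_high_,
            ci_method=self.ci_method,
            n_cultures=self.n_cultures_,
            mean_frequency=self.mean_frequency_,
            boundary=self.boundary_,
            denominator_mode=self.denominator_mode,
            genotype=self.genotype_,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "m_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def summary(self) -> dict:
        """Fitted quantities and the method flags that produced them."""
        est = self.estimate_().to_dict()
        est.update(
            {
                "m_plate": self.m_plate_,
                "plated_fraction": self.epsilon_,
                "confirmation_fraction": self.confirmation_fraction_,
                "correction_mode": self.correction_mode,
                "frequency_reciprocal": self.frequency_reciprocal_,
            }
        )
        return est


class CompetitionFitness(BaseEstimator):
    """Swap-corrected selection-coefficient estimator for competition data.

    Fits on a table in the competition CSV schema (or a list of
    ``CompetitionObservation``); computes s per replicate, excludes
    zero-count replicates with a flag, and averages across the two marker
    orientations so the fluorophore cost cancels.

    Attributes
    ----------
    s_ : float
        Swap-corrected mean selection coefficient per generation.
    s_sd_ : float
        Standard deviation of per-replicate s.
    orientation_means_ : dict
        Mean s per marker orientation (diagnostic of the marker cost).
    """

    def fit(self, X, y=None):
        obs = observations_from_frame(X) if isinstance(X, pd.DataFrame) else list(X)
        summary = swap_corrected_fitness(obs)
        self.s_ = summary.mean_s
        self.s_sd_ = summary.sd_s
        self.orientation_means_ = summary.orientation_means
        self.per_replicate_ = summary.per_replicate
        self.n_used_ = summary.n_used
        self.n_excluded_ = summary.n_excluded
        self.single_orientation_ = summary.single_orientation
        return self


class RelativeExpression(BaseEstimator):
    """ddCq relative-expression estimator for Cq tables.

    Parameters
    ----------
    calibrator : str or None
        ``sample_id`` of the calibrator condition; None selects rows with
        ``role == "calibrator"``.

    Attributes
    ----------
    fold_changes_ : pandas.DataFrame
        Per-(sample, biological replicate) fold changes with per-sample
        mean and sd columns.
    summary_ : pandas.DataFrame
        One row per sample: mean and sd of the fold change.
    """

    def __init__(self, calibrator: str | None = None):
        self.calibrator = calibrator

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame in the Cq schema")
        folds = fold_change_table(X, calibrator=self.calibrator)
        self.fold_changes_ = folds
        self.summary_ = (
            folds[["sample_id", "mean_fold", "sd_fold"]]
            .drop_duplicates("sample_id")
            .reset_index(drop=True)
        )
        return self
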