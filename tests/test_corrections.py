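"""Count correction, plating-fraction handling, rates, folds, frequencies."""

import math

import numpy as np
import pandas as pd
import pytest

from fluctassay.fluctuation import (
    FluctuationDataset,
    apply_plating_fraction,
    correct_candidate_counts,
    estimate_m,
    fold_difference,
    mutant_frequency,
    mutation_rate,
)
from fluctassay.simulate import simulate_fluctuation_experiment
from tests.conftest import neutral_params


class TestCorrectCandidateCounts:
    def test_simple_fraction(self):
        # 40 candidates, 5 of 8 sequenced confirmed -> 25
        out = correct_candidate_counts(40, 5, 8, mode="per_culture")
        assert out.counts[0] == 25

    def test_pooled_fraction_applies_to_every_culture(self):
        cand = np.array([40, 16, 0, 8])
        conf = np.array([5, 5, 0, 5])
        seq = np.array([8, 8, 0, 8])
        out = correct_candidate_counts(cand, conf, seq, mode="pooled")
        assert out.fraction_pooled == pytest.approx(15 / 24)
        assert list(out.counts) == [25, 10, 0, 5]

    def test_zero_candidates_stay_zero(self):
        out = correct_candidate_counts(0, 0, 0)
        assert out.counts[0] == 0

    def test_per_culture_falls_back_to_pooled_with_warning(self):
        with pytest.warns(UserWarning, match="pooled"):
            out = correct_candidate_counts(
                [40, 40], [5, 0], [8, 0], mode="per_culture"
            )
        assert out.fallback.tolist() == [False, True]
        assert out.counts[1] == 25  # pooled fraction 5/8

    def test_rounding_half_up(self):
        # 5 * 0.5 = 2.5 rounds to 3
        out = correct_candidate_counts([5], [1], [2], mode="per_culture")
        assert out.counts[0] == 3

    def test_confirmed_exceeding_sequenced_rejected(self):
        with pytest.raises(ValueError):
            correct_candidate_counts(10, 9, 8)


class TestPlatingFraction:
    def test_identity_and_linear_scaling(self):
        assert apply_plating_fraction(1.3, 1.0) == 1.3
        assert apply_plating_fraction(1.0, 0.5) == 2.0

    @pytest.mark.parametrize("eps", [0.0, -0.1, 1.5])
    def test_rejects_invalid_fraction(self, eps):
        with pytest.raises(ValueError):
            apply_plating_fraction(1.0, eps)

    def test_thinning_bias_is_upward_and_bounded(self):
        # Partial plating distorts the count law, so the linear 1/eps
        # rescaling is an approximation. At eps=0.1, m=2 it overestimates:
        # thinning removes small clones, deflating the zero class relative
        # to a genuine MSS law at eps*m. Document direction and magnitude.
        full = simulate_fluctuation_experiment(neutral_params(2.0), 2000, seed=11)
        p_thin = neutral_params(2.0)
        p_thin.plating_fraction_selective = 0.1
        thin = simulate_fluctuation_experiment(p_thin, 2000, seed=11)
        m_full = estimate_m(full.counts).m_hat
        m_corr = apply_plating_fraction(estimate_m(thin.counts).m_hat, 0.1)
        assert m_corr > m_full
        assert m_corr / m_full < 4.0


class TestMutationRate:
    def test_final_n_denominator(self):
        assert mutation_rate(1.0, 1e7, "final_n") == pytest.approx(1e-7)

    def test_net_growth_denominator(self):
        assert mutation_rate(1.0, 1e7, "net_growth", n_initial=5e6) == pytest.approx(2e-7)

    def test_denominator_linearity(self):
        # multiplying Nt by c divides the rate by c
        mu1 = mutation_rate(2.5, 1e8)
        mu2 = mutation_rate(2.5, 3e8)
        assert mu1 / mu2 == pytest.approx(3.0)

    def test_rejects_nonpositive_population(self):
        with pytest.raises(ValueError):
            mutation_rate(1.0, 0.0)


class TestFoldDifference:
    def test_printed_rate_comparison_rounds_to_sixty(self):
        assert fold_difference(4.2e-7, 7.2e-9) == pytest.approx(58.33, abs=0.01)
        assert fold_difference(4.2e-7, 7.2e-9, "nearest_ten") == 60.0

    def test_comparison_against_genomic_average(self):
        assert fold_difference(4.2e-7, 7.4e-11) == pytest.approx(5675.7, abs=0.1)

    def test_equal_rates(self):
        assert fold_difference(3e-9, 3e-9) == 1.0

    def test_one_sig_fig(self):
        assert fold_difference(58.33, 1.0, "one_sig_fig") == 60.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_difference(1.0, 0.0)


class TestMutantFrequency:
    def test_fully_confirmed_counts(self):
        table = pd.DataFrame(
            {
                "culture_id": ["c1"],
                "genotype": ["g"],
                "n_initial": [100],
                "n_final": [1_000_000],
                "plated_fraction_selective": [1.0],
                "candidate_colonies": [10],
                "n_sequenced": [8],
                "n_confirmed_target": [8],
                "n_confirmed_other": [0],
            }
        )
        ds = FluctuationDataset(genotype="g", table=table)
        per, mean, recip = mutant_frequency(ds)
        assert per[0] == pytest.approx(1e-5)
        assert mean == pytest.approx(1e-5)
        assert recip == pytest.approx(1e5)

    def test_zero_mutants_everywhere(self):
        table = pd.DataFrame(
            {
                "culture_id": ["c1", "c2"],
                "genotype": ["g", "g"],
                "n_initial": [100, 100],
                "n_final": [1e6, 1e6],
                "plated_fraction_selective": [1.0, 1.0],
                "candidate_colonies": [0, 0],
                "n_sequenced": [0, 0],
                "n_confirmed_target": [0, 0],
                "n_confirmed_other": [0, 0],
            }
        )
        per, mean, recip = mutant_frequency(FluctuationDataset("g", table))
        assert mean == 0.0
        assert math.isinf(recip)
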