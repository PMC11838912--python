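"""Synthetic-data generator: invariants, determinism, oracle consistency."""

import math

import numpy as np
import pandas as pd
import pytest

from fluctassay.expression import fold_change_table
from fluctassay.fitness import selection_coefficient, swap_corrected_fitness
from fluctassay.fluctuation import estimate_m
from fluctassay.simulate import (
    LDSimParams,
    simulate_competition,
    simulate_competition_replicates,
    simulate_cq,
    simulate_culture,
    simulate_fluctuation_experiment,
)
from tests.conftest import neutral_params


class TestSimulateCulture:
    def test_mu_zero_never_mutates(self):
        params = neutral_params(2.0)
        params.mu = 0.0
        for seed in range(25):
            real = simulate_culture(params, seed)
            assert real.true_mutation_events == 0
            assert real.mutant_cells_final == 0
            assert real.candidate_colonies == 0

    def test_realization_invariants(self):
        params = neutral_params(3.0)
        params.plating_fraction_selective = 0.3
        for seed in range(50):
            real = simulate_culture(params, seed)
            assert real.candidate_colonies <= real.mutant_cells_final
            # neutral clones never go extinct: every event leaves >= 1 cell
            assert (real.mutant_cells_final == 0) == (real.true_mutation_events == 0)
            assert real.mutant_cells_final >= real.true_mutation_events

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            simulate_culture(LDSimParams(n_initial=10, n_final=5), 0)
        with pytest.raises(ValueError):
            simulate_culture(LDSimParams(mutant_fitness=0.0), 0)

    def test_zero_class_matches_closed_form(self):
        # P(no mutant) = exp(-m), m = mu * (Nf - N0)
        params = neutral_params(1.0)
        n = 3000
        zeros = sum(
            simulate_culture(params, np.random.default_rng([5, i])).candidate_colonies
            == 0
            for i in range(n)
        )
        p0 = math.exp(-1.0)
        se = math.sqrt(p0 * (1 - p0) / n)
        assert abs(zeros / n - p0) < 4 * se

    def test_expected_candidates_monotone_in_mu_w_eps(self):
        def mean_candidates(mu_scale=1.0, w=1.0, eps=1.0):
            params = neutral_params(2.0)
            params.mu *= mu_scale
            params.mutant_fitness = w
            params.plating_fraction_selective = eps
            return np.mean(
                [
                    simulate_culture(params, np.random.default_rng([9, i])).candidate_colonies
                    for i in range(400)
                ]
            )

        base = mean_candidates()
        assert mean_candidates(mu_scale=3.0) > base
        assert mean_candidates(w=1.3) > base
        assert mean_candidates(eps=0.2) < base

    def test_induction_window_reduces_mutation_supply(self):
        # inducing late in growth shrinks m = mu * (Nf - N_ind) and with it
        # the expected mutant count
        late = neutral_params(2.0)
        late.induction_generation = 18.0
        assert late.expected_mutations < neutral_params(2.0).expected_mutations
        zeros = np.mean(
            [
                simulate_culture(late, np.random.default_rng([4, i])).candidate_colonies == 0
                for i in range(500)
            ]
        )
        assert zeros > math.exp(-2.0)  # more empty cultures than full induction


class TestSimulateExperiment:
    def test_mu_zero_dataset_all_zero(self):
        params = neutral_params(1.0)
        params.mu = 0.0
        ds = simulate_fluctuation_experiment(params, 12, seed=0)
        assert (ds.table["candidate_colonies"] == 0).all()

    def test_schema_round_trip_into_estimator(self, wt_like_dataset):
        wt_like_dataset.validate()
        est = estimate_m(wt_like_dataset.counts)
        assert est.n_cultures == 12

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_fluctuation_experiment(neutral_params(2.0), 10, seed=7)
        b = simulate_fluctuation_experiment(neutral_params(2.0), 10, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_growing_n_cultures_preserves_prefix(self):
        a = simulate_fluctuation_experiment(neutral_params(2.0), 6, seed=7)
        b = simulate_fluctuation_experiment(neutral_params(2.0), 12, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table.iloc[:6])

    def test_ground_truth_sidecar_records_params(self):
        ds = simulate_fluctuation_experiment(neutral_params(0.5), 3, seed=1)
        assert ds.ground_truth["seed"] == 1
        assert ds.ground_truth["expected_mutations"] == pytest.approx(0.5)

    def test_sequencing_confirmations_respect_candidates(self):
        params = LDSimParams.wildtype_reporter()
        ds = simulate_fluctuation_experiment(params, 12, seed=2)
        t = ds.table
        assert (t["n_sequenced"] <= np.maximum(t["candidate_colonies"], 0)).all()
        assert (
            t["n_confirmed_target"] + t["n_confirmed_other"] <= t["n_sequenced"]
        ).all()


class TestSimulateCompetition:
    def test_no_selection_no_cost_exact(self):
        gfp, scarlet = simulate_competition(0.0, 10.0, depth=None)
        assert selection_coefficient(gfp) == pytest.approx(0.0, abs=1e-12)
        assert selection_coefficient(scarlet) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_limit_recovers_s(self):
        gfp, _ = simulate_competition(0.1, 10.0, depth=None, marker_cost=0.0)
        assert selection_coefficient(gfp) == pytest.approx(0.1, abs=1e-12)

    def test_marker_cost_has_opposite_sign_per_orientation(self):
        gfp, scarlet = simulate_competition(0.0, 20.0, depth=None, marker_cost=0.02)
        assert selection_coefficient(gfp) == pytest.approx(0.02, abs=1e-12)
        assert selection_coefficient(scarlet) == pytest.approx(-0.02, abs=1e-12)

    def test_swap_average_cancels_marker_cost(self):
        obs = simulate_competition_replicates(
            0.05, n_replicates=16, marker_cost=0.02, seed=5
        )
        summary = swap_corrected_fitness(obs)
        # binomial noise at depth 20000: se of s per replicate ~ 1e-3
        assert summary.mean_s == pytest.approx(0.05, abs=0.004)


class TestSimulateCq:
    def test_no_induction_no_noise_gives_unit_fold(self):
        tab = simulate_cq(1.0, noise_sd=0.0, n_replicates=3, seed=0)
        folds = fold_change_table(tab)
        assert folds["fold"].to_numpy() == pytest.approx(1.0)

    def test_sixteen_fold_exact_without_noise(self):
        tab = simulate_cq(16.0, noise_sd=0.0, n_replicates=3, seed=0)
        assert fold_change_table(tab)["mean_fold"].iloc[0] == pytest.approx(16.0)

    def test_noisy_recovery_within_twenty_percent(self):
        tab = simulate_cq(6.6, noise_sd=0.2, n_replicates=6, seed=8)
        assert fold_change_table(tab)["mean_fold"].iloc[0] == pytest.approx(6.6, rel=0.2)
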