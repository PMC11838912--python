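"""Synthetic data generators with known ground truth.

Emulates the three kinds of measurement the hotspot analysis consumes:

* fluctuation assays — parallel cultures grown from a small inoculum,
  plated on selective medium, candidate mutant colonies counted and a
  subset Sanger-sequenced to confirm the target mutation;
* pairwise competition assays — fluorophore-labelled strains competed and
  sampled by flow cytometry at two time points, with marker orientation
  swapped in half the replicates;
* RT-qPCR — target/reference quantification cycles for samples and a
  calibrator under the ddCq model.

The fluctuation generator realises the Lea-Coulson process: mutation
events are Poisson along the growth of the culture (in proportion to cells
produced), and each event founds a clone that expands deterministically for
the remainder of growth. With neutral mutants, full-growth mutation and the
whole culture plated, the resulting mutant-count law is exactly the MSS
distribution (up to O(N0/Nf) edge terms), which is what makes the simulator
usable as an independent oracle for the estimator and vice versa.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fluctuation import FLUCTUATION_COLUMNS, FluctuationDataset
from .fitness import CompetitionObservation

__all__ = [
    "LDSimParams",
    "CultureRealization",
    "simulate_culture",
    "simulate_fluctuation_experiment",
    "simulate_competition",
    "simulate_competition_replicates",
    "simulate_cq",
]

#: Confirmed-class mix observed when sequencing candidate colonies: the
#: target C565T mutation, the nearby A564G mutation, and colonies with no
#: mutation in the reporter (fractions 60/96, 6/96, 30/96).
DEFAULT_CONFIRM_PROBABILITY = {"C565T": 60 / 96, "A564G": 6 / 96}


@dataclass
class LDSimParams:
    """Ground-truth parameters of the fluctuation-assay generative process.

    Defaults emulate the wild-type reporter assay: ~1000 CFU/mL inoculated
    into a 6 mL microcosm (N0 = 6000 cells) grown through ~21 doublings to
    stationary phase (the final density is a configurable choice, not a
    reported value), with a per-replication mutation probability ``mu`` for
    the selectable phenotype as a whole and the sequenced-colony class mix
    above. ``mutant_fitness`` (w) bends mutant clone expansion away from
    neutrality; ``induction_generation`` delays the mutagenic process to
    model transcription induced late in growth.
    """

    n_initial: int = 6000
    n_final: int = 6000 * 2**21
    mu: float = 6.72e-7
    mutant_fitness: float = 1.0
    induction_generation: float = 0.0
    plating_fraction_selective: float = 1e-3
    plating_fraction_total: float = 1e-6
    confirm_probability: dict = field(
        default_factory=lambda: dict(DEFAULT_CONFIRM_PROBABILITY)
    )
    n_sequenced_per_culture: int = 8
    target_class: str = "C565T"

    @classmethod
    def wildtype_reporter(cls) -> "LDSimParams":
        """Wild-type reporter scenario: high hotspot rate, diluted plating.

        The phenotype-level mutation probability 6.72e-7 per cell per
        division splits over sequenced classes as 60/96 target (giving a
        target-mutation rate of 4.2e-7), 6/96 near-target; selective plating
        at 1e-3 of the culture corresponds to the 100-1000-fold dilution
        design.
        """
        return cls()

    @classmethod
    def psra_deletion(cls) -> "LDSimParams":
        """Transcription-activator-deletion scenario: ~60-fold lower rate.

        Target-mutation rate 7.2e-9 (phenotype-level 1.152e-8 with the same
        class mix); cultures are plated on selective medium without dilution
        (a 100 uL sample of a 6 mL microcosm, fraction 1/60).
        """
        return cls(mu=1.152e-8, plating_fraction_selective=1.0 / 60.0)

    def validate(self) -> None:
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if self.n_final <= self.n_initial:
            raise ValueError("n_final must exceed n_initial")
        if not 0 <= self.mu < 1:
            raise ValueError("mu must lie in [0, 1)")
        if self.mutant_fitness <= 0:
            raise ValueError("mutant fitness w must be positive")
        if not 0 < self.plating_fraction_selective <= 1:
            raise ValueError("plating_fraction_selective must lie in (0, 1]")
        if not 0 < self.plating_fraction_total <= 1:
            raise ValueError("plating_fraction_total must lie in (0, 1]")
        if self.induction_generation < 0:
            raise ValueError("induction_generation must be >= 0")
        if self.n_sequenced_per_culture < 0:
            raise ValueError("n_sequenced_per_culture must be >= 0")
        probs = np.array(list(self.confirm_probability.values()), dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or probs.sum() > 1 + 1e-12:
            raise ValueError("class probabilities must be in [0,1] and sum to <= 1")
        if self.target_class not in self.confirm_probability:
            raise ValueError("target_class missing from confirm_probability")

    @property
    def n_generations(self) -> int:
        """Number of doublings from N0 to Nf, rounded up."""
        return math.ceil(math.log2(self.n_final / self.n_initial))

    @property
    def expected_mutations(self) -> float:
        """Expected mutation events per culture, m = mu * (Nf - N_induced)."""
        return self.mu * max(self.n_final - self._n_at_induction(), 0.0)

    def _n_at_induction(self) -> float:
        return min(self.n_initial * 2.0**self.induction_generation, self.n_final)

    def to_json(self, path=None) -> str:
        """Serialise the ground truth as the sidecar JSON."""
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


@dataclass
class CultureRealization:
    """One simulated culture of the clonal-expansion process."""

    true_mutation_events: int
    mutant_cells_final: int
    n_final_realized: int
    candidate_colonies: int
    sequenced_confirmations: dict


def _rng_for_culture(seed: int, index: int) -> np.random.Generator:
    # Seeds derived by fixed arithmetic on (master seed, culture index), so
    # growing n_cultures never reshuffles earlier cultures.
    return np.random.default_rng([int(seed), int(index)])


def simulate_culture(
    params: LDSimParams,
    seed: int | np.random.Generator,
) -> CultureRealization:
    """Realise one culture of the Lea-Coulson clonal-expansion process.

    Mutation events are Poisson with mean ``mu * (Nf - N_ind)`` where
    ``N_ind`` is the population size at the induction generation; each event
    occurs at a population size drawn uniformly on (N_ind, Nf] (occurrence
    in proportion to cells produced) and founds a clone of final size
    ``floor((Nf/N_event)^w)``, never below one cell. Candidate colonies are
    a binomial thinning of the final mutant cells by the selective plating
    fraction; sequenced colonies classify multinomially by the per-class
    confirmation probabilities.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nf = float(params.n_final)
    n_ind = params._n_at_induction()
    w = params.mutant_fitness

    n_events = int(rng.poisson(params.mu * max(nf - n_ind, 0.0)))
    if n_events > 0:
        n_at_event = rng.uniform(n_ind, nf, size=n_events)
        clone_sizes = np.floor((nf / n_at_event) ** w)
        mutant_cells = int(np.maximum(clone_sizes, 1.0).sum())
    else:
        mutant_cells = 0

    candidates = int(rng.binomial(mutant_cells, params.plating_fraction_selective))

    n_seq = min(params.n_sequenced_per_culture, candidates)
    classes = list(params.confirm_probability)
    probs = np.array([params.confirm_probability[c] for c in classes], dtype=float)
    probs = np.append(probs, max(1.0 - probs.sum(), 0.0))
    draws = rng.multinomial(n_seq, probs / probs.sum())
    confirmations = dict(zip(classes, (int(d) for d in draws[:-1])))
    confirmations["unconfirmed"] = int(draws[-1])

    return CultureRealization(
        true_mutation_events=n_events,
        mutant_cells_final=mutant_cells,
        n_final_realized=params.n_final,
        candidate_colonies=candidates,
        sequenced_confirmations=confirmations,
    )


def simulate_fluctuation_experiment(
    params: LDSimParams,
    n_cultures: int,
    seed: int,
    genotype: str = "WT",
) -> FluctuationDataset:
    """Simulate a parallel-culture fluctuation assay as a tabular dataset.

    Returns a :class:`FluctuationDataset` in the schema the estimation chain
    consumes, with the generating parameters attached as ground truth.
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    params.validate()
    rows = []
    target = params.target_class
    for i in range(n_cultures):
        real = simulate_culture(params, _rng_for_culture(seed, i))
        conf = real.sequenced_confirmations
        n_seq = sum(conf.values())
        n_target = conf.get(target, 0)
        n_other = n_seq - n_target - conf.get("unconfirmed", 0)
        rows.append(
            {
                "culture_id": f"{genotype}_c{i + 1:03d}",
                "genotype": genotype,
                "n_initial": params.n_initial,
                "n_final": real.n_final_realized,
                "plated_fraction_selective": params.plating_fraction_selective,
                "candidate_colonies": real.candidate_colonies,
                "n_sequenced": n_seq,
                "n_confirmed_target": n_target,
                "n_confirmed_other": n_other,
            }
        )
    table = pd.DataFrame(rows, columns=FLUCTUATION_COLUMNS)
    truth = asdict(params)
    truth["seed"] = int(seed)
    truth["expected_mutations"] = params.expected_mutations
    return FluctuationDataset(genotype=genotype, table=table, ground_truth=truth)


def simulate_competition(
    s_true: float,
    generations: float,
    initial_ratio: float = 1.0,
    depth: int | None = 20_000,
    marker_cost: float = 0.0,
    seed: int | np.random.Generator = 0,
    replicate_id: str = "rep1",
) -> tuple[CompetitionObservation, CompetitionObservation]:
    """Simulate one marker-swapped pair of competition assays.

    The true focal/reference ratio evolves as ``R(t) = R(0) *
    exp((s_true ± marker_cost) * t)``, the sign of the marker cost following
    the fluorophore carried by the focal strain. Observed event counts are
    binomial samples of size ``depth`` from the implied proportions
    (independent samples at t0 and t); ``depth=None`` returns the exact
    expected counts (the no-noise limit).
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    if depth is not None and depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def one(orientation: str, cost_sign: float) -> CompetitionObservation:
        r0 = initial_ratio
        rt = r0 * math.exp((s_true + cost_sign * marker_cost) * generations)
        p0, pt = r0 / (1 + r0), rt / (1 + rt)
        if depth is None:
            f0, ft = p0, pt
            total = 1.0
        else:
            f0 = rng.binomial(depth, p0)
            ft = rng.binomial(depth, pt)
            total = depth
        return CompetitionObservation(
            counts_focal_t0=f0,
            counts_ref_t0=total - f0,
            counts_focal_t=ft,
            counts_ref_t=total - ft,
            generations=generations,
            marker_orientation=orientation,
            replicate_id=replicate_id,
        )

    return one("focal_gfp", +1.0), one("focal_scarlet", -1.0)


def simulate_competition_replicates(
    s_true: float,
    n_replicates: int,
    generations: float = 23.25,
    initial_ratio: float = 1.0,
    depth: int | None = 20_000,
    marker_cost: float = 0.0,
    seed: int = 0,
) -> list[CompetitionObservation]:
    """Simulate a replicated competition assay, half per marker orientation.

    ``n_replicates`` counts marker-swapped pairs; the returned list holds
    ``2 * n_replicates`` observations ready for swap-corrected averaging.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    obs: list[CompetitionObservation] = []
    for i in range(n_replicates):
        pair = simulate_competition(
            s_true,
            generations,
            initial_ratio=initial_ratio,
            depth=depth,
            marker_cost=marker_cost,
            seed=np.random.default_rng([int(seed), i]),
            replicate_id=f"rep{i + 1}",
        )
        obs.extend(pair)
    return obs


def simulate_cq(
    fold_change: float,
    base_cq: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 4,
    n_technical: int = 2,
    seed: int = 0,
    sample_id: str = "sample",
    calibrator_id: str = "calibrator",
) -> pd.DataFrame:
    """Simulate target/reference Cq values under the ddCq model.

    The sample's target amplicon starts ``log2(fold_change)`` cycles earlier
    than the calibrator's, so the expected ddCq is ``-log2(fold_change)``;
    independent Gaussian noise of sd ``noise_sd`` perturbs every Cq.
    Returns a table in the CqMeasurement schema (one row per technical
    replicate).
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if n_replicates < 1 or n_technical < 1:
        raise ValueError("replicate counts must be >= 1")
    rng = np.random.default_rng(seed)
    shift = -math.log2(fold_change)
    rows = []
    for role, sid, delta in (
        ("calibrator", calibrator_id, 0.0),
        ("sample", sample_id, shift),
    ):
        for b in range(1, n_replicates + 1):
            for t in range(1, n_technical + 1):
                rows.append(
                    {
                        "sample_id": sid,
                        "role": role,
                        "biological_rep": b,
                        "technical_rep": t,
                        "cq_target": base_cq + delta + rng.normal(0.0, noise_sd),
                        "cq_reference": base_cq + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
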