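# Methods

This note records the models, numerical choices and known limitations of
the package, in the order data flow through it.

## Generative model for fluctuation assays

`simulate_culture` realises the Lea–Coulson process for a culture growing
from N0 to Nf cells:

1. The number of mutation events is Poisson with mean
   `m = μ · (Nf − N_ind)`, where `N_ind = min(N0 · 2^g_ind, Nf)` is the
   population size at the induction generation `g_ind`
   (`induction_generation = 0` means the mutagenic process runs through the
   whole growth; a late value models transcription-coupled mutagenesis
   switched on only as the culture approaches stationary phase).
2. Each event occurs at a population size drawn uniformly on
   `(N_ind, Nf]` — mutation opportunity is proportional to cells produced —
   and founds a clone of final size `floor((Nf/N_event)^w)`, never below
   one cell, where `w` is the relative mutant fitness.
3. Candidate colonies are a binomial thinning of the final mutant cells by
   the selective plating fraction ε; sequenced colonies (default 8 per
   culture) classify multinomially by per-class confirmation
   probabilities.

**Why continuous founding sizes rather than synchronous doublings.** With
neutral mutants (w = 1) the clone-size law of step 2 is
`P(size = j) = 1/(j(j+1))` up to O(N0/Nf) edge terms — exactly the
clone-size law the MSS recursion encodes — so the simulated mutant-count
distribution *is* the MSS distribution and the simulator and estimator can
serve as independent oracles for each other (empirical total-variation
distance < 0.01 against `mss_pmf` at 10⁵ cultures, m ∈ {0.5, 2}). A
synchronous-doubling model, in which clones take only power-of-two sizes
with `P(2^j) = 2^−(j+1)`, cannot satisfy that equivalence: its count law
differs from the MSS pmf by TV ≈ 0.1–0.2 at m of order one. The
discrete-generation picture is retained only for locating the induction
window.

Mutant fitness `w ≠ 1` bends clone sizes deterministically
(`(Nf/N_event)^w`); stochastic lineage growth is deliberately not modelled
— the parameter exists to probe the neutrality assumption of the analysis,
not to simulate realistic non-neutral demography. Cell death, phenotypic
lag and continuous-time (Gillespie) growth are likewise out of scope.

The class-mix abstraction treats every candidate colony as classifiable
with fixed probabilities (target mutation, near-target mutation,
unconfirmed); μ is therefore the rate of candidate-producing events as a
whole, and the target-specific rate is μ times the target class
probability. False-positive colonies are not modelled as a separate
process.

**Seeds.** One master seed; the culture with index i uses
`default_rng([seed, i])`, so increasing the number of cultures never
reshuffles earlier ones, and a fixed seed reproduces datasets
bit-identically.

## Default study conditions of the generator

* `n_initial = 6000` cells: a ~1000 CFU/mL inoculum in a 6 mL microcosm.
* `n_final = 6000·2²¹ ≈ 1.26×10¹⁰` cells (≈ 2×10⁹ CFU/mL at stationary
  phase). No final density is reported for the fluctuation cultures, so
  this is the package's own choice of a realistic stationary density; it
  is recorded in every ground-truth sidecar.
* Wild-type-like scenario (`LDSimParams.wildtype_reporter`): phenotype
  μ = 6.72×10⁻⁷ per cell per division with target-class probability 60/96
  (target rate 4.2×10⁻⁷) and a 6/96 near-target class; selective plating
  fraction 10⁻³, within the 100–1000-fold dilution design.
* Activator-deletion scenario (`LDSimParams.psra_deletion`):
  μ = 1.152×10⁻⁸ (target rate 7.2×10⁻⁹), plated without dilution — taken
  as a 100 µL sample of the 6 mL culture, ε = 1/60. The same sequencing
  class mix is assumed for both genotypes.

## MSS estimation chain

* **pmf**: the recursion `p_0 = e^{−m}`, `p_k = (m/k) Σ p_i/(k−i+1)`,
  evaluated iteratively in linear space; cost O(k²).
* **Likelihood**: counts above `k_cap` pool into a tail class of mass
  `1 − Σ_{k≤k_cap} p_k`, keeping the likelihood proper for jackpot
  cultures. `k_cap` defaults to the maximum observed count with a hard
  ceiling of 5000 (beyond which the recursion cost dominates and the body
  of the pmf carries all usable information). A dataset whose *every*
  count exceeds the cap is rejected rather than fitted, since the
  likelihood is then uninformative.
* **Optimizer**: coarse log-spaced grid scan over m followed by bounded
  Brent refinement, absolute tolerance 10⁻⁷; the likelihood is unimodal on
  all tested data and the result matches an exhaustive grid at step 10⁻⁴.
  All-zero data return m̂ = 0 with a boundary flag, never an error.
* **Confidence intervals**: default is Stewart's large-sample interval on
  ln m, sd `1.225·m̂^{−0.315}/√C` for C cultures, with normal quantiles —
  the interval FALCOR-style MSS-MLE analyses report. Profile likelihood
  (log-likelihood drop of χ²₁(level)/2, roots by Brent) is provided as a
  cross-check; the two agree within 10% relative width on 1000-culture
  data, and profile CIs cover the truth in ≈95% of 200 simulated
  12-culture experiments at m = 2. At the m̂ = 0 boundary both return the
  degenerate interval (0, χ²₁/2 / C) from the all-zero likelihood.
* **Confirmation correction**: corrected count = round(candidates ×
  confirmed fraction), ties half up (the likelihood needs integers). The
  fraction is pooled over the genotype by default — eight colonies per
  culture are too few for stable per-culture fractions — with a
  per-culture mode that falls back to the pooled value (flagged) where
  nothing was sequenced.
* **Plating fraction**: `m_whole = m_plate / ε`, the expected-count
  scaling. This is a knowing approximation: thinning removes small clones
  entirely, so the thinned count law is *not* MSS at ε·m, and the linear
  rescaling is biased upward — a factor ≈2.3 at ε = 0.1, m = 2, growing
  with dilution (a factor ≈3 under the wild-type-like scenario above).
  The direction and magnitude are asserted in the tests; the exact
  partial-plating likelihood is a listed extension. Because both genotypes
  are analysed identically, genotype *fold* comparisons are far more
  stable than absolute rates (the simulated wild-type/deletion fold is
  recovered near its true ≈58 despite the absolute bias). The fitted
  pipeline uses the mean ε across cultures of a genotype.
* **Rate denominator**: μ = m̂/Nt by default (`final_n`; a culture grown
  from a tiny inoculum performs ≈Nt replications), with `net_growth`
  (Nt − N0) available; per-culture Nt is averaged across the dataset and
  the mode is recorded in the output provenance.
* **Mutant frequency**: per culture, corrected count / ε / Nt; the mean is
  also reported as "one in N cells".

## Competition fitness

`s = ln(R(t)/R(0))/t` per replicate, with R the focal/reference event
ratio and t the number of generations (`log2(Nf/N0)` when computed from
densities). Replicate-level s values are averaged (not pooled-count
regression), matching per-competition error bars; the two fluorophore
orientations carry the marker cost with opposite sign, so the pooled mean
of a balanced swap design cancels it. Zero counts make s undefined: such
replicates are excluded with a flag rather than pseudocounted, because at
sampling depths of ≥20,000 events a zero is diagnostic of failure, not of
sampling. The simulator draws binomial counts at configurable depth from
the exact ratio trajectory; `depth=None` gives the deterministic no-noise
limit.

## Relative expression (ΔΔCq)

Technical replicates are averaged on the Cq scale, then
`ΔCq = Cq_target − Cq_reference` per biological replicate; fold change is
`2^−(ΔCq_sample − ΔCq_calibrator)` with the calibrator ΔCq averaged over
its biological replicates; biological replicates are summarised on the
fold scale (mean ± sd). Base 2 assumes 100% amplification efficiency; no
Pfaffl-style efficiency correction is applied, and that is the method's
documented limitation.

## Parallelism statistics

Spectrum tallies are exact counts per (position, ref, alt) and per
mutation class, 1-based positions on the coding strand, codon =
⌈position/3⌉. The two-site equal-rate, equal-fitness null gives
`p^n` for all n hits at one site (computed in log space; 0.5¹³⁷ =
5.7×10⁻⁴²), and the k-of-n generalisation is an exact binomial upper tail
summed in log space. The null is an argument device, not a fitted model;
alternative nulls are user-supplied probabilities.

## Problem sizes in tests and the acceptance script

Oracle equivalence uses 10⁵ simulated cultures per m; estimator
calibration uses 200 experiments of 12 cultures; competition contracts use
16 swapped pairs at depth 20,000; expression recovery uses 6 biological ×
2 technical replicates at noise sd 0.2 cycles. These sizes put Monte-Carlo
error comfortably below the asserted tolerances while keeping a full run
in tens of seconds.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes
(Lea–Coulson counts, binomial sampling of markers, Gaussian Cq noise) and
the specific violations the analysis is probed with (non-neutral mutants,
late induction, partial plating). It does not emulate plate-level
artifacts (slow-growing spontaneous mutants, colony-size scoring), copy
number effects of reporter constructs, cytometry gating, or
amplification-efficiency drift; agreement on synthetic data therefore
validates the inference chain, not the upstream measurement process.
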