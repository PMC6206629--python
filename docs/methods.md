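# Methods

## Model

Input is a sparse hit table: for each read `j`, the set of candidate
genomes reported by the aligner, with matched length `M_ji` (identical
bases) and an alignment length. Because a read's alignment lengths are
nearly identical across its hits, each read keeps one length
`L_j = max_i L_ji`; per-hit alignment lengths are not used further.

Reads are i.i.d. draws from a finite mixture over the `k` genomes with
parameters `θ = (R, p)`: `R_i ≥ 0, Σ R_i = 1` are the genome proportions
and `p_i ∈ (0, 1)` the per-base mismatch probabilities. The likelihood
contribution of read `j` is `Σ_i R_i p_i^(L_j−M_ji) (1−p_i)^M_ji`, where
the sum runs over the read's *candidate* genomes only: the aligner reports
no `M_ji` for other genomes, and imputing one would invent data, so
non-candidates carry zero component probability. Fitting is by EM:

* E-step: responsibilities `T_ji ∝ R_i p_i^(L_j−M_ji) (1−p_i)^M_ji`,
  normalized within each read's candidate set;
* M-step: `R_i = mean_j T_ji` and
  `p_i = 1 − Σ_j T_ji M_ji / Σ_j T_ji L_j` (the responsibility-weighted
  mismatch rate); in shared-probability (TAMER) mode the rate is pooled
  over all genomes, giving one `p`.

The posterior used for assignment, `P_ji`, is the same expression at the
converged parameters; a read is assigned to its argmax genome, with every
genome within `tie_tol` (default 1e-9) of the maximum included, so only
near-exact ties produce multiple assignment.

## Numerical choices

* All likelihood arithmetic is in log space with a per-read log-sum-exp;
  a read whose every candidate term underflows raises an error naming it.
* Initialization is deterministic and data-driven: uniform `R`, naive
  per-genome rates `1 − ΣM/ΣL` over each genome's reported hits (pooled
  in shared mode).
* Convergence: relative log-likelihood change `|Δl|/(|l|+1) < 1e-8`,
  at most 500 iterations. The log-likelihood trace is retained and is
  non-decreasing up to 1e-8 slack (asserted in tests).
* `p` is clipped to `[1e-6, 1−1e-6]`: a genome with only perfect matches
  would otherwise drive `p → 0` and spike the log-likelihood.
* A genome whose posterior mass falls below 1e-12 has an undefined rate
  update (0/0); it keeps its previous `p` while `R_i → 0`.
* Duplicate (read, genome) hits — multiple HSPs — collapse to the
  largest matched length, the standard best-HSP summary.

## Model-choice tests

Under `H0: p_1 = ... = p_k = p_0` the shared-probability model is
adequate. `p_0` is the shared-mode EM estimate, and each genome's
effective sample size is `E_i = Σ_j T_ji L_j` at that fit — the
posterior-weighted aligned bases behind `p̂_i`, so
`Var(p̂_i | H0) ≈ p_0(1−p_0)/E_i`. Per-genome weights are the
Beta(a1, a2) density at `p̂_i` (defaults a1 = 96, a2 = 100); both
statistics are invariant to the weights' overall scale, so weights are
normalized by their maximum to avoid underflow (the raw Beta(96,100)
density at rates near 0.01 is ~1e-135). The collapsing coefficients are
`C_i = 2 w_i` (the weight times the row sum of the exchangeable design
matrix with unit diagonal and `1/(k−1)` off-diagonal).

* Burden: `Q = (C'(p̂ − p_0·1))² / Σ_i C_i² p_0(1−p_0)/E_i`, referred to
  chi-square(1). The squared score alone has no fixed null scale; the
  plug-in variance standardization is what makes it chi-square(1), as in
  standard burden-score constructions.
* Variance component: `Q = Σ_i C_i² (p̂_i − p_0)²` — the collapsed
  (diagonal-kernel) weighted sum of squared deviations. Its null law is
  `Σ λ_i χ²₁` with `λ_i = C_i² p_0(1−p_0)/E_i`. The kernel is kept
  diagonal for every `k`: the alternative full quadratic form built from
  the exchangeable design degenerates to a rank-one matrix at `k = 2`,
  where it is blind to opposite deviations and has essentially no power —
  inconsistent with this statistic's purpose — while the diagonal form
  detects mixed-direction alternatives at every `k`.
* Tail probabilities `Pr(Σ λ_i χ²₁ > q)` use Imhof's exact
  characteristic-function inversion integral (equal eigenvalues reduce
  analytically to a scaled chi-square, which also covers the
  chi-square(1)/(2) closed-form checks); if the quadrature is unreliable
  a Liu-type four-moment chi-square approximation is used and flagged in
  the result's null description.
* The Wald test `(p̂−p_0·1)'Σ⁻¹(p̂−p_0·1)` ~ chi-square(k−1) is provided
  but warns: it needs a caller-supplied invertible covariance, which
  sparse data rarely support, and has poor power under sparse
  alternatives.
* Recommendation rule: the per-genome model is recommended when either
  test rejects at alpha (default 0.05).

Calibration note: in the full pipeline `p_0` is estimated by pooling the
same data, so the deviations `p̂_i − p_0` sum to approximately zero with
the `E_i` weights. At `k = 2` with equal abundances this cancellation
makes both tests conservative (empirical size well below nominal); the
parametric-null calibration in the test suite — independent binomial
`p̂_i` with the true `p_0` plugged in — shows both tests near the nominal
0.05 level. Power against clearly separated rates is essentially 1 either
way.

## Synthetic data generator

The generator emulates a read simulator + aligner pipeline at the
hit-summary level (`M`, `L` per read-genome pair), not the nucleotide
level — the model consumes only these summaries, and nucleotide-level
simulation would require re-running an aligner. Per read: a true genome
drawn from the configured abundances; `L ~ round(Normal(mean, sd))`
truncated at 50 bp; `M ~ Binomial(L, 1 − p_true)`. Homology between a
designated genome pair `(a, b)` produces, with probability
`homology_hit_prob` (default 0.3), an extra hit on `b` with per-base
match probability `(1 − p_b)(1 − d_ab)` (default divergence
`d_ab = 0.02`). These defaults create the multi-genome ambiguity the
mixture exists to resolve; they are configuration, not estimates. Read
length defaults to 500 ± 50 bp ("long reads"), with 150 bp the
conventional short-read setting. Study designs: `fixed_error_config`
(every genome shares one rate, default 0.01 — within empirical
per-platform error ranges) and `varying_two_error_config` (two genomes at
0.005 and 0.015). Datasets are bit-reproducible given the seed.

What the generator does **not** emulate: indels and structural events as
sequence features (only their aggregate effect on match counts),
platform-specific error profiles, chimeras, database incompleteness, and
the extra between-genome dispersion real aligner pipelines introduce.
Consequently the null simulation is exactly model-consistent, and
passing size/power results here do not guarantee calibration on real
aligner output, where mismatch-rate heterogeneity beyond binomial noise
is common (and pushes the tests toward rejection).

One identifiability consequence of the homology model: a cross-hit on
genome `b` scores match probability `(1−p_b)(1−d_ab)`, which can *exceed*
the true genome's own `1 − p_a` when `p_a > p_b + d_ab`. Reads in that
regime are genuinely better explained by the wrong genome, so proportion
estimates absorb the misassigned mass; parameter-recovery checks
therefore use homology-free (unambiguous) configurations.

## Evaluation

Assignments are scored against simulator truth at each of the seven ranks
species → kingdom. A read is a true positive at rank `r` if any assigned
genome shares the true genome's rank-`r` taxon, and a false positive if
any assigned genome conflicts there; both fractions are over all reads,
so a multiply-assigned read can count in both and TP + FP can exceed 1.
An `"unknown"` taxon never matches anything (conservative: missing
lineage information cannot create true positives).

## Study sizes and runtime

The type-I-error and power studies use 100 replicates of 1000 reads
(two genomes, ~1300 hits per dataset); each replicate refits both model
modes and runs both tests, ~15 s total for the pair of studies on one
CPU. Test-suite calibration checks use 10000 parametric-null replicates
with vectorized statistics; the two-eigenvalue mixture tail is evaluated
by an exact conditioning integral (cross-checked against the Imhof route)
to keep the loop fast.

## Known limitations

* The candidate-set (sparse) mixture cannot rescue a read whose true
  genome the aligner never reported.
* The tests compare rates through plug-in binomial variances; strong
  overdispersion in real data is not modelled (it makes the tests
  anti-conservative, which in practice means recommending the per-genome
  model more often — the safer direction).
* With `k = 2` and pooled `p_0`, null rejection is conservative (see the
  calibration note); the tests remain valid (size below nominal) but
  sizes quoted at nominal alpha overstate the realized error rate there.
* The Beta(96, 100) weight sharply favors the genome with the larger
  estimated rate when rates are small; this is inherited from the
  weighting convention, and alternative shapes can be configured.
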