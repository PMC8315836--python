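# Methods

This note documents the models, estimators and design choices behind
`crowdwise`, and what the synthetic experiments do and do not establish.

## Variables and conventions

All estimates are log-normalised: `X = log10(E / T)` for a raw estimate
`E` of a quantity with true value `T`. Base 10 is fixed throughout so
that `X` reads as "orders of magnitude off"; every formula in the
package is base-invariant given consistency, so this is purely an
interpretability choice. The social information `M` is computed in the
same normalised log space as the arithmetic mean of the peers' `X`
values, which is identically `log10` of the geometric mean of their raw
estimates divided by `T` (the package asserts this equivalence to
1e-12 in its tests). Medians of even-sized samples use the midpoint of
the two central order statistics everywhere.

## The synthetic experiment

`design.build_design` reproduces the balanced geometry of a
three-treatment estimation experiment: groups of `N = 12` subjects,
each group assigned one display treatment (sorted / unsorted /
aggregated, 6 groups each), 42 questions in 7 blocks of 6, and
`τ ∈ {1, 3, 5, 7, 9, 11}` peers shown, with each block containing every
τ once and — across the 6 groups of a treatment — every question asked
exactly once at every τ. The construction stacks random Latin squares
(row/column/symbol shuffles of the cyclic square) into a
question × group rectangle, so all balance constraints hold by
construction; it requires the number of groups per treatment to be a
multiple of the number of τ levels and fails loudly otherwise. The
randomisation is not uniform over all feasible designs, only over a
large shuffle orbit; nothing downstream depends on which feasible
design is drawn. Peer sets are drawn uniformly among the `N − 1` other
group members, never including the subject.

Per question, personal estimates are drawn from a Laplace distribution
(centre `c` = median, width `w` = mean absolute deviation) truncated to
`X > −log10(T)`, sampled exactly by inverse CDF on the truncated
support. Question parameters default to `c ~ Normal(−0.3, 0.35²)`,
`w ~ Uniform(0.3, 0.8)`, `log10 T ~ Uniform(2, 9)` — magnitudes typical
of general-knowledge estimation questions, with the negative mean of
`c` encoding the underestimation bias that the accuracy analyses
require (without it, the D-sign stratifications are uninformative). All
are configurable through `QuestionConfig`.

Randomness policy: one master seed; child streams are derived per
(purpose, group) via `numpy` `SeedSequence` spawn keys, so enlarging
the design does not perturb existing draws, and every public function
is deterministic given its seed.

## The agent model

For each record the model (i) draws `X_p` as above, (ii) forms `M` from
τ freshly drawn peers, (iii) draws the sensitivity `S` from the hurdle
law with `P_g(τ, D) = ⟨S⟩(τ, D) / m_g(τ)` and
`⟨S⟩(τ, D) = α(τ) + β_± |D − D_0|`, where `α`, `m_g` and `σ_g` follow
the shared-rate exponential saturation
`Y(τ) = Y_∞ − (1 − ε)^(τ−1)(Y_∞ − Y_1)`, and (iv) sets
`X_s = (1 − S) X_p + S M`. Treatment presets carry the ten calibrated
parameters per display regime.

Three choices the behavioural equations leave open:

- **`P_g` clipping.** The ratio `⟨S⟩ / m_g` exceeds 1 for large
  `|D − D_0|`. It is clipped to `[0, 1]` — the minimal fix that keeps
  `E[S] = P_g m_g` well defined. The consequence, measured by feeding
  the cusp estimator noise-free conditional means, is a flattening of
  `E[S]` beyond `|D − D_0| ≈ (m_g − α)/β`, which biases recovered cusp
  slopes downward (see *Recovery fidelity* below).
- **No generation-side truncation of `S`.** The `[−1.05, 2.05]` window
  is an analysis-side filter only; Gaussian mass outside it is ≤ 0.01%
  for the preset parameters, so generation and analysis remain
  consistent.
- **The bound `X_s > −log10(T)`** is enforced by redrawing `S` (at most
  100 attempts, then `S = 0`). A violation requires `S ∉ [0, 1]`
  together with an extreme `|M − X_p|`, and essentially never occurs at
  the preset parameters; the mechanism exists for exotic parameter sets.

`simulate` defaults to 10 000 runs (the convention for averaged model
curves) but every entry point takes `n_runs`; summaries (mean `S` per
condition and D-sign, run-averaged accuracies) are accumulated exactly
and equal recomputation from the kept records.

## Estimators

**Hurdle fit.** Default is maximum likelihood on the exact-zero /
non-zero split: `P_0` = zero fraction, `(m_g, σ_g)` = Gaussian MLE of
the non-zero values. On simulated data exact zeros are identifiable, so
this is unbiased and binning-free, and it satisfies `⟨S⟩ = P_g m_g`
exactly. The alternative `estimator="binned"` reproduces the
empirical-data procedure: least squares of the hurdle density
`(1 − P_g) δ(S) + P_g φ(S; m_g, σ_g)` against a histogram of bin width
0.1, with `P_g` tied to the sample mean via `P_g = ⟨S⟩ / m_g`. Values
of `S = 1` receive no special handling (they are absorbed into the
Gaussian part).

**Saturation fit.** `P_g`, `m_g`, `σ_g` across τ are fitted
simultaneously with a single shared rate ε by nonlinear least squares
(7 free parameters), deterministically initialised at
`Y_1 = Y(τ_min)`, `Y_∞ = Y(τ_max)`, `ε = 0.3`, with
`ε ∈ [1e-4, 1 − 1e-4]`. Flat input (all three curves constant) leaves ε
unidentifiable and is flagged as such rather than reported as an
arbitrary rate. `α(τ)` is then refitted with the same form at the same
ε, which makes the problem linear in `(α_1, α_∞)` and exactly solvable.

**Cusp fit.** Mean `S` against `D` is summarised by moving bins: width
1, centres from −2 to 2 in steps of 0.1 (41 points), each record
entering every bin within half a width — deliberate replication of the
same data, trading bin noise against vertex resolution. Weights are the
fraction of records per bin, normalised over non-empty bins (the
normalisation cancels in the arg-min); empty bins are dropped rather
than imputed, since the weighted objective already ignores them. For
each candidate vertex `D_0` on a grid (−1.5 to 1.5, step 0.01) the
remaining parameters solve the 3×3 weighted normal equations in closed
form; the grid minimiser of the weighted residual sum wins, ties broken
toward the smallest `|D_0|`. Slopes are unconstrained in sign; a side
of the vertex with no data leaves that slope flagged `NaN`. `D_0`,
`β_−`, `β_+` are treated as τ-independent and summarised as unweighted
means over the per-τ fits.

**Accuracy.** Collective accuracy `|median(X)|`, individual accuracy
`median(|X|)`; stratifications by the sign of `D` (records with `D = 0`
excluded — measure zero in simulation) and by `S` strictly below versus
at-or-above the condition's median of `S`, with the split point
replaced by 0.001 when that median is exactly 0 (a median sitting on
the point mass makes the raw split meaningless).

**Bootstrap.** Uncertainty is with respect to the set of questions
asked: `n_exp = 1000` resamples redraw the N_Q distinct questions with
replacement and the error bars are nearest-rank one-sided quantiles at
`C = 0.683` of the deviations above/below the full-data value —
asymmetric by construction. An empty one-sided deviation set yields a
zero bar with a warning.

## Recovery fidelity and problem sizes

The test suite and `scripts/acceptance.py` close the loop: simulate all
three treatments with the preset parameters, refit everything, compare.
50 replicate experiments (≈ 25 000 restricted sensitivities per
(treatment, τ) condition, ≈ 4.5 × 10⁵ records in total) are used —
enough that Monte-Carlo noise on every recovered parameter is well
below the comparison tolerances, while the whole loop runs in seconds.

At these sizes the saturation loop is faithful: ε, `m_g(∞)`, `σ_g(∞)`
come back within a few hundredths of their generating values in every
treatment. The cusp loop is faithful up to two known systematic
effects: (i) the bin-width-1 smoothing of the V, strongest exactly
where the data density (and hence the fit weight) peaks, compresses
recovered slopes by ~0.015 even on noise-free input; (ii) `P_g`
clipping flattens the far tails, costing another ~0.02 on the steeper
slope of the Unsorted treatment and shifting the Sorted vertex left by
up to ~0.1. These are properties of the estimator-plus-model pair, not
of the sample size: they do not shrink with more replicates. The
corresponding acceptance test asserts the nominal recovery band and is
expected to fail on the Unsorted `β_+`, documenting the bias rather
than hiding it.

## What the synthetic data does not show

The generator emulates the statistical structure the estimators assume:
Laplace personal estimates, hurdle-Gaussian sensitivities, the cusp
distance effect, exchangeable questions. Real estimation data deviate
in ways the package deliberately does not model: per-subject
consistency of `S` across questions, confidence effects, cognitive
overload at large τ, round-number clumping of raw estimates, and
non-Laplace tails for individual questions. Passing recovery tests
therefore certifies the pipeline's correctness on its own assumptions,
not the adequacy of those assumptions for any particular dataset.
Group-size extrapolations (e.g. `N = 50`, τ up to `N − 1`) inherit the
same caveat: the behavioural parameters were calibrated at `N = 12`,
τ ≤ 11.
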