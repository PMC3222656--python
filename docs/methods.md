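# Methods

This note documents the statistical machinery implemented in `dsenorm`:
the models and their assumptions, the defaults and why they were chosen,
what the simulator does and does not emulate, and the numerical details
that matter for reproducibility.

## The skewness model

A two-group experiment (treatment vs reference, `k` replicates per arm,
`n` ordered variables) is *skewed* when the distribution of the true
log-ratios of the altered variables is not symmetric around zero. Under
symmetry, rank-based normalizations are safe: forcing all samples onto a
common distribution cancels technical offsets without touching the
signal's location. Under skewness that same forcing removes part of the
signal itself — if a fraction α of variables is shifted up by
`log2 δ`, equalizing the sample distributions subtracts roughly
`α·log2 δ` from every variable, biasing altered variables toward zero and
pushing unaltered variables below it.

## DSE-test

For a pair of samples `(a, b)` the per-variable log-ratios
`r_i = x_ia − x_ib` (log2 scale) are summarized by the Bowley quartile
skewness

    qs = (Q3 + Q1 − 2·median) / (Q3 − Q1),

bounded in [−1, 1], zero for quartile-symmetric data, positive for right
skew, and invariant under location/scale changes. Quartiles use linear
interpolation of order statistics (the type-7 rule, the default in most
statistical environments); the convention is pinned because `qs` of small
samples depends on it.

Heterogeneous pairs (one sample per arm) mix the asymmetric biological
signal into `r`; homogeneous pairs (both samples from one arm) contain
technical noise only. The test statistic is Welch's two-sided t comparing
the mean heterogeneous `qs` against the mean homogeneous `qs`, with
Satterthwaite degrees of freedom. A one-sided alternative is exposed but
not default: the test is for *any* asymmetry.

Pair construction is deterministic: samples are sorted by id and paired
first-come. The homogeneous pairs of an arm with `n` samples can be chosen
in many ways (three samples already admit three one-pair matchings; two
arms of three give nine alternatives) — one alternative is used, and an
optional seeded shuffle supports sensitivity analysis.
`enumerate_homogeneous_pairings` enumerates all alternatives for
inspection.

*Dependent variant*: all `min(n_T, n_R)` heterogeneous pairs plus
`⌊n_T/2⌋ + ⌊n_R/2⌋` homogeneous pairs, every sample appearing in both
sets. The shared samples make the coefficients dependent, which can
inflate the false-positive rate slightly, but for small experiments
(fewer than ~8 replicates per arm) the extra pairs buy substantial power;
it is the only option at `k = 2`.

*Independent variant*: the first `⌈n/2⌉` samples of each arm (sorted ids)
form heterogeneous pairs, the remaining halves form homogeneous pairs, so
no sample is used twice and the coefficients are independent. This
controls the false-positive rate but needs at least 4 samples per arm and
uses half as many observations.

`pre_normalize` (standard quantile normalization before pairing) defaults
to on for user data; the simulation harness disables it because the
simulator emits data that emulate already-normalized intensities.

## Reference-set quantile normalization

All normalizations share one primitive: quantile normalization driven by a
reference set `S` of variables. The target distribution is the
across-sample mean of each sample's sorted values restricted to `S`; each
sample is mapped through the monotone piecewise-linear function from its
own `S`-quantiles to the target, applied to *all* variables, with linear
tail extrapolation using the outermost segment slopes. Tied input values
receive the mean of the target values their ranks span, which keeps the
map single-valued and monotone. With `S` = all variables this is exactly
classic quantile normalization (sorted columns become identical); the map
is idempotent for any `S`.

Reference-set selectors:

* **standard** — all variables;
* **rank-invariant** — the `⌈fraction·n⌉` variables (default 50%) with the
  smallest absolute difference between their mean rank across treatment
  samples and across reference samples, ties broken by variable index.
  This is a transparent re-implementation of the rank-invariant idea used
  as a comparator; it is not a port of any specific published selector.
* **hmm** — variables decoded as unaltered by the HMM (below);
* **ideal** — the complement of the true altered set; an oracle usable
  only on simulated data, serving as the positive control.

## HMM-assisted normalization

Steps: (1) standard quantile normalization; (2) M-values
`M_i = mean(log2 x_T) − mean(log2 x_R)` per variable, i.e. the log-ratio
of the arms' geometric-mean intensities (an `average="arithmetic"` switch
averages raw intensities instead — the geometric default is
scale-robust and consistent with the log-domain normalization); (3) a
two-state Gaussian HMM on the ordered M-track; (4) re-normalization of the
*original* data with the decoded unaltered variables as reference set.
The re-normalization is a general monotone map, not a constant shift of
M-values.

The HMM has states unaltered/altered with Normal emissions
`N(μ_1, σ_1²)`, `N(μ_2, σ_2²)`. Starting values are moment-matched under
the mixture assumption `(1−ρ)·N(0, σ²) + ρ·N(μ_2, σ²)` with a guessed
altered fraction ρ (default 0.1, configurable; results are insensitive to
the guess because transitions and means are re-estimated):
`μ_2 = mean(M)/ρ` and `σ² = var(M) − ρ(1−ρ)μ_2²`, floored at `var(M)/2`.
Transition rates encode the expected altered-region length `L` (default
50 variables): altered→unaltered `1/L`, unaltered→altered `ρ/((1−ρ)L)`,
giving the stationary distribution `(1−ρ, ρ)`; the chain starts from it.

**Degenerate-init rescue.** Quantile-normalized samples are permutations
of a common target vector, so their means are identical and `mean(M) ≈ 0`
to machine precision — the moment estimate `μ_2 = mean(M)/ρ` then
coincides with `μ_1 = 0`. Two identical emission states are an *exact*
fixed point of EM: the responsibilities reduce to the stationary
distribution at every position and the means can never separate (and the
near-flat likelihood trips the convergence test immediately). The
pipeline therefore restarts `μ_2` at the mean of the upper (or lower,
chosen by the sign of the Bowley coefficient of M) ρ-tail of the M-values
whenever `|μ_2 − μ_1| < 0.25·sd(M)`. This is only a starting value; EM
re-estimates everything.

Fitting is Baum–Welch EM (via `hmmlearn`) with numerically stable
forward–backward; multiple order blocks (e.g. chromosomes) are independent
chains sharing one parameter set through joint EM accumulators.
Convergence: relative log-likelihood change below `tol = 1e-6` or
`max_iter = 500`; the full likelihood trace is recorded and is
non-decreasing (checked to 1e-8 slack in the tests). Emission variances
are floored at `(1e-4·sd(M))²`; hitting the floor is flagged, not fatal.
Decoding is Viterbi by default — contiguous regions are the method's
premise — with posterior-argmax as an option. The unaltered state is the
one with fitted mean closest to zero; on a tie, the state with the larger
stationary probability (unaltered variables are assumed the majority). A
perfectly flat M-track (identical arms) skips the HMM and uses all
variables as the reference set.

## Simulator

The generator emulates *already-normalized, bias-free* data from a skewed
experiment — the harness feeds it to the normalizers directly, and the
ideal normalization is a near-identity on it. Reference intensities are
`x_R ~ N(μ_i, σ_i)` (raw scale), treated intensities
`x_T ~ N(δ_i·μ_i, σ_i)` with `δ_i = δ` inside altered regions and 1
elsewhere. The treated standard deviation is *not* scaled by δ (the
simplest reading of "δ is the ratio of the intensities"; a scaled-σ
variant exists for sensitivity checks). Draws are truncated below at one
intensity unit so log2 is defined; with the default parameters truncation
is vanishingly rare and the count is recorded. `round(α·n/m)` regions of
exactly `m` consecutive altered variables are placed at constant spacing
`s = ⌊n/r⌋`, starting at `⌊s/2⌋`; the altered count is exactly
`round(α·n/m)·m`. Several effect sizes cycle over regions (≈ equal shares).

Per-variable parameters come either from real raw reference data
(`estimate_variable_params`: keep variables above the median average
intensity; `μ_i` = average intensity; variance regularized toward the mean
sample variance of the `window` = 101 variables nearest in average
intensity, `σ̂² = (ν₀·σ₀² + (n_s−1)s²)/(ν₀+n_s−2)` with prior df ν₀ = 10)
or from a synthetic prior (`synth_variable_params`:
`log2 μ ~ N(9, 0.8)`, `σ = cv·μ` with `cv ~ U(0.05, 0.25)`), chosen to
mimic the intensity spread and replicate noise of above-median tiling
array probes. All randomness flows from explicit seeds; identical
configuration and seed reproduce bit-identical experiments.

What the simulator does **not** emulate: between-array systematic
variation, spatial artefacts, dye bias, probe-level correlation beyond the
region structure, heavy-tailed noise, or negative (down-altered) regions.
Real data have lower signal-to-noise than these simulations, so passing
benchmarks here bounds idealized behaviour — the relative ordering of the
methods is the transferable result, not the absolute sensitivities.

## Downstream evaluation

M-values are smoothed with a centered moving median of length 21
(windows truncate at track edges); variables whose smoothed value is
strictly above `0.7·log2(δ)` are called altered. Sensitivity and
specificity are the true-positive and true-negative fractions. Bias is
the mean *signed* shrinkage over altered variables,
`mean(sign(t_i)·(t_i − M_i))` with `t_i` the true log-ratio, computed on
non-smoothed M-values; it reduces to `mean(log2 δ − M)` for purely
positive alterations. For mixed-δ experiments the calling cutoff uses the
smallest δ (a single, conservative operating point) while bias uses each
region's own δ. Relative sensitivity/specificity are ratios to the ideal
normalization, relative bias is the difference. Spike-in-style evaluation
at a fixed false-positive rate thresholds scores at the type-7
`(1 − fpr)` quantile of the null scores (strictly-above rule, default
fpr = 0.5%).

DSE-test power over a configuration grid is the fraction of simulated
experiments with p < 0.05 (with α = 0 this estimates the false-positive
rate), with binomial standard errors; per-variable parameters are drawn
once per grid cell and shared across simulations, mirroring parameters
estimated once from a real data set.

## Problem sizes and runtime choices

The bundled experiments use 300 simulations (dependent-test power,
n = 100,000, k = 2), 1000 simulations (independent-test false-positive
rate, n = 10,000, k = 4), and 3 replicates for the normalization benchmark
(n = 100,000, k = 2, α = 25%, δ = 1.5), each with 4 normalization methods.
Three replicates already give stable sensitivity ratios because each
replicate averages over 125,000 altered variables; the package-level
benchmark helper accepts any replicate count and reports per-method
averages.

## Known limitations

* The DSE-test's dependent variant does not control the false-positive
  rate exactly; use the independent variant when `k ≥ 4` and the decision
  matters.
* The HMM assumes one dominant alteration direction per experiment and
  two states; experiments with balanced up/down regions need neither the
  test (they are not skewed) nor the invariant normalization, which can
  underperform standard methods on symmetric data.
* The rank-invariant comparator is intentionally simple; published
  rank-invariant selectors differ in detail.
* Windows defined in base pairs (rather than probe counts) for smoothing
  are not implemented; genomic order enters only through block structure.
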