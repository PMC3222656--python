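# dsenorm

Detection and normalization of *skewed experiments* in high-dimensional
genomics data.

Standard normalization techniques (quantile, MA) assume that only a small
fraction of variables respond to treatment and that the true log-ratios of
the responders are symmetric around zero. Many routine experiments violate
both assumptions: ChIP-chip / ChIP-seq enrichment is almost entirely
positive, apoptosis or heat-shock expression studies perturb large swathes
of the genome in one direction, and tumour copy-number profiles are
dominated by gains or losses. Normalizing such a *skewed experiment* with
a standard method absorbs genuine biological signal into the normalization
function: altered variables are shrunk toward zero (bias) and many fall
below detection cutoffs (lost sensitivity).

`dsenorm` implements a complete workflow for this situation, aimed at
analysts of tiling-array, sequencing-count, or any ordered, replicated
two-group data:

1. **DSE-test** — a statistical test for skewness. For sample pairs the
   per-variable log-ratios are summarized by the Bowley quartile-skewness
   coefficient `qs = (Q3 + Q1 − 2·median) / (Q3 − Q1)`. *Heterogeneous*
   pairs (one treated, one reference sample) see the asymmetric signal;
   *homogeneous* pairs (same arm) see technical noise only. Welch's t-test
   (Satterthwaite df) compares the two groups of coefficients; a
   significant difference flags a skewed experiment. A *dependent* variant
   reuses each sample in both pair sets (`min(n_T, n_R)` heterogeneous and
   `⌊n_T/2⌋ + ⌊n_R/2⌋` homogeneous pairs — maximal power for small
   experiments) and an *independent* variant splits each arm in half so no
   sample is used twice, which controls the false-positive rate.
2. **HMM-assisted normalization** — for experiments found (or known) to be
   skewed. After a standard quantile normalization, the per-variable
   M-values `M_i = log2(avg treated / avg reference)` are segmented by a
   two-state Gaussian hidden Markov model along the genomic order; the
   state whose mean is closest to zero marks *unaltered* variables, and
   the original data are re-normalized using only those variables to
   estimate the quantile-normalization function (all variables are
   normalized). The HMM exploits the fact that altered variables come in
   contiguous regions.
3. **Simulator and evaluation harness** — region-structured synthetic
   experiments (`x_R ~ N(μ_i, σ_i)`, `x_T ~ N(δ·μ_i, σ_i)` inside altered
   regions), rank-invariant and oracle (ideal) reference-set comparators,
   moving-median smoothing, `0.7·log2(δ)` calling cutoff, and
   sensitivity / specificity / bias / power estimation.

## Worked example

Simulate a small, heavily skewed experiment (50,000 variables, two
replicates per arm, 25% of variables positively altered in regions of 50
with effect size δ = 1.5), test it for skewness, and re-normalize:

```python
from dsenorm import (SimulationConfig, synth_variable_params,
                     simulate_experiment, to_log2, DSETest, HMMNormalizer)

cfg = SimulationConfig(n=50_000, k=2, alpha=0.25, m=50, delta=1.5, seed=7)
sim = simulate_experiment(cfg, synth_variable_params(cfg.n, seed=8))
log2m = to_log2(sim.matrix)

print(DSETest(log2m, sim.design).fit(pre_normalize=False).summary())
```

```
DSE-test (Detection of Skewed Experiments)
  variant             : dependent
  pre-normalized      : False
  het. qs-coefficients: [0.219  0.2102]
  hom. qs-coefficients: [-0.0087  0.0014]
  Welch t             : 32.5880
  Satterthwaite df    : 1.961
  two-sided p-value   : 0.001052
  skewed at 5% level  : True
```

The heterogeneous pairs show a clear right skew (qs ≈ 0.21) that the
homogeneous pairs lack, so the experiment is flagged as skewed and gets
the HMM-assisted re-normalization:

```python
result = HMMNormalizer(log2m, sim.design, rho_guess=0.1).fit()
print(result.summary())
normalized = result.matrix            # IntensityMatrix, log2 scale
```

```
HMM-assisted invariant quantile normalization
  variables              : 50000
  unaltered (reference)  : 37460 (74.9%)
  state means            : -0.1486 (unaltered), 0.4424 (altered)
  state std deviations   : 0.2433, 0.2161
  stationary distribution: [0.749 0.251]
  EM iterations          : 8
  converged              : True
  final log-likelihood   : -1536.81
```

The HMM recovers the simulated structure (75% unaltered; the "unaltered"
state mean of −0.15 is exactly the offset the standard normalization
imposed on the null variables). Scoring both normalizations downstream
(moving median of 21, calls above 0.7·log2 1.5 ≈ 0.41) against the known
truth:

```
standard  sensitivity=0.521 specificity=1.000 bias=+0.144
hmm       sensitivity=0.941 specificity=0.998 bias=-0.016
```

i.e. the HMM-assisted normalization nearly doubles the sensitivity at
similar specificity and removes the shrinkage bias.

The same operations are available from the shell:

```sh
dsenorm --seed 7 simulate --n 50000 --k 2 --alpha 0.25 --m 50 --delta 1.5 \
        --out matrix.tsv --truth truth.tsv --design design.tsv
dsenorm dse --in matrix.tsv --design design.tsv --variant dependent
dsenorm normalize --method hmm --in matrix.tsv --design design.tsv \
        --out normalized.tsv --sidecar fit.json
dsenorm evaluate --normalized normalized.tsv --design design.tsv \
        --truth truth.tsv --delta 1.5
dsenorm density --in matrix.tsv --design design.tsv --out density.tsv
```

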