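# Methods

## Model and procedure

`dcnet` tests, gene by gene, whether network connectivity differs between two
biological conditions after adjusting for covariates. The analysed quantity is
the weighted degree centrality ("total connectivity") of each gene in a
per-group gene association network; the statistical engine is a pseudo-value
regression:

1. For each group *z* (sizes n₁, n₂), an association matrix W⁽ᶻ⁾ is estimated
   from that group's samples and reduced to per-gene degrees
   θ̂_k⁽ᶻ⁾ = Σ_{j≠k} W⁽ᶻ⁾_kj.
2. For every sample *i* of group *z*, the degree vector is re-estimated with
   that sample deleted, and the first-order jackknife pseudo-value
   θ̃_ik = n_z θ̂_k − (n_z − 1) θ̂_k^(−i) is formed. For a linear statistic
   (a column mean) this recovers the observation itself; in general it is the
   sample's estimated contribution to the group's connectivity, with
   first-order bias correction built in.
3. The pooled pseudo-values (n = n₁ + n₂ rows, aligned with the phenotype
   table) are regressed, per gene, on an intercept, the 0/1 condition
   indicator and all covariates, with an MM robust estimator. The two-sided
   t-test of the condition coefficient (df = n − design columns) is the
   gene's differential-connectivity test.
4. Per-predictor p-value families (one family = p genes) are converted to
   adjusted values by empirical Bayes screening; genes with adjusted
   condition p < α are reported as DC.

### Assumptions

- Samples are independent; the two condition levels are fixed by design.
- Expression values are analysis-ready (normalised counts or log-expression).
  Both association estimators are rank-based, so any strictly monotone
  per-gene transformation (log, CPM scaling) leaves results unchanged.
- Each group has at least 4 samples (leave-one-out needs ≥ 3 remaining);
  meaningful operating characteristics need tens of samples per group.
- Pseudo-values are treated as approximately independent responses. This is
  the standard pseudo-value working assumption; it is approximate, which is
  why the adjusted inference is validated by simulation (below).

## Why the degree statistic must be smooth

Jackknife pseudo-values are statistically valid only for functionals that are
smooth in the empirical distribution: the leave-one-out difference
θ̂ − θ̂^(−i) is multiplied by n − 1, so any component of θ̂ that responds
*discontinuously* to deleting one sample injects an O(n)-amplified jump into
the pseudo-values. Two natural-looking choices are discontinuous in exactly
this way and were measured (during development, at n = 2×60, p = 30) to
destroy the test's calibration — null differential-connectivity call rates of
50–80% and pooled null p-value distributions with Kolmogorov–Smirnov distance
0.57–0.77 from uniform, identically under Welch, least-squares and robust
regression, so the failure is in the statistic, not the regression:

- **Equal-frequency binned MI.** Deleting one sample shifts bin boundaries
  and relabels many cells at once; the plug-in MI jumps.
- **DPI pruning.** The data-processing-inequality rule removes edge (i, j)
  when w_ij < min(w_ik, w_kj) − ε for some k. Near-ties flip entire edges in
  and out of the degree sum under leave-one-out.

The default degree statistic is therefore the weighted degree of the
**unpruned** Gaussian-copula MI matrix, MI = −½ log(1 − ρ̂²) with ρ̂ the
Spearman rank correlation — a smooth, rank-based association measure (the
same estimator family the established MI-network ecosystem defaults to).
With these defaults the pipeline is well calibrated (20-seed null scenario:
mean DC call rate ≈ 0, pooled KS ≈ 0.05–0.08) and powered (20-seed hub
scenario: mean hub recall ≈ 0.7, background false-positive rate ≈ 0).

Both excluded primitives remain first-class, fully tested, and selectable
(`NetworkConfig(estimator="empirical")`, `NetworkConfig(prune=True)`): the
binned estimator for network estimation and cross-checks, DPI pruning for
the edge-list export, where removing indirect edges is exactly what a
network viewer wants. Users who enable them for the pseudo-value pipeline
should expect anti-conservative DC calls for the reasons above.

A related estimator property: with the conventional b = ⌊√n⌋ equal-frequency
bins, the plug-in MI of two *independent* genes has expected value
≈ (b − 1)²/(2n) → ½ as n grows; it does not vanish. The bias is common to
all pairs and both groups, so it cancels in group contrasts, but consistency
checks must pin the bin count.

## Robust regression

No installed library provides an S-initialised MM regression, so it is
implemented here: an M-estimate of scale (Tukey bisquare, c = 1.5476, 50%
breakdown) minimised over seeded elemental subsamples plus the least-squares
candidate (fast-S with two reweighting refinements per candidate), followed
by iteratively reweighted least squares with bisquare ψ at c = 4.685 (95%
Gaussian efficiency), fixed scale, convergence at max |Δβ| < 1e−8 or 200
iterations. Standard errors use the MM asymptotic covariance
s²·mean(ψ²)/mean(ψ′)²·(XᵀX)⁻¹ with an n/(n − q) small-sample factor.
The subsampling RNG seed is fixed, so fits are bit-reproducible and
independent of worker count.

The robust step is not cosmetic: pseudo-values of a degree functional are
heavy-tailed, and the Efron–Stein inequality makes the jackknife variance
estimate biased upward. Measured on the null scenario, ordinary least squares
is conservative (pooled KS ≈ 0.17 from uniform) while the MM fit is
calibrated (KS ≈ 0.06) — the bisquare's downweighting of the jackknife tails
offsets the variance inflation.

Degenerate cases never abort a run: a gene whose fit does not converge falls
back to OLS and is flagged `ols_fallback`; a zero residual scale (e.g.
constant pseudo-values) is flagged `perfect_fit` with p-values 0 for nonzero
coefficients and 1 otherwise.

## Empirical Bayes screening

Raw p-values in a family are modelled as the mixture
f(p) = π₀·1 + (1 − π₀)·f₁(p). The marginal f is estimated by a Gaussian KDE
of the probit-transformed p-values (back-transformed with the normal-density
Jacobian; bandwidth: Scott's rule, configurable); π̂₀ is the median of f̂ on
p ∈ [0.95, 1], capped at `pi0_cap` (default 1). Each p maps to the estimated
posterior null probability min(1, π̂₀/f̂(p)); an isotonic-regression pass
enforces monotonicity in p. Families smaller than 10, or with all p-values
identical, fall back to Benjamini–Hochberg with a warning — density
estimation has no mass to work with there. Adjustment is applied per
predictor family (each predictor's p gene-level p-values form one family).
EBS implementations differ in transform, bandwidth and π₀ estimator; exact
numeric agreement with other EBS codes is not expected, and BH is provided
as a bit-reproducible alternative (`AdjustmentConfig(method="bh")`).

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `NetworkConfig.estimator` | `"spearman"` | association measure (smooth copula MI) |
| `NetworkConfig.n_bins` | `"auto"` = ⌊√n⌋ | bins for the empirical estimator, recomputed per leave-one-out subset |
| `NetworkConfig.epsilon` | 0 | DPI slack (nats); larger prunes less |
| `NetworkConfig.prune` | `False` | apply DPI before degree (non-smooth; see above) |
| `RegressionConfig.tuning_efficiency` | 4.685 | bisquare c, 95% Gaussian efficiency |
| `AdjustmentConfig.method` / `alpha` | `"ebs"` / 0.05 | adjustment and DC significance level |
| `RunConfig.jobs` | 1 | worker count; never affects results |

Group coding is deterministic: the lexicographically smaller level of the
condition variable is group A (regression reference) unless levels are named
explicitly, so a positive condition coefficient always means "more connected
in group B". Categorical covariates are treatment-coded against the
lexicographically first level.

## What the simulator emulates — and what it does not

`SyntheticScenario` draws each group from a multivariate normal whose
"hub" block is equicorrelated (ρ = `base_rho` in group A, `perturbed_rho`
in group B) over independent background genes, plus N(0, 0.1²) measurement
noise (small, so realised correlations track the nominal ρ). Under
`count_model=("negbin", mu, size)` the latent normals pass through a
Gaussian copula to negative-binomial quantiles — overdispersed counts whose
rank structure, which is all the estimator sees, equals the latent one.
`covariate_driven_rho=True` ties the hub correlation to a numeric covariate
instead of the condition; combined with `confounding_strength > 0` this
creates the confounded situation that covariate adjustment exists to fix,
and the paired simulation check confirms adjustment reduces false DC calls
(run at 8 seeds in the suite for runtime; the effect is large).

Real RNA-seq features *not* emulated: library-size variation, gene-specific
mean–dispersion relationships, zero inflation, batch structure, and
non-equicorrelated network topologies. A green simulation establishes
calibration and power under the stated generative world, not performance on
any particular cohort. The 406 × 28 COPD-like fixture reproduces only the
shape of the published smoking-status panel (samples, gene count, six
clinical variables); its values are synthetic, so published gene lists are
not reproducible from it.

## Numerical choices and degenerate inputs

- Rank ties: equal-frequency binning breaks ties by original sample position
  (stable sort); Spearman uses average ranks. Both are deterministic.
- |ρ̂| is capped at 1 − 1e−12 so duplicated genes give a large finite MI.
- A constant gene (zero entropy) gets a zero MI row/column — never an error,
  because leave-one-out subsets can make a gene constant mid-jackknife.
- DPI removals are decided on the input matrix and applied simultaneously
  (iteration-order independent); the strict inequality carries a 1e−12
  tolerance for float noise.
- Samples with missing covariates are dropped (complete-case) with a logged
  count; a categorical level observed in only one group triggers a
  confounding warning; a rank-deficient design is an error naming the
  collinear columns.
- p-values at the probit boundary are clipped to [1e−10, 1 − 1e−10].

## Limitations

- Runtime scales as (n + 2) network estimations per analysis; each is
  O(p²·n log n). The 406 × 28 panel takes seconds; thousands of genes call
  for `jobs > 1` and patience.
- Pseudo-value independence is approximate; inference at very small group
  sizes (< ~20) should be treated as exploratory.
- Only two-level conditions are supported; no variable selection is
  performed (all supplied covariates enter the model).
- EBS assumes the null p-values are roughly uniform; families of highly
  dependent tests can distort π̂₀.
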