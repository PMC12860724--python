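# Methods

This note documents the models, algorithms and design choices behind
`ccnet`: what each stage assumes, which parameters matter, what the
synthetic cohort generator does and does not emulate, and the numerical
conventions the implementation fixes where the field's software differs.

## The analysis in one paragraph

The pipeline compares structural cognitive-control brain networks and a
latent cognitive-control construct between adults born very preterm (VPT)
and at full term (FT).  Per subject, a 66-region streamline-count matrix
is normalised by tract length, symmetrised, and proportionally thresholded
at densities 5%–50% in 5% steps (ten graphs per subject).  Average binary
degree, average clustering and weighted global efficiency are computed at
every density, z-standardised across the pooled sample, and compared
between groups with two-tailed t-tests, Benjamini–Hochberg corrected over
the 30-cell (metric × density) family; node-wise weighted betweenness is
compared at 50% density in its own 66-test family.  Cognitive control is
modelled as two correlated latent factors ("speed of cognitive control",
five indicators; "sustained attention", two indicators with equal
loadings) estimated by normal-theory maximum likelihood; group differences
in latent means are tested after establishing (at least partial) strong
measurement invariance; brain–behaviour associations regress the latent
factors on density-aggregated topology metrics with loadings fixed to the
pooled measurement model.  Scanner effects can be removed with
empirical-Bayes ComBat on balanced subsamples.

## Connectome construction

* **Weights.** `w_ij = counts_ij / length_ij`, zeros preserved; the
  matrix is then symmetrised by averaging the two triangles.  A positive
  count over a non-positive length is treated as corrupt input, not
  repaired.
* **Proportional thresholding.** At density `t` the `K = ceil(t·n(n−1)/2)`
  largest-weight edges are retained with their weights (no binarisation).
  The ceiling rule makes achieved density ≥ nominal and monotone in `t`;
  ties are broken by lexicographic node-index order so sweeps are nested
  and platform-independent.  Subjects whose positive-edge count falls
  below `K` keep all their edges — this deliberate property, not a defect,
  is the mechanism that makes binary degree differ between groups only at
  high densities.
* **Metrics.** Binary average degree `2|E|/n`; average clustering in
  binary (default for group contrasts; nodes of degree < 2 contribute 0),
  Onnela and Barrat variants (both reduce to binary on unit weights);
  weighted global efficiency as the mean inverse geodesic distance with
  edge distance `d = 1/w` (disconnected pairs contribute 0; the rule is
  injectable); weighted betweenness via Brandes' algorithm with Dijkstra
  searches, endpoint pairs excluded.  Shortest paths use
  `scipy.sparse.csgraph`; clustering and betweenness are first-principles
  implementations cross-checked in the tests against exhaustive path/
  triangle enumeration and against networkx.
* **z-standardisation** uses the sample SD (n−1) pooled over both groups,
  so each column's weighted mean is zero and group means sit on opposite
  sides of it.  A column that is constant because every subject saturates
  the edge quota maps to zeros under the pipeline's `on_constant="zero"`
  policy (the library default is to raise).

## Group contrasts

Student's two-sample t-test is the default (the Welch variant is
selectable); Cohen's d always uses the pooled SD with `n1+n2−2`
denominator and is signed VPT − FT, so negative d means the VPT group is
lower.  FDR correction is Benjamini–Hochberg, applied separately to the
30-contrast global family and the 66-contrast betweenness family — the
two families are never merged.  Subject screening drops cases with more
than 50% missing behavioural indicators or an unusable connectome;
outlier flagging marks observations strictly beyond 3 sample SDs on
either member of a brain/behaviour pair but never excludes them itself.

## SEM engine

The engine estimates multi-group structural equation models by direct
minimisation of the ML discrepancy

    F = Σ_g (n_g/N) [ ln|Σ_g| − ln|S_g| + tr(S_g Σ_g⁻¹) − p
                      + (x̄_g − μ_g)' Σ_g⁻¹ (x̄_g − μ_g) ]

with implied moments `Σ = Λ(ΓΦ_xΓ' + Ψ)Λ' + Θ`,
`μ = τ + Λ(α + Γκ)` (predictors, when present, are modelled as exogenous
observed variables with saturated moments).  Conventions and choices:

* **Identification.** Reference-group standardisation: first-group latent
  variances fixed at 1 and latent means at 0; non-reference latent
  variances and means are freed exactly when invariance constraints make
  them estimable (variances under weak, means under strong invariance).
  When loadings are fixed a priori (brain–behaviour models) the latent
  scale is anchored by the loadings and all latent (disturbance)
  variances are free.
* **Equality constraints** are shared parameter labels; the model's df is
  literally "sample moments minus distinct free labels", which is how the
  14-df single-group and 36-df two-group partial-strong values arise.
* **Positivity.** Residual and latent variances are log-parameterised;
  a non-positive-definite implied covariance is penalised (objective
  `1e8`), not fatal, so the optimiser backs off rather than crashing.
* **Optimisation.** L-BFGS-B from a crude data-driven start (loadings
  `0.7·sd`, residuals at half the sample variance, intercepts at sample
  means) plus jittered restarts (5 by default, deterministic per seed);
  the best optimum is kept and the convergence flag is honest.
* **Test statistic.** `T = (N − G)·F` (single group: `(N−1)F`), with the
  plain `N·F` convention available as a switch; SEM packages differ here,
  which is why the acceptance surface uses df and parameter recovery,
  both convention-free.
* **Missing data.** FIML sums the casewise log-likelihood over
  missingness patterns; the saturated log-likelihood for the statistic
  comes from an EM estimate of the unstructured MVN.  On complete data
  FIML and moment-based ML coincide (tested to 1e−4).
* **Fit indices.** CFI against an independence baseline (free variances
  and means, zero covariances — closed form for complete data, univariate
  MLEs under FIML); RMSEA `sqrt(G)·sqrt(max(χ²−df,0)/(df(N−1)))`
  (multi-group convention); SRMR as the n-weighted RMS of sample-vs-
  implied correlation residuals plus standardised mean residuals when
  means are modelled.
* **Standard errors** from the inverse expected information, assembled
  from a central-difference Jacobian of the implied moments and the
  normal-theory weight matrix `0.5·D'(Σ⁻¹⊗Σ⁻¹)D` (plus `Σ⁻¹` for means).
* **Invariance ladder.** configural → weak (equal loadings) → strong
  (equal intercepts), each compared to its predecessor by χ² difference.
  If strong is rejected at α = 0.05, the single intercept whose release
  most reduces the discrepancy (full refit search over indicators) is
  freed, giving partial strong invariance; the search releases one
  intercept, mirroring how a two-indicator factor's identification and a
  single offending indicator are handled in practice.
* **Latent mean test.** The accepted model is refit with non-reference
  latent means constrained to zero; Δχ² with 2 df.  Estimates are
  differences from the reference group in latent SD units.
* **Latent regressions.** Predictors are z-scored; loadings fixed;
  standardised paths are `γ̂·sd(x)/sd(η)` from the implied moments, with
  Wald p-values carried over from the unstandardised coefficient.  With
  the equality flag one pooled path is estimated and a likelihood-ratio
  test of group equality attached.
* **Robust (MLR) corrections are not implemented**; plain ML is used
  throughout.  Robustness scaling alters test statistics, not estimates,
  and every quantitative check in this package is an estimate or a df.

## Synthetic cohort generator

The generator produces cohorts (default 79 FT / 61 VPT, 66 nodes) whose
downstream behaviour under this pipeline reproduces the qualitative and
quantitative structure of the study data, with full ground truth.  One
seed spawns a fixed hierarchy of RNG streams (behaviour, covariates, one
per subject), so a spec is bit-reproducible and adding subjects never
reshuffles earlier ones.

**Atlas.** Node coordinates are canonical per node count — two mirrored
hemispheric blocks with the eight bilateral subcortical regions (caudate,
putamen, thalamus, cerebellum) labelled explicitly — and do not depend on
the cohort seed, just as a parcellation atlas is fixed across studies.
Per-subject anatomy varies through a coordinate jitter (sd 0.12 in
coordinate units) and a per-subject presence-decay-length factor
(lognormal sd 0.4), which together supply realistic between-subject
variance in clustering and efficiency.

**Edge model (hurdle-Poisson).** A node pair is present with probability
`1 − exp(−A·r_ij)` where `r` decays exponentially with inter-node
distance (decay length 0.6) and `A` is solved by bisection so the
expected raw density matches the subject's target — the group default
(FT 0.55, VPT 0.40; the study does not report raw densities, so these are
free parameters of the emulation) plus N(0, 0.04) subject jitter.  Both
groups share the identical below-median presence field; the VPT deficit
and the jitter are carried entirely by the beyond-median block, so the
group difference in raw density is concentrated in long-range
connections.  For present pairs each directed count is
`1 + Poisson(λ_ij)` with magnitude growing sub-linearly with tract length
below the median distance (normalised weight ≈ `d^−0.6`, making path cost
`1/w` concave in distance so mid-range tracts are genuine shortcuts) and
decaying steeply beyond it (`d^−1.8`), scaled by `count_scale = 300` at
the median length, a per-subject lognormal factor (sd 0.12), a small
per-edge lognormal factor (sd 0.02), and the scanner gain.  Tract lengths
are Euclidean distances with symmetric lognormal tortuosity (sd 0.03).

**VPT weight attenuation.** VPT edge magnitudes are attenuated by
`exp(−γ·max(0, q_on − q))` where `q` is the edge's percentile in the
subject's own weight ordering (γ = 3.0, onset percentile 0.6): the
weakest — predominantly longest — tracts are most attenuated while the
strongest core is untouched.  Because the factor is monotone in the
subject's weight ranking, proportional thresholding retains (to close
approximation) the same edge sets as without attenuation: binary metrics
are driven by presence structure alone, while weighted efficiency loses
ground progressively as the density quota digs into the attenuated range.
A distance-formula attenuation was evaluated first and rejected: any
multiplier deterministic in distance competes with ranking noise,
systematically re-composes the thresholded edge sets, and manufactures
binary-clustering group differences that the study does not show.

**Hub perturbation.** VPT edges incident to the right caudate get a ×1.3
magnitude boost, raising that node's weighted betweenness in the VPT
group at 50% density above the background of attenuation-induced
centrality shifts.

**Behaviour.** Latent scores are bivariate normal with unit variances,
correlation 0.564, FT means 0 and VPT means (−0.742, 0); indicators are
`y_j = τ_j + λ_j η_{f(j)} + ε_j` with population loadings
(0.471, 0.379, 0.459, 0.902, 0.836, 0.715, 0.715) — indicators 1–5 on the
speed factor, 6–7 on sustained attention with equal loadings — and
residual SDs completing unit indicator variances.  With a non-zero
coupling β the first latent score becomes
`mean + β·x + sqrt(1−β²)·disturbance`, where `x` is the subject's own
z-scored, density-averaged subcortical-subnetwork clustering; the default
is β = 0.  An optional monotone skew transform
(`(exp(s·z)−1)/s`) and MCAR missingness are applied afterwards; both
default off and are switched on only in the tests that exercise them.

**Covariates and scanners.** Group-conditional covariates are loose
caricatures used for plumbing (e.g. gestational age N(40,1) FT vs
N(30,1.9) VPT); intensity-of-neonatal-treatment and ventilation exist
only for VPT rows.  Four scanner batches with frequencies echoing a
two-site design carry multiplicative count gains (0.90–1.10), the target
of the ComBat stage.

**What the generator does not emulate.** No diffusion signal,
tractography or anatomy beyond two mirrored point clouds; no
non-normality of connectome weights beyond the hurdle-lognormal-Poisson
construction; missingness is MCAR where the study's indicators were
plausibly MAR; indicator skew is a stylised monotone transform.  Passing
tests therefore validate the pipeline's statistics and its mechanism
reproduction on data with the study's *structure*, not inferences about
any real cohort.

**Known limitation.** A small systematic composition effect in binary
clustering (d ≈ +0.3 at mid densities) survives the design; it stays
below FDR significance in the typical cohort draw but crosses it in a
minority of seeds.  Degree and efficiency deficits, by contrast, appear
robustly and only at upper densities (degree 40–50%, efficiency 25–50%),
with the VPT group lower — the study's pattern.

## ComBat harmonisation

Location-scale ComBat with parametric empirical Bayes: feature-wise OLS
on batch indicators plus protected covariates; standardisation by the
pooled residual variance; per-batch additive (γ) and multiplicative (δ²)
effects shrunk by moment-matched normal and inverse-gamma priors via the
standard iterative conditional-mode solution; adjust and restore scale.
Per-batch scale uses the MLE (1/n_b) so a single homogeneous batch
round-trips exactly; Bioconductor `sva::ComBat` (which uses n−1) agrees
cellwise to O(1/n), verified in a test that shells out to Rscript.
Batches with fewer than two subjects are refused; constant features pass
through with a warning.  Balanced subsampling downsamples the larger
group per scanner to the smaller one and drops scanners whose smaller
group is below a floor (default 4, mirroring exclusion of scanners with
n = 3).  In the harmonised pipeline, ComBat is applied to the
subject × edge weight table with group and sex protected, adjusted
weights are clipped at zero, and the metric contrasts are recomputed per
subsample.

## Problem sizes in the test suite

Monte-Carlo suites are sized to keep the default `pytest` run fast while
leaving estimator checks well-powered; the sizes are the package's own
choices and are stated here so they can be scaled up: loading/factor-
correlation recovery at n = 5000; latent-mean recovery at n = 2500 per
group; brain–behaviour path recovery over 500 cohorts of n = 140 with
24-node connectomes (the subcortical subnetwork is complete at ≥ 8
nodes, so the feature of interest is unchanged); null FDR calibration
over 300 cohorts of 20 + 20 subjects and 16 nodes; invariance LR-test
calibration over 150 replicates at the study's 79/61 sizes; metric
oracles exhaustively up to 6 nodes.  The acceptance script runs the full
66-node, 2500-per-group recovery.
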