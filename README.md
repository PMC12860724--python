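# ccnet

Structural cognitive-control connectome topology and latent-variable
group analysis for very-preterm (VPT) versus full-term (FT) adult
cohorts, with a seeded synthetic cohort generator.

## The problem

Adults born very preterm show lasting deficits in cognitive control.
Two data streams speak to this: diffusion-MRI structural connectomes of
the cognitive-control network (66 regions, streamline counts and tract
lengths per region pair) and a battery of seven behavioural indicators.
`ccnet` implements the complete analysis chain linking them:

1. **Connectome build** — normalise streamline counts by tract length
   (`w_ij = c_ij / L_ij`), symmetrise, and proportionally threshold at
   densities t = 5%, 10%, …, 50% (retain the `K = ⌈t·n(n−1)/2⌉`
   strongest edges), yielding ten graphs per subject.
2. **Graph metrics** — average binary degree `2|E|/n`, average
   clustering coefficient `C` (binary, Onnela, Barrat), weighted global
   efficiency `E_glob = mean(1/d_ij)` with edge distance `1/w`, and
   weighted betweenness centrality `b_v` (Brandes).
3. **Group contrasts** — per (metric, density) cell, two-tailed t-tests
   with Cohen's d (sign VPT − FT), Benjamini–Hochberg FDR over the
   30-cell family; node-wise betweenness at 50% density in its own
   66-test family.
4. **Latent-variable engine** — a multi-group ML SEM implementation:
   cognitive control as two correlated factors
   (`Σ = ΛΦΛ' + Θ`, `μ = τ + Λα`), the measurement-invariance ladder
   (configural → weak → strong, with a single-intercept release to
   partial strong when needed), latent mean differences in SD units,
   FIML for missing indicators, CFI/RMSEA/SRMR, and latent-on-brain
   regressions with a priori fixed loadings.
5. **Harmonisation** — location-scale ComBat with empirical-Bayes
   shrinkage on subject × edge weight tables, run on group-balanced
   scanner subsamples.

The cohort that motivates this pipeline is access-restricted, so the
package ships a generator (`ccnet.cohort`) that emulates its structure —
group sizes 79/61, a long-range-concentrated connectome density deficit,
a right-caudate hub perturbation, and indicators from a two-factor model
with a −0.742 SD latent shift — with every generating parameter recorded
as ground truth.  All statistical machinery is validated against that
truth; see `docs/methods.md` for the model and every numerical
convention.

## Worked example

```python
from ccnet.cohort import CohortSpec, generate_cohort
from ccnet.connectome import build_network
from ccnet.metrics import compute_metric_table, zstandardise
from ccnet.stats import compare_global_metrics
from ccnet.sem import fit_invariance_ladder, latent_mean_test

spec = CohortSpec(seed=1)          # 79 FT + 61 VPT, 66 nodes
bundle = generate_cohort(spec)

networks = [build_network(raw) for raw in bundle.subjects]
ztable = zstandardise(compute_metric_table(networks), on_constant="zero")
groups = bundle.table.set_index("id")["group"]
contrasts = compare_global_metrics(ztable, groups)
print(contrasts[contrasts.p_fdr <= 0.05].round(3).to_string(index=False))

ladder = fit_invariance_ladder(bundle.table, seed=1)
lm = latent_mean_test(ladder, bundle.table, seed=1)
print(ladder.summary())
print(lm.summary())
```

prints

```
    metric  density  mean_ft  mean_vpt  t_statistic    df  p_raw  cohen_d  p_fdr
    degree     0.40    0.303    -0.392       -4.327 138.0  0.000   -0.737  0.000
    degree     0.45    0.623    -0.807      -11.893 138.0  0.000   -2.027  0.000
    degree     0.50    0.786    -1.018      -23.891 138.0  0.000   -4.072  0.000
efficiency     0.25    0.199    -0.258       -2.747 138.0  0.007   -0.468  0.023
efficiency     0.30    0.290    -0.375       -4.121 138.0  0.000   -0.702  0.000
efficiency     0.35    0.347    -0.449       -5.065 138.0  0.000   -0.863  0.000
efficiency     0.40    0.381    -0.493       -5.670 138.0  0.000   -0.967  0.000
efficiency     0.45    0.397    -0.515       -5.982 138.0  0.000   -1.020  0.000
efficiency     0.50    0.402    -0.521       -6.071 138.0  0.000   -1.035  0.000
Measurement invariance ladder
  configural      chi2(28) = 33.051, CFI = 0.979, RMSEA = 0.051
  weak            chi2(32) = 34.146, CFI = 0.991, RMSEA = 0.031
  strong          chi2(37) = 37.836, CFI = 0.997, RMSEA = 0.018
  weak vs configural           dchi2 = 1.095, ddf = 4, p = 0.8951
  strong vs weak               dchi2 = 3.690, ddf = 5, p = 0.5948
  final model: strong
Latent mean test: dchi2(2) = 14.872, p = 0.0005896
  alpha_speed_g1: -0.543 (SE 0.185)
  alpha_attention_g1: +0.284 (SE 0.280)
```

Reading this: the VPT group has significantly lower binary degree only
at 40–50% density and lower weighted global efficiency from 25% density
upward (negative d = VPT lower), while clustering shows no FDR
discovery at any density — lower network integration with preserved
segregation.  The behavioural indicators support strong measurement
invariance, and the VPT group sits 0.54 SD lower on the latent speed
factor in this single 140-subject draw (the generating value is
−0.742; a study-sized cohort estimates it with SE ≈ 0.19).

The same analysis runs from the shell:

```
ccnet --config cfg.yaml simulate     # write <id>_counts.tsv / _lengths.tsv + subjects.csv
ccnet --config cfg.yaml analyse      # contrasts, SEMs, report.md under output_dir
ccnet --config cfg.yaml harmonise    # ComBat on balanced scanner subsamples
```

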