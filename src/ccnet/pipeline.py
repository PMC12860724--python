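"""End-to-end analysis pipeline mirroring the study's analysis sequence.

Stages: subject screening -> connectome build -> density sweep -> graph
metrics -> pooled z-standardisation -> global metric contrasts (3 metrics
x 10 densities, one FDR family) -> node betweenness contrasts at 50%
density (one 66-test family) -> pooled measurement model -> measurement
invariance ladder -> latent mean test -> density-aggregated
brain-behaviour SEMs (full network, then the subcortical subnetwork) ->
covariate regressions.  Every number in the markdown report is read back
from a CSV/JSON artefact written by the stage that computed it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import DataError, InvalidParameterError
from .cohort import (
    INDICATORS,
    INDICATOR_FACTOR,
    CohortBundle,
    CohortSpec,
    generate_cohort,
    subcortical_labels,
)
from .connectome import DEFAULT_DENSITIES, WeightedNetwork, build_network
from .harmonize import balanced_subsample, harmonise_combat
from .metrics import (
    MetricTable,
    aggregate_densities,
    compute_betweenness_table,
    compute_metric_table,
    zstandardise,
)
from .sem import (
    factor_scores,
    fit_invariance_ladder,
    fit_measurement_model,
    latent_mean_test,
    regress_latent_on_predictor,
)
from .stats import (
    compare_betweenness,
    compare_global_metrics,
    fdr_bh,
    screen_subjects,
    significance_summary,
)

log = logging.getLogger("ccnet")

#: Fit verdict thresholds applied in the report.
FIT_CRITERIA = {"chi2_df_ratio": 2.5, "rmsea": 0.08, "srmr": 0.08, "cfi": 0.90}


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    input_dir: str = "cohort"
    output_dir: str = "results"
    densities: tuple = DEFAULT_DENSITIES
    clustering_variant: str = "binary"
    betweenness_density: float = 0.50
    t_variant: str = "student"
    alpha: float = 0.05
    subsamples: int = 5
    subsample_floor: int = 4
    seed: int = 0
    covariates: tuple = ("sex", "ses", "optimality", "head_circumference")
    vpt_only_covariates: tuple = ("inti", "ventilation")
    cohort: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config key(s): {sorted(unknown)}")
        if "cohort" in raw:
            spec_fields = {f.name for f in dataclasses.fields(CohortSpec)}
            bad = set(raw["cohort"]) - spec_fields
            if bad:
                raise InvalidParameterError(f"unknown cohort key(s): {sorted(bad)}")
        for key in ("densities", "covariates", "vpt_only_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, **self.cohort)


def run_simulate(cfg: PipelineConfig) -> CohortBundle:
    """Generate a cohort from the config and write it to ``input_dir``."""
    spec = cfg.cohort_spec()
    log.info("simulating cohort: %d FT + %d VPT, seed %d", spec.n_ft, spec.n_vpt, spec.seed)
    bundle = generate_cohort(spec)
    bundle.to_dir(cfg.input_dir)
    log.info("wrote %d subjects to %s", len(bundle.subjects), cfg.input_dir)
    return bundle


def _verdict(chi2, df, cfi, rmsea, srmr) -> dict:
    return {
        "chi2_df_ok": bool(df > 0 and chi2 / df < FIT_CRITERIA["chi2_df_ratio"]),
        "rmsea_ok": bool(rmsea <= FIT_CRITERIA["rmsea"]),
        "srmr_ok": bool(srmr <= FIT_CRITERIA["srmr"]),
        "cfi_ok": bool(cfi >= FIT_CRITERIA["cfi"]),
    }


def _fit_record(fit) -> dict:
    d = fit.to_dict()
    d["verdict"] = _verdict(d["chi_square"], d["df"], d["cfi"], d["rmsea"], d["srmr"])
    return d


def _build_networks(bundle: CohortBundle, retained) -> list[WeightedNetwork]:
    return [build_network(raw) for raw in bundle.subjects if raw.subject_id in set(retained)]


def run_analyse(cfg: PipelineConfig, bundle: CohortBundle | None = None) -> dict:
    """Run the full analysis; returns the result record written to disk."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = CohortBundle.from_dir(cfg.input_dir)
    results: dict = {}

    # -- screening -------------------------------------------------------
    retained, exclusions = screen_subjects(bundle)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    table = bundle.table.set_index("id").loc[retained]
    groups = table["group"]
    log.info("screening: retained %d / %d subjects", len(retained), len(bundle.subjects))
    results["n_retained"] = len(retained)

    # -- connectomes and metrics -----------------------------------------
    nets = _build_networks(bundle, retained)
    mt = compute_metric_table(nets, cfg.densities, cfg.clustering_variant)
    mt.to_csv(out / "metrics_raw.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zt = zstandardise(mt, on_constant="zero")
    zt.to_csv(out / "metrics_z.csv")

    contrasts = compare_global_metrics(zt, groups, cfg.t_variant)
    contrasts.to_csv(out / "global_contrasts.csv", index=False)
    (out / "global_contrasts.txt").write_text(significance_summary(contrasts, cfg.alpha))

    btable = compute_betweenness_table(nets, cfg.betweenness_density)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zb = zstandardise(btable, on_constant="zero")
    bc = compare_betweenness(zb, groups, cfg.t_variant)
    bc.to_csv(out / "betweenness_contrasts.csv", index=False)
    log.info(
        "contrasts: %d global, %d node-wise", len(contrasts), len(bc)
    )

    # -- measurement model and invariance --------------------------------
    data = table.reset_index()
    pooled = fit_measurement_model(data, seed=cfg.seed)
    results["measurement_model"] = _fit_record(pooled)
    ladder = fit_invariance_ladder(data, alpha=cfg.alpha, seed=cfg.seed)
    results["invariance"] = {
        "levels": {k: _fit_record(v) for k, v in ladder.fits.items()},
        "tests": ladder.tests.to_dict(orient="records"),
        "released": list(ladder.released),
        "final": ladder.final_level,
    }
    lm = latent_mean_test(ladder, data, seed=cfg.seed)
    results["latent_means"] = {
        "dchi2": lm.dchi2,
        "ddf": lm.ddf,
        "p": lm.p,
        "estimates": dict(lm.means),
        "se": dict(lm.se),
    }
    log.info("latent mean test: dchi2(%d) = %.3f, p = %.4g", lm.ddf, lm.dchi2, lm.p)

    # -- brain-behaviour SEMs --------------------------------------------
    loadings = {
        ind: float(pooled.params[f"lambda_{_eq_name(ind)}_g0"]) for ind in INDICATORS
    }
    agg = aggregate_densities(zt)
    for metric in agg.columns:
        data[f"net_{metric}"] = agg[metric].reindex(data["id"]).to_numpy()
    sub_mt = compute_metric_table(
        nets, cfg.densities, cfg.clustering_variant,
        node_subset=subcortical_labels(nets[0].labels),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub_agg = aggregate_densities(zstandardise(sub_mt, on_constant="zero"))
    data["subnet_clustering"] = sub_agg["clustering"].reindex(data["id"]).to_numpy()

    bb_rows = []
    for feature in ["net_clustering", "net_degree", "net_efficiency"]:
        reg = regress_latent_on_predictor(
            data, feature, loadings, groups=("FT", "VPT"), seed=cfg.seed
        )
        for key in reg.beta.index:
            bb_rows.append(
                {"feature": feature, "path": key, "beta": reg.beta[key],
                 "se": reg.se[key], "p_raw": reg.p[key]}
            )
    bb = pd.DataFrame(bb_rows)
    bb["p_fdr"] = fdr_bh(bb["p_raw"])
    bb["meaningful"] = bb["beta"].abs() > 0.1
    bb.to_csv(out / "brain_behaviour.csv", index=False)

    sub_reg = regress_latent_on_predictor(
        data, "subnet_clustering", loadings, groups=("FT", "VPT"), seed=cfg.seed
    )
    sub_df = pd.DataFrame(
        {"path": sub_reg.beta.index, "beta": sub_reg.beta.values,
         "se": sub_reg.se.values, "p_raw": sub_reg.p.values}
    )
    sub_df["p_fdr"] = fdr_bh(sub_df["p_raw"])
    sub_df.to_csv(out / "subnetwork_brain_behaviour.csv", index=False)

    # factor scores for the bivariate visualisation surface
    scores = factor_scores(ladder.final, data)
    scores.insert(0, "id", data["id"].to_numpy())
    scores.to_csv(out / "factor_scores.csv", index=False)

    # -- covariate adjustment models (one SEM per covariate) -------------
    cov_rows = []
    for cov in cfg.covariates:
        sub = data.dropna(subset=[cov]).copy()
        if cov == "sex":
            sub[cov] = (sub[cov] == "F").astype(float)
        reg = regress_latent_on_predictor(
            sub, cov, loadings, groups=("FT", "VPT"), seed=cfg.seed
        )
        for key in reg.beta.index:
            cov_rows.append(
                {"covariate": cov, "sample": "both", "path": key,
                 "beta": reg.beta[key], "p_raw": reg.p[key]}
            )
    for cov in cfg.vpt_only_covariates:
        sub = data[data["group"] == "VPT"].dropna(subset=[cov]).copy()
        if sub[cov].std() == 0:
            continue
        reg = regress_latent_on_predictor(sub, cov, loadings, groups=None, seed=cfg.seed)
        for key in reg.beta.index:
            cov_rows.append(
                {"covariate": cov, "sample": "VPT", "path": key,
                 "beta": reg.beta[key], "p_raw": reg.p[key]}
            )
    cov_df = pd.DataFrame(cov_rows)
    if len(cov_df):
        cov_df["p_fdr"] = fdr_bh(cov_df["p_raw"])
    cov_df.to_csv(out / "covariate_models.csv", index=False)

    (out / "analysis.json").write_text(json.dumps(results, indent=1, default=float))
    write_report(cfg)
    return results


def _eq_name(ind: str) -> str:
    # the two sustained-attention loadings share one label (equality pair)
    return "trab" if ind == "yabcl" else ind


def run_harmonise(cfg: PipelineConfig, bundle: CohortBundle | None = None) -> dict:
    """ComBat-harmonised re-analysis on balanced scanner subsamples.

    For each of ``cfg.subsamples`` draws, the larger group is downsampled
    per scanner, the subject x edge weight table is ComBat-adjusted
    (preserving the group effect), and the global metric contrasts are
    recomputed from the adjusted networks.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = CohortBundle.from_dir(cfg.input_dir)
    retained, _ = screen_subjects(bundle)
    table = bundle.table.set_index("id").loc[retained]
    nets = _build_networks(bundle, retained)
    n = nets[0].n_nodes
    iu = np.triu_indices(n, k=1)
    wtab = pd.DataFrame(
        [net.weights[iu] for net in nets], index=[net.subject_id for net in nets]
    )
    if table["batch"].nunique() < 2:
        warnings.warn("single scanner batch: harmonisation is a no-op", stacklevel=2)
    draws = balanced_subsample(
        table["group"], table["batch"], k=cfg.subsamples,
        seed=cfg.seed, floor=cfg.subsample_floor,
    )
    summary = []
    for k, idx in enumerate(draws):
        ids = table.index[idx]
        design = pd.DataFrame(
            {
                "group": (table.loc[ids, "group"] == "VPT").astype(float),
                "sex": (table.loc[ids, "sex"] == "F").astype(float),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            adj, est = harmonise_combat(
                wtab.loc[ids], table.loc[ids, "batch"], design
            )
        adj_nets = []
        for sid in ids:
            w = np.zeros((n, n))
            w[iu] = np.clip(adj.loc[sid].to_numpy(), 0.0, None)
            w = w + w.T
            adj_nets.append(WeightedNetwork(w, nets[0].labels, subject_id=sid))
        mt = compute_metric_table(adj_nets, cfg.densities, cfg.clustering_variant)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zt = zstandardise(mt, on_constant="zero")
        contrasts = compare_global_metrics(zt, table.loc[ids, "group"], cfg.t_variant)
        contrasts.to_csv(out / f"harmonised_contrasts_s{k + 1}.csv", index=False)
        upper = contrasts[contrasts["density"] >= 0.35]
        summary.append(
            {
                "subsample": k + 1,
                "n": len(ids),
                "n_significant": int((contrasts["p_fdr"] <= cfg.alpha).sum()),
                "mean_d_degree_upper": float(
                    upper.loc[upper["metric"] == "degree", "cohen_d"].mean()
                ),
                "mean_d_efficiency_upper": float(
                    upper.loc[upper["metric"] == "efficiency", "cohen_d"].mean()
                ),
            }
        )
    rep = pd.DataFrame(summary)
    rep.to_csv(out / "harmonised_summary.csv", index=False)
    return {"subsamples": summary}


def write_report(cfg: PipelineConfig) -> str:
    """Assemble the markdown report from artefacts already on disk."""
    out = Path(cfg.output_dir)
    results = json.loads((out / "analysis.json").read_text())
    contrasts = pd.read_csv(out / "global_contrasts.csv")
    bc = pd.read_csv(out / "betweenness_contrasts.csv")
    lines = ["# Cognitive-control network analysis report", ""]

    mm = results["measurement_model"]
    lines += ["## Measurement model (pooled sample)", ""]
    lines.append(
        f"chi2({mm['df']}) = {mm['chi_square']:.3f}, p = {mm['p']:.4f}; "
        f"CFI = {mm['cfi']:.3f}, RMSEA = {mm['rmsea']:.3f}, SRMR = {mm['srmr']:.3f}"
    )
    v = mm["verdict"]
    lines.append(
        f"fit criteria: chi2/df < {FIT_CRITERIA['chi2_df_ratio']}: "
        f"{'pass' if v['chi2_df_ok'] else 'fail'}; "
        f"RMSEA <= {FIT_CRITERIA['rmsea']}: {'pass' if v['rmsea_ok'] else 'fail'}; "
        f"SRMR <= {FIT_CRITERIA['srmr']}: {'pass' if v['srmr_ok'] else 'fail'}; "
        f"CFI >= {FIT_CRITERIA['cfi']}: {'pass' if v['cfi_ok'] else 'fail'}"
    )

    inv = results["invariance"]
    lines += ["", "## Measurement invariance", ""]
    for name, rec in inv["levels"].items():
        lines.append(
            f"- {name}: chi2({rec['df']}) = {rec['chi_square']:.3f}, "
            f"CFI = {rec['cfi']:.3f}, RMSEA = {rec['rmsea']:.3f}"
        )
    for t in inv["tests"]:
        lines.append(
            f"- {t['comparison']}: dchi2 = {t['dchi2']:.3f}, "
            f"ddf = {t['ddf']:.0f}, p = {t['p']:.4f}"
        )
    if inv["released"]:
        lines.append(f"- released intercept(s): {', '.join(inv['released'])}")

    lm = results["latent_means"]
    lines += ["", "## Latent mean differences (VPT relative to FT)", ""]
    lines.append(f"equal-means test: dchi2({lm['ddf']}) = {lm['dchi2']:.3f}, p = {lm['p']:.4g}")
    for k, v_ in lm["estimates"].items():
        lines.append(f"- {k}: {v_:+.3f} SD (SE {lm['se'][k]:.3f})")

    lines += ["", "## Network topology contrasts (VPT - FT)", ""]
    sig = contrasts[contrasts["p_fdr"] <= cfg.alpha]
    lines.append(f"{len(sig)} of {len(contrasts)} (metric, density) contrasts FDR-significant:")
    for _, r in sig.iterrows():
        lines.append(
            f"- {r['metric']} at {r['density']:.0%}: d = {r['cohen_d']:+.2f}, "
            f"p_fdr = {r['p_fdr']:.4f}"
        )
    bsig = bc[bc["p_fdr"] <= cfg.alpha]
    lines += ["", f"betweenness (density 50%): {len(bsig)} of {len(bc)} nodes significant"]
    for _, r in bsig.iterrows():
        lines.append(f"- {r['node']}: d = {r['cohen_d']:+.2f}, p_fdr = {r['p_fdr']:.4f}")

    bb = pd.read_csv(out / "brain_behaviour.csv")
    sub = pd.read_csv(out / "subnetwork_brain_behaviour.csv")
    lines += ["", "## Brain-behaviour associations (density-aggregated)", ""]
    for _, r in bb.iterrows():
        lines.append(
            f"- {r['feature']} -> {r['path']}: beta = {r['beta']:+.3f}, "
            f"p_fdr = {r['p_fdr']:.4f}"
        )
    lines += ["", "### Subcortical subnetwork", ""]
    for _, r in sub.iterrows():
        lines.append(
            f"- subnet_clustering -> {r['path']}: beta = {r['beta']:+.3f}, "
            f"p_fdr = {r['p_fdr']:.4f}"
        )
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
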