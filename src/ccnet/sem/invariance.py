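"""Measurement-invariance ladder, latent mean tests, brain-behaviour
regressions and factor scores for the two-group cognitive-control model.

The ladder fits the standard sequence — configural (all measurement
parameters group-specific), weak (equal loadings), strong (equal loadings
and intercepts) — comparing neighbouring rungs with likelihood-ratio
tests.  When strong invariance is rejected, the single intercept whose
release yields the largest discrepancy drop is freed (a refit search over
indicators), giving a partial strong model.  Latent means are compared by
refitting the accepted model with the non-reference latent means
constrained to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._errors import DataError, EstimationError
from ..cohort import INDICATOR_FACTOR
from .model import SemModel, SemResults, implied_moments, lr_test
from .spec import SemModelSpec

DEFAULT_EQUALITY = (("trab", "yabcl"),)


def _fit(spec, data, group_col, method, starts, seed):
    return SemModel(spec, data, group_col=group_col).fit(
        method=method, starts=starts, seed=seed
    )


def fit_measurement_model(
    data: pd.DataFrame,
    indicator_map: dict[str, str] = INDICATOR_FACTOR,
    equality_within=DEFAULT_EQUALITY,
    method: str = "ml",
    starts: int = 5,
    seed: int = 0,
) -> SemResults:
    """Single-group (pooled) measurement model with standardised factors."""
    spec = SemModelSpec.cfa(
        indicator_map,
        groups=("all",),
        equality_within=equality_within,
        meanstructure=False,
        description="pooled measurement model",
    )
    return _fit(spec, data, None, method, starts, seed)


@dataclass
class InvarianceLadder:
    """Ordered invariance fits plus the tests that led to the final model."""

    fits: dict[str, SemResults]
    tests: pd.DataFrame
    released: tuple[str, ...]
    final_level: str

    @property
    def final(self) -> SemResults:
        return self.fits[self.final_level]

    def summary(self) -> str:
        lines = ["Measurement invariance ladder"]
        for name, fit in self.fits.items():
            lines.append(
                f"  {name:<15} chi2({fit.df}) = {fit.chi_square:.3f}, "
                f"CFI = {fit.cfi:.3f}, RMSEA = {fit.rmsea:.3f}"
            )
        for _, t in self.tests.iterrows():
            lines.append(
                f"  {t['comparison']:<28} dchi2 = {t['dchi2']:.3f}, "
                f"ddf = {t['ddf']:.0f}, p = {t['p']:.4f}"
            )
        if self.released:
            lines.append(f"  released intercept(s): {', '.join(self.released)}")
        lines.append(f"  final model: {self.final_level}")
        return "\n".join(lines)


def fit_invariance_ladder(
    data: pd.DataFrame,
    groups: tuple[str, str] = ("FT", "VPT"),
    group_col: str = "group",
    indicator_map: dict[str, str] = INDICATOR_FACTOR,
    equality_within=DEFAULT_EQUALITY,
    alpha: float = 0.05,
    method: str = "ml",
    starts: int = 3,
    seed: int = 0,
) -> InvarianceLadder:
    """Fit configural -> weak -> strong, releasing one intercept if needed."""
    common = dict(
        indicator_map=indicator_map,
        groups=groups,
        equality_within=equality_within,
        meanstructure=True,
    )

    def build(level, **kw):
        return SemModelSpec.cfa(**{**common, "invariance": level, **kw})

    fits = {
        "configural": _fit(build("configural"), data, group_col, method, starts, seed),
        "weak": _fit(build("weak"), data, group_col, method, starts, seed),
        "strong": _fit(build("strong"), data, group_col, method, starts, seed),
    }
    tests = [
        ("weak vs configural", *lr_test(fits["weak"], fits["configural"])),
        ("strong vs weak", *lr_test(fits["strong"], fits["weak"])),
    ]
    released: tuple[str, ...] = ()
    final = "strong"
    if tests[-1][3] <= alpha:
        # strong rejected: free the intercept with the largest misfit drop
        candidates = {}
        for ind in indicator_map:
            fit = _fit(
                build("strong", free_intercepts=(ind,)),
                data, group_col, method, starts, seed,
            )
            candidates[ind] = fit
        best = min(candidates, key=lambda i: candidates[i].chi_square)
        released = (best,)
        fits["partial_strong"] = candidates[best]
        tests.append(
            ("partial strong vs weak", *lr_test(fits["partial_strong"], fits["weak"]))
        )
        final = "partial_strong"
    return InvarianceLadder(
        fits=fits,
        tests=pd.DataFrame(tests, columns=["comparison", "dchi2", "ddf", "p"]),
        released=released,
        final_level=final,
    )


@dataclass
class LatentMeanTest:
    """Free-means vs equal-means comparison plus the mean estimates."""

    dchi2: float
    ddf: int
    p: float
    means: pd.Series  # non-reference latent mean estimates (SD units)
    se: pd.Series
    fit_free: SemResults
    fit_equal: SemResults

    def summary(self) -> str:
        lines = [
            f"Latent mean test: dchi2({self.ddf}) = {self.dchi2:.3f}, p = {self.p:.4g}"
        ]
        for lab in self.means.index:
            lines.append(f"  {lab}: {self.means[lab]:+.3f} (SE {self.se[lab]:.3f})")
        return "\n".join(lines)


def latent_mean_test(
    ladder: InvarianceLadder,
    data: pd.DataFrame,
    groups: tuple[str, str] = ("FT", "VPT"),
    group_col: str = "group",
    indicator_map: dict[str, str] = INDICATOR_FACTOR,
    equality_within=DEFAULT_EQUALITY,
    method: str = "ml",
    starts: int = 3,
    seed: int = 0,
) -> LatentMeanTest:
    """Compare the accepted invariance model against equal latent means.

    Requires at least partial strong invariance; the free-means estimates
    are differences from the reference group in latent SD units.
    """
    if ladder.final_level not in ("strong", "partial_strong"):
        raise EstimationError("latent mean test needs (partial) strong invariance")
    spec_equal = SemModelSpec.cfa(
        indicator_map,
        groups=groups,
        equality_within=equality_within,
        invariance="strong",
        free_intercepts=ladder.released,
        meanstructure=True,
        latent_means="zero",
    )
    fit_free = ladder.final
    fit_equal = _fit(spec_equal, data, group_col, method, starts, seed)
    dchi, ddf, p = lr_test(fit_equal, fit_free)
    mean_labels = [l for l in fit_free.params.index if l.startswith("alpha_")]
    return LatentMeanTest(
        dchi2=dchi,
        ddf=ddf,
        p=p,
        means=fit_free.params[mean_labels],
        se=fit_free.bse[mean_labels],
        fit_free=fit_free,
        fit_equal=fit_equal,
    )


# ---------------------------------------------------------------------------
# latent-on-predictor regressions


@dataclass
class LatentRegression:
    """Standardised structural paths of factors on an observed predictor."""

    beta: pd.Series  # standardised path per (factor[, group])
    se: pd.Series
    p: pd.Series
    fit: SemResults
    equality_test: tuple[float, int, float] | None = None

    def summary(self) -> str:
        lines = ["Latent regression (standardised paths)"]
        for lab in self.beta.index:
            lines.append(
                f"  {lab}: beta = {self.beta[lab]:+.3f} "
                f"(SE {self.se[lab]:.3f}, p = {self.p[lab]:.4f})"
            )
        if self.equality_test is not None:
            d, ddf, p = self.equality_test
            lines.append(f"  group-equality LR test: dchi2({ddf}) = {d:.3f}, p = {p:.4f}")
        return "\n".join(lines)


def _standardised_paths(fit: SemResults) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Convert raw gamma estimates to standardised betas per group.

    beta_std = gamma * sd(x) / sd(eta_total); the Wald p-value of the raw
    coefficient carries over (the rescaling is a smooth monotone map).
    """
    spec = fit.spec
    rows, ses, ps = {}, {}, {}
    pvals = fit.pvalues()
    for g, mats in enumerate(fit.group_matrices()):
        gam, phx, psi = mats["gamma"], mats["phi_x"], mats["psi"]
        c = gam @ phx @ gam.T + psi
        for a, fac in enumerate(spec.factors):
            for b, pred in enumerate(spec.predictors):
                for lab in (f"beta_{fac}_{pred}", f"beta_{fac}_{pred}_g{g}"):
                    if lab in fit.params.index:
                        scale = np.sqrt(phx[b, b] / c[a, a])
                        key = lab.replace("beta_", "")
                        rows[key] = fit.params[lab] * scale
                        ses[key] = fit.bse[lab] * scale
                        ps[key] = pvals[lab]
    return pd.Series(rows), pd.Series(ses), pd.Series(ps)


def regress_latent_on_predictor(
    data: pd.DataFrame,
    predictor: str,
    fixed_loadings: dict[str, float],
    groups: tuple[str, ...] | None = None,
    group_col: str = "group",
    indicator_map: dict[str, str] = INDICATOR_FACTOR,
    equality: bool = True,
    method: str = "ml",
    starts: int = 3,
    seed: int = 0,
) -> LatentRegression:
    """Regress the latent factors on a z-scored observed predictor.

    Loadings are fixed (to a-priori measurement-model estimates or truth),
    which anchors the latent scale and leaves latent disturbance variances
    free.  With ``equality`` the paths are pooled across groups and an LR
    test of group equality is attached.
    """
    col = data[predictor].to_numpy(dtype=float)
    finite = col[np.isfinite(col)]
    if abs(finite.mean()) > 0.2 or abs(finite.std(ddof=1) - 1.0) > 0.2:
        data = data.copy()
        data[predictor] = (col - finite.mean()) / finite.std(ddof=1)
    use_groups = groups if groups is not None else ("all",)

    def build(equal_paths):
        return SemModelSpec.cfa(
            indicator_map,
            groups=use_groups,
            fixed_loadings=fixed_loadings,
            meanstructure=False,
            predictors=(predictor,),
            equal_paths=equal_paths,
            description=f"latent regression on {predictor}",
        )

    gc = group_col if groups is not None else None
    fit = _fit(build(equality), data, gc, method, starts, seed)
    eq_test = None
    if equality and groups is not None and len(groups) > 1:
        fit_free = _fit(build(False), data, gc, method, starts, seed)
        eq_test = lr_test(fit, fit_free)
    beta, se, p = _standardised_paths(fit)
    return LatentRegression(beta=beta, se=se, p=p, fit=fit, equality_test=eq_test)


# ---------------------------------------------------------------------------
# factor scores


def factor_scores(
    fit: SemResults, data: pd.DataFrame, method: str = "regression",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-subject factor scores from a converged fit.

    ``regression`` (empirical-Bayes) scores shrink toward the latent mean;
    ``bartlett`` scores are the GLS unbiased variant.  Rows with any
    missing indicator use the observed sub-vector (regression method only).
    """
    if not fit.converged:
        raise EstimationError("refusing to score from a non-converged fit")
    spec = fit.spec
    mats_all = fit.group_matrices()
    out = np.full((len(data), len(spec.factors)), np.nan)
    for g, gname in enumerate(spec.groups):
        mats = mats_all[g]
        rows = (
            np.flatnonzero((data[group_col] == gname).to_numpy())
            if len(spec.groups) > 1
            else np.arange(len(data))
        )
        x = data.iloc[rows][list(spec.observed)].to_numpy(dtype=float)
        lam, th = mats["lambda"], mats["theta"]
        sigma, mu = implied_moments(mats)
        gam, phx = mats["gamma"], mats["phi_x"]
        c = mats["psi"] + (gam @ phx @ gam.T if phx.size else 0.0)
        eta_mean = mats["alpha"] + (gam @ mats["kappa"] if phx.size else 0.0)
        # cov(eta, observed)
        cov_ey = c @ lam.T
        cov = cov_ey if phx.size == 0 else np.hstack([cov_ey, gam @ phx])
        if method == "regression":
            for i, row in enumerate(x):
                obs = np.flatnonzero(np.isfinite(row))
                if obs.size == 0:
                    continue
                sub = sigma[np.ix_(obs, obs)]
                out[rows[i]] = eta_mean + cov[:, obs] @ np.linalg.solve(
                    sub, row[obs] - mu[obs]
                )
        elif method == "bartlett":
            thi = np.diag(1.0 / th)
            a = np.linalg.solve(lam.T @ thi @ lam, lam.T @ thi)
            yc = x[:, : len(spec.indicators)] - mats["tau"]
            sc = yc @ a.T
            sc[~np.isfinite(yc).all(axis=1)] = np.nan
            out[rows] = sc
        else:
            raise DataError(f"unknown factor-score method {method!r}")
    return pd.DataFrame(out, index=data.index, columns=list(spec.factors))
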