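"""Normal-theory maximum-likelihood estimation of structural equation models.

The model is estimated by direct minimisation of the multi-group ML
discrepancy

    F = sum_g (n_g / N) * [ ln|Sigma_g| - ln|S_g| + tr(S_g Sigma_g^-1) - p
                            + (xbar_g - mu_g)' Sigma_g^-1 (xbar_g - mu_g) ]

over the free parameters (variances log-parameterised; non-positive-
definite implied covariances penalised rather than fatal), using multiple
jittered quasi-Newton starts.  The test statistic is ``T = (N - G) * F``
(single group: the familiar ``(N - 1) * F``); a documented switch selects
the plain ``N * F`` convention instead.  With missing indicator cells the
casewise (full-information) log-likelihood is maximised over missingness
patterns and the statistic is the likelihood ratio against the saturated
model, itself estimated by EM.

Standard errors come from the inverse expected information, assembled from
a numerically differentiated moment Jacobian and the normal-theory weight
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .._errors import DataError, EstimationError
from .spec import SemModelSpec

_PENALTY = 1e8
_LN2PI = math.log(2.0 * math.pi)


def implied_moments(mats: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied covariance and mean of (indicators, predictors).

    With Lambda the loadings, C = Gamma Phi_x Gamma' + Psi the total latent
    covariance, the blocks are::

        Sigma_yy = Lambda C Lambda' + diag(theta)
        Sigma_yx = Lambda Gamma Phi_x       Sigma_xx = Phi_x
        mu_y     = tau + Lambda (alpha + Gamma kappa)     mu_x = kappa
    """
    lam, psi, th = mats["lambda"], mats["psi"], mats["theta"]
    gam, phx, kap = mats["gamma"], mats["phi_x"], mats["kappa"]
    q = phx.shape[0]
    c = psi if q == 0 else gam @ phx @ gam.T + psi
    syy = lam @ c @ lam.T + np.diag(th)
    mu_y = mats["tau"] + lam @ (mats["alpha"] + (gam @ kap if q else 0.0))
    if q == 0:
        return syy, mu_y
    syx = lam @ gam @ phx
    sigma = np.block([[syy, syx], [syx.T, phx]])
    mu = np.concatenate([mu_y, kap])
    return sigma, mu


def fml_discrepancy(
    s: np.ndarray,
    xbar: np.ndarray | None,
    sigma: np.ndarray,
    mu: np.ndarray | None,
    with_means: bool = False,
) -> float:
    """Single-group normal-theory ML discrepancy (0 at a saturated fit)."""
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    if sign_s <= 0:
        raise DataError("sample covariance is singular; more data or a simpler model")
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return _PENALTY
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        return _PENALTY
    f = logdet - logdet_s + float(np.trace(s @ sigma_inv)) - p
    if with_means:
        d = xbar - mu
        f += float(d @ sigma_inv @ d)
    return f


# ---------------------------------------------------------------------------
# missing-data machinery


def _em_mvn(x: np.ndarray, max_iter: int = 500, tol: float = 1e-9):
    """EM estimate of the saturated MVN mean/covariance with missing cells."""
    n, p = x.shape
    mu = np.nanmean(x, axis=0)
    var = np.nanvar(x, axis=0)
    sigma = np.diag(np.where(var > 0, var, 1.0))
    miss = np.isnan(x)
    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.flatnonzero((miss == key).all(axis=1))
        patterns[key.tobytes()] = (np.flatnonzero(~key), rows)
    prev = -np.inf
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        ll = 0.0
        for obs, rows in patterns.values():
            xo = x[np.ix_(rows, obs)]
            if obs.size == 0:
                sum_x += mu * rows.size
                sum_xx += (sigma + np.outer(mu, mu)) * rows.size
                continue
            mis = np.setdiff1d(np.arange(p), obs)
            soo = sigma[np.ix_(obs, obs)]
            soo_inv = np.linalg.inv(soo)
            resid = xo - mu[obs]
            sign, logdet = np.linalg.slogdet(soo)
            ll += -0.5 * rows.size * (obs.size * _LN2PI + logdet) - 0.5 * float(
                np.einsum("ij,jk,ik->", resid, soo_inv, resid)
            )
            xhat = np.zeros((rows.size, p))
            xhat[:, obs] = xo
            cc = np.zeros((p, p))
            if mis.size:
                smo = sigma[np.ix_(mis, obs)]
                b = smo @ soo_inv
                xhat[:, mis] = mu[mis] + resid @ b.T
                cond = sigma[np.ix_(mis, mis)] - b @ smo.T
                cc[np.ix_(mis, mis)] = cond * rows.size
            sum_x += xhat.sum(axis=0)
            sum_xx += xhat.T @ xhat + cc
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        mu, sigma = mu_new, 0.5 * (sigma_new + sigma_new.T)
        if abs(ll - prev) < tol * (1 + abs(ll)):
            break
        prev = ll
    return mu, sigma, ll


def _pattern_loglik(x: np.ndarray, sigma: np.ndarray, mu: np.ndarray) -> float:
    """Casewise MVN log-likelihood over observed sub-vectors (FIML)."""
    miss = np.isnan(x)
    ll = 0.0
    for key in np.unique(miss, axis=0):
        rows = np.flatnonzero((miss == key).all(axis=1))
        obs = np.flatnonzero(~key)
        if obs.size == 0:
            continue
        sub = sigma[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return -_PENALTY
        resid = x[np.ix_(rows, obs)] - mu[obs]
        sub_inv = np.linalg.inv(sub)
        ll += -0.5 * rows.size * (obs.size * _LN2PI + logdet) - 0.5 * float(
            np.einsum("ij,jk,ik->", resid, sub_inv, resid)
        )
    return ll


# ---------------------------------------------------------------------------


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix mapping vech to vec for symmetric p x p."""
    rows = []
    d = np.zeros((p * p, p * (p + 1) // 2))
    k = 0
    for j in range(p):
        for i in range(j, p):
            d[i * p + j, k] = 1.0
            d[j * p + i, k] = 1.0
            k += 1
    return d


def _vech(m: np.ndarray) -> np.ndarray:
    p = m.shape[0]
    return np.concatenate([m[j:, j] for j in range(p)])


@dataclass
class SemResults:
    """Estimates, uncertainties and fit statistics of one fitted model."""

    model: "SemModel"
    params: pd.Series
    bse: pd.Series
    chi_square: float
    df: int
    converged: bool
    loglike: float | None
    method: str
    n_starts: int
    optimizer_log: list = field(repr=False, default_factory=list)
    _fmin: float = 0.0

    @property
    def spec(self) -> SemModelSpec:
        return self.model.spec

    @property
    def pvalue(self) -> float:
        if self.df == 0:
            return 1.0
        return float(sps.chi2.sf(self.chi_square, self.df))

    @property
    def n_total(self) -> int:
        return int(sum(self.model.ns))

    def group_matrices(self) -> list[dict[str, np.ndarray]]:
        return self.spec.matrices(dict(self.params))

    def implied(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [implied_moments(m) for m in self.group_matrices()]

    def tvalues(self) -> pd.Series:
        return self.params / self.bse.replace(0, np.nan)

    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * sps.norm.sf(np.abs(self.tvalues())), index=self.params.index
        )

    # -- fit indices ------------------------------------------------------

    def _baseline(self) -> tuple[float, int]:
        return self.model.baseline_chi2(self.method)

    @property
    def cfi(self) -> float:
        chi_b, df_b = self._baseline()
        num = max(self.chi_square - self.df, 0.0)
        den = max(chi_b - df_b, self.chi_square - self.df, 0.0)
        return 1.0 if den == 0 else 1.0 - num / den

    @property
    def rmsea(self) -> float:
        if self.df == 0:
            return 0.0
        n = self.n_total
        g = len(self.spec.groups)
        val = max(self.chi_square - self.df, 0.0) / (self.df * max(n - 1, 1))
        return math.sqrt(g) * math.sqrt(val)

    @property
    def srmr(self) -> float:
        """n-weighted RMS difference of sample vs implied correlations
        (plus standardised mean residuals when means are modelled)."""
        total, weight = 0.0, 0.0
        for g, (sigma, mu) in enumerate(self.implied()):
            s, xbar, n = self.model.s[g], self.model.xbar[g], self.model.ns[g]
            sd_s = np.sqrt(np.diag(s))
            sd_i = np.sqrt(np.diag(sigma))
            rs = s / np.outer(sd_s, sd_s)
            ri = sigma / np.outer(sd_i, sd_i)
            iu = np.triu_indices(s.shape[0], k=1)
            res = list((rs - ri)[iu] ** 2)
            if self.spec.meanstructure and xbar is not None:
                res += list(((xbar - mu) / sd_s) ** 2)
            total += n * float(np.mean(res))
            weight += n
        return math.sqrt(total / weight)

    def fit_indices(self) -> dict[str, float]:
        return {"cfi": self.cfi, "rmsea": self.rmsea, "srmr": self.srmr}

    def summary(self) -> str:
        lines = [
            f"SEM fit ({self.method}), groups: {', '.join(self.spec.groups)}",
            f"  chi2({self.df}) = {self.chi_square:.3f}, p = {self.pvalue:.4f}"
            + ("" if self.converged else "   [NOT CONVERGED]"),
            f"  CFI = {self.cfi:.3f}, RMSEA = {self.rmsea:.3f}, SRMR = {self.srmr:.3f}",
            f"  N = {self.n_total} ({', '.join(str(n) for n in self.model.ns)})",
            "",
            f"  {'parameter':<28}{'est':>10}{'se':>10}{'z':>8}{'p':>10}",
        ]
        tv, pv = self.tvalues(), self.pvalues()
        for lab in self.params.index:
            lines.append(
                f"  {lab:<28}{self.params[lab]:>10.4f}{self.bse[lab]:>10.4f}"
                f"{tv[lab]:>8.2f}{pv[lab]:>10.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "converged": self.converged,
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.pvalue,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "n": self.n_total,
            "params": dict(self.params),
            "se": dict(self.bse),
        }


class SemModel:
    """A structural equation model bound to data (statsmodels-style).

    Construct from a tidy DataFrame (indicator columns, optional predictor
    columns and a group column) or from per-group moments via
    :meth:`from_moments`; then :meth:`fit` returns a :class:`SemResults`.
    """

    def __init__(
        self,
        spec: SemModelSpec,
        data: pd.DataFrame | None = None,
        group_col: str | None = "group",
        chi2_convention: str = "n-1",
    ):
        self.spec = spec
        self.chi2_convention = chi2_convention
        self.s: list[np.ndarray] = []
        self.xbar: list[np.ndarray | None] = []
        self.ns: list[int] = []
        self.raw: list[np.ndarray] | None = None
        if data is None:
            return
        cols = list(spec.observed)
        if len(spec.groups) > 1:
            if group_col is None or group_col not in data:
                raise DataError("multi-group spec needs a group column")
            frames = [data.loc[data[group_col] == g, cols] for g in spec.groups]
            for g, fr in zip(spec.groups, frames):
                if fr.empty:
                    raise DataError(f"no rows for group {g!r}")
        else:
            frames = [data[cols]]
        self.raw = []
        self._any_missing = False
        for fr in frames:
            x = fr.to_numpy(dtype=float)
            keep = ~np.all(np.isnan(x), axis=1)
            x = x[keep]
            self.raw.append(x)
            if np.isnan(x).any():
                self._any_missing = True
            cc = x[~np.isnan(x).any(axis=1)]
            if cc.shape[0] >= x.shape[1] + 2:
                self.s.append(np.cov(cc, rowvar=False, ddof=0))
                self.xbar.append(cc.mean(axis=0))
            else:  # complete cases too few: moment via EM later
                self.s.append(None)
                self.xbar.append(None)
            self.ns.append(x.shape[0])

    @classmethod
    def from_moments(
        cls,
        spec: SemModelSpec,
        s: list[np.ndarray],
        ns: list[int],
        xbar: list[np.ndarray] | None = None,
        chi2_convention: str = "n-1",
    ) -> "SemModel":
        mod = cls(spec, data=None, chi2_convention=chi2_convention)
        mod.s = [np.asarray(m, dtype=float) for m in s]
        mod.ns = list(ns)
        mod.xbar = (
            [np.asarray(v, dtype=float) for v in xbar]
            if xbar is not None
            else [None] * len(s)
        )
        if spec.meanstructure and xbar is None:
            raise DataError("meanstructure spec needs sample means")
        return mod

    # -- objective --------------------------------------------------------

    def _labels(self):
        return self.spec.free_labels()

    def _pack(self, values: dict[str, float]) -> np.ndarray:
        pos = self.spec.label_positive()
        return np.array(
            [
                math.log(max(values[l], 1e-8)) if pos[l] else values[l]
                for l in self._labels()
            ]
        )

    def _unpack(self, theta: np.ndarray) -> dict[str, float]:
        pos = self.spec.label_positive()
        out = {}
        for l, v in zip(self._labels(), theta):
            out[l] = math.exp(min(v, 30.0)) if pos[l] else v
        return out

    def _discrepancy(self, values: dict[str, float]) -> float:
        n_tot = sum(self.ns)
        f = 0.0
        for g, mats in enumerate(self.spec.matrices(values)):
            sigma, mu = implied_moments(mats)
            fg = fml_discrepancy(
                self.s[g], self.xbar[g], sigma, mu, self.spec.meanstructure
            )
            f += self.ns[g] / n_tot * fg
        return f

    def _neg_loglik_fiml(self, values: dict[str, float]) -> float:
        ll = 0.0
        for g, mats in enumerate(self.spec.matrices(values)):
            sigma, mu = implied_moments(mats)
            ll += _pattern_loglik(self.raw[g], sigma, mu)
        return -ll

    # -- starting values --------------------------------------------------

    def _starts(self, n_starts: int, seed: int) -> list[np.ndarray]:
        values = self.spec.start_values()
        # crude data-driven initialisation
        for g in range(len(self.spec.groups)):
            s, xbar = self.s[g], self.xbar[g]
            if s is None:
                continue
            for prm in self.spec.params:
                if not prm.free or prm.group != g:
                    continue
                if prm.matrix == "theta":
                    values[prm.label] = max(0.5 * s[prm.row, prm.row], 0.05)
                elif prm.matrix == "lambda":
                    values[prm.label] = 0.7 * math.sqrt(max(s[prm.row, prm.row], 0.1))
                elif prm.matrix == "tau" and xbar is not None:
                    values[prm.label] = xbar[prm.row]
                elif prm.matrix == "kappa" and xbar is not None:
                    values[prm.label] = xbar[len(self.spec.indicators) + prm.row]
                elif prm.matrix == "phi_x":
                    j = len(self.spec.indicators) + prm.row
                    k = len(self.spec.indicators) + prm.col
                    values[prm.label] = s[j, k] if s[j, j] > 0 else 1.0
        theta0 = self._pack(values)
        rng = np.random.default_rng(seed)
        starts = [theta0]
        for _ in range(n_starts - 1):
            starts.append(theta0 + 0.15 * rng.standard_normal(theta0.size))
        return starts

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        method: str = "ml",
        starts: int = 5,
        seed: int = 0,
        maxiter: int = 2000,
    ) -> SemResults:
        """Estimate the model; ``method`` is ``ml`` (complete-case moments)
        or ``fiml`` (casewise likelihood over missingness patterns)."""
        if method == "ml":
            if any(m is None for m in self.s):
                raise DataError("too few complete cases for ML moments; use fiml")
            objective = lambda th: self._discrepancy(self._unpack(th))
        elif method == "fiml":
            if self.raw is None:
                raise DataError("fiml requires raw data, not moments")
            n_tot = sum(self.ns)
            objective = lambda th: self._neg_loglik_fiml(self._unpack(th)) / n_tot
        else:
            raise EstimationError(f"unknown method {method!r}")

        best, log = None, []
        for k, th0 in enumerate(self._starts(starts, seed)):
            res = optimize.minimize(
                objective, th0, method="L-BFGS-B", options={"maxiter": maxiter}
            )
            log.append(
                {"start": k, "fun": float(res.fun), "success": bool(res.success),
                 "nit": int(res.nit)}
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        values = self._unpack(best.x)
        converged = bool(best.success) and best.fun < _PENALTY / 2
        n_tot = sum(self.ns)
        n_groups = len(self.spec.groups)
        scale = (n_tot - n_groups) if self.chi2_convention == "n-1" else n_tot

        if method == "ml":
            fmin = float(best.fun)
            chi2 = max(scale * fmin, 0.0)
            loglike = None
        else:
            loglike = -float(best.fun) * n_tot
            ll_sat = 0.0
            for x in self.raw:
                mu_s, sig_s, ll_s = _em_mvn(x)
                ll_sat += ll_s
            fmin = 2.0 * (ll_sat - loglike) / n_tot
            chi2 = max(scale * fmin, 0.0)

        labels = self._labels()
        params = pd.Series({l: values[l] for l in labels})
        bse = self._standard_errors(values, method)
        return SemResults(
            model=self,
            params=params,
            bse=bse,
            chi_square=float(chi2),
            df=self.spec.count_df(),
            converged=converged,
            loglike=loglike,
            method=method,
            n_starts=starts,
            optimizer_log=log,
            _fmin=float(fmin),
        )

    # -- inference --------------------------------------------------------

    def _moment_vector(self, values: dict[str, float], g: int) -> np.ndarray:
        sigma, mu = implied_moments(self.spec.matrices(values)[g])
        v = _vech(sigma)
        if self.spec.meanstructure:
            v = np.concatenate([v, mu])
        return v

    def _standard_errors(self, values: dict[str, float], method: str) -> pd.Series:
        """Inverse expected information from the numeric moment Jacobian."""
        labels = self._labels()
        k = len(labels)
        info = np.zeros((k, k))
        p = self.spec.n_observed
        dup = _duplication(p)
        try:
            for g in range(len(self.spec.groups)):
                sigma, mu = implied_moments(self.spec.matrices(values)[g])
                sigma_inv = np.linalg.inv(sigma)
                w_cov = 0.5 * dup.T @ np.kron(sigma_inv, sigma_inv) @ dup
                jac = np.zeros((len(_vech(sigma)) + (p if self.spec.meanstructure else 0), k))
                for j, lab in enumerate(labels):
                    h = 1e-5 * max(1.0, abs(values[lab]))
                    up = dict(values); up[lab] += h
                    dn = dict(values); dn[lab] -= h
                    jac[:, j] = (
                        self._moment_vector(up, g) - self._moment_vector(dn, g)
                    ) / (2 * h)
                nc = dup.shape[1]
                jc, jm = jac[:nc], jac[nc:]
                gi = jc.T @ w_cov @ jc
                if self.spec.meanstructure:
                    gi = gi + jm.T @ sigma_inv @ jm
                info += self.ns[g] * gi
            cov = np.linalg.pinv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except (np.linalg.LinAlgError, ValueError):
            se = np.full(k, np.nan)
        return pd.Series(se, index=labels)

    # -- baseline ---------------------------------------------------------

    def baseline_chi2(self, method: str = "ml") -> tuple[float, int]:
        """Chi-square and df of the independence model (free variances and
        means, zero covariances) on the same data."""
        p = self.spec.n_observed
        n_tot = sum(self.ns)
        n_groups = len(self.spec.groups)
        scale = (n_tot - n_groups) if self.chi2_convention == "n-1" else n_tot
        df_b = n_groups * p * (p - 1) // 2
        if method == "ml" or self.raw is None or not getattr(self, "_any_missing", False):
            f = 0.0
            for g in range(n_groups):
                s = self.s[g]
                sign, logdet_s = np.linalg.slogdet(s)
                f += self.ns[g] / n_tot * (float(np.log(np.diag(s)).sum()) - logdet_s)
            return max(scale * f, 0.0), df_b
        # FIML baseline: independence factorises into univariate MLEs
        ll_b, ll_sat = 0.0, 0.0
        for x in self.raw:
            for j in range(x.shape[1]):
                col = x[:, j]
                col = col[~np.isnan(col)]
                var = col.var(ddof=0)
                ll_b += -0.5 * col.size * (_LN2PI + math.log(var) + 1.0)
            mu_s, sig_s, ll_s = _em_mvn(x)
            ll_sat += ll_s
        f = 2.0 * (ll_sat - ll_b) / n_tot
        return max(scale * f, 0.0), df_b


def lr_test(fit_restricted: SemResults, fit_free: SemResults) -> tuple[float, int, float]:
    """Likelihood-ratio (chi-square difference) test of nested fits."""
    dchi = fit_restricted.chi_square - fit_free.chi_square
    ddf = fit_restricted.df - fit_free.df
    if ddf <= 0:
        raise EstimationError("models are not nested (delta df <= 0)")
    return float(dchi), int(ddf), float(sps.chi2.sf(max(dchi, 0.0), ddf))
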