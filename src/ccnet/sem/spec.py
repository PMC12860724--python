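"""Declarative specification of multi-group structural equation models.

A model is a list of :class:`Parameter` entries addressing cells of the
standard LISREL-style matrices per group:

======== ===========================================================
lambda   factor loadings (indicator x factor)
psi      latent (disturbance) covariance matrix
theta    residual variances (diagonal)
tau      indicator intercepts
alpha    latent means
gamma    structural paths from exogenous observed predictors to factors
phi_x    covariance of exogenous predictors
kappa    means of exogenous predictors
======== ===========================================================

Equality constraints — across groups or within a group — are expressed by
giving two parameters the same label; each distinct free label is one free
parameter, which makes degree-of-freedom counting a pure bookkeeping
exercise.  Identification follows the reference-group standardisation
convention: in the first group latent variances are fixed at 1 and latent
means at 0, and non-reference latent variances/means are freed only once
invariance constraints make them estimable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .._errors import InvalidSpecError

MATRICES = ("lambda", "psi", "theta", "tau", "alpha", "gamma", "phi_x", "kappa")


@dataclass
class Parameter:
    group: int
    matrix: str
    row: int
    col: int
    label: str | None  # None for fixed parameters
    free: bool
    value: float  # fixed value, or start value when free
    positive: bool = False  # variance-type (log-parameterised during fit)


@dataclass
class SemModelSpec:
    """A fully resolved parameterisation of a multi-group SEM."""

    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    groups: tuple[str, ...]
    params: list[Parameter]
    predictors: tuple[str, ...] = ()
    meanstructure: bool = False
    description: str = ""

    # -- bookkeeping ------------------------------------------------------

    @property
    def observed(self) -> tuple[str, ...]:
        return self.indicators + self.predictors

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    def free_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.params:
            if p.free and p.label not in seen:
                seen[p.label] = None
        return list(seen)

    def label_positive(self) -> dict[str, bool]:
        return {p.label: p.positive for p in self.params if p.free}

    def start_values(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for p in self.params:
            if p.free and p.label not in out:
                out[p.label] = p.value
        return out

    def count_df(self) -> int:
        """Sample moments minus free parameters (the model's test df)."""
        p = self.n_observed
        per_group = p * (p + 1) // 2 + (p if self.meanstructure else 0)
        df = len(self.groups) * per_group - len(self.free_labels())
        if df < 0:
            raise InvalidSpecError(
                f"model not identified by counting: df = {df} < 0"
            )
        return df

    def matrices(self, values: dict[str, float]) -> list[dict[str, np.ndarray]]:
        """Materialise the per-group matrices for a label -> value mapping."""
        p, m, q = len(self.indicators), len(self.factors), len(self.predictors)
        out = []
        for _ in self.groups:
            out.append(
                {
                    "lambda": np.zeros((p, m)),
                    "psi": np.zeros((m, m)),
                    "theta": np.zeros(p),
                    "tau": np.zeros(p),
                    "alpha": np.zeros(m),
                    "gamma": np.zeros((m, q)),
                    "phi_x": np.zeros((q, q)),
                    "kappa": np.zeros(q),
                }
            )
        for prm in self.params:
            v = values[prm.label] if prm.free else prm.value
            mat = out[prm.group][prm.matrix]
            if mat.ndim == 1:
                mat[prm.row] = v
            else:
                mat[prm.row, prm.col] = v
                if prm.matrix in ("psi", "phi_x") and prm.row != prm.col:
                    mat[prm.col, prm.row] = v
        return out

    # -- serialisation ----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        """Serialise the spec (including the resolved parameter table)."""
        doc = {
            "indicators": list(self.indicators),
            "factors": list(self.factors),
            "groups": list(self.groups),
            "predictors": list(self.predictors),
            "meanstructure": self.meanstructure,
            "description": self.description,
            "params": [asdict(p) for p in self.params],
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SemModelSpec":
        if isinstance(source, Path) or ("\n" not in str(source) and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(text)
        return cls(
            indicators=tuple(doc["indicators"]),
            factors=tuple(doc["factors"]),
            groups=tuple(doc["groups"]),
            predictors=tuple(doc.get("predictors", ())),
            meanstructure=bool(doc.get("meanstructure", False)),
            description=doc.get("description", ""),
            params=[Parameter(**p) for p in doc["params"]],
        )

    # -- constructor ------------------------------------------------------

    @classmethod
    def cfa(
        cls,
        indicator_map: dict[str, str],
        groups: tuple[str, ...] = ("all",),
        *,
        equality_within: tuple[tuple[str, str], ...] = (),
        invariance: str = "configural",
        free_intercepts: tuple[str, ...] = (),
        meanstructure: bool | None = None,
        latent_means: str = "auto",
        fixed_loadings: dict[str, float] | None = None,
        predictors: tuple[str, ...] = (),
        equal_paths: bool = True,
        description: str = "",
    ) -> "SemModelSpec":
        """Build a (multi-group) congeneric factor model.

        Parameters
        ----------
        indicator_map
            Ordered mapping indicator -> factor (congeneric: one factor
            per indicator).
        equality_within
            Pairs of indicators whose loadings are constrained equal
            within every group (e.g. a two-indicator factor).
        invariance
            ``configural`` (all measurement parameters group-specific),
            ``weak`` (equal loadings) or ``strong`` (equal loadings and
            intercepts).  Ignored for a single group.
        free_intercepts
            Indicators released from the intercept equality in
            non-reference groups (partial strong invariance).
        latent_means
            ``auto``: non-reference latent means free exactly when strong
            (or partial strong) invariance makes them estimable;
            ``zero``: fixed at 0 in every group (the equal-means model);
            ``free``: force free in non-reference groups.
        fixed_loadings
            Fix every loading to the given value (e.g. estimates from a
            prior measurement model); latent variances then become free in
            all groups.
        predictors
            Exogenous observed variables regressed onto every factor
            (``gamma`` paths), with saturated predictor moments.
        equal_paths
            Share each gamma path across groups.
        """
        indicators = tuple(indicator_map)
        factors = tuple(dict.fromkeys(indicator_map.values()))
        n_groups = len(groups)
        multi = n_groups > 1
        if invariance not in ("configural", "weak", "strong"):
            raise InvalidSpecError(f"unknown invariance level {invariance!r}")
        if meanstructure is None:
            meanstructure = multi
        if free_intercepts and invariance != "strong":
            raise InvalidSpecError("free_intercepts only applies to strong invariance")
        eq_partner = {}
        for a, b in equality_within:
            eq_partner[b] = a
        params: list[Parameter] = []
        fix_lam = fixed_loadings is not None
        share_lam = fix_lam or (multi and invariance in ("weak", "strong"))
        share_tau = multi and invariance == "strong"

        for g in range(n_groups):
            # loadings
            for j, ind in enumerate(indicators):
                f = factors.index(indicator_map[ind])
                if fix_lam:
                    params.append(
                        Parameter(g, "lambda", j, f, None, False, float(fixed_loadings[ind]))
                    )
                    continue
                name = eq_partner.get(ind, ind)
                label = f"lambda_{name}" if share_lam else f"lambda_{name}_g{g}"
                params.append(Parameter(g, "lambda", j, f, label, True, 0.6))
            # latent covariance: variances + free covariances
            ref_scaled = not fix_lam
            var_free = (not ref_scaled) or (
                g > 0 and (share_lam and (multi and invariance in ("weak", "strong")))
            )
            if fix_lam:
                var_free = True
            for a in range(len(factors)):
                if var_free:
                    params.append(
                        Parameter(g, "psi", a, a, f"psi_{factors[a]}_g{g}", True, 1.0, True)
                    )
                else:
                    params.append(Parameter(g, "psi", a, a, None, False, 1.0))
                for b in range(a + 1, len(factors)):
                    params.append(
                        Parameter(
                            g, "psi", a, b, f"psi_{factors[a]}_{factors[b]}_g{g}", True, 0.3
                        )
                    )
            # residual variances: free per group
            for j, ind in enumerate(indicators):
                params.append(Parameter(g, "theta", j, 0, f"theta_{ind}_g{g}", True, 0.5, True))
            if meanstructure:
                for j, ind in enumerate(indicators):
                    if share_tau and not (g > 0 and ind in free_intercepts):
                        label = f"tau_{ind}"
                    else:
                        label = f"tau_{ind}_g{g}"
                    params.append(Parameter(g, "tau", j, 0, label, True, 0.0))
                means_estimable = multi and invariance == "strong" and not fix_lam
                for a, fac in enumerate(factors):
                    free_mean = (
                        g > 0
                        and latent_means != "zero"
                        and (means_estimable or latent_means == "free")
                    )
                    if free_mean:
                        params.append(Parameter(g, "alpha", a, 0, f"alpha_{fac}_g{g}", True, 0.0))
                    else:
                        params.append(Parameter(g, "alpha", a, 0, None, False, 0.0))
            # structural paths and predictor moments
            for a, fac in enumerate(factors):
                for b, pred in enumerate(predictors):
                    label = (
                        f"beta_{fac}_{pred}" if equal_paths else f"beta_{fac}_{pred}_g{g}"
                    )
                    params.append(Parameter(g, "gamma", a, b, label, True, 0.0))
            for b, pred in enumerate(predictors):
                params.append(
                    Parameter(g, "phi_x", b, b, f"phix_{pred}_g{g}", True, 1.0, True)
                )
                for c in range(b + 1, len(predictors)):
                    params.append(
                        Parameter(
                            g, "phi_x", b, c, f"phix_{pred}_{predictors[c]}_g{g}", True, 0.0
                        )
                    )
                if meanstructure:
                    params.append(Parameter(g, "kappa", b, 0, f"kappa_{pred}_g{g}", True, 0.0))
        return cls(
            indicators=indicators,
            factors=factors,
            groups=tuple(groups),
            params=params,
            predictors=tuple(predictors),
            meanstructure=bool(meanstructure),
            description=description,
        )
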