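"""Screening rules, two-sample contrasts and FDR correction.

The group analysis compares the three global topology metrics between VPT
and FT subjects at every density (3 metrics x 10 densities = one family of
30 two-tailed t-tests) and per-node betweenness at 50% density (a second
family of 66 tests).  Each family is Benjamini-Hochberg corrected on its
own; effect sizes are Cohen's d with pooled SD, signed VPT minus FT so a
negative d means the VPT group is lower.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._errors import DataError, InvalidParameterError
from .cohort import INDICATORS, CohortBundle
from .metrics import MetricTable


def screen_subjects(
    bundle: CohortBundle, max_missing: float = 0.5
) -> tuple[list[str], pd.DataFrame]:
    """Retained subject ids plus an exclusion log.

    A subject is dropped when more than ``max_missing`` of the behavioural
    indicator block is missing, or when the connectome is unusable (empty
    or non-finite count matrix).
    """
    log = []
    retained = []
    table = bundle.table.set_index("id")
    for raw in bundle.subjects:
        sid = raw.subject_id
        reasons = []
        frac = table.loc[sid, list(INDICATORS)].isna().mean()
        if frac > max_missing:
            reasons.append(f"behavioural missingness {frac:.0%} > {max_missing:.0%}")
        if not np.all(np.isfinite(raw.counts)) or raw.counts.sum() == 0:
            reasons.append("unusable connectome")
        if reasons:
            log.append({"id": sid, "reason": "; ".join(reasons)})
        else:
            retained.append(sid)
    log_df = pd.DataFrame(log, columns=["id", "reason"])
    if not retained:
        warnings.warn("screening excluded every subject", stacklevel=2)
    return retained, log_df


def flag_outliers(x, y=None, threshold: float = 3.0) -> np.ndarray:
    """Flag observations strictly beyond ``threshold`` sample SDs on either
    of a pair of brain/behaviour variables (flags only, no exclusion)."""
    x = np.asarray(x, dtype=float)
    cols = [x] if y is None else [x, np.asarray(y, dtype=float)]
    n = cols[0].size
    if sum(np.isfinite(c).sum() for c in cols[:1]) < 3:
        raise DataError("need at least 3 non-missing values")
    flags = np.zeros(n, dtype=bool)
    for c in cols:
        sd = np.nanstd(c, ddof=1)
        if sd == 0:
            warnings.warn("zero variance: no outliers flagged", stacklevel=2)
            continue
        zz = (c - np.nanmean(c)) / sd
        flags |= np.abs(zz) > threshold  # strictly beyond
    return flags


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    cohen_d: float
    mean_x: float
    mean_y: float


def two_sample_t(x, y, variant: str = "student") -> TTestResult:
    """Two-tailed two-sample t-test plus Cohen's d.

    ``cohen_d`` always uses the pooled (Student) SD with ``n1 + n2 - 2``
    denominator regardless of the t variant; its sign is mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise DataError("each sample needs at least 2 non-missing values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        # degenerate but well-defined: identical constant samples
        return TTestResult(
            t=0.0, df=float(x.size + y.size - 2), p=1.0, cohen_d=0.0,
            mean_x=float(x.mean()), mean_y=float(y.mean()),
        )
    if variant == "student":
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    elif variant == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    else:
        raise InvalidParameterError(f"unknown t-test variant {variant!r}")
    sp = np.sqrt(
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    d = 0.0 if sp == 0 else (x.mean() - y.mean()) / sp
    return TTestResult(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        cohen_d=float(d),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
    )


def fdr_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _contrast_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_bh(df["p_raw"].to_numpy())
    return df


def compare_global_metrics(
    ztable: MetricTable, groups: pd.Series, variant: str = "student"
) -> pd.DataFrame:
    """VPT-vs-FT contrast for every (metric, density) cell, one FDR family.

    ``groups`` is indexed by subject id with values FT/VPT.  The t and d
    sign convention is VPT minus FT.
    """
    if ztable.kind != "z":
        raise DataError("compare_global_metrics expects a z-standardised table")
    df = ztable.data
    g = groups.loc[df.index]
    rows = []
    for metric, density in df.columns:
        col = df[(metric, density)]
        res = two_sample_t(col[g == "VPT"], col[g == "FT"], variant)
        rows.append(
            {
                "metric": metric,
                "density": density,
                "mean_ft": res.mean_y,
                "mean_vpt": res.mean_x,
                "t_statistic": res.t,
                "df": res.df,
                "p_raw": res.p,
                "cohen_d": res.cohen_d,
            }
        )
    return _contrast_frame(rows)


def compare_betweenness(
    btable: pd.DataFrame, groups: pd.Series, variant: str = "student"
) -> pd.DataFrame:
    """Node-wise VPT-vs-FT betweenness contrasts, FDR over the node family."""
    g = groups.loc[btable.index]
    rows = []
    for node in btable.columns:
        col = btable[node]
        res = two_sample_t(col[g == "VPT"], col[g == "FT"], variant)
        rows.append(
            {
                "node": node,
                "mean_ft": res.mean_y,
                "mean_vpt": res.mean_x,
                "t_statistic": res.t,
                "df": res.df,
                "p_raw": res.p,
                "cohen_d": res.cohen_d,
            }
        )
    return _contrast_frame(rows)


def significance_summary(contrasts: pd.DataFrame, alpha: float = 0.05) -> str:
    """Plain-text family summary with stars at p_fdr <= alpha."""
    lines = []
    key_cols = [c for c in ("metric", "density", "node") if c in contrasts]
    for _, row in contrasts.iterrows():
        star = " *" if row["p_fdr"] <= alpha else ""
        key = " ".join(str(row[c]) for c in key_cols)
        lines.append(
            f"{key}: t={row['t_statistic']:+.3f}, d={row['cohen_d']:+.3f}, "
            f"p_fdr={row['p_fdr']:.4f}{star}"
        )
    return "\n".join(lines)
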