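"""Empirical-Bayes batch harmonisation (ComBat) and balanced subsampling.

Multi-scanner studies carry scanner ("batch") effects in derived imaging
features.  ComBat models each feature as a linear combination of design
covariates plus a per-batch additive (gamma) and multiplicative (delta)
effect, shrinks the per-batch estimates across features with parametric
empirical-Bayes priors (normal for gamma, inverse-gamma for delta), and
removes the shrunken effects while preserving covariate-associated
variation.

When batch is confounded with group, harmonisation is run on balanced
subsamples: within each retained scanner the larger group is randomly
downsampled to the smaller one, and scanners whose smaller group falls
below a floor are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError, InvalidParameterError


@dataclass
class CombatEstimates:
    """Per-batch location/scale estimates, raw and EB-shrunken."""

    batches: list
    gamma_hat: pd.DataFrame  # batch x feature, standardised scale
    delta_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta_star: pd.DataFrame
    skipped_features: list


def _eb_iterate(z: np.ndarray, g_hat, d_hat, g_bar, t2, a_prior, b_prior, tol=1e-6):
    """Iterative joint solution of the EB-conditional posterior modes."""
    n = z.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(500):
        g_old, d_old = g_new.copy(), d_new.copy()
        g_new = (n * t2 * g_hat + d_new * g_bar) / (n * t2 + d_new)
        sse = ((z - g_new) ** 2).sum(axis=0)
        d_new = (b_prior + 0.5 * sse) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max(initial=0), np.abs(d_new - d_old).max(initial=0)
        )
        if change < tol:
            break
    return g_new, d_new


def harmonise_combat(
    features: pd.DataFrame,
    batch,
    design: pd.DataFrame | None = None,
    eb: bool = True,
) -> tuple[pd.DataFrame, CombatEstimates]:
    """Location-scale ComBat adjustment of a subject x feature table.

    ``design`` holds covariate columns (numeric) whose associated variation
    is preserved.  Returns the adjusted table (same shape, order and
    feature names) plus the per-batch estimates.  Constant features are
    passed through unchanged with a warning; a batch with fewer than two
    subjects is an error because its scale is inestimable.
    """
    x = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("feature table must be finite")
    batch = pd.Series(np.asarray(batch), index=features.index)
    levels = list(pd.unique(batch))
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small) > 0:
        raise DataError(
            f"batch(es) with fewer than 2 subjects: {list(small.index)}; "
            "scale effects are inestimable"
        )
    n, p = x.shape
    sds = x.std(axis=0)
    const = sds == 0
    skipped = list(features.columns[const])
    if skipped:
        warnings.warn(f"constant feature(s) skipped: {skipped}", stacklevel=2)
    work = x[:, ~const]
    b_onehot = np.column_stack([(batch == lv).to_numpy(float) for lv in levels])
    design_mat = b_onehot
    q = 0
    if design is not None and design.shape[1] > 0:
        dm = design.to_numpy(dtype=float)
        if not np.all(np.isfinite(dm)):
            raise DataError("design matrix must be finite")
        design_mat = np.column_stack([b_onehot, dm])
        q = dm.shape[1]
    beta, *_ = np.linalg.lstsq(design_mat, work, rcond=None)
    nb = b_onehot.sum(axis=0)
    grand = (nb / n) @ beta[: len(levels)]
    stand_mean = np.tile(grand, (n, 1))
    if q:
        stand_mean = stand_mean + design_mat[:, len(levels):] @ beta[len(levels):]
    resid = work - design_mat @ beta
    var_pooled = (resid**2).mean(axis=0)
    z = (work - stand_mean) / np.sqrt(var_pooled)

    g_hat = np.vstack([z[(batch == lv).to_numpy()].mean(axis=0) for lv in levels])
    # MLE (1/n_b) scale so a single homogeneous batch round-trips exactly
    d_hat = np.vstack([z[(batch == lv).to_numpy()].var(axis=0, ddof=0) for lv in levels])

    if eb and work.shape[1] >= 2:
        g_star, d_star = np.empty_like(g_hat), np.empty_like(d_hat)
        for bi, lv in enumerate(levels):
            g_bar, t2 = g_hat[bi].mean(), g_hat[bi].var(ddof=1)
            dmean, dvar = d_hat[bi].mean(), d_hat[bi].var(ddof=1)
            if t2 <= 0 or dvar <= 0:
                g_star[bi], d_star[bi] = g_hat[bi], d_hat[bi]
                continue
            a_prior = (2.0 * dvar + dmean**2) / dvar
            b_prior = (dmean * dvar + dmean**3) / dvar
            zb = z[(batch == lv).to_numpy()]
            g_star[bi], d_star[bi] = _eb_iterate(
                zb, g_hat[bi], d_hat[bi], g_bar, t2, a_prior, b_prior
            )
    else:
        g_star, d_star = g_hat, d_hat

    adj = z.copy()
    for bi, lv in enumerate(levels):
        rows = (batch == lv).to_numpy()
        adj[rows] = (z[rows] - g_star[bi]) / np.sqrt(d_star[bi])
    adj = adj * np.sqrt(var_pooled) + stand_mean

    out = x.copy()
    out[:, ~const] = adj
    adjusted = pd.DataFrame(out, index=features.index, columns=features.columns)
    kept = list(features.columns[~const])
    est = CombatEstimates(
        batches=levels,
        gamma_hat=pd.DataFrame(g_hat, index=levels, columns=kept),
        delta_hat=pd.DataFrame(d_hat, index=levels, columns=kept),
        gamma_star=pd.DataFrame(g_star, index=levels, columns=kept),
        delta_star=pd.DataFrame(d_star, index=levels, columns=kept),
        skipped_features=skipped,
    )
    return adjusted, est


def balanced_subsample(
    groups, batch, k: int = 5, seed: int = 0, floor: int = 4
) -> list[np.ndarray]:
    """``k`` reproducible index sets with equal group counts per scanner.

    Within each batch both groups appear with count equal to the smaller
    group's count there (the larger group is randomly downsampled).
    Batches whose smaller group has fewer than ``floor`` subjects are
    dropped entirely.  Returned arrays hold positional indices.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    groups = np.asarray(groups)
    batch = np.asarray(batch)
    glabels = np.unique(groups)
    if glabels.size != 2:
        raise DataError("expected exactly two groups")
    rng = np.random.default_rng(seed)
    draws: list[np.ndarray] = []
    retained_any = False
    for _ in range(k):
        picked: list[np.ndarray] = []
        for b in pd.unique(batch):
            idx_b = np.flatnonzero(batch == b)
            by_group = [idx_b[groups[idx_b] == g] for g in glabels]
            m = min(len(ix) for ix in by_group)
            if m < floor:
                continue
            retained_any = True
            for ix in by_group:
                if len(ix) == m:
                    picked.append(ix)
                else:
                    picked.append(rng.choice(ix, size=m, replace=False))
        if picked:
            draws.append(np.sort(np.concatenate(picked)))
        else:
            draws.append(np.array([], dtype=int))
    if not retained_any:
        raise DataError(
            f"no batch has at least {floor} subjects in each group; "
            "balanced subsampling impossible"
        )
    return draws
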