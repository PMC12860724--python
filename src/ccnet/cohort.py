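"""Synthetic cohort generator with known ground truth.

The generator emulates the data structure of a very-preterm (VPT) versus
full-term (FT) adult cohort so that every downstream stage — connectome
construction, graph metrics, group contrasts, and latent-variable models —
can be exercised and validated without restricted data.  It produces, per
subject:

* a **raw connectome**: a 66-region streamline-count matrix (Poisson counts
  whose rate decays with Euclidean inter-node distance between two mirrored
  hemispheric blocks) plus a symmetric positive tract-length matrix.  The
  base rate is calibrated so the expected raw density matches a per-group
  target; for VPT subjects, edges longer than the median inter-node
  distance are exponentially attenuated (a long-range deficit) and one
  subcortical node may receive a hub weight boost;
* **behavioural indicators** from a standardised two-factor latent model
  (five speed-of-cognitive-control indicators, two sustained-attention
  indicators with equal loadings), with a configurable VPT latent mean
  shift, optional monotone skew, optional MCAR missingness, and optional
  coupling of the first factor to the subject's own subcortical-subnetwork
  clustering;
* group-conditional **covariates** and a scanner/batch label with a
  per-batch multiplicative gain on connectome rates.

Every random draw descends from a single seed through a spawned RNG
hierarchy, so an identical spec reproduces a byte-identical cohort and
adding subjects never reshuffles earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidSpecError
from .connectome import DEFAULT_DENSITIES, RawConnectome, build_network, density_sweep
from .metrics import average_clustering, induced_subgraph

#: Behavioural indicators in fixed order; the first five indicate the
#: "speed of cognitive control" factor, the last two "sustained attention".
INDICATORS = ("word", "congruency", "vsat", "interference", "bar", "trab", "yabcl")
FACTORS = ("speed", "attention")
INDICATOR_FACTOR = {
    "word": "speed",
    "congruency": "speed",
    "vsat": "speed",
    "interference": "speed",
    "bar": "speed",
    "trab": "attention",
    "yabcl": "attention",
}

#: Population loadings of the restricted measurement model (the two
#: sustained-attention loadings are constrained equal).
DEFAULT_LOADINGS = (0.471, 0.379, 0.459, 0.902, 0.836, 0.715, 0.715)
DEFAULT_FACTOR_CORR = 0.564
DEFAULT_LATENT_SHIFT = (-0.742, 0.0)

#: Bilateral subcortical structures forming the subnetwork of interest.
SUBCORTICAL = ("caudate", "putamen", "thalamus", "cerebellum")

_CORTICAL = (
    "dlpfc_sup",
    "dlpfc_mid",
    "dlpfc_inf",
    "acc",
    "mcc",
    "insula_ant",
    "insula_post",
    "parietal_sup",
    "parietal_inf",
    "intraparietal",
    "supramarginal",
    "angular",
    "precuneus",
    "ifg_opercular",
    "ifg_triangular",
    "ifg_orbital",
    "mfg_rostral",
    "mfg_caudal",
    "sfg_medial",
    "pre_sma",
    "sma",
    "frontopolar",
    "orbitofrontal",
    "inferotemporal",
    "temporal_mid",
    "temporal_sup",
    "occipital_sup",
    "fusiform",
    "precentral",
)

#: Scanner batches with (n_ft, n_vpt) frequencies echoing a two-site,
#: two-scanner-model study design, plus a multiplicative gain per scanner.
DEFAULT_BATCHES = {
    "bonn_achieva": {"n_ft": 9, "n_vpt": 3, "gain": 0.90},
    "bonn_ingenia": {"n_ft": 13, "n_vpt": 26, "gain": 1.00},
    "munich_achieva": {"n_ft": 43, "n_vpt": 29, "gain": 1.10},
    "munich_ingenia": {"n_ft": 14, "n_vpt": 3, "gain": 0.95},
}


def node_labels(n_nodes: int = 66) -> tuple[str, ...]:
    """Region labels in two mirrored hemispheric blocks (suffix _L/_R).

    The subcortical structures come first in each hemisphere so they are
    present in any scaled-down network of at least 8 nodes.
    """
    per_hemi = n_nodes // 2
    base = (SUBCORTICAL + _CORTICAL)[:per_hemi]
    if len(base) < per_hemi:
        base = base + tuple(f"ctx_{i:02d}" for i in range(per_hemi - len(base)))
    left = tuple(f"{b}_L" for b in base)
    right = tuple(f"{b}_R" for b in base)
    return left + right


def subcortical_labels(labels) -> tuple[str, ...]:
    return tuple(l for l in labels if l.rsplit("_", 1)[0] in SUBCORTICAL)


@dataclass
class CohortSpec:
    """All generating parameters of a synthetic cohort (the ground truth)."""

    n_ft: int = 79
    n_vpt: int = 61
    n_nodes: int = 66
    seed: int = 0
    loadings: tuple = DEFAULT_LOADINGS
    factor_corr: float = DEFAULT_FACTOR_CORR
    latent_mean_shift: tuple = DEFAULT_LATENT_SHIFT
    intercepts: tuple = (0.0,) * 7
    residual_sd: tuple | None = None  # default: sqrt(1 - loading^2)
    skew: tuple = ()  # indicator names given a monotone skew transform
    skew_strength: float = 0.6
    missing_rate: float = 0.0
    raw_density_ft: float = 0.55
    raw_density_vpt: float = 0.40
    density_sd: float = 0.04  # per-subject spread of the raw-density target
    longrange_attenuation: float = 3.0
    attenuation_onset_q: float = 0.6  # weight percentile below which attenuation bites
    hub_boost_node: str | None = "caudate_R"
    hub_boost: float = 1.3
    coupling_beta: float = 0.0
    batches: dict = field(default_factory=lambda: dict(DEFAULT_BATCHES))
    distance_scale: float = 0.6  # presence decay length, coordinate units
    field_jitter: float = 0.4  # lognormal sd of the per-subject decay length
    weight_exponent: float = 0.6  # weight ~ d^-alpha below the median distance
    weight_exponent_far: float = 1.8  # steeper decay beyond the median
    count_scale: float = 300.0  # count magnitude at the median tract length
    scale_jitter: float = 0.12  # lognormal sd of the per-subject count scale
    edge_jitter: float = 0.02  # lognormal sd of per-tract count magnitude
    coord_jitter: float = 0.12  # per-subject anatomical variation of node positions
    length_jitter: float = 0.03  # lognormal sd of tract tortuosity

    def __post_init__(self) -> None:
        if self.n_ft <= 0 or self.n_vpt <= 0:
            raise InvalidSpecError("group sizes must be positive")
        if self.n_nodes < 4:
            raise InvalidSpecError("need at least 4 nodes")
        if not abs(self.factor_corr) < 1:
            raise InvalidSpecError("|factor_corr| must be < 1")
        if not 0 <= self.missing_rate < 1:
            raise InvalidSpecError("missing_rate must be in [0, 1)")
        for name in ("raw_density_ft", "raw_density_vpt"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidSpecError(f"{name} must be in (0, 1]")
        if self.longrange_attenuation < 0:
            raise InvalidSpecError("longrange_attenuation must be >= 0")
        if len(self.loadings) != 7 or not np.all(np.isfinite(self.loadings)):
            raise InvalidSpecError("loadings must be 7 finite values")
        if not -1 < self.coupling_beta < 1:
            raise InvalidSpecError("|coupling_beta| must be < 1")
        if self.residual_sd is not None:
            if len(self.residual_sd) != 7 or np.any(np.asarray(self.residual_sd) <= 0):
                raise InvalidSpecError("residual_sd must be 7 positive values")

    def resolved_residual_sd(self) -> np.ndarray:
        if self.residual_sd is not None:
            return np.asarray(self.residual_sd, dtype=float)
        lam = np.asarray(self.loadings)
        return np.sqrt(np.clip(1.0 - lam**2, 1e-6, None))

    @property
    def n_total(self) -> int:
        return self.n_ft + self.n_vpt


@dataclass
class CohortBundle:
    """A generated cohort: connectomes + subject table + truth record."""

    subjects: list[RawConnectome]
    table: pd.DataFrame
    truth: dict

    def connectome(self, subject_id: str) -> RawConnectome:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def to_dir(self, path) -> None:
        """Write matrices as TSV (one per subject per kind), table as CSV,
        truth as JSON."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for raw in self.subjects:
            header = "\t".join(raw.labels)
            np.savetxt(
                path / f"{raw.subject_id}_counts.tsv",
                raw.counts,
                fmt="%.0f",
                delimiter="\t",
                header=header,
                comments="",
            )
            np.savetxt(
                path / f"{raw.subject_id}_lengths.tsv",
                raw.lengths,
                fmt="%.6f",
                delimiter="\t",
                header=header,
                comments="",
            )
        self.table.to_csv(path / "subjects.csv", index=False)
        truth = _jsonable(self.truth)
        (path / "truth.json").write_text(json.dumps(truth, indent=1))

    @classmethod
    def from_dir(cls, path) -> "CohortBundle":
        path = Path(path)
        table = pd.read_csv(path / "subjects.csv")
        subjects = []
        for sid in table["id"]:
            cfile = path / f"{sid}_counts.tsv"
            lfile = path / f"{sid}_lengths.tsv"
            labels = tuple(cfile.read_text().splitlines()[0].split("\t"))
            counts = np.loadtxt(cfile, skiprows=1)
            lengths = np.loadtxt(lfile, skiprows=1)
            subjects.append(
                RawConnectome(counts=counts, lengths=lengths, labels=labels, subject_id=sid)
            )
        truth = json.loads((path / "truth.json").read_text())
        return cls(subjects=subjects, table=table, truth=truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# geometry


def network_geometry(spec: CohortSpec) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Node labels, 3-D coordinates and distance matrix of the atlas.

    The atlas is canonical: coordinates depend only on the node count (two
    mirrored hemispheric blocks separated along x), never on the cohort
    seed, just as a parcellation atlas is fixed across studies.  Per-subject
    anatomical variation enters through ``coord_jitter`` instead.
    """
    labels = node_labels(spec.n_nodes)
    per_hemi = spec.n_nodes // 2
    rng = np.random.default_rng(np.random.SeedSequence([8391, spec.n_nodes]))
    left = np.column_stack(
        [
            rng.uniform(-1.0, -0.15, per_hemi),
            rng.uniform(-1.0, 1.0, per_hemi),
            rng.uniform(-1.0, 1.0, per_hemi),
        ]
    )
    right = left.copy()
    right[:, 0] *= -1.0  # mirror across the midline
    coords = np.vstack([left, right])
    if coords.shape[0] < spec.n_nodes:  # odd n: one midline node
        coords = np.vstack([coords, [[0.0, 0.0, 0.0]]])
        labels = labels + ("midline_00",)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return labels, coords, dist


def _magnitude_multipliers(spec: CohortSpec, group: str, labels, dist: np.ndarray) -> np.ndarray:
    """Group-specific multipliers on the streamline-count magnitude."""
    n = dist.shape[0]
    m = np.ones((n, n))
    if group == "VPT":
        if spec.hub_boost_node is not None and spec.hub_boost_node in labels:
            h = labels.index(spec.hub_boost_node)
            m[h, :] *= spec.hub_boost
            m[:, h] *= spec.hub_boost
    np.fill_diagonal(m, 0.0)
    return m


def _rank_attenuation(spec: CohortSpec, proxy_w: np.ndarray, present: np.ndarray) -> np.ndarray:
    """VPT weight attenuation by realized weight rank (weakest tracts most
    affected, the strongest core untouched).

    Because the factor is a monotone function of the subject's own weight
    ordering, proportional thresholding retains exactly the same edge sets
    as without attenuation; only the retained *weights* weaken, and they
    weaken more the deeper the density quota digs into the ranking.  Since
    weight rank tracks tract length, this is the long-range/weak-tract
    deficit of the preterm connectome.
    """
    q = np.zeros_like(proxy_w)
    idx = np.flatnonzero(present)
    order = np.argsort(np.argsort(proxy_w[idx]))
    q[idx] = (order + 0.5) / idx.size  # ascending percentile: weakest ~ 0
    gap = np.clip(spec.attenuation_onset_q - q, 0.0, None)
    return np.where(present, np.exp(-spec.longrange_attenuation * gap), 1.0)


def _solve_rate(target_mean: float, shape: np.ndarray, weight: float = 1.0) -> float:
    """Bisection for A in mean(1 - exp(-A * shape)) * weight = target_mean."""
    if target_mean >= weight * 0.999:
        return 45.0 / max(shape.min(), 1e-12)

    def achieved(a: float) -> float:
        return weight * float(np.mean(1.0 - np.exp(-a * shape)))

    lo, hi = 1e-9, 1.0
    while achieved(hi) < target_mean and hi < 1e12:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if achieved(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _presence_probabilities(
    spec: CohortSpec, group: str, dist: np.ndarray, target: float,
    scale_factor: float = 1.0,
) -> np.ndarray:
    """Upper-triangle pair-presence probabilities for one subject.

    Both groups share a common distance-decayed presence field calibrated
    to the FT density; a subject's own density target is met by rescaling
    the *long-range* block only (edges beyond the median distance), so the
    group density deficit is concentrated in long-range connections, as is
    the jitter around each subject's target.
    """
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    r = np.exp(-d / (spec.distance_scale * scale_factor))
    med = np.median(d)
    long_mask = d > med
    if target >= 0.999:
        return np.ones(d.size)
    a_base = _solve_rate(spec.raw_density_ft, r)
    prob = 1.0 - np.exp(-a_base * r)
    short_mean = prob[~long_mask].mean() * (~long_mask).mean()
    # long-range block: attenuation shapes how the deficit tilts with
    # distance; its overall rate is solved to meet the subject's target
    shape_long = r[long_mask] * np.exp(
        -spec.longrange_attenuation * (d[long_mask] - med) * (group == "VPT")
    )
    long_target = max(target - short_mean, 0.0)
    b = _solve_rate(long_target, shape_long, weight=long_mask.mean())
    prob[long_mask] = 1.0 - np.exp(-b * shape_long)
    return prob


def expected_raw_density(spec: CohortSpec, group: str, subset: str = "all") -> float:
    """The generator's own expectation formula for raw pair density.

    ``subset`` restricts the average to ``"long"`` or ``"short"`` edges
    (relative to the median inter-node distance).
    """
    _, _, dist = network_geometry(spec)
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    target = spec.raw_density_ft if group == "FT" else spec.raw_density_vpt
    prob = _presence_probabilities(spec, group, dist, target)
    long_mask = dist[iu] > np.median(dist[iu])
    if subset == "long":
        prob = prob[long_mask]
    elif subset == "short":
        prob = prob[~long_mask]
    return float(np.mean(prob))


def generate_connectome(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "s0",
    gain: float = 1.0,
    _geometry=None,
) -> RawConnectome:
    """Draw one subject's streamline-count and tract-length matrices.

    The edge model is hurdle-Poisson.  A node pair is present with a
    distance-decayed probability calibrated by bisection so the expected
    raw density matches the subject's target (the group value plus a
    per-subject jitter); the VPT density deficit and its long-range
    attenuation load on the long-range block only (see
    :func:`_presence_probabilities`).  For present pairs each directed
    count is ``1 + Poisson(gain * s * count_scale * r_ij m_ij)`` with a
    per-subject lognormal scale factor ``s`` and ``m`` the VPT long-range
    attenuation / hub boost, so expected counts also decay with distance
    and VPT long-range tracts carry attenuated weights.  Tract lengths
    are Euclidean distances with symmetric lognormal tortuosity.
    """
    if group not in ("FT", "VPT"):
        raise InvalidSpecError(f"unknown group {group!r}")
    labels, coords, dist = _geometry if _geometry is not None else network_geometry(spec)
    n = dist.shape[0]
    if spec.coord_jitter > 0:
        # per-subject anatomical variation: nodes shift, distances follow
        cs = coords + rng.normal(0.0, spec.coord_jitter, coords.shape)
        diff = cs[:, None, :] - cs[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
    mult = _magnitude_multipliers(spec, group, labels, dist)
    iu = np.triu_indices(n, k=1)
    # count magnitude grows sub-linearly with tract length, so the
    # length-normalised weight decays shallowly (w ~ d^-alpha): path cost
    # 1/w is concave in distance and long tracts act as genuine
    # shortcuts (the small-world property of association bundles)
    dmed = np.median(dist[iu])
    rel = np.maximum(dist / dmed, 1e-9)
    shape = np.where(
        rel <= 1.0,
        np.power(rel, 1.0 - spec.weight_exponent),
        np.power(rel, 1.0 - spec.weight_exponent_far),
    )
    rm = (shape * mult)[iu]
    target = spec.raw_density_ft if group == "FT" else spec.raw_density_vpt
    if target < 1.0 and spec.density_sd > 0:
        target = float(np.clip(rng.normal(target, spec.density_sd), 0.02, 0.98))
    # per-subject anatomy: how sharply connection probability decays with
    # distance varies across individuals, spreading clustering/efficiency
    sf = float(np.exp(rng.normal(0.0, spec.field_jitter))) if spec.field_jitter > 0 else 1.0
    present = rng.random(iu[0].size) < _presence_probabilities(spec, group, dist, target, sf)
    subj_scale = float(np.exp(rng.normal(0.0, spec.scale_jitter)))
    edge_noise = np.exp(rng.normal(0.0, spec.edge_jitter, iu[0].size))
    lam = gain * subj_scale * spec.count_scale * rm * edge_noise
    if group == "VPT" and spec.longrange_attenuation > 0:
        tort_proxy = dist[iu]  # lengths ~ dist; rank unaffected by tortuosity scale
        lam = lam * _rank_attenuation(spec, lam / np.maximum(tort_proxy, 1e-9), present)
    counts = np.zeros((n, n))
    up = np.zeros(iu[0].size)
    dn = np.zeros(iu[0].size)
    up[present] = 1.0 + rng.poisson(lam[present])
    dn[present] = 1.0 + rng.poisson(lam[present])
    counts[iu] = up
    counts[(iu[1], iu[0])] = dn
    tort = np.ones((n, n))
    tort[iu] = np.exp(rng.normal(0.0, spec.length_jitter, iu[0].size))
    tort = np.triu(tort, 1) + np.triu(tort, 1).T
    lengths = dist * tort
    np.fill_diagonal(lengths, 1.0)  # unused but must stay strictly positive
    return RawConnectome(counts=counts, lengths=lengths, labels=labels, subject_id=subject_id)


# ---------------------------------------------------------------------------
# behaviour


def generate_behaviour(
    spec: CohortSpec,
    groups,
    rng: np.random.Generator,
    brain_feature: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Indicator rows plus the generating latent scores.

    Latent scores are bivariate normal with unit variances and correlation
    ``factor_corr``; FT means are 0, VPT means are ``latent_mean_shift``.
    With a non-zero ``coupling_beta`` the first (speed) factor becomes
    ``mean + beta * brain_feature + sqrt(1 - beta^2) * disturbance`` so its
    marginal variance stays 1 for a standardised feature.  Indicators are
    ``y_j = tau_j + lambda_j * eta_f(j) + eps_j``; optional monotone skew
    and MCAR missingness are applied afterwards.
    """
    groups = np.asarray(groups)
    n = groups.size
    if spec.coupling_beta != 0 and brain_feature is None:
        raise InvalidSpecError("coupling_beta != 0 requires a brain_feature")
    phi = spec.factor_corr
    chol = np.linalg.cholesky(np.array([[1.0, phi], [phi, 1.0]]))
    zeta = rng.standard_normal((n, 2)) @ chol.T
    means = np.zeros((n, 2))
    means[groups == "VPT"] = np.asarray(spec.latent_mean_shift)
    eta = means + zeta
    if spec.coupling_beta != 0:
        b = spec.coupling_beta
        x = np.asarray(brain_feature, dtype=float)
        eta[:, 0] = means[:, 0] + b * x + np.sqrt(1.0 - b**2) * zeta[:, 0]
    lam = np.asarray(spec.loadings)
    fidx = np.array([FACTORS.index(INDICATOR_FACTOR[i]) for i in INDICATORS])
    res_sd = spec.resolved_residual_sd()
    eps = rng.standard_normal((n, 7)) * res_sd
    y = np.asarray(spec.intercepts) + eta[:, fidx] * lam + eps
    df = pd.DataFrame(y, columns=list(INDICATORS))
    for name in spec.skew:
        col = df[name]
        z = (col - col.mean()) / col.std(ddof=1)
        s = spec.skew_strength
        df[name] = (np.exp(s * z) - 1.0) / s  # monotone, identity as s -> 0
    if spec.missing_rate > 0:
        mask = rng.random((n, 7)) < spec.missing_rate
        df = df.mask(mask)
    return df, eta


# ---------------------------------------------------------------------------
# covariates and batches


def _assign_batches(spec: CohortSpec, groups: np.ndarray) -> np.ndarray:
    """Deterministic allocation of subjects to scanner batches.

    Within each group, batch counts follow the spec's batch table rescaled
    to the actual group size (largest-remainder rounding); subjects are
    assigned in index order so the allocation is seed-independent.
    """
    names = list(spec.batches)
    out = np.empty(groups.size, dtype=object)
    for group, key in (("FT", "n_ft"), ("VPT", "n_vpt")):
        idx = np.flatnonzero(groups == group)
        weights = np.array([spec.batches[b][key] for b in names], dtype=float)
        if weights.sum() == 0:
            weights = np.ones(len(names))
        quota = weights / weights.sum() * idx.size
        base = np.floor(quota).astype(int)
        rem = idx.size - base.sum()
        order = np.argsort(-(quota - base))
        base[order[:rem]] += 1
        pos = 0
        for b, cnt in zip(names, base):
            out[idx[pos : pos + cnt]] = b
            pos += cnt
    return out


def _generate_covariates(spec: CohortSpec, groups: np.ndarray, rng) -> pd.DataFrame:
    """Group-conditional covariates (loose caricatures for plumbing only)."""
    n = groups.size
    vpt = groups == "VPT"
    sex = rng.choice(["F", "M"], size=n, p=[0.39, 0.61])
    ses = rng.integers(1, 4, size=n).astype(float)
    ga = np.where(vpt, rng.normal(30.0, 1.9, n), rng.normal(40.0, 1.0, n))
    head = np.where(vpt, rng.normal(28.0, 2.7, n), rng.normal(35.0, 1.2, n))
    optim = np.where(vpt, rng.normal(4.8, 1.3, n), rng.normal(2.3, 1.5, n))
    inti = np.where(vpt, rng.normal(1.5, 0.6, n), np.nan)
    vent = np.where(vpt, (rng.random(n) < 0.5).astype(float), np.nan)
    motor6 = rng.normal(0.0, 1.0, n) + 0.5 * vpt
    motor8 = rng.normal(0.0, 1.0, n) + 0.4 * vpt
    return pd.DataFrame(
        {
            "sex": sex,
            "ses": ses,
            "ga": ga,
            "head_circumference": head,
            "optimality": optim,
            "inti": inti,
            "ventilation": vent,
            "motor_6y": motor6,
            "motor_8y": motor8,
        }
    )


def _subnetwork_clustering_feature(
    raws: list[RawConnectome], densities=DEFAULT_DENSITIES
) -> np.ndarray:
    """Per-subject subcortical-subnetwork binary clustering, density-averaged
    and z-scored across the cohort (the brain feature used for coupling)."""
    vals = []
    for raw in raws:
        net = build_network(raw)
        subs = subcortical_labels(net.labels)
        cs = [
            average_clustering(induced_subgraph(g, subs), "binary")
            for g in density_sweep(net, densities)
        ]
        vals.append(np.mean(cs))
    vals = np.asarray(vals)
    sd = vals.std(ddof=1)
    if sd == 0:
        return np.zeros_like(vals)
    return (vals - vals.mean()) / sd


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Assemble a complete synthetic cohort with its truth record."""
    root = np.random.SeedSequence(int(spec.seed))
    # fixed stream layout: 0 behaviour, 1 covariates, then one per subject
    children = root.spawn(2 + spec.n_total)
    groups = np.array(["FT"] * spec.n_ft + ["VPT"] * spec.n_vpt)
    ids = [f"sub{idx:04d}" for idx in range(spec.n_total)]
    batches = _assign_batches(spec, groups)
    geometry = network_geometry(spec)
    raws = []
    for idx, (sid, group, batch) in enumerate(zip(ids, groups, batches)):
        srng = np.random.default_rng(children[2 + idx])
        raws.append(
            generate_connectome(
                spec,
                group,
                srng,
                subject_id=sid,
                gain=spec.batches[batch].get("gain", 1.0),
                _geometry=geometry,
            )
        )
    feature = None
    if spec.coupling_beta != 0:
        feature = _subnetwork_clustering_feature(raws)
    beh_rng = np.random.default_rng(children[0])
    indicators, eta = generate_behaviour(spec, groups, beh_rng, brain_feature=feature)
    cov_rng = np.random.default_rng(children[1])
    covars = _generate_covariates(spec, groups, cov_rng)
    table = pd.concat(
        [
            pd.DataFrame({"id": ids, "group": groups, "batch": batches}),
            covars,
            indicators,
        ],
        axis=1,
    )
    truth = {
        "spec": asdict(spec),
        "eta": eta,
        "subject_ids": ids,
        "brain_feature": feature,
    }
    return CohortBundle(subjects=raws, table=table, truth=truth)
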