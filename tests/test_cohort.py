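"""Synthetic cohort generator: determinism, density algebra, factor model."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ccnet._errors import InvalidSpecError
from ccnet.cohort import (
    DEFAULT_LOADINGS,
    INDICATORS,
    CohortBundle,
    CohortSpec,
    expected_raw_density,
    generate_behaviour,
    generate_cohort,
    generate_connectome,
    network_geometry,
    node_labels,
    subcortical_labels,
)


def _raw_density(raw):
    n = raw.n_nodes
    iu = np.triu_indices(n, k=1)
    present = (raw.counts + raw.counts.T)[iu] > 0
    return present.mean()


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_nodes": 3},
            {"factor_corr": 1.0},
            {"missing_rate": 1.0},
            {"raw_density_ft": 0.0},
            {"longrange_attenuation": -0.5},
            {"n_ft": 0},
            {"residual_sd": (0.0,) * 7},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            CohortSpec(**kwargs)

    def test_default_residual_sd_completes_unit_variance(self):
        spec = CohortSpec()
        lam = np.asarray(spec.loadings)
        assert np.allclose(spec.resolved_residual_sd() ** 2 + lam**2, 1.0, atol=1e-5)


class TestGeometry:
    def test_labels_are_mirrored_hemispheres(self):
        labels = node_labels(66)
        assert len(labels) == 66
        assert sum(l.endswith("_L") for l in labels) == 33
        assert "caudate_R" in labels
        assert len(subcortical_labels(labels)) == 8

    def test_coordinates_mirror_across_midline(self):
        labels, coords, dist = network_geometry(CohortSpec(seed=3))
        half = len(labels) // 2
        assert np.allclose(coords[:half, 0], -coords[half : 2 * half, 0])
        assert np.allclose(coords[:half, 1:], coords[half : 2 * half, 1:])


class TestGenerateConnectome:
    def test_full_density_forces_every_edge(self):
        spec = CohortSpec(n_nodes=6, raw_density_ft=1.0, density_sd=0.0)
        rng = np.random.default_rng(0)
        raw = generate_connectome(spec, "FT", rng)
        off = ~np.eye(6, dtype=bool)
        assert np.all(raw.counts[off] > 0)

    def test_determinism_same_seed_same_counts(self):
        spec = CohortSpec(n_nodes=16, seed=5)
        a = generate_connectome(spec, "VPT", np.random.default_rng(42))
        b = generate_connectome(spec, "VPT", np.random.default_rng(42))
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.lengths, b.lengths)

    def test_group_density_ordering_and_longrange_gap(self):
        """Monte-Carlo check against the generator's expectation formula."""
        spec = CohortSpec(n_nodes=30, seed=9, density_sd=0.0, coord_jitter=0.0,
                          field_jitter=0.0)
        labels, _, dist = network_geometry(spec)
        iu = np.triu_indices(30, k=1)
        long_mask = dist[iu] > np.median(dist[iu])
        dens = {"FT": [], "VPT": []}
        long_dens = {"FT": [], "VPT": []}
        rng = np.random.default_rng(7)
        for g in ("FT", "VPT"):
            for _ in range(60):
                raw = generate_connectome(spec, g, rng)
                present = (raw.counts + raw.counts.T)[iu] > 0
                dens[g].append(present.mean())
                long_dens[g].append(present[long_mask].mean())
        for g in ("FT", "VPT"):
            assert np.mean(dens[g]) == pytest.approx(
                expected_raw_density(spec, g), abs=0.02
            )
        # overall ordering and the widened long-range gap
        assert np.mean(dens["VPT"]) < np.mean(dens["FT"])
        overall_gap = np.mean(dens["FT"]) - np.mean(dens["VPT"])
        long_gap = np.mean(long_dens["FT"]) - np.mean(long_dens["VPT"])
        assert long_gap > overall_gap

    def test_lengths_positive_and_symmetric(self):
        raw = generate_connectome(CohortSpec(n_nodes=12), "FT", np.random.default_rng(1))
        assert np.all(raw.lengths > 0)
        assert np.allclose(raw.lengths, raw.lengths.T)


class TestGenerateBehaviour:
    def test_no_common_factor_gives_identity_covariance(self, rng):
        spec = CohortSpec(loadings=(0.0,) * 7, residual_sd=(1.0,) * 7)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 4000), rng)
        c = df.cov().to_numpy()
        assert np.allclose(c, np.eye(7), atol=0.1)

    def test_implied_correlation_closed_form(self, rng):
        """corr(interference, bar) = lambda_i * lambda_b under the model."""
        spec = CohortSpec()
        df, _ = generate_behaviour(spec, np.array(["FT"] * 5000), rng)
        want = 0.902 * 0.836
        assert df["interference"].corr(df["bar"]) == pytest.approx(want, abs=0.03)

    def test_group_shift_propagates_by_loading(self, rng):
        """Large-n VPT-FT difference on an indicator = shift * loading."""
        spec = CohortSpec()
        groups = np.array(["FT"] * 20000 + ["VPT"] * 20000)
        df, _ = generate_behaviour(spec, groups, rng)
        diff = df["word"][20000:].mean() - df["word"][:20000].mean()
        assert diff == pytest.approx(-0.742 * 0.471, abs=0.03)

    def test_implied_covariance_matches_sample(self, rng):
        """Sigma = Lambda Phi Lambda' + Theta, entrywise within 3 MC SE."""
        spec = CohortSpec()
        n = 8000
        df, _ = generate_behaviour(spec, np.array(["FT"] * n), rng)
        lam = np.zeros((7, 2))
        lam[:5, 0] = DEFAULT_LOADINGS[:5]
        lam[5:, 1] = DEFAULT_LOADINGS[5:]
        phi = np.array([[1, spec.factor_corr], [spec.factor_corr, 1]])
        sigma = lam @ phi @ lam.T + np.diag(spec.resolved_residual_sd() ** 2)
        s = df.cov().to_numpy()
        mc_se = 3.0 * np.sqrt((sigma**2 + np.outer(np.diag(sigma), np.diag(sigma))) / n)
        assert np.all(np.abs(s - sigma) < 3 * mc_se + 0.02)

    def test_missingness_rate(self, rng):
        spec = CohortSpec(missing_rate=0.25)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 3000), rng)
        assert df.isna().to_numpy().mean() == pytest.approx(0.25, abs=0.02)

    def test_skew_transform_is_monotone(self, rng):
        spec = CohortSpec(skew=("word",))
        spec2 = CohortSpec()
        df, _ = generate_behaviour(spec, np.array(["FT"] * 500), np.random.default_rng(3))
        df2, _ = generate_behaviour(spec2, np.array(["FT"] * 500), np.random.default_rng(3))
        # same ranks, different shape
        assert (df["word"].rank() == df2["word"].rank()).all()
        from scipy.stats import skew

        assert skew(df["word"]) > skew(df2["word"]) + 0.5

    def test_coupling_requires_feature(self, rng):
        spec = CohortSpec(coupling_beta=0.3)
        with pytest.raises(InvalidSpecError):
            generate_behaviour(spec, np.array(["FT"] * 10), rng)


class TestGenerateCohort:
    def test_default_sizes(self, small_bundle):
        spec = CohortSpec()
        assert spec.n_total == 140
        assert spec.n_ft == 79 and spec.n_vpt == 61

    def test_small_cohort_assembles(self, small_bundle):
        assert len(small_bundle.subjects) == 54
        assert (small_bundle.table["group"] == "FT").sum() == 30

    def test_no_missing_when_rate_zero(self, small_bundle):
        assert not small_bundle.table[list(INDICATORS)].isna().any().any()

    def test_vpt_only_covariates_absent_for_ft(self, small_bundle):
        t = small_bundle.table
        assert t.loc[t["group"] == "FT", "inti"].isna().all()
        assert t.loc[t["group"] == "FT", "ventilation"].isna().all()
        assert t.loc[t["group"] == "VPT", "inti"].notna().all()

    def test_determinism_bit_identical(self):
        spec = CohortSpec(n_ft=6, n_vpt=5, n_nodes=12, seed=77)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for ra, rb in zip(a.subjects, b.subjects):
            assert np.array_equal(ra.counts, rb.counts)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_adding_subjects_keeps_earlier_ones(self):
        # uniform scanner gains: batch allocation quotas change with n,
        # but each subject's RNG stream must not
        batches = {"s1": {"n_ft": 1, "n_vpt": 1, "gain": 1.0},
                   "s2": {"n_ft": 1, "n_vpt": 1, "gain": 1.0}}
        small = generate_cohort(
            CohortSpec(n_ft=5, n_vpt=4, n_nodes=12, seed=8, batches=batches)
        )
        big = generate_cohort(
            CohortSpec(n_ft=9, n_vpt=4, n_nodes=12, seed=8, batches=batches)
        )
        for i in range(5):
            assert np.array_equal(small.subjects[i].counts, big.subjects[i].counts)

    def test_null_coupling_feature_uncorrelated(self):
        spec = CohortSpec(n_ft=60, n_vpt=60, n_nodes=16, seed=21, coupling_beta=0.0,
                          latent_mean_shift=(0.0, 0.0))
        b = generate_cohort(spec)
        from ccnet.cohort import _subnetwork_clustering_feature

        feat = _subnetwork_clustering_feature(b.subjects)
        eta = np.asarray(b.truth["eta"])
        r = np.corrcoef(feat, eta[:, 0])[0, 1]
        assert abs(r) < 0.2

    def test_round_trip_to_dir(self, tmp_path):
        spec = CohortSpec(n_ft=3, n_vpt=3, n_nodes=10, seed=4)
        b = generate_cohort(spec)
        b.to_dir(tmp_path / "c")
        back = CohortBundle.from_dir(tmp_path / "c")
        assert len(back.subjects) == 6
        for ra, rb in zip(b.subjects, back.subjects):
            assert np.array_equal(ra.counts, rb.counts)
            assert ra.labels == rb.labels
        assert back.truth["spec"]["seed"] == 4
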