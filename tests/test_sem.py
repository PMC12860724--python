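"""SEM engine: moment algebra, fit function, df counting, estimation."""

import numpy as np
import pandas as pd
import pytest

from ccnet._errors import EstimationError, InvalidSpecError
from ccnet.cohort import (
    DEFAULT_LOADINGS,
    INDICATOR_FACTOR,
    INDICATORS,
    CohortSpec,
    generate_behaviour,
)
from ccnet.sem import (
    SemModel,
    SemModelSpec,
    fml_discrepancy,
    implied_moments,
    lr_test,
)
from ccnet.sem.invariance import DEFAULT_EQUALITY, fit_measurement_model


def _mats(lam, psi, theta, tau=None, alpha=None):
    lam = np.asarray(lam, float)
    p, m = lam.shape
    return {
        "lambda": lam,
        "psi": np.asarray(psi, float),
        "theta": np.asarray(theta, float),
        "tau": np.zeros(p) if tau is None else np.asarray(tau, float),
        "alpha": np.zeros(m) if alpha is None else np.asarray(alpha, float),
        "gamma": np.zeros((m, 0)),
        "phi_x": np.zeros((0, 0)),
        "kappa": np.zeros(0),
    }


class TestImpliedMoments:
    def test_zero_loadings_give_theta(self):
        sigma, mu = implied_moments(_mats(np.zeros((3, 1)), [[1.0]], [0.3, 0.4, 0.5]))
        assert np.allclose(sigma, np.diag([0.3, 0.4, 0.5]))

    def test_one_factor_hand_computation(self):
        sigma, _ = implied_moments(
            _mats([[0.8], [0.6]], [[1.0]], [0.36, 0.64])
        )
        assert np.allclose(sigma, [[1.0, 0.48], [0.48, 1.0]])

    def test_mean_structure(self):
        _, mu = implied_moments(
            _mats([[0.9]], [[1.0]], [0.19], tau=[0.0], alpha=[0.5])
        )
        assert mu[0] == pytest.approx(0.45)


class TestDiscrepancy:
    def test_saturated_fit_is_zero(self, rng):
        s = np.cov(rng.normal(size=(50, 3)), rowvar=False)
        assert fml_discrepancy(s, None, s, None) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_two_variable(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        f = fml_discrepancy(s, None, np.eye(2), None)
        assert f == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_mean_term_vanishes_at_sample_mean(self):
        s = np.array([[2.0, 0.3], [0.3, 1.0]])
        xbar = np.array([1.0, -1.0])
        f0 = fml_discrepancy(s, xbar, s, xbar, with_means=True)
        assert f0 == pytest.approx(0.0, abs=1e-10)


class TestCountDf:
    def test_single_group_measurement_model(self):
        spec = SemModelSpec.cfa(
            INDICATOR_FACTOR, groups=("all",),
            equality_within=DEFAULT_EQUALITY, meanstructure=False,
        )
        assert spec.count_df() == 14

    def test_saturated_model_df_zero(self):
        # two indicators, one factor, equal loadings: exactly identified
        spec = SemModelSpec.cfa(
            {"a": "f", "b": "f"}, groups=("g",), meanstructure=False,
            equality_within=(("a", "b"),),
        )
        assert spec.count_df() == 0

    def test_two_group_partial_strong(self):
        spec = SemModelSpec.cfa(
            INDICATOR_FACTOR, groups=("FT", "VPT"),
            equality_within=DEFAULT_EQUALITY, invariance="strong",
            free_intercepts=("congruency",), meanstructure=True,
        )
        assert spec.count_df() == 36

    @pytest.mark.parametrize(
        "invariance,free_int,means,df",
        [
            ("configural", (), "auto", 28),
            ("weak", (), "auto", 32),
            ("strong", (), "auto", 37),
            ("strong", ("congruency",), "zero", 38),
        ],
    )
    def test_invariance_ladder_dfs(self, invariance, free_int, means, df):
        spec = SemModelSpec.cfa(
            INDICATOR_FACTOR, groups=("FT", "VPT"),
            equality_within=DEFAULT_EQUALITY, invariance=invariance,
            free_intercepts=free_int, meanstructure=True, latent_means=means,
        )
        assert spec.count_df() == df

    def test_partial_release_frees_exactly_one_df(self):
        strong = SemModelSpec.cfa(
            INDICATOR_FACTOR, groups=("FT", "VPT"),
            equality_within=DEFAULT_EQUALITY, invariance="strong",
            meanstructure=True,
        )
        partial = SemModelSpec.cfa(
            INDICATOR_FACTOR, groups=("FT", "VPT"),
            equality_within=DEFAULT_EQUALITY, invariance="strong",
            free_intercepts=("vsat",), meanstructure=True,
        )
        assert strong.count_df() - partial.count_df() == 1


class TestFitML:
    def test_zero_residual_identity(self):
        """Fitting exact implied moments recovers theta with chi2 ~ 0."""
        spec = SemModelSpec.cfa(
            INDICATOR_FACTOR, groups=("all",),
            equality_within=DEFAULT_EQUALITY, meanstructure=False,
        )
        truth = dict.fromkeys(spec.free_labels(), 0.0)
        lam = dict(zip(INDICATORS, DEFAULT_LOADINGS))
        for ind, v in lam.items():
            truth[f"lambda_{'trab' if ind == 'yabcl' else ind}_g0"] = v
        truth["psi_speed_attention_g0"] = 0.564
        for j, ind in enumerate(INDICATORS):
            truth[f"theta_{ind}_g0"] = 1.0 - lam[ind] ** 2
        sigma, _ = implied_moments(spec.matrices(truth)[0])
        model = SemModel.from_moments(spec, [sigma], [500])
        fit = model.fit(starts=3)
        assert fit.converged
        assert fit.chi_square == pytest.approx(0.0, abs=1e-4)
        for lab, v in truth.items():
            assert fit.params[lab] == pytest.approx(v, abs=1e-3), lab

    def test_multi_start_stability(self, rng):
        spec = CohortSpec(seed=1)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 800), rng)
        m = SemModel(
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("all",),
                equality_within=DEFAULT_EQUALITY, meanstructure=False,
            ),
            df,
        )
        a = m.fit(starts=1, seed=1)
        b = m.fit(starts=4, seed=2)
        assert np.allclose(a.params, b.params, atol=1e-3)

    def test_indicator_reordering_invariance(self, rng):
        spec = CohortSpec(seed=2)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 600), rng)
        fit1 = fit_measurement_model(df, starts=2)
        perm = ["bar", "word", "vsat", "interference", "congruency", "yabcl", "trab"]
        imap = {k: INDICATOR_FACTOR[k] for k in perm}
        fit2 = fit_measurement_model(df, indicator_map=imap,
                                     equality_within=(("yabcl", "trab"),), starts=2)
        assert fit2.chi_square == pytest.approx(fit1.chi_square, abs=1e-3)
        assert fit2.params["lambda_word_g0"] == pytest.approx(
            fit1.params["lambda_word_g0"], abs=1e-4
        )

    def test_cross_check_against_statsmodels_factor(self, rng):
        """1-factor ML CFA equals statsmodels ML factor analysis (EFA with
        one factor is rotation-free, so the two estimators coincide)."""
        from statsmodels.multivariate.factor import Factor

        lam_true = np.array([0.8, 0.7, 0.6, 0.5])
        n = 4000
        eta = rng.standard_normal(n)
        y = eta[:, None] * lam_true + rng.standard_normal((n, 4)) * np.sqrt(
            1 - lam_true**2
        )
        df = pd.DataFrame(y, columns=list("abcd"))
        spec = SemModelSpec.cfa(
            {c: "f" for c in "abcd"}, groups=("all",), meanstructure=False
        )
        fit = SemModel(spec, df).fit(starts=2)
        zdf = (df - df.mean()) / df.std()
        fa = Factor(zdf.to_numpy(), n_factor=1, method="ml").fit()
        ours = np.array([fit.params[f"lambda_{c}_g0"] for c in "abcd"])
        sds = df.std(ddof=0).to_numpy()
        theirs = np.abs(fa.loadings[:, 0]) * sds  # statsmodels standardises
        assert np.allclose(ours, theirs, atol=0.01)


class TestFIML:
    def test_equals_ml_on_complete_data(self, rng):
        spec = CohortSpec(seed=4)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 400), rng)
        m = SemModel(
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("all",),
                equality_within=DEFAULT_EQUALITY, meanstructure=True,
            ),
            df,
        )
        a = m.fit(method="ml", starts=2)
        b = m.fit(method="fiml", starts=2)
        assert np.allclose(a.params, b.params[a.params.index], atol=1e-4)

    def test_mcar_recovery(self, rng):
        spec = CohortSpec(seed=5, missing_rate=0.10)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 2000), rng)
        m = SemModel(
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("all",),
                equality_within=DEFAULT_EQUALITY, meanstructure=True,
            ),
            df,
        )
        fit = m.fit(method="fiml", starts=2)
        assert fit.converged
        assert fit.params["lambda_interference_g0"] == pytest.approx(0.902, abs=0.05)
        assert fit.params["lambda_word_g0"] == pytest.approx(0.471, abs=0.05)

    def test_all_missing_case_dropped(self, rng):
        spec = CohortSpec(seed=6)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 120), rng)
        df.iloc[0] = np.nan
        m = SemModel(
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("all",),
                equality_within=DEFAULT_EQUALITY, meanstructure=True,
            ),
            df,
        )
        assert m.ns[0] == 119


class TestFitIndices:
    def test_perfect_fit_saturates_indices(self):
        spec = SemModelSpec.cfa(
            {"a": "f", "b": "f", "c": "f"}, groups=("all",), meanstructure=False
        )
        truth = {l: v for l, v in zip(spec.free_labels(), [0.8, 0.7, 0.6, 0.36, 0.51, 0.64])}
        vals = spec.start_values()
        vals.update(
            {
                "lambda_a_g0": 0.8, "lambda_b_g0": 0.7, "lambda_c_g0": 0.6,
                "theta_a_g0": 0.36, "theta_b_g0": 0.51, "theta_c_g0": 0.64,
            }
        )
        sigma, _ = implied_moments(spec.matrices(vals)[0])
        fit = SemModel.from_moments(spec, [sigma], [300]).fit(starts=2)
        assert fit.cfi == pytest.approx(1.0)
        assert fit.rmsea == pytest.approx(0.0)
        assert fit.srmr == pytest.approx(0.0, abs=1e-5)

    def test_srmr_hand_computation(self):
        """Sample r = 0.48 vs implied r = 0.40 on 2 indicators -> 0.08."""
        spec = SemModelSpec.cfa(
            {"a": "f", "b": "f"}, groups=("all",), meanstructure=False,
            fixed_loadings={"a": 0.8, "b": 0.5},
        )
        s = np.array([[1.0, 0.48], [0.48, 1.0]])
        model = SemModel.from_moments(spec, [s], [200])
        fit = model.fit(starts=2)
        # force the implied correlation to exactly 0.40 by pinning params
        vals = dict(fit.params)
        vals["psi_f_g0"] = 1.0
        vals["theta_a_g0"] = 1 - 0.64
        vals["theta_b_g0"] = 1 - 0.25
        pinned = fit.params.copy()
        for k, v in vals.items():
            pinned[k] = v
        object.__setattr__(fit, "params", pinned)
        assert fit.srmr == pytest.approx(0.08, abs=1e-6)


class TestLrTest:
    def test_identical_models(self, rng):
        spec = CohortSpec(seed=7)
        df, _ = generate_behaviour(spec, np.array(["FT"] * 300), rng)
        fit = fit_measurement_model(df, starts=2)
        with pytest.raises(EstimationError):
            lr_test(fit, fit)  # delta df = 0 is a nesting error

    def test_nested_comparison_positive(self, rng):
        spec = CohortSpec(seed=8)
        groups = np.array(["FT"] * 300 + ["VPT"] * 300)
        df, _ = generate_behaviour(spec, groups, rng)
        df["group"] = groups
        weak = SemModel(
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("FT", "VPT"),
                equality_within=DEFAULT_EQUALITY, invariance="weak",
                meanstructure=True,
            ),
            df,
        ).fit(starts=2)
        conf = SemModel(
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("FT", "VPT"),
                equality_within=DEFAULT_EQUALITY, invariance="configural",
                meanstructure=True,
            ),
            df,
        ).fit(starts=2)
        d, ddf, p = lr_test(weak, conf)
        assert ddf == 4
        assert 0 <= p <= 1


class TestSpecErrors:
    def test_unknown_invariance(self):
        with pytest.raises(InvalidSpecError):
            SemModelSpec.cfa(INDICATOR_FACTOR, groups=("a", "b"), invariance="ultra")

    def test_free_intercepts_need_strong(self):
        with pytest.raises(InvalidSpecError):
            SemModelSpec.cfa(
                INDICATOR_FACTOR, groups=("a", "b"), invariance="weak",
                free_intercepts=("word",),
            )
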