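import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ldlsim.gam import (
    AdditiveModel,
    FitSummary,
    LinearTerm,
    ModelSpec,
    SmoothTerm,
    TensorTerm,
    compare_models,
    estimate_rho,
    fit_additive_model,
    nonword_model_spec,
    prewhiten,
    tally_across_subjects,
    word_model_spec,
)


def ar1_series(n, rho, rng, sd=1.0):
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    innov = sd * np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + rng.normal(0, innov)
    return x


class TestEstimateRho:
    def test_iid_residuals_near_zero(self):
        rng = np.random.default_rng(0)
        r = rng.normal(size=10_000)
        sessions = np.repeat(np.arange(10), 1000)
        assert abs(estimate_rho(r, sessions)) < 0.05

    def test_recovers_true_rho(self):
        rng = np.random.default_rng(1)
        sessions = np.repeat(np.arange(4), 2500)
        r = np.concatenate([ar1_series(2500, 0.5, rng) for _ in range(4)])
        assert estimate_rho(r, sessions) == pytest.approx(0.5, abs=0.05)

    def test_alternating_sequence_near_minus_one(self):
        r = np.tile([1.0, -1.0], 500)
        assert estimate_rho(r, np.zeros(1000)) == pytest.approx(-1.0, abs=0.01)

    def test_cross_session_pairs_excluded(self):
        # only the two within-session pairs enter the numerator
        r = np.array([1.0, 1.0, -1.0, -1.0])
        assert estimate_rho(r, np.array([0, 0, 1, 1])) == pytest.approx(0.5)

    def test_singleton_sessions_rejected(self):
        with pytest.raises(ValueError):
            estimate_rho(np.array([1.0, 2.0]), np.array([0, 1]))


class TestPrewhiten:
    def test_rho_zero_identity(self, rng):
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 3))
        yw, Xw = prewhiten(y, X, 0.0, np.zeros(20))
        assert np.array_equal(yw, y) and np.array_equal(Xw, X)

    def test_session_first_rows_untouched(self, rng):
        y = rng.normal(size=9)
        X = rng.normal(size=(9, 2))
        sessions = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        yw, Xw = prewhiten(y, X, 0.7, sessions)
        for start in (0, 3, 6):
            assert yw[start] == y[start]
            assert np.array_equal(Xw[start], X[start])
        assert yw[1] == pytest.approx(y[1] - 0.7 * y[0])

    def test_single_row_sessions_all_untouched(self, rng):
        y = rng.normal(size=5)
        X = rng.normal(size=(5, 2))
        yw, Xw = prewhiten(y, X, 0.9, np.arange(5))
        assert np.array_equal(yw, y) and np.array_equal(Xw, X)

    def test_prewhitening_removes_ar1_autocorrelation(self):
        rng = np.random.default_rng(2)
        sessions = np.repeat(np.arange(5), 2000)
        y = np.concatenate([ar1_series(2000, 0.6, rng) for _ in range(5)])
        X = np.ones((10_000, 1))
        yw, _ = prewhiten(y, X, 0.6, sessions)
        assert abs(estimate_rho(yw, sessions)) < 0.05
        assert abs(estimate_rho(yw, sessions)) < abs(estimate_rho(y, sessions))


def sim_table(rng, n=800, f=lambda x: 2.0 * x, noise=0.3):
    x = rng.uniform(-1, 1, size=n)
    y = f(x) + rng.normal(0, noise, size=n)
    return pd.DataFrame({"rt_inv": y, "x": x, "session": np.repeat([1, 2], n // 2)})


class TestAdditiveModel:
    def test_linear_truth_recovered_with_low_edf(self):
        rng = np.random.default_rng(3)
        df = sim_table(rng)
        spec = ModelSpec(label="lin", terms=(SmoothTerm("x", k=10),))
        m = AdditiveModel(spec=spec).fit(df)
        grid = pd.DataFrame({"x": np.linspace(-0.8, 0.8, 9)})
        eff = m.partial_effect("s(x)", grid)
        slopes = np.diff(eff) / np.diff(grid["x"])
        assert np.all(slopes > 0)
        assert np.mean(slopes) == pytest.approx(2.0, abs=0.25)
        assert m.edf_by_term_["s(x)"] < 3.0
        assert m.pvalues_["s(x)"] < 1e-6

    def test_sine_truth_recovered(self):
        rng = np.random.default_rng(4)
        df = sim_table(rng, n=1500, f=lambda x: np.sin(3.0 * x), noise=0.2)
        spec = ModelSpec(label="sin", terms=(SmoothTerm("x", k=12),))
        m = AdditiveModel(spec=spec).fit(df)
        grid = pd.DataFrame({"x": np.linspace(-0.9, 0.9, 50)})
        eff = m.partial_effect("s(x)", grid)
        truth = np.sin(3.0 * grid["x"].to_numpy())
        truth -= truth.mean()
        rms = np.sqrt(np.mean((eff - eff.mean() - truth) ** 2))
        assert rms < 0.1

    def test_true_predictor_lowers_aic(self):
        rng = np.random.default_rng(5)
        df = sim_table(rng, n=600, f=lambda x: 1.5 * x, noise=0.3)
        null = AdditiveModel(spec=ModelSpec(label="null", terms=())).fit(df)
        full = AdditiveModel(spec=ModelSpec(label="full", terms=(SmoothTerm("x", k=8),))).fit(df)
        assert full.aic_ < null.aic_ - 10

    def test_matches_statsmodels_glmgam_oracle(self):
        """Independent cross-check of the penalized fit against GLMGam."""
        from statsmodels.gam.api import GLMGam
        from statsmodels.gam.smooth_basis import BSplines

        rng = np.random.default_rng(6)
        df = sim_table(rng, n=700, f=lambda x: np.sin(2.5 * x), noise=0.25)
        m = AdditiveModel(spec=ModelSpec(label="s", terms=(SmoothTerm("x", k=10),))).fit(df)
        bs = BSplines(df[["x"]].to_numpy(), df=[10], degree=[3])
        gg = GLMGam(df["rt_inv"], exog=np.ones((len(df), 1)), smoother=bs, alpha=[0.01])
        gg.fit()
        alpha = gg.select_penweight()[0]  # statsmodels' own smoothing selection
        ggr = GLMGam(df["rt_inv"], exog=np.ones((len(df), 1)), smoother=bs, alpha=alpha).fit()
        # compare fitted values (partial effects differ by centering convention)
        yhat_ours = m.predict(df)
        yhat_theirs = ggr.fittedvalues
        assert np.corrcoef(yhat_ours, yhat_theirs)[0, 1] > 0.999
        assert np.sqrt(np.mean((yhat_ours - yhat_theirs) ** 2)) < 0.02

    def test_rank_deficient_design_names_terms(self, rng):
        df = pd.DataFrame({
            "rt_inv": rng.normal(size=50),
            "a": np.ones(50),  # aliased with the intercept
            "session": 1,
        })
        spec = ModelSpec(label="bad", terms=(LinearTerm("a"),))
        with pytest.raises(ValueError, match="rank-deficient"):
            AdditiveModel(spec=spec).fit(df)

    def test_missing_columns_rejected(self, rng):
        df = pd.DataFrame({"rt_inv": rng.normal(size=30), "session": 1})
        with pytest.raises(ValueError, match="missing"):
            AdditiveModel(spec=ModelSpec(label="m", terms=(SmoothTerm("zz"),))).fit(df)

    def test_by_smooth_only_affects_gated_rows(self):
        rng = np.random.default_rng(7)
        n = 1000
        x = rng.uniform(-1, 1, n)
        g = (rng.random(n) < 0.5).astype(float)
        y = np.where(g == 1, 2.0 * x, 0.0) + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"rt_inv": y, "x": x, "g": g, "session": 1})
        spec = ModelSpec(label="by", terms=(LinearTerm("g"), SmoothTerm("x", by="g", k=8)))
        m = AdditiveModel(spec=spec).fit(df)
        gated = pd.DataFrame({"x": [0.5, -0.5], "g": [1.0, 1.0]})
        off = pd.DataFrame({"x": [0.5, -0.5], "g": [0.0, 0.0]})
        assert abs(np.diff(m.partial_effect("s(x,by=g)", gated))[0]) > 1.0
        assert np.allclose(m.partial_effect("s(x,by=g)", off), 0.0)

    def test_tensor_interaction_recovered(self):
        rng = np.random.default_rng(8)
        n = 1200
        x1 = rng.uniform(-1, 1, n)
        x2 = rng.uniform(-1, 1, n)
        y = x1 * x2 + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"rt_inv": y, "x1": x1, "x2": x2, "session": 1})
        spec = ModelSpec(label="te", terms=(TensorTerm("x1", "x2", k=5),))
        m = AdditiveModel(spec=spec).fit(df)
        grid = pd.DataFrame({"x1": [0.8, 0.8, -0.8, -0.8], "x2": [0.8, -0.8, 0.8, -0.8]})
        eff = m.partial_effect("te(x1,x2)", grid)
        assert eff[0] > eff[1] and eff[0] > eff[2]  # saddle shape of x1*x2
        assert eff[3] > eff[1] and eff[3] > eff[2]

    def test_ar1_fit_beats_unwhitened_on_ar1_data(self):
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.uniform(-1, 1, n)
        sessions = np.repeat(np.arange(4), n // 4)
        noise = np.concatenate([ar1_series(n // 4, 0.6, rng, sd=0.3) for _ in range(4)])
        y = 1.2 * x + noise
        df = pd.DataFrame({"rt_inv": y, "x": x, "session": sessions})
        spec = ModelSpec(label="m", terms=(SmoothTerm("x", k=8),))
        raw = AdditiveModel(spec=spec, rho=0.0).fit(df)
        rho = estimate_rho(raw.residuals_, raw.sessions_)
        assert rho == pytest.approx(0.6, abs=0.07)
        white = AdditiveModel(spec=spec, rho=rho).fit(df)
        assert abs(estimate_rho(white.residuals_, white.sessions_)) < 0.05

    def test_sklearn_clone_compat(self):
        spec = ModelSpec(label="m", terms=(SmoothTerm("x", k=8),))
        m = AdditiveModel(spec=spec, rho=0.3)
        assert clone(m).get_params()["rho"] == 0.3


def summary(aic, n=100, label="a", subject=1, pvals=None):
    return FitSummary(label=label, aic=aic, edf=5.0, pvalues=pvals or {}, rho=0.0,
                      n=n, converged=True, subject=subject)


class TestComparisonsAndTallies:
    def test_equal_aics(self):
        c = compare_models(summary(100.0), summary(100.0, label="b"))
        assert c.delta_aic == 0.0 and c.relative_likelihood == 1.0

    def test_delta_two_gives_e(self):
        c = compare_models(summary(102.0), summary(100.0, label="b"))
        assert c.relative_likelihood == pytest.approx(np.e)
        assert c.better == "b"

    def test_hand_arithmetic_and_row_count_guard(self):
        c = compare_models(summary(87.3), summary(90.1, label="b"))
        assert c.delta_aic == pytest.approx(-2.8)
        assert c.better == "a"
        with pytest.raises(ValueError):
            compare_models(summary(1.0), summary(2.0, n=99))

    def test_tally_hand_counts(self):
        comps = [
            compare_models(summary(100 + d, subject=i), summary(100.0, label="b", subject=i))
            for i, d in enumerate([3.0, 1.0, -2.0, 4.0, 0.5])
        ]
        fits = [
            summary(0, label="b", subject=i, pvals={"s(x)": p})
            for i, p in enumerate([1e-5, 1e-2, 1e-6, 1e-9, 0.5])
        ]
        t = tally_across_subjects(comps, fits, alpha=0.001)
        assert t["pct_b_better"] == pytest.approx(80.0)
        assert t["mean_delta_aic"] == pytest.approx(np.mean([3, 1, -2, 4, 0.5]))
        assert t["reliability_pct"]["s(x)"] == pytest.approx(60.0)


class TestCanonicalSpecs:
    def test_static_specs_exclude_yes_activation(self):
        for spec_of in (word_model_spec, nonword_model_spec):
            for family in ("classical", "static_dlm", "dynamic_dlm_no_yesact"):
                assert "yes_activation" not in spec_of(family).columns()
            assert "yes_activation" in spec_of("dynamic_dlm").columns()

    def test_nonword_dynamic_has_tensor_by_response(self):
        spec = nonword_model_spec("dynamic_dlm")
        tensors = [t for t in spec.terms if isinstance(t, TensorTerm)]
        assert {t.by for t in tensors} == {"response_word", "response_nonword"}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            word_model_spec("bayesian")
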