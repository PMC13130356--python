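"""KDM estimator: closed-form OLS oracles, formula identities, invariances."""
import math

import numpy as np
import pandas as pd
import pytest

import bioaging as ba
from bioaging.kdm import BiomarkerFit, KDMModel, _ba_e


def frame(age, **cols):
    return pd.DataFrame({"age": age, **cols})


class TestBiomarkerRegressions:
    def test_noiseless_line_recovered_exactly(self):
        df = frame([40.0, 50.0, 60.0, 70.0])
        df["x"] = 2.0 + 0.5 * df["age"]
        (fit,) = ba.fit_biomarker_regressions(df, ["x"])
        assert fit.q == pytest.approx(2.0, abs=1e-10)
        assert fit.k == pytest.approx(0.5, abs=1e-12)
        assert fit.s == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_ols_oracle(self):
        # (40,10), (50,20), (60,24): slope 0.7, intercept -17,
        # residuals (-1, 2, -1), RMSE sqrt(6/3) = sqrt(2)
        df = frame([40.0, 50.0, 60.0], x=[10.0, 20.0, 24.0])
        (fit,) = ba.fit_biomarker_regressions(df, ["x"])
        assert fit.k == pytest.approx(0.7)
        assert fit.q == pytest.approx(-17.0)
        assert fit.s == pytest.approx(math.sqrt(2.0))
        # the n-2 divisor flavour
        (fit2,) = ba.fit_biomarker_regressions(df, ["x"], rmse_divisor="n-2")
        assert fit2.s == pytest.approx(math.sqrt(6.0))

    def test_constant_biomarker_warns_and_keeps_zero_slope(self):
        df = frame([40.0, 50.0, 60.0], x=[5.0, 5.0, 5.0])
        with pytest.warns(UserWarning, match="zero KDM weight"):
            (fit,) = ba.fit_biomarker_regressions(df, ["x"])
        assert fit.k == 0.0

    def test_degenerate_age_errors(self):
        df = frame([50.0, 50.0, 50.0], x=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate age"):
            ba.fit_biomarker_regressions(df, ["x"])

    def test_too_few_records_errors(self):
        df = frame([40.0, 50.0], x=[1.0, 2.0])
        with pytest.raises(ValueError, match="fewer than 3"):
            ba.fit_biomarker_regressions(df, ["x"])


class TestSba:
    def test_direct_evaluation_oracle(self):
        # single biomarker q=0,k=1,s=1; CAs {40,60}, x={41,59}:
        # BA_E = {41,59}, deviations {1,-1}, Var=2, noise 1, s_ba = 1
        fit = BiomarkerFit("x", q=0.0, k=1.0, s=1.0, n_train=3)
        df = frame([40.0, 60.0], x=[41.0, 59.0])
        assert ba.estimate_sba(df, [fit]) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        age = rng.uniform(30, 80, 400)
        df = frame(age, x=1.0 + 0.4 * age + rng.normal(0, 3, 400))
        fits = ba.fit_biomarker_regressions(df, ["x"])
        s_ba = ba.estimate_sba(df, fits)
        df2 = df.assign(x=2.5 * df["x"] - 7.0)
        fits2 = ba.fit_biomarker_regressions(df2, ["x"])
        assert ba.estimate_sba(df2, fits2) == pytest.approx(s_ba, abs=1e-8)

    def test_degenerate_limit_floors_with_warning(self, rng):
        age = rng.uniform(30, 80, 100)
        df = frame(age, x=1.0 + 0.4 * age)  # noiseless
        fits = ba.fit_biomarker_regressions(df, ["x"])
        with pytest.warns(UserWarning, match="s_ba floored"):
            s_ba = ba.estimate_sba(df, fits)
        assert s_ba == pytest.approx(math.sqrt(1e-6))

    def test_all_zero_slopes_error(self):
        fit = BiomarkerFit("x", q=5.0, k=0.0, s=1.0, n_train=3)
        df = frame([40.0, 60.0], x=[5.0, 5.0])
        with pytest.raises(ValueError, match="no informative biomarkers"):
            ba.estimate_sba(df, [fit])


def two_marker_model(s_ba=10.0):
    return KDMModel(
        fits=[
            BiomarkerFit("a", q=0.0, k=1.0, s=1.0, n_train=10),
            BiomarkerFit("b", q=10.0, k=2.0, s=2.0, n_train=10),
        ],
        s_ba=s_ba,
        sba_method="fixed",
    )


class TestComputeKdm:
    def test_direct_formula_oracle(self):
        # terms 57 and 45, CA term 0.5; denominator 2.01 -> 102.5/2.01
        df = frame([50.0], a=[57.0], b=[100.0])
        scores = ba.compute_kdm(two_marker_model(), df)
        assert scores["kdm_age"].iloc[0] == pytest.approx(102.5 / 2.01, abs=1e-9)

    @pytest.mark.parametrize("s_ba", [0.5, 10.0, 1e4])
    def test_mean_trajectory_identity(self, s_ba, rng):
        model = two_marker_model(s_ba)
        age = rng.uniform(20, 90, 50)
        df = frame(age, a=age, b=10.0 + 2.0 * age)
        scores = ba.compute_kdm(model, df)
        assert np.allclose(scores["kdm_age"], age, atol=1e-9)

    def test_sba_limits(self, rng):
        age = rng.uniform(30, 80, 30)
        df = frame(age, a=age + rng.normal(0, 1, 30), b=10.0 + 2.0 * age + rng.normal(0, 2, 30))
        pure = _ba_e(df, two_marker_model().fits)
        near_inf = ba.compute_kdm(two_marker_model(1e8), df)["kdm_age"]
        assert np.allclose(near_inf, pure, atol=1e-6)
        near_zero = ba.compute_kdm(two_marker_model(1e-7), df)["kdm_age"]
        assert np.allclose(near_zero, age, atol=1e-6)

    def test_incomplete_records_are_excluded(self):
        df = frame([50.0, 60.0, 70.0], a=[57.0, np.nan, 70.0], b=[100.0, 120.0, 150.0])
        scores = ba.compute_kdm(two_marker_model(), df)
        assert len(scores) == 2
        assert 1 not in scores.index

    def test_oracle_equivalence_on_random_records(self, rng):
        """Vectorized scorer matches a naive per-record evaluation of the
        published formula to 1e-10 on 1000 random records."""
        fits = [
            BiomarkerFit(f"m{i}", q=rng.normal(0, 50), k=rng.normal(0.5, 0.3) + 0.05,
                         s=rng.uniform(0.5, 5), n_train=100)
            for i in range(10)
        ]
        model = KDMModel(fits=fits, s_ba=rng.uniform(2, 20), sba_method="fixed")
        n = 1000
        df = frame(rng.uniform(20, 90, n), **{f.name: rng.normal(30, 40, n) for f in fits})
        scores = ba.compute_kdm(model, df)
        for idx in range(n):
            ca = df["age"].iloc[idx]
            num = sum((df[f.name].iloc[idx] - f.q) * f.k / f.s**2 for f in fits)
            den = sum(f.k**2 / f.s**2 for f in fits)
            expected = (num + ca / model.s_ba**2) / (den + 1 / model.s_ba**2)
            assert scores["kdm_age"].iloc[idx] == pytest.approx(expected, abs=1e-10)


class TestInvariances:
    def test_affine_invariance_of_scores(self, small_cohort):
        names = list(ba.KDM_BIOMARKERS)
        model = ba.fit_kdm(small_cohort, names)
        scores = ba.compute_kdm(model, small_cohort)
        warped = small_cohort.copy()
        warped["total_cholesterol"] = 0.3 * warped["total_cholesterol"] + 7.0
        warped["albumin"] = -2.0 * warped["albumin"] + 1.0
        model2 = ba.fit_kdm(warped, names)
        scores2 = ba.compute_kdm(model2, warped)
        assert np.allclose(scores["kdm_age"], scores2["kdm_age"], atol=1e-8)

    def test_zero_slope_marker_carries_no_weight(self, small_cohort):
        names = list(ba.KDM_BIOMARKERS)
        with_flat = small_cohort.assign(flat=3.14)
        with pytest.warns(UserWarning, match="zero KDM weight"):
            fits = ba.fit_biomarker_regressions(with_flat, names + ["flat"])
        s_ba = ba.estimate_sba(with_flat, fits)
        model_flat = KDMModel(fits=fits, s_ba=s_ba, sba_method="fixed")
        model_base = KDMModel(fits=fits[:-1], s_ba=s_ba, sba_method="fixed")
        k_flat = ba.compute_kdm(model_flat, with_flat)["kdm_age"]
        k_base = ba.compute_kdm(model_base, with_flat)["kdm_age"]
        assert np.allclose(k_flat, k_base, atol=1e-10)


class TestAcceleration:
    def test_kdm_equal_to_age_gives_zero_residuals(self):
        df = frame([40.0, 50.0, 60.0])
        scores = pd.DataFrame({"kdm_age": df["age"]}, index=df.index)
        out = ba.compute_age_acceleration(scores, df)
        assert np.allclose(out["acceleration"], 0.0, atol=1e-12)
        assert (out["accelerated"] == 0).all()

    def test_closed_form_residual_oracle(self):
        # kdm = CA + {+2,-2,0}: slope 0.9, intercept 5, residuals {1,-2,1}
        df = frame([40.0, 50.0, 60.0])
        scores = pd.DataFrame({"kdm_age": [42.0, 48.0, 60.0]}, index=df.index)
        out = ba.compute_age_acceleration(scores, df)
        assert np.allclose(out["acceleration"], [1.0, -2.0, 1.0], atol=1e-10)
        assert list(out["accelerated"]) == [1, 0, 1]

    def test_residuals_sum_to_zero_on_fitting_sample(self, analytic_cohort):
        analytic, _, _ = analytic_cohort
        assert analytic["acceleration"].sum() == pytest.approx(0.0, abs=1e-8 * len(analytic))
        assert analytic["acceleration"].mean() == pytest.approx(0.0, abs=1e-8)


def test_model_serialization_round_trip(tmp_path, small_cohort):
    model = ba.fit_kdm(small_cohort, list(ba.KDM_BIOMARKERS))
    path = tmp_path / "kdm.yaml"
    model.to_file(path)
    loaded = KDMModel.from_file(path)
    assert loaded.s_ba == pytest.approx(model.s_ba)
    assert loaded.biomarker_names == model.biomarker_names
    s1 = ba.compute_kdm(model, small_cohort)["kdm_age"]
    s2 = ba.compute_kdm(loaded, small_cohort)["kdm_age"]
    assert np.array_equal(s1.to_numpy(), s2.to_numpy())


def test_parameter_recovery_within_3_se():
    """Fitted (q, k) land within 3 SEs of the generative values at n=10,000."""
    cfg = ba.default_config(n_participants=10_000, seed=13)
    cohort = ba.generate_cohort(cfg)
    fits = {f.name: f for f in ba.fit_biomarker_regressions(cohort, list(ba.KDM_BIOMARKERS))}
    age = cohort["age"].to_numpy()
    sxx = np.sum((age - age.mean()) ** 2)
    for spec in cfg.biomarker_specs:
        fit = fits[spec.name]
        # residual SD includes the +/-10y latent shift contribution
        resid_sd = math.sqrt(spec.s_true**2 + (cfg.latent_shift_years * spec.k_true) ** 2)
        se_k = resid_sd / math.sqrt(sxx)
        assert abs(fit.k - spec.k_true) < 3 * se_k, spec.name
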