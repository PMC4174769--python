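import numpy as np
import pandas as pd
import pytest

from spiroquant import (
    ancova_group_compare,
    age_trend,
    brainvol_association,
    correlate_measures,
    exclusion_filter,
    transform_and_zscore,
    tremor_prevalence,
)
from spiroquant.analysis import (
    LOG_MEASURES,
    MEASURE_COLUMNS,
    _fit_ols,
    score_to_numeric,
)
from spiroquant.errors import CollinearityError, DegenerateInputError


def _measures_frame(rng, n):
    return pd.DataFrame(
        {
            "length_cm": rng.normal(57.6, 3.9, n),
            "movement_time_s": rng.lognormal(np.log(16.4), 0.35, n),
            "avg_speed": rng.lognormal(np.log(3.5), 0.34, n),
            "speed_variability": rng.lognormal(np.log(1.7), 0.3, n),
            "deviation_area": rng.lognormal(np.log(5.8), 0.44, n),
            "crossings": rng.poisson(5.3, n).astype(float) + 0.5,
        }
    )


class TestTransformAndZscore:
    def test_matches_manual_recomputation(self):
        rng = np.random.default_rng(1)
        df = _measures_frame(rng, 5)
        std = transform_and_zscore(df)
        for col in MEASURE_COLUMNS:
            v = df[col].to_numpy()
            if col in LOG_MEASURES:
                v = np.log(v)
            expected = (v - v.mean()) / v.std(ddof=1)
            np.testing.assert_allclose(std.frame[col].to_numpy(), expected, atol=1e-12)

    def test_columns_standardized(self):
        std = transform_and_zscore(_measures_frame(np.random.default_rng(2), 200))
        for col in MEASURE_COLUMNS:
            assert std.frame[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert std.frame[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert set(std.log_transformed) == set(LOG_MEASURES)

    def test_standardization_is_idempotent(self):
        std = transform_and_zscore(_measures_frame(np.random.default_rng(3), 50))
        again = transform_and_zscore(std.frame, log_measures=())
        pd.testing.assert_frame_equal(std.frame, again.frame)

    def test_zero_variance_rejected(self):
        df = _measures_frame(np.random.default_rng(4), 20)
        df["length_cm"] = 57.6
        with pytest.raises(DegenerateInputError):
            transform_and_zscore(df)

    def test_non_positive_log_measure_names_rows(self):
        df = _measures_frame(np.random.default_rng(5), 20)
        df.loc[7, "deviation_area"] = 0.0
        with pytest.raises(DegenerateInputError, match="deviation_area.*7"):
            transform_and_zscore(df)


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.normal(77.4, 6.8, n),
            "sex": np.where(rng.random(n) < 0.6, "female", "male"),
            "primary_education_only": rng.random(n) < 0.2,
        }
    )


class TestAncova:
    def test_type_one_error_near_nominal(self):
        # 1,000 null replicates, n=100/group: rejection rate at alpha=0.05
        rng = np.random.default_rng(20260)
        rejections = 0
        n = 200
        for _ in range(1000):
            df = _covariates(rng, n)
            df["tremor"] = np.arange(n) < 100
            df["y"] = rng.standard_normal(n)
            p = ancova_group_compare(df, "y").term("tremor")["p"]
            rejections += p < 0.05
        assert 35 <= rejections <= 65

    def test_recovers_injected_group_shift(self):
        rng = np.random.default_rng(77)
        covered = 0
        n = 400
        for _ in range(100):
            df = _covariates(rng, n)
            df["tremor"] = np.arange(n) < 200
            df["y"] = rng.standard_normal(n) + 1.0 * df["tremor"]
            r = ancova_group_compare(df, "y").term("tremor")
            covered += r["ci_low"] <= 1.0 <= r["ci_high"]
        assert covered >= 93

    def test_single_group_rejected(self):
        df = _covariates(np.random.default_rng(0), 20)
        df["tremor"] = True
        df["y"] = 0.0
        with pytest.raises(DegenerateInputError):
            ancova_group_compare(df, "y")

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(1)
        df = _covariates(rng, 50)
        df["tremor"] = np.arange(50) < 25
        df["age_copy"] = df["age"]
        df["y"] = rng.standard_normal(50)
        with pytest.raises(CollinearityError):
            ancova_group_compare(df, "y", covariates=("age", "age_copy"))


class TestAgeTrend:
    def test_quadratic_rarely_significant_on_pure_linear_outcome(self):
        rng = np.random.default_rng(404)
        false_hits = 0
        for _ in range(100):
            df = _covariates(rng, 600)
            df["y"] = 0.03 * df["age"] + rng.standard_normal(600)
            quad = age_trend(df, "y").quadratic.term("age_c_sq")
            false_hits += quad["p"] < 0.05
        assert false_hits <= 6

    def test_linear_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(505)
        hits = 0
        for _ in range(200):
            df = _covariates(rng, 300)
            df["y"] = rng.standard_normal(300)
            hits += age_trend(df, "y").linear.term("age")["p"] < 0.05
        assert 2 <= hits <= 20

    def test_detects_knee_shaped_quadratic(self):
        rng = np.random.default_rng(9)
        df = _covariates(rng, 2000)
        knot = np.maximum(df["age"] - 75.0, 0.0)
        df["y"] = 0.02 * df["age"] + 0.004 * knot**2 + rng.standard_normal(2000)
        assert age_trend(df, "y").quadratic.term("age_c_sq")["p"] < 0.01

    def test_binned_means_track_truth(self):
        rng = np.random.default_rng(10)
        df = _covariates(rng, 4000)
        df["y"] = 0.1 * (df["age"] - 77.4) + 0.05 * rng.standard_normal(4000)
        res = age_trend(df, "y")
        b = res.binned_means.set_index("age_bin")
        assert b.loc["75-79", "adjusted_mean"] == pytest.approx(0.1 * (77.5 - 77.4), abs=0.05)
        assert b.loc["85-89", "adjusted_mean"] > b.loc["70-74", "adjusted_mean"]
        assert int(b["n"].sum()) == 4000

    def test_empty_bin_reported_missing(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "age": rng.uniform(66, 76, 200),
                "sex": np.where(rng.random(200) < 0.5, "female", "male"),
            }
        )
        df["y"] = rng.standard_normal(200)
        res = age_trend(df, "y")
        b = res.binned_means.set_index("age_bin")
        assert np.isnan(b.loc["90+", "adjusted_mean"])
        assert b.loc["90+", "n"] == 0

    def test_narrow_age_span_rejected(self):
        df = pd.DataFrame({"age": [70.0, 71.0, 72.0] * 10, "sex": ["female"] * 30, "y": 0.0})
        with pytest.raises(DegenerateInputError):
            age_trend(df, "y")


class TestPartialCorrelation:
    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(12)
        cov = _covariates(rng, 2000)
        frame = pd.DataFrame(rng.standard_normal((2000, 2)), columns=["a", "b"])
        r = correlate_measures(frame, cov, columns=("a", "b")).loc["a", "b"]
        assert abs(r) < 0.06

    def test_equals_pearson_without_covariate_effect(self):
        rng = np.random.default_rng(13)
        cov = _covariates(rng, 500)
        a = rng.standard_normal(500)
        b = 0.7 * a + rng.standard_normal(500)
        frame = pd.DataFrame({"a": a, "b": b})
        partial = correlate_measures(frame, cov, columns=("a", "b")).loc["a", "b"]
        plain = np.corrcoef(a, b)[0, 1]
        assert partial == pytest.approx(plain, abs=0.01)

    def test_too_few_rows(self):
        cov = _covariates(np.random.default_rng(1), 2)
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(DegenerateInputError):
            correlate_measures(frame, cov, columns=("a", "b"))


def _volume_frame(rng, n):
    df = _covariates(rng, n)
    df["icv_ml"] = rng.normal(1462.5, 162.7, n)
    icv_z = (df["icv_ml"] - 1462.5) / 162.7
    for col, mean, sd in [
        ("cerebral_gm_ml", 454.8, 41.8),
        ("cerebral_wm_ml", 392.7, 52.8),
        ("cerebellar_gm_ml", 97.8, 10.6),
        ("cerebellar_wm_ml", 22.0, 2.9),
    ]:
        df[col] = mean + sd * (0.6 * icv_z + 0.8 * rng.standard_normal(n))
    df["wml_ml"] = np.exp(rng.normal(np.log(6.9), 1.05, n))
    return df


class TestBrainVolumeAssociation:
    def test_zero_coupling_confidence_coverage(self):
        rng = np.random.default_rng(14)
        covered = 0
        for _ in range(200):
            df = _volume_frame(rng, 300)
            df["y"] = rng.standard_normal(300)
            r = brainvol_association(df, "y", "cerebral_gm_ml").term("volume_z")
            covered += r["ci_low"] <= 0.0 <= r["ci_high"]
        assert 176 <= covered <= 200  # ~95% nominal, 3 sigma slack

    def test_recovers_injected_loading(self):
        rng = np.random.default_rng(15)
        df = _volume_frame(rng, 1500)
        gm_z = (df["cerebral_gm_ml"] - 454.8) / 41.8
        df["y"] = -0.2 * gm_z + rng.standard_normal(1500)
        r = brainvol_association(df, "y", "cerebral_gm_ml").term("volume_z")
        assert r["ci_low"] < -0.2 * 0.5 and r["ci_high"] < 0.0

    def test_wml_enters_as_log_z(self):
        rng = np.random.default_rng(16)
        df = _volume_frame(rng, 1500)
        lw = np.log(df["wml_ml"])
        df["y"] = 0.3 * (lw - lw.mean()) / lw.std(ddof=1) + 0.5 * rng.standard_normal(1500)
        r = brainvol_association(df, "y", "wml_ml").term("volume_z")
        assert r["estimate"] == pytest.approx(0.3, abs=0.06)

    def test_duplicated_volume_covariate_collinear(self):
        rng = np.random.default_rng(17)
        df = _volume_frame(rng, 100)
        df["y"] = rng.standard_normal(100)
        with pytest.raises(CollinearityError):
            brainvol_association(
                df, "y", "cerebral_gm_ml", extra_covariates=("cerebral_gm_ml",)
            )

    def test_unknown_volume_rejected(self):
        df = _volume_frame(np.random.default_rng(18), 50)
        df["y"] = 0.0
        with pytest.raises(DegenerateInputError):
            brainvol_association(df, "y", "age")


class TestOlsAgainstNormalEquations:
    def test_small_fixture_equivalence(self):
        rng = np.random.default_rng(19)
        n, p = 40, 3
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=["a", "b", "c"])
        y = rng.standard_normal(n)
        res = _fit_ols(y, X)
        Xm = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        np.testing.assert_allclose(res.terms["estimate"].to_numpy(), beta, atol=1e-10)
        resid = y - Xm @ beta
        sigma2 = resid @ resid / (n - p - 1)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xm.T @ Xm)))
        from scipy.stats import t as tdist

        tcrit = tdist.ppf(0.975, n - p - 1)
        np.testing.assert_allclose(
            res.terms["ci_low"].to_numpy(), beta - tcrit * se, atol=1e-10
        )


class TestExclusionAndPrevalence:
    @staticmethod
    def assessed_population():
        n = 1922
        df = pd.DataFrame({"subject_id": [f"P{i:05d}" for i in range(n)]})
        df["parkinson"] = False
        df["joint_problems"] = False
        df["unusable"] = False
        df.loc[:7, "parkinson"] = True
        df.loc[8:32, "joint_problems"] = True
        df.loc[33:34, "unusable"] = True
        return df

    def test_printed_exclusion_arithmetic(self):
        out, acc = exclusion_filter(self.assessed_population())
        assert acc["n_input"] == 1922
        assert acc["n_parkinson_excluded"] == 8
        assert acc["n_unusable_excluded"] == 2
        assert acc["n_retained"] == len(out) == 1912

    def test_joint_exclusion_policy(self):
        out, acc = exclusion_filter(self.assessed_population(), joint_policy="exclude")
        assert acc["n_joint_excluded"] == 25
        assert len(out) == 1912 - 25

    def test_no_flags_is_identity(self):
        df = self.assessed_population()
        df[["parkinson", "joint_problems", "unusable"]] = False
        out, acc = exclusion_filter(df)
        assert len(out) == 1922 and acc["n_retained"] == 1922

    def test_covariate_policy_keeps_flag_column(self):
        out, _ = exclusion_filter(self.assessed_population())
        assert out["joint_problems"].sum() == 25

    def test_prevalence_matches_printed_percentages(self):
        prev = tremor_prevalence()
        assert round(prev["overall_pct"], 1) == 1.3
        assert round(prev["men_pct"], 1) == 2.1
        assert round(prev["women_pct"], 1) == 0.7


def test_score_rank_encoding():
    s = pd.Series(["0A", "0B", "1", "2"])
    assert score_to_numeric(s).tolist() == [0.0, 1.0, 2.0, 3.0]
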