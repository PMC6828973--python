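"""Smoothing-spline ANOVA: solver correctness, GCV, Bayesian intervals."""

import numpy as np
import pandas as pd
import pytest

import flexrelax as fr
from flexrelax.errors import ConfigError, InputError
from flexrelax.ssanova import DEFAULT_LAMBDA_GRID

CUBIC = fr.SplineDesign(response="y", axes=("t",), kind="cubic")


def dense_ridge_oracle(A, Lam, y):
    """Independent dense solve of the regularized normal equations."""
    return np.linalg.solve(A.T @ A + Lam, A.T @ y)


class TestDesignValidation:
    def test_kind_must_match_axis_count(self):
        with pytest.raises(ConfigError):
            fr.SplineDesign(response="y", axes=("a", "b"), kind="cubic")
        with pytest.raises(ConfigError):
            fr.SplineDesign(response="y", axes=("a",), kind="thin_plate")

    def test_zero_variance_response_rejected(self):
        df = pd.DataFrame({"y": np.ones(20), "t": np.linspace(0, 1, 20)})
        with pytest.raises(InputError):
            fr.fit_ssanova(df, CUBIC, lambdas=1.0)

    def test_factor_level_without_subjects_rejected(self):
        df = pd.DataFrame(
            {"y": np.arange(8.0), "t": np.linspace(0, 1, 8),
             "g": ["a"] * 4 + ["b"] * 4, "s": ["s1"] * 4 + ["s2"] * 4}
        )
        design = fr.SplineDesign(
            response="y", axes=("t",), factors=("g",), subject="s"
        )
        with pytest.raises(InputError):
            fr.fit_ssanova(df, design, lambdas=1.0)


class TestSolver:
    def test_cubic_polynomial_recovered(self, rng):
        t = np.linspace(0, 1, 60)
        truth = 2 * t**3 - 1.5 * t**2 + 0.3 * t
        df = pd.DataFrame({"y": truth + rng.normal(0, 1e-4, 60), "t": t})
        fit = fr.fit_ssanova(df, CUBIC)
        err = np.max(np.abs(fit.fitted_values - truth)) / (truth.max() - truth.min())
        assert err < 0.01

    @pytest.mark.parametrize("lam", [1e-4, 1e-2, 1.0])
    def test_fixed_lambda_matches_dense_oracle(self, lam, rng):
        n = 28
        t = rng.uniform(0, 1, n)
        df = pd.DataFrame(
            {"y": np.sin(2 * np.pi * t) + rng.normal(0, 0.2, n), "t": t,
             "g": ["a", "b"] * (n // 2)}
        )
        design = fr.SplineDesign(response="y", axes=("t",), factors=("g",))
        fit = fr.fit_ssanova(df, design, lambdas=lam)
        theta = dense_ridge_oracle(fit.design_matrix, fit.penalty_matrix, df["y"].to_numpy())
        ref = fit.design_matrix @ theta
        rel = np.max(np.abs(ref - fit.fitted_values)) / np.max(np.abs(ref))
        assert rel < 1e-8

    def test_infinite_smoothing_collapses_to_line(self, rng):
        t = np.linspace(0, 1, 50)
        df = pd.DataFrame({"y": np.sin(2 * np.pi * t) + rng.normal(0, 0.1, 50), "t": t})
        fit = fr.fit_ssanova(df, CUBIC, lambdas=1e12)
        line = np.polyval(np.polyfit(t, fit.fitted_values, 1), t)
        assert np.max(np.abs(fit.fitted_values - line)) < 1e-8

    def test_thin_plate_reproduces_exact_plane(self, rng):
        xy = rng.uniform(0, 1, (40, 2))
        z = 1.0 + 2.0 * xy[:, 0] - 3.0 * xy[:, 1]
        df = pd.DataFrame({"y": z, "x1": xy[:, 0], "x2": xy[:, 1]})
        design = fr.SplineDesign(response="y", axes=("x1", "x2"), kind="thin_plate")
        fit = fr.fit_ssanova(df, design, lambdas=1.0)
        assert np.max(np.abs(fit.fitted_values - z)) < 1e-8

    def test_row_permutation_leaves_fit_unchanged(self, rng):
        n = 40
        df = pd.DataFrame(
            {"y": rng.normal(0, 1, n), "t": rng.uniform(0, 1, n),
             "g": rng.choice(["a", "b"], n)}
        )
        design = fr.SplineDesign(response="y", axes=("t",), factors=("g",))
        fit1 = fr.fit_ssanova(df, design, lambdas=0.01)
        perm = rng.permutation(n)
        fit2 = fr.fit_ssanova(df.iloc[perm].reset_index(drop=True), design, lambdas=0.01)
        assert np.allclose(fit1.fitted_values[perm], fit2.fitted_values, atol=1e-8)


class TestRSquared:
    def test_near_interpolation_r2_near_one(self, rng):
        t = np.linspace(0, 1, 30)
        df = pd.DataFrame({"y": np.sin(2 * np.pi * t) + rng.normal(0, 0.01, 30), "t": t})
        fit = fr.fit_ssanova(df, CUBIC, lambdas=1e-9)
        assert fr.model_r_squared(fit) > 0.999

    def test_pure_smoothing_r2_near_zero_on_noise(self, rng):
        t = np.linspace(0, 1, 100)
        df = pd.DataFrame({"y": rng.normal(0, 1, 100), "t": t})
        fit = fr.fit_ssanova(df, CUBIC, lambdas=1e12)
        assert 0.0 <= fr.model_r_squared(fit) < 0.1

    def test_r2_bounds_on_cohort_amplitude_model(self):
        cfg = fr.SyntheticConfig(
            n_per_group=(3, 3, 3), sampling_rate=1024.0, n_repetitions=1, seed=21
        )
        cohort = fr.generate_cohort(cfg, materialize=False)
        res = fr.pipeline.analyze_cohort(cohort, fr.pipeline.PipelineConfig(synthetic=cfg))
        # strong group/time structure by construction
        assert fr.model_r_squared(res.amplitude_fit) > 0.5


class TestGCV:
    def test_grid_must_span_six_orders(self):
        df = pd.DataFrame({"y": np.arange(10.0), "t": np.linspace(0, 1, 10)})
        with pytest.raises(ConfigError):
            fr.gcv_select(df, CUBIC, lambda_grid=np.logspace(-1, 1, 5))

    def test_argmin_contract(self, rng):
        t = np.linspace(0, 1, 80)
        df = pd.DataFrame({"y": np.sin(2 * np.pi * t) + rng.normal(0, 0.3, 80), "t": t})
        lam = fr.gcv_select(df, CUBIC)["smooth"]
        fit_best = fr.fit_ssanova(df, CUBIC, lambdas=lam)
        for trial_lam in DEFAULT_LAMBDA_GRID:
            other = fr.fit_ssanova(df, CUBIC, lambdas=float(trial_lam))
            assert fit_best.gcv_score <= other.gcv_score + 1e-12

    def test_noiseless_smooth_response_selects_small_lambda(self):
        t = np.linspace(0, 1, 200)
        df = pd.DataFrame({"y": np.sin(2 * np.pi * t), "t": t})
        assert fr.gcv_select(df, CUBIC)["smooth"] <= 1e-4

    def test_pure_noise_selects_heavy_smoothing(self):
        # GCV is known to undersmooth occasionally on pure noise; the median
        # selection must be maximal smoothing and a clear majority of runs
        # must land in the grid's top decade
        t = np.linspace(0, 1, 200)
        lams = []
        for s in range(50):
            r = np.random.default_rng(s)
            df = pd.DataFrame({"y": r.normal(0, 1, 200), "t": t})
            lams.append(fr.gcv_select(df, CUBIC)["smooth"])
        lams = np.asarray(lams)
        top = DEFAULT_LAMBDA_GRID.max() / 10.0
        assert np.median(lams) >= top
        assert np.mean(lams >= top) > 0.55


@pytest.fixture(scope="module")
def group_fit():
    rng = np.random.default_rng(7)
    rows = []
    for subj in range(12):
        g = "a" if subj < 6 else "b"
        shift = 0.0 if g == "a" else 2.0
        u = rng.normal(0, 0.3)
        for t in np.linspace(0, 1, 10):
            rows.append(
                {"y": np.sin(2 * np.pi * t) + shift + u + rng.normal(0, 0.1),
                 "t": t, "g": g, "s": f"s{subj}"}
            )
    df = pd.DataFrame(rows)
    design = fr.SplineDesign(response="y", axes=("t",), factors=("g",), subject="s")
    return fr.fit_ssanova(df, design)


class TestContrasts:

    def test_self_contrast_is_zero_and_not_significant(self, group_fit):
        c = fr.contrast_difference(group_fit, "a", "a")
        assert np.allclose(c.difference, 0.0)
        assert not c.significant

    def test_known_shift_recovered(self, group_fit):
        c = fr.contrast_difference(group_fit, "b", "a")
        assert c.mean_difference == pytest.approx(2.0, abs=0.5)
        assert c.significant
        assert c.mean_ci[0] <= 2.0 <= c.mean_ci[1]

    def test_pointwise_bands_bracket_estimate(self, group_fit):
        c = fr.contrast_difference(group_fit, "b", "a")
        assert np.all(c.ci_lower <= c.difference)
        assert np.all(c.difference <= c.ci_upper)

    def test_unknown_level_rejected(self, group_fit):
        with pytest.raises(InputError):
            fr.contrast_difference(group_fit, "a", "zzz")

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n_subj in (4, 8, 16):
            rng = np.random.default_rng(11)
            rows = []
            for subj in range(2 * n_subj):
                g = "a" if subj < n_subj else "b"
                u = rng.normal(0, 0.3)
                for t in np.linspace(0, 1, 8):
                    rows.append(
                        {"y": t + (0.0 if g == "a" else 1.0) + u + rng.normal(0, 0.1),
                         "t": t, "g": g, "s": f"s{subj}"}
                    )
            design = fr.SplineDesign(response="y", axes=("t",), factors=("g",), subject="s")
            fit = fr.fit_ssanova(pd.DataFrame(rows), design)
            c = fr.contrast_difference(fit, "b", "a")
            widths.append(c.mean_ci[1] - c.mean_ci[0])
        assert widths[2] < widths[1] < widths[0]


class TestBayesianCalibration:
    def test_average_pointwise_coverage_between_90_and_98(self):
        # simulate from a smooth truth, fit with GCV, measure the
        # across-the-function average coverage of pointwise 95% intervals
        t = np.linspace(0, 1, 60)
        truth = np.sin(2 * np.pi * t) + 0.5 * t
        coverages = []
        for s in range(40):
            rng = np.random.default_rng(300 + s)
            df = pd.DataFrame({"y": truth + rng.normal(0, 0.3, t.size), "t": t})
            fit = fr.fit_ssanova(df, CUBIC)
            _, est, lo, hi = fr.evaluate_group(fit, {}, grid=t[:, None])
            coverages.append(np.mean((lo <= truth) & (truth <= hi)))
        avg = np.mean(coverages)
        assert 0.90 <= avg <= 0.98
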