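import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from eegqual.io import ClassLabel
from eegqual.unimodal import (
    NOISE_ABOVE,
    NOISE_BELOW,
    FeatureModel,
    UnimodalQualityModel,
    UnimodalQualityResults,
    _fit_feature,
    critical_value,
    delta_metric,
    feature_subscore,
    fit_density,
    total_error,
)
from tests.conftest import gaussian_feature_tables


class TestDensity:
    def test_standard_normal_density_at_zero(self):
        # KDE consistency: at large n the Scott-bandwidth estimate converges
        # on the analytic standard-normal density
        values = np.random.default_rng(0).standard_normal(20_000)
        d = fit_density(values)
        assert d(0.0)[0] == pytest.approx(norm.pdf(0.0), abs=0.02)

    def test_normalisation(self, rng):
        d = fit_density(rng.gamma(2.0, 1.5, size=400))
        lo, hi = d.support_samples.min() - 10, d.support_samples.max() + 10
        xs = np.linspace(lo, hi, 20001)
        integral = np.trapezoid(d(xs), xs)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_scott_bandwidth(self):
        values = np.random.default_rng(1).standard_normal(1000)
        d = fit_density(values)
        expected = values.std(ddof=1) * 1000 ** (-1 / 5)
        assert d.bandwidth == pytest.approx(expected, rel=1e-6)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            fit_density(np.full(100, 1.0))


class TestCriticalValue:
    def test_equal_variance_gaussians_cross_at_midpoint(self):
        rng = np.random.default_rng(5)
        d_c = fit_density(rng.normal(10, 1, 2000))
        d_n = fit_density(rng.normal(0, 1, 2000))
        assert critical_value(d_c, d_n) == pytest.approx(5.0, abs=0.3)

    def test_unequal_variance_crossing_matches_analytic(self):
        rng = np.random.default_rng(6)
        d_c = fit_density(rng.normal(0, 1, 4000))
        d_n = fit_density(rng.normal(4, 2, 4000))
        # analytic crossing of N(0,1) and N(4,4) densities between the means
        analytic = brentq(
            lambda x: norm.pdf(x, 0, 1) - norm.pdf(x, 4, 2), 0.0, 4.0
        )
        assert critical_value(d_c, d_n) == pytest.approx(analytic, abs=0.3)

    def test_identical_samples_tie_break_to_midpoint(self):
        values = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        d = fit_density(values)
        assert critical_value(d, d) == pytest.approx(values.mean())


class TestErrorProbabilities:
    def test_fully_separated_classes(self):
        rng = np.random.default_rng(3)
        fm = _fit_feature(
            "f", rng.normal(100, 0.1, 500),
            np.concatenate([rng.normal(100, 0.1, 250),
                            rng.normal(0, 0.1, 250)]),
            rng.normal(0, 0.1, 500),
        )
        err_c, err_r, err_n = fm.error_probs
        assert err_c == pytest.approx(0.0, abs=0.01)
        assert err_n == pytest.approx(0.0, abs=0.01)
        assert err_r == pytest.approx(0.5, abs=0.05)
        assert fm.e_total == pytest.approx(0.0, abs=0.1)

    def test_single_shared_distribution_is_uninformative(self):
        rng = np.random.default_rng(4)
        fm = _fit_feature(
            "f", rng.normal(0, 1, 2000), rng.normal(0, 1, 2000),
            rng.normal(0, 1, 2000),
        )
        err_c, _, err_n = fm.error_probs
        assert err_c == pytest.approx(0.5, abs=0.05)
        assert err_n == pytest.approx(0.5, abs=0.05)
        assert fm.e_total == pytest.approx(1.0, abs=0.1)


class TestTotalError:
    @pytest.mark.parametrize("probs,expected", [
        ((0.04, 0.54, 0.02), 0.10),   # relative mu power row
        ((0.12, 0.18, 0.73), 1.17),   # relative delta power row
        ((0.0, 0.5, 0.0), 0.0),       # ideal feature
        ((1.0, 1.0, 1.0), 2.5),       # worst case
    ])
    def test_exact_formula(self, probs, expected):
        assert total_error(*probs) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            total_error(-0.1, 0.5, 0.2)


class TestDeltaMetric:
    @pytest.mark.parametrize("means,expected", [
        ((0.75, 0.50, 0.25), 0.0),
        ((0.73, 0.50, 0.23), 0.04),
        ((0.72, 0.49, 0.27), 0.06),
    ])
    def test_exact_formula(self, means, expected):
        assert delta_metric(*means) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_metric(1.2, 0.5, 0.2)


def hand_model(values_c, values_n, orientation=NOISE_BELOW, vstar=None):
    values_c = np.sort(np.asarray(values_c, dtype=float))
    values_n = np.sort(np.asarray(values_n, dtype=float))
    if vstar is None:
        vstar = 0.5 * (values_c.mean() + values_n.mean())
    return FeatureModel(
        "f", values_c, values_c.copy(), values_n,
        orientation=orientation, critical_value=vstar,
        error_probs=(0.0, 0.5, 0.0), e_total=0.0,
    )


def subscore_oracle(v, values_c, values_n, orientation, vstar):
    """Literal count-based evaluation of the sub-score definition."""
    c = np.asarray(values_c, dtype=float)
    n = np.asarray(values_n, dtype=float)
    if orientation == NOISE_BELOW:
        if v >= vstar:
            return 0.5 + 0.5 * np.mean(v > c)
        return 0.5 * np.mean(v <= n)
    if v <= vstar:
        return 0.5 + 0.5 * np.mean(v < c)
    return 0.5 * np.mean(v >= n)


class TestFeatureSubscore:
    def test_above_all_clean_values(self):
        fm = hand_model([4, 5, 6], [1, 2, 3])
        assert feature_subscore(7.0, fm) == 1.0

    def test_below_critical_value(self):
        fm = hand_model([4, 5, 6], [1, 2, 3])
        # Q = 0.5 * P(3 <= x | N) = 0.5 * (1/3)
        assert feature_subscore(3.0, fm) == pytest.approx(1 / 6)

    def test_literal_lower_branch_far_below_noise(self):
        fm = hand_model([4, 5, 6], [1, 2, 3])
        # deep in the noise tail the printed lower branch returns 0.5
        assert feature_subscore(0.0, fm) == 0.5

    @pytest.mark.parametrize("orientation", [NOISE_BELOW, NOISE_ABOVE])
    def test_brute_force_enumeration_oracle(self, orientation):
        rng = np.random.default_rng(11)
        for trial in range(50):
            nc = rng.integers(2, 11)
            nn = rng.integers(2, 11)
            c = rng.integers(-5, 6, size=nc).astype(float)
            n = rng.integers(-5, 6, size=nn).astype(float)
            if np.unique(c).size < 2 or np.unique(n).size < 2:
                continue
            vstar = float(rng.uniform(-5, 5))
            fm = hand_model(c, n, orientation, vstar)
            # probe stored values exactly (tie handling) plus off-grid points
            probes = np.concatenate([c, n, rng.uniform(-7, 7, 5), [vstar]])
            for v in probes:
                assert feature_subscore(float(v), fm) == pytest.approx(
                    subscore_oracle(float(v), c, n, orientation, vstar),
                    abs=1e-12,
                )


class TestFitAndScore:
    def test_included_set_is_exactly_the_separating_features(self):
        rng = np.random.default_rng(21)
        n = 300
        names_good = [f"good{i}" for i in range(7)]
        names_bad = [f"bad{i}" for i in range(23)]
        tables = {}
        for label in ("C", "R", "N"):
            cols = {}
            for name in names_good:
                if label == "C":
                    cols[name] = rng.normal(10, 1, n)
                elif label == "N":
                    cols[name] = rng.normal(-10, 1, n)
                else:
                    cols[name] = np.concatenate(
                        [rng.normal(10, 1, n // 2), rng.normal(-10, 1, n // 2)]
                    )
            for name in names_bad:
                cols[name] = rng.normal(0, 1, n)
            tables[label] = pd.DataFrame(cols)
        res = UnimodalQualityModel(
            tables["C"], tables["R"], tables["N"]).fit(0.35)
        assert sorted(res.included_features) == sorted(names_good)

    def test_threshold_extremes(self):
        tables = gaussian_feature_tables(n_per_class=100, seed=2)
        model = UnimodalQualityModel(*(tables[l] for l in ClassLabel))
        res = model.fit(inclusion_threshold=2.5)
        assert len(res.included_features) == 3  # all features at E_total <= 2.5
        with pytest.warns(UserWarning):
            res0 = UnimodalQualityModel(
                pd.DataFrame({"f": np.random.default_rng(0).normal(0, 1, 50)}),
                pd.DataFrame({"f": np.random.default_rng(1).normal(0, 1, 50)}),
                pd.DataFrame({"f": np.random.default_rng(2).normal(0, 1, 50)}),
            ).fit(inclusion_threshold=0.0)
        with pytest.raises(ValueError):
            res0.score(pd.DataFrame({"f": [0.0]}))

    def test_score_is_mean_of_subscores(self):
        tables = gaussian_feature_tables(n_per_class=100, seed=3)
        res = UnimodalQualityModel(*(tables[l] for l in ClassLabel)).fit()
        table = tables[ClassLabel.CLEAN].head(10)
        sub = res.subscores(table, res.included_features).to_numpy()
        np.testing.assert_allclose(
            res.score(table), sub.mean(axis=1), atol=1e-15)

    def test_hand_built_model_matches_manual_computation(self):
        fms = {
            "a": hand_model([4, 5, 6], [1, 2, 3], vstar=3.5),
            "b": hand_model([4, 5, 6], [1, 2, 3], vstar=3.5),
            "c": hand_model([-1, -2, -3], [-4, -5, -6], vstar=-3.5),
        }
        res = UnimodalQualityResults(fms, inclusion_threshold=0.35)
        row = pd.DataFrame([{"a": 7.0, "b": 3.0, "c": 0.0}])
        expected = (1.0 + 1 / 6 + 1.0) / 3
        assert res.score(row)[0] == pytest.approx(expected, abs=1e-12)

    def test_orientation_flip_invariance(self):
        tables = gaussian_feature_tables(n_per_class=150, seed=4)
        res = UnimodalQualityModel(*(tables[l] for l in ClassLabel)).fit()
        neg = {l: -df for l, df in tables.items()}
        res_neg = UnimodalQualityModel(*(neg[l] for l in ClassLabel)).fit()
        probe = tables[ClassLabel.RAW].head(40)
        np.testing.assert_allclose(
            res.score(probe), res_neg.score(-probe), atol=1e-12)
        for name in res.feature_models:
            assert res.feature_models[name].e_total == pytest.approx(
                res_neg.feature_models[name].e_total, abs=1e-12)

    def test_design_target_means(self):
        """Held-out draws from the clean / noise / mixture generating
        distributions score 0.75 / 0.25 / 0.50 on average (law of the
        empirical CDF under the sub-score definition)."""
        tables = gaussian_feature_tables(n_per_class=2000, seed=5)
        res = UnimodalQualityModel(*(tables[l] for l in ClassLabel)).fit()
        heldout = gaussian_feature_tables(n_per_class=2000, seed=6)
        assert res.score(heldout[ClassLabel.CLEAN]).mean() == pytest.approx(
            0.75, abs=0.02)
        assert res.score(heldout[ClassLabel.NOISE]).mean() == pytest.approx(
            0.25, abs=0.02)
        assert res.score(heldout[ClassLabel.RAW]).mean() == pytest.approx(
            0.50, abs=0.02)

    def test_save_load_scores_bit_identical(self, tmp_path):
        tables = gaussian_feature_tables(n_per_class=120, seed=8)
        res = UnimodalQualityModel(*(tables[l] for l in ClassLabel)).fit()
        res.save(tmp_path / "model.json")
        back = UnimodalQualityResults.load(tmp_path / "model.json")
        probe = gaussian_feature_tables(n_per_class=50, seed=9)[ClassLabel.RAW]
        np.testing.assert_array_equal(res.score(probe), back.score(probe))

    def test_min_sample_floor(self):
        tables = gaussian_feature_tables(n_per_class=5, seed=1)
        with pytest.raises(ValueError, match="floor"):
            UnimodalQualityModel(*(tables[l] for l in ClassLabel)).fit()


@pytest.fixture(scope="module")
def sweep_fitted():
    rng = np.random.default_rng(31)
    n = 250
    tables = {}
    for label in ("C", "R", "N"):
        cols = {}
        for i in range(3):   # separating features
            mu = {"C": 10, "N": -10}.get(label)
            if mu is None:
                cols[f"good{i}"] = np.concatenate(
                    [rng.normal(10, 1, n // 2), rng.normal(-10, 1, n // 2)])
            else:
                cols[f"good{i}"] = rng.normal(mu, 1, n)
        for i in range(3):   # uninformative features
            cols[f"bad{i}"] = rng.normal(0, 1, n)
        tables[label] = pd.DataFrame(cols)
    res = UnimodalQualityModel(tables["C"], tables["R"], tables["N"]).fit()
    return res, tables


class TestSweep:
    def test_single_threshold_grid_includes_everything(self, sweep_fitted):
        res, tables = sweep_fitted
        sweep = res.sweep(tables, np.array([2.5]))
        assert len(sweep) == 1
        assert sweep["n_features"].iloc[0] == 6

    def test_feature_count_monotone_and_delta_consistent(self, sweep_fitted):
        res, tables = sweep_fitted
        sweep = res.sweep(tables, np.arange(0.0, 2.51, 0.25))
        assert (np.diff(sweep["n_features"]) >= 0).all()
        ok = sweep["n_features"] > 0
        np.testing.assert_allclose(
            sweep.loc[ok, "delta"],
            [delta_metric(c, r, nn) for c, r, nn in zip(
                sweep.loc[ok, "mean_C"], sweep.loc[ok, "mean_R"],
                sweep.loc[ok, "mean_N"])],
            atol=1e-15,
        )

    def test_admitting_bad_features_worsens_delta(self, sweep_fitted):
        res, tables = sweep_fitted
        sweep = res.sweep(tables, np.array([0.35, 2.5]))
        assert sweep["delta"].iloc[0] <= sweep["delta"].iloc[1]

    def test_empty_grid_rejected(self, sweep_fitted):
        res, tables = sweep_fitted
        with pytest.raises(ValueError):
            res.sweep(tables, np.array([]))
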