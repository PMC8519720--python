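"""Baseline imputers and the benchmark harness."""

import numpy as np
import pytest

import psoimpute.baselines as baselines
from psoimpute.baselines import (BenchmarkReport, benchmark, impute_deletion, impute_em,
                                 impute_mean, impute_mice, impute_missforest)
from psoimpute.errors import DegenerateInputError
from psoimpute.fixtures import FixtureSpec, gastric_spec, generate
from psoimpute.pool import get_spec

from conftest import MISSING, make_dataset


def _rmse(imputed, truth):
    errs = [float(imputed.values.at[r, v]) - float(val) for (r, v), val in truth.items()]
    return float(np.sqrt(np.mean(np.square(errs))))


class TestDeletion:
    def test_drops_incomplete_records(self):
        ds = make_dataset(
            {"x": [1.0, MISSING, 2.0, 3.0, MISSING, 4.0, MISSING, 5.0, MISSING, MISSING],
             "y": [0, 1] * 5},
            {"x": "continuous", "y": "discrete"}, dependent="y",
        )
        assert impute_deletion(ds).n_records == 5

    def test_identity_without_missing(self, toy_binary_dataset):
        assert impute_deletion(toy_binary_dataset).n_records == 10

    def test_matches_complete_row_scan_on_gastric_profile(self):
        _, amputed, _ = generate(gastric_spec(seed=9))
        expected = int(amputed.complete_row_mask().sum())
        if expected == 0:
            with pytest.raises(DegenerateInputError):
                impute_deletion(amputed)
        else:
            assert impute_deletion(amputed).n_records == expected


class TestMean:
    def test_continuous_mean_fill(self):
        ds = make_dataset(
            {"x": [1.0, 2.0, 3.0, MISSING], "y": [0, 1, 0, 1]},
            {"x": "continuous", "y": "discrete"}, dependent="y",
        )
        assert impute_mean(ds).values.at[3, "x"] == pytest.approx(2.0)

    def test_discrete_mode_fill(self):
        ds = make_dataset(
            {"d": ["A", "A", "B", MISSING], "y": [0, 1, 0, 1]},
            {"d": "discrete", "y": "discrete"}, dependent="y",
        )
        assert impute_mean(ds).values.at[3, "d"] == "A"

    def test_mixed_table_matches_hand_arithmetic(self):
        ds = make_dataset(
            {
                "c": [2.0, 4.0, MISSING, 6.0, MISSING, 8.0],
                "d": [1, 1, 2, MISSING, 2, MISSING],
                "y": [0, 1, 0, 1, 0, 1],
            },
            {"c": "continuous", "d": "discrete", "y": "discrete"}, dependent="y",
        )
        out = impute_mean(ds)
        assert out.values.at[2, "c"] == pytest.approx(5.0)
        assert out.values.at[4, "c"] == pytest.approx(5.0)
        assert out.values.at[3, "d"] == 1  # tie 1 vs 2 -> first level
        assert out.values.at[5, "d"] == 1


class TestEM:
    def test_beats_mean_on_correlated_bivariate_normal(self):
        spec = FixtureSpec(n_records=200, continuous_vars=2, discrete_vars=0,
                           correlation=0.9, missing_profile={"c1": 0.2},
                           mechanism="MCAR", seed=13)
        _, amputed, truth = generate(spec)
        assert _rmse(impute_em(amputed), truth) < _rmse(impute_mean(amputed), truth)

    def test_identity_with_zero_iterations_when_complete(self, toy_binary_dataset):
        out, info = impute_em(toy_binary_dataset, return_info=True)
        assert info["n_iter"] == 0
        assert out.values.equals(toy_binary_dataset.values)

    def test_single_continuous_column_fills_with_mean(self):
        ds = make_dataset(
            {"x": [1.0, 3.0, MISSING, 5.0], "y": [0, 1, 0, 1]},
            {"x": "continuous", "y": "discrete"}, dependent="y",
        )
        assert impute_em(ds).values.at[2, "x"] == pytest.approx(3.0)


class TestMice:
    def test_identity_without_missing(self, toy_binary_dataset):
        out = impute_mice(toy_binary_dataset, seed=0)
        assert out.values.equals(toy_binary_dataset.values)

    def test_deterministic_under_seed(self):
        spec = FixtureSpec(n_records=60, continuous_vars=3, discrete_vars=1,
                           correlation=0.5, missing_profile={"c1": 0.3, "d1": 0.2},
                           mechanism="MCAR", seed=5)
        _, amputed, _ = generate(spec)
        a = impute_mice(amputed, seed=42)
        b = impute_mice(amputed, seed=42)
        assert a.values.equals(b.values)

    def test_beats_mean_on_linear_fixture(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(2000 + seed)
            n = 100
            x = rng.standard_normal(n)
            lin = 2.0 * x + rng.normal(scale=0.1, size=n)
            miss = set(rng.choice(n, size=30, replace=False).tolist())
            ds = make_dataset(
                {
                    "x": x.tolist(),
                    "l": [MISSING if i in miss else float(v) for i, v in enumerate(lin)],
                    "y": (x > 0).astype(int).tolist(),
                },
                {"x": "continuous", "l": "continuous", "y": "discrete"}, dependent="y",
            )
            truth = {(i, "l"): lin[i] for i in miss}
            wins += _rmse(impute_mice(ds, seed=seed), truth) < \
                _rmse(impute_mean(ds), truth)
        assert wins >= 45  # >= 90%


class TestMissForest:
    def test_identity_without_missing(self, toy_binary_dataset):
        out, info = impute_missforest(toy_binary_dataset, seed=0, return_info=True)
        assert info["n_accepted"] == 0
        assert out.values.equals(toy_binary_dataset.values)

    def test_beats_linear_mice_on_quadratic_fixture(self):
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(3000 + seed)
            n = 100
            x = rng.uniform(-2, 2, n)
            y2 = x ** 2 + rng.normal(scale=0.1, size=n)
            miss = set(rng.choice(n, size=30, replace=False).tolist())
            ds = make_dataset(
                {
                    "x": x.tolist(),
                    "q": [MISSING if i in miss else float(v) for i, v in enumerate(y2)],
                    "y": (x > 0).astype(int).tolist(),
                },
                {"x": "continuous", "q": "continuous", "y": "discrete"}, dependent="y",
            )
            truth = {(i, "q"): y2[i] for i in miss}
            rf = _rmse(impute_missforest(ds, seed=seed, n_estimators=50), truth)
            mice = _rmse(impute_mice(ds, seed=seed), truth)
            wins += rf < mice
        assert wins >= 35  # >= 70%

    def test_stops_when_difference_criterion_increases(self, monkeypatch):
        # scripted sweeps: iteration 1 fills with 10 (small change from the
        # mean init of ~9), iteration 2 with 20 (larger change) -> only the
        # first iteration is accepted and its values are kept
        ds = make_dataset(
            {
                "v": [9.0, 9.1, 8.9, MISSING, MISSING],
                "w": [1.0, 2.0, 3.0, 4.0, 5.0],
                "y": [0, 1, 0, 1, 0],
            },
            {"v": "continuous", "w": "continuous", "y": "discrete"}, dependent="y",
        )
        calls = {"n": 0}

        def scripted(vtype, X_train, y_train, X_query, seed, n_estimators):
            calls["n"] += 1
            fill = 10.0 if calls["n"] == 1 else 20.0
            return np.full(len(X_query), fill)

        monkeypatch.setattr(baselines, "_rf_fit_predict", scripted)
        out, info = impute_missforest(ds, seed=0, return_info=True)
        assert info["n_accepted"] == 1
        assert len(info["criteria"]) == 2
        assert info["criteria"][1] > info["criteria"][0]
        assert out.values.at[3, "v"] == pytest.approx(10.0)


class TestBenchmark:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_fixture():
        spec = FixtureSpec(n_records=80, continuous_vars=3, discrete_vars=1,
                           correlation=0.5, outcome_coefficients=[1.5, 1.0, 0.5, 0.5],
                           missing_profile={"c1": 0.25, "c2": 0.15},
                           mechanism="MCAR", seed=31)
        return generate(spec)[1]

    def test_all_imputers_are_completions(self, small_fixture):
        ds = small_fixture
        observed = ds.mask.to_numpy()
        for f in (impute_mean, impute_em,
                  lambda d: impute_mice(d, seed=1),
                  lambda d: impute_missforest(d, seed=1, n_estimators=30)):
            out = f(ds)
            assert out.mask.to_numpy().all()
            for r, c in zip(*np.nonzero(observed)):
                name = ds.var_names[c]
                assert out.values.at[r, name] == ds.values.at[r, name]

    def test_tenfold_each_record_predicted_once(self, small_fixture):
        from psoimpute.fitness import _cv_predictions
        from psoimpute.data import encode_matrix
        imputed = impute_mean(small_fixture)
        X = encode_matrix(imputed, [v.name for v in imputed.independents])
        y = imputed.values["outcome"].to_numpy(object)
        preds = _cv_predictions(X, y, get_spec("discrete", 17), seed=0, n_splits=10)
        assert all(p is not None for p in preds)

    def test_report_shape_and_protocols(self, small_fixture):
        report = benchmark(
            small_fixture, methods=["deletion", "mean", "mice"],
            protocol="split_70_30", n_runs=2, seed=1,
        )
        assert set(report.rows) == {"deletion", "mean", "mice"}
        assert report.protocol == "split_70_30"
        text = report.to_text()
        assert "Mean algorithm" in text and "Sensitivity (%)" in text

    def test_single_method_report(self, small_fixture):
        report = benchmark(small_fixture, methods=["mean"], protocol="tenfold",
                           n_runs=2, seed=1)
        assert list(report.rows) == ["mean"]
        panel = report.rows["mean"]
        assert all(0 <= v <= 100 for v in panel.as_dict().values())

    def test_deletion_marked_not_evaluable_when_too_few_rows(self):
        rng = np.random.default_rng(6)
        ds = make_dataset(
            {"x": [float(v) if i % 2 == 0 else MISSING
                   for i, v in enumerate(rng.standard_normal(24))],
             "y": [0, 1] * 12},
            {"x": "continuous", "y": "discrete"}, dependent="y",
        )
        report = benchmark(ds, methods=["deletion", "mean"], protocol="tenfold",
                           n_runs=1, seed=0)
        assert report.rows["deletion"] is None
        assert "deletion" in report.notes
        assert report.rows["mean"] is not None
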