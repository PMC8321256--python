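import numpy as np
import pandas as pd
import pytest

from veglatent.evaluation import (
    LabelledFeatures,
    bootstrap_evaluate,
    compare_methods,
    extract_at_points,
    percentile_ci,
    rf_top_features,
)
from veglatent.raster import Raster


def _separable_data(n_per_class=12, n_classes=4, noise=0.0, seed=0):
    """One distinct constant feature level per class (optionally jittered)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        X.append(np.full((n_per_class, 2), float(c)) + noise * rng.standard_normal((n_per_class, 2)))
        y += [f"class{c}"] * n_per_class
    return LabelledFeatures(X=np.vstack(X), y=np.array(y))


class TestExtractAtPoints:
    def _raster(self):
        data = np.arange(2 * 3 * 4, dtype=np.float32).reshape(2, 3, 4)
        return Raster(data=data, valid=np.ones_like(data, dtype=bool),
                      band_names=["a", "b"])

    def test_exact_lookup(self):
        pts = pd.DataFrame({"class": ["x"], "x": [2], "y": [1]})
        out = extract_at_points(self._raster(), pts)
        np.testing.assert_array_equal(out.X[0], [6.0, 18.0])

    def test_duplicated_point_duplicated_row(self):
        pts = pd.DataFrame({"class": ["x", "x"], "x": [2, 2], "y": [1, 1]})
        out = extract_at_points(self._raster(), pts)
        assert len(out.X) == 2
        np.testing.assert_array_equal(out.X[0], out.X[1])

    def test_out_of_bounds_skipped(self):
        pts = pd.DataFrame({"class": ["x", "y"], "x": [0, 99], "y": [0, 0]})
        out = extract_at_points(self._raster(), pts)
        assert list(out.y) == ["x"]

    def test_invalid_cells_dropped(self):
        r = self._raster()
        r.valid[0, 1, 2] = False
        pts = pd.DataFrame({"class": ["x", "y"], "x": [2, 0], "y": [1, 0]})
        out = extract_at_points(r, pts)
        assert list(out.y) == ["y"]

    def test_label_distribution_matches_generator(self, small_config, small_scenes, small_composite):
        _, pts = small_scenes
        comp, _ = small_composite
        out = extract_at_points(comp.to_raster(), pts)
        counts = pd.Series(out.y).value_counts()
        for prof in small_config.profiles:
            assert counts[prof.class_name] == prof.n_points

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            extract_at_points(self._raster(), pd.DataFrame({"x": [0]}))


class TestRfTopFeatures:
    def test_perfect_column_ranked_first(self):
        rng = np.random.default_rng(1)
        n = 80
        y = np.repeat(np.arange(4), n // 4)
        X = rng.standard_normal((n, 6))
        X[:, 0] = y  # column 0 equals the class id
        data = LabelledFeatures(X=X, y=y.astype(str))
        _, sel = rf_top_features(data, 1, n_estimators=50, seed=0)
        assert sel[0] == 0

    def test_k_equals_d_identity_selection(self):
        data = _separable_data()
        out, sel = rf_top_features(data, 2, n_estimators=20, seed=0)
        assert sorted(sel.tolist()) == [0, 1]
        assert out.n_features == 2

    def test_deterministic_selection(self):
        data = _separable_data(noise=0.5)
        _, a = rf_top_features(data, 1, n_estimators=20, seed=3)
        _, b = rf_top_features(data, 1, n_estimators=20, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            rf_top_features(_separable_data(), 3, n_estimators=10)


class TestPercentileCI:
    def test_injected_list_matches_order_statistic_oracle(self):
        accs = np.arange(0.1, 1.05, 0.1)  # 0.1 .. 1.0
        # order-statistic oracle, by hand: quantile positions on (n-1) steps;
        # 0.025 * 9 = 0.225 -> floor = index 0; 0.975 * 9 = 8.775 -> ceil = 9
        lo, hi = percentile_ci(accs, 0.95)
        assert lo == pytest.approx(0.1)
        assert hi == pytest.approx(1.0)
        lo50, hi50 = percentile_ci(accs, 0.5)
        # 0.25 * 9 = 2.25 -> index 2 (0.3); 0.75 * 9 = 6.75 -> index 7 (0.8)
        assert lo50 == pytest.approx(0.3)
        assert hi50 == pytest.approx(0.8)

    def test_bounds_within_range_and_monotone_in_confidence(self, rng):
        accs = rng.uniform(size=200)
        prev = (1.0, 0.0)
        for conf in (0.5, 0.8, 0.95, 0.99):
            lo, hi = percentile_ci(accs, conf)
            assert accs.min() <= lo <= hi <= accs.max()
            assert lo <= prev[0] or prev == (1.0, 0.0)
            prev_lo, prev_hi = prev
            if prev != (1.0, 0.0):
                assert lo <= prev_lo and hi >= prev_hi
            prev = (lo, hi)

    def test_injected_via_bootstrap_evaluate(self):
        rep = bootstrap_evaluate(None, accuracies=np.arange(0.1, 1.05, 0.1))
        assert rep.ci_low == pytest.approx(0.1)
        assert rep.ci_high == pytest.approx(1.0)


class TestBootstrapEvaluate:
    def test_perfectly_separable_ci_is_one_one(self):
        rep = bootstrap_evaluate(_separable_data(), n_boot=20, seed=0, n_estimators=10)
        assert np.all(rep.accuracies == 1.0)
        assert (rep.ci_low, rep.ci_high) == (1.0, 1.0)

    def test_same_seed_identical_report(self):
        data = _separable_data(noise=0.8)
        a = bootstrap_evaluate(data, n_boot=15, seed=5, n_estimators=10)
        b = bootstrap_evaluate(data, n_boot=15, seed=5, n_estimators=10)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.importances, b.importances)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_importances_sum_to_one(self):
        rep = bootstrap_evaluate(_separable_data(noise=0.5), n_boot=10, seed=1, n_estimators=10)
        np.testing.assert_allclose(rep.importances.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(rep.importances >= 0)

    def test_ci_within_accuracy_range(self):
        rep = bootstrap_evaluate(_separable_data(noise=1.5), n_boot=30, seed=2, n_estimators=10)
        assert rep.accuracies.min() <= rep.ci_low <= rep.ci_high <= rep.accuracies.max()

    def test_no_replacement_mode(self):
        rep = bootstrap_evaluate(_separable_data(), n_boot=10, seed=0,
                                 replacement=False, n_estimators=10)
        assert np.all(rep.accuracies == 1.0)

    def test_class_recall_reported(self):
        rep = bootstrap_evaluate(_separable_data(), n_boot=5, seed=0, n_estimators=10)
        assert set(rep.class_recall) == {"class0", "class1", "class2", "class3"}
        assert all(v == 1.0 for v in rep.class_recall.values())

    def test_too_few_rows_rejected(self):
        data = LabelledFeatures(X=np.zeros((4, 2)), y=np.array(["a", "a", "b", "b"]))
        with pytest.raises(ValueError, match="8 rows"):
            bootstrap_evaluate(data)

    def test_single_class_rejected(self):
        data = LabelledFeatures(X=np.zeros((10, 2)), y=np.array(["a"] * 10))
        with pytest.raises(ValueError, match="2 classes"):
            bootstrap_evaluate(data)


class TestCompareMethods:
    def test_shape_contract_nine_ci_pairs(self):
        raw = _separable_data(n_per_class=10, noise=0.3)
        # widen raw to 12 columns so top-10 selection is possible
        rng = np.random.default_rng(0)
        raw = LabelledFeatures(
            X=np.hstack([raw.X, rng.standard_normal((len(raw.X), 10))]), y=raw.y
        )
        latents = {
            m: {k: LabelledFeatures(X=raw.X[:, :k], y=raw.y) for k in (3, 5, 10)}
            for m in ("cae", "ae")
        }
        table = compare_methods(latents, raw, ks=(3, 5, 10), n_boot=5, n_estimators=10)
        assert len(table) == 9
        assert set(table["method"]) == {"cae", "ae", "rf"}
        assert (table["ci_low"] <= table["ci_high"]).all()

    def test_identical_features_identical_cis(self):
        raw = _separable_data(n_per_class=10, noise=0.5)
        same = LabelledFeatures(X=raw.X.copy(), y=raw.y.copy())
        latents = {"cae": {2: same}, "ae": {2: same}}
        table = compare_methods(latents, raw, ks=(2,), n_boot=8, n_estimators=10)
        cae = table[table.method == "cae"].iloc[0]
        ae = table[table.method == "ae"].iloc[0]
        assert cae["ci_low"] == ae["ci_low"] and cae["ci_high"] == ae["ci_high"]

    def test_misaligned_rows_rejected(self):
        raw = _separable_data(n_per_class=10)
        bad = LabelledFeatures(X=raw.X[:-2], y=raw.y[:-2])
        with pytest.raises(ValueError, match="row-aligned"):
            compare_methods({"ae": {2: bad}}, raw, ks=(2,), n_boot=3, n_estimators=5)
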