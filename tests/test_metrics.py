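import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specblend import (
    composition_confusion,
    emr,
    evaluate,
    ha,
    regression_metrics,
)
from specblend.metrics import CONFUSION_LABELS


class TestExactMatchRatio:
    def test_identical_is_one(self, rng):
        m = rng.integers(0, 2, (20, 3))
        assert emr(m, m) == 1.0

    def test_module_example(self):
        t = np.array([[1, 0, 1], [1, 1, 1]])
        p = np.array([[1, 0, 1], [1, 1, 0]])
        assert emr(t, p) == 0.5

    def test_complement_is_zero(self, rng):
        m = rng.integers(0, 2, (15, 3))
        assert emr(m, 1 - m) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            emr(np.zeros((2, 3)), np.zeros((3, 3)))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            emr(np.full((2, 3), 0.5), np.zeros((2, 3)))


class TestHammingAccuracy:
    def test_module_example(self):
        t = np.array([[1, 0, 1], [1, 1, 1]])
        p = np.array([[1, 0, 1], [1, 1, 0]])
        assert ha(t, p) == pytest.approx(5 / 6)

    def test_bounds_ha_at_least_emr(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            t = rng.integers(0, 2, (50, 3))
            p = rng.integers(0, 2, (50, 3))
            e, h = emr(t, p), ha(t, p)
            assert 0.0 <= e <= h <= 1.0

    @given(
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_ha_dominates_emr_property(self, m, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 2, (m, 3))
        p = rng.integers(0, 2, (m, 3))
        assert 0.0 <= emr(t, p) <= ha(t, p) <= 1.0


class TestCompositionConfusion:
    def test_perfect_predictions_identity(self, rng):
        from specblend import CLASS_MASKS, MIXTURE_CLASSES

        ci = np.array([CLASS_MASKS[c] for c in MIXTURE_CLASSES for _ in range(3)])
        conf = composition_confusion(ci, ci)
        obs = conf.normalized[:7, :7]
        assert np.allclose(obs, np.eye(7))
        assert conf.labels == CONFUSION_LABELS

    def test_single_error_counting(self):
        # ten W samples, one predicted as MW
        t = np.tile([0, 0, 1], (10, 1))
        p = t.copy()
        p[0] = [1, 0, 1]  # MW
        conf = composition_confusion(t, p)
        w = CONFUSION_LABELS.index("W")
        mw = CONFUSION_LABELS.index("MW")
        assert conf.normalized[w, w] == pytest.approx(0.9)
        assert conf.normalized[w, mw] == pytest.approx(0.1)

    def test_all_absent_goes_to_none_bucket(self):
        t = np.array([[1, 0, 0]])
        p = np.array([[0, 0, 0]])
        conf = composition_confusion(t, p)
        m = CONFUSION_LABELS.index("M")
        none = CONFUSION_LABELS.index("none")
        assert conf.counts[m, none] == 1

    def test_rows_stochastic_or_zero(self, rng):
        t = rng.integers(0, 2, (100, 3))
        p = rng.integers(0, 2, (100, 3))
        conf = composition_confusion(t, p)
        sums = conf.normalized.sum(axis=1)
        observed = conf.counts.sum(axis=1) > 0
        assert np.allclose(sums[observed], 1.0)
        assert np.allclose(sums[~observed], 0.0)

    def test_csv_export(self, tmp_path, rng):
        t = rng.integers(0, 2, (30, 3))
        conf = composition_confusion(t, t)
        path = tmp_path / "conf.csv"
        conf.to_csv(path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 9  # header + 8 classes
        assert lines[0].split(",")[1:] == list(CONFUSION_LABELS)


class TestRegressionMetrics:
    def test_exact_predictions(self, rng):
        c = rng.uniform(1, 50, (20, 3))
        out = regression_metrics(c, c)
        for d in out.values():
            assert d["r2"] == 1.0 and d["mae"] == 0.0 and d["mre"] == 0.0

    def test_constant_mean_prediction_r2_zero(self, rng):
        c = rng.uniform(1, 50, (20, 1))
        pred = np.full_like(c, c.mean())
        out = regression_metrics(c, pred)
        assert out["gas1"]["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_case(self):
        t = np.array([[10.0], [20.0]])
        p = np.array([[11.0], [18.0]])
        d = regression_metrics(t, p)["gas1"]
        assert d["mae"] == pytest.approx(1.5)
        assert d["mre"] == pytest.approx(0.1)
        assert d["r2"] == pytest.approx(1 - 5 / 50)

    def test_mre_over_present_only(self):
        t = np.array([[0.0], [10.0]])
        p = np.array([[2.0], [9.0]])
        d = regression_metrics(t, p)["gas1"]
        assert d["mre"] == pytest.approx(0.1)  # the c=0 row is excluded
        assert d["mae"] == pytest.approx(1.5)  # but MAE covers all rows

    def test_zero_variance_warns_nan(self):
        t = np.full((5, 1), 7.0)
        p = t + 0.1
        with pytest.warns(UserWarning, match="variance"):
            d = regression_metrics(t, p)["gas1"]
        assert np.isnan(d["r2"])

    def test_matches_scalar_loop_oracle(self, rng):
        t = rng.uniform(0, 50, (17, 3))
        p = t + rng.normal(0, 2, (17, 3))
        out = regression_metrics(t, p)
        for i, name in enumerate(out):
            ss_res = sum((t[j, i] - p[j, i]) ** 2 for j in range(17))
            mean = sum(t[j, i] for j in range(17)) / 17
            ss_tot = sum((t[j, i] - mean) ** 2 for j in range(17))
            mae = sum(abs(t[j, i] - p[j, i]) for j in range(17)) / 17
            assert out[name]["r2"] == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)
            assert out[name]["mae"] == pytest.approx(mae, rel=1e-12)


def test_evaluate_bundles_consistent_report(rng):
    Y = np.hstack([rng.integers(0, 2, (25, 3)), rng.uniform(0, 50, (25, 3))])
    Y[:, 3:] *= Y[:, :3]
    pred_ci = Y[:, :3].astype(int)
    pred_c = Y[:, 3:]
    rep = evaluate(Y, pred_ci, pred_c)
    assert rep.emr == 1.0 and rep.ha == 1.0
    assert rep.n_samples == 25
    summary = rep.summary()
    assert set(summary["per_gas"]) == {"methane", "acetone", "water"}
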