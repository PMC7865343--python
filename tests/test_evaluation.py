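import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brute_oracles import (
    brute_confusion,
    brute_offsets,
    brute_rejection,
    brute_tolerance_accuracy,
)
from gaitphase.errors import DataError
from gaitphase.evaluation import (
    activation_heatmap,
    certainty,
    certainty_stats,
    confusion_and_accuracy,
    expected_transition_error_pct,
    frame_ms,
    frame_ms_label,
    loocv,
    loocv_summary,
    misprediction_offsets,
    reject_by_certainty,
    tolerance_accuracy,
)
from gaitphase.nn.network import PredictionSet, TrainConfig, build_model
from gaitphase.synthetic import SyntheticConfig, simulate_dataset
from gaitphase.windowing import WindowSpec
from conftest import tiny_model_cfg

# the eleven per-subject hold-out accuracies used to validate the summary code
TABLE1_ACCURACIES = [
    0.9218, 0.9469, 0.9204, 0.9428, 0.9451, 0.9209,
    0.9161, 0.9020, 0.8952, 0.9168, 0.9234,
]


def _pred_set(true, pred, probs=None):
    true = np.asarray(true)
    pred = np.asarray(pred)
    if probs is None:
        probs = np.zeros((len(pred), 5))
        probs[np.arange(len(pred)), pred] = 1.0
    return PredictionSet(probs=probs, pred=pred, true=true)


class TestCertainty:
    def test_uniform(self):
        np.testing.assert_allclose(certainty(np.zeros(5)), 0.2)

    def test_single_high_logit(self):
        # exp(5) / (exp(5) + 4) = 0.97383...
        out = certainty(np.array([5.0, 0, 0, 0, 0]))
        assert out[0] == pytest.approx(0.9738, abs=1e-4)

    def test_shift_invariance(self, rng):
        z = rng.standard_normal(5)
        np.testing.assert_allclose(certainty(z), certainty(z + 123.4), atol=1e-12)

    def test_large_logits_stable(self):
        out = certainty(np.array([1000.0, 999.0, 0.0]))
        assert np.all(np.isfinite(out))
        assert out.sum() == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            certainty(np.array([]))

    def test_nonfinite_errors(self):
        with pytest.raises(DataError):
            certainty(np.array([np.nan, 0.0]))


class TestConfusion:
    def test_perfect_predictions(self):
        rep = confusion_and_accuracy(_pred_set([0, 1, 2, 3, 4], [0, 1, 2, 3, 4]))
        assert rep.accuracy == 1.0
        np.testing.assert_array_equal(rep.confusion, np.eye(5, dtype=int))

    def test_swapped_pair(self):
        rep = confusion_and_accuracy(_pred_set([0, 1], [1, 0]))
        assert rep.accuracy == 0.0
        assert rep.confusion[0, 1] == 1
        assert rep.confusion[1, 0] == 1

    def test_hand_built_vs_brute_tally(self, rng):
        true = rng.integers(0, 5, 10)
        pred = rng.integers(0, 5, 10)
        rep = confusion_and_accuracy(_pred_set(true, pred))
        np.testing.assert_array_equal(rep.confusion, brute_confusion(true, pred, 5))

    def test_length_mismatch(self):
        with pytest.raises(DataError, match="mismatch"):
            confusion_and_accuracy(_pred_set([0, 1], [0, 1, 2]))


class TestOffsets:
    def test_no_mispredictions(self):
        offs, unmatched = misprediction_offsets([0, 1, 2], [0, 1, 2], 120.0)
        assert len(offs) == 0 and len(unmatched) == 0

    def test_single_frame_miss(self):
        # (A,A,A,B,B,B) vs (A,A,A,A,B,B): one 1-frame miss = 8.33 ms
        offs, unmatched = misprediction_offsets(
            [0, 0, 0, 1, 1, 1], [0, 0, 0, 0, 1, 1], 120.0
        )
        assert len(unmatched) == 0
        np.testing.assert_allclose(offs, [1000.0 / 120.0])

    def test_shifted_boundaries_constant_offset_per_event(self):
        # shifting every transition by k frames yields constant k-frame
        # offsets under the per-event reading
        true = np.repeat([0, 1, 2, 3, 4], 40)
        k = 3
        pred = np.concatenate([true[k:], true[-1] * np.ones(k, dtype=true.dtype)])
        offs, unmatched = misprediction_offsets(true, pred, 120.0, per_event=True)
        assert len(unmatched) == 0
        assert len(offs) == 4
        np.testing.assert_allclose(offs, k * 1000.0 / 120.0)

    def test_shifted_boundaries_per_frame_bounded_by_shift(self):
        # per-frame offsets of a k-shifted stream run 1..k at each boundary
        true = np.repeat([0, 1, 2, 3, 4], 40)
        k = 3
        pred = np.concatenate([true[k:], true[-1] * np.ones(k, dtype=true.dtype)])
        offs, _ = misprediction_offsets(true, pred, 120.0)
        frames = np.asarray(offs) / (1000.0 / 120.0)
        assert frames.max() == pytest.approx(k)
        np.testing.assert_allclose(np.unique(np.round(frames)), [1, 2, 3])

    def test_unmatched_class_reported(self):
        offs, unmatched = misprediction_offsets([0, 0, 0], [0, 4, 0], 120.0)
        assert len(offs) == 0
        np.testing.assert_array_equal(unmatched, [1])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 300))
        true = r.integers(0, 5, n)
        pred = r.integers(0, 5, n)
        offs, unmatched = misprediction_offsets(true, pred, 120.0)
        b_offs, b_un = brute_offsets(true, pred, 120.0)
        np.testing.assert_allclose(offs, b_offs)
        np.testing.assert_array_equal(unmatched, b_un)


class TestToleranceAccuracy:
    def test_perfect_any_tol(self):
        true = np.array([0, 1, 2, 3, 4] * 4)
        for tol in (0, 1, 5):
            assert tolerance_accuracy(true, true, tol) == 1.0

    def test_worked_example(self):
        true = [0, 0, 0, 1, 1, 1]
        pred = [0, 0, 0, 0, 1, 1]
        assert tolerance_accuracy(true, pred, 0) == pytest.approx(5 / 6)
        assert tolerance_accuracy(true, pred, 1) == 1.0

    def test_tol_zero_is_plain_accuracy(self, rng):
        true = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        plain = float(np.mean(true == pred))
        assert tolerance_accuracy(true, pred, 0) == pytest.approx(plain)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 300))
        true = r.integers(0, 5, n)
        pred = r.integers(0, 5, n)
        for tol in (0, 1, 2, 5):
            assert tolerance_accuracy(true, pred, tol) == pytest.approx(
                brute_tolerance_accuracy(true, pred, tol)
            )

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_tolerance(self, data):
        n = data.draw(st.integers(min_value=1, max_value=120))
        true = np.array(data.draw(st.lists(
            st.integers(0, 4), min_size=n, max_size=n)))
        pred = np.array(data.draw(st.lists(
            st.integers(0, 4), min_size=n, max_size=n)))
        vals = [tolerance_accuracy(true, pred, tol) for tol in range(4)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(float(np.mean(true == pred)))


class TestRejection:
    def test_threshold_zero_keeps_all(self, rng):
        true = rng.integers(0, 5, 50)
        pred = rng.integers(0, 5, 50)
        probs = np.full((50, 5), 0.05)
        probs[np.arange(50), pred] = 0.8
        rep = reject_by_certainty(_pred_set(true, pred, probs), 0.0)
        assert rep.n_unknown == 0
        assert rep.accuracy_retained == pytest.approx(float(np.mean(true == pred)))

    def test_threshold_one_rejects_all(self, rng):
        true = rng.integers(0, 5, 20)
        pred = rng.integers(0, 5, 20)
        rep = reject_by_certainty(_pred_set(true, pred), 1.0)
        assert rep.n_unknown == 20
        assert rep.accuracy_retained is None

    def test_hand_built_bookkeeping(self):
        # 5 predictions: certainties .95 .85 .75 .65 .55; correct T T F F T
        true = np.array([0, 1, 2, 3, 4])
        pred = np.array([0, 1, 0, 0, 4])
        probs = np.full((5, 5), 0.01)
        for i, c in enumerate([0.95, 0.85, 0.75, 0.65, 0.55]):
            probs[i, pred[i]] = c
        rep = reject_by_certainty(_pred_set(true, pred, probs), 0.8)
        assert rep.n_unknown == 3
        assert rep.n_correct_to_unknown == 1
        assert rep.n_wrong_to_unknown == 2
        assert rep.accuracy_retained == 1.0
        assert rep.frac_unknown == pytest.approx(3 / 5)
        assert rep.frac_correct_to_unknown == pytest.approx(1 / 3)
        assert rep.frac_wrong_to_unknown == pytest.approx(2 / 2)

    def test_counts_conserved(self, rng):
        true = rng.integers(0, 5, 100)
        pred = rng.integers(0, 5, 100)
        probs = rng.dirichlet(np.ones(5), size=100)
        ps = PredictionSet(probs=probs, pred=pred, true=true)
        for thr in (0.2, 0.5, 0.8):
            rep = reject_by_certainty(ps, thr)
            assert rep.n_unknown == rep.n_correct_to_unknown + rep.n_wrong_to_unknown
            assert rep.n_total == 100

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 300))
        true = r.integers(0, 5, n)
        pred = r.integers(0, 5, n)
        probs = r.dirichlet(np.ones(5), size=n)
        ps = PredictionSet(probs=probs, pred=pred, true=true)
        thr = float(r.uniform(0, 1))
        rep = reject_by_certainty(ps, thr)
        ref = brute_rejection(pred == true, probs.max(axis=1), thr)
        for key, val in ref.items():
            got = getattr(rep, key)
            if val is None:
                assert got is None
            else:
                assert got == pytest.approx(val)

    def test_monotone_certainty_transform_keeps_confusion(self, rng):
        true = rng.integers(0, 5, 50)
        probs = rng.dirichlet(np.ones(5), size=50)
        pred = probs.argmax(axis=1)
        a = confusion_and_accuracy(_pred_set(true, pred, probs))
        b = confusion_and_accuracy(_pred_set(true, pred, probs**3))
        np.testing.assert_array_equal(a.confusion, b.confusion)


class TestLoocvSummary:
    def test_summary_statistics_of_published_table(self):
        s = loocv_summary(TABLE1_ACCURACIES)
        assert round(s["mean"], 4) == 0.9229
        # population sd of the printed values; the source table's own sd
        # figure (0.01586) was evidently computed before rounding
        assert s["sd"] == pytest.approx(0.0158518346, abs=1e-9)
        assert s["median"] == pytest.approx(0.9209)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            loocv_summary([])


class TestLoocvDriver:
    def test_two_subjects_two_models(self):
        cfg = SyntheticConfig(
            n_subjects=2, duration_s=8.0, noise_sd_imu=0.02, seed=5
        )
        dataset = simulate_dataset(cfg)
        res = loocv(
            dataset,
            tiny_model_cfg(),
            TrainConfig(epochs=2, batch_size=2, seed=0),
            window_spec=WindowSpec(window_len=20, shift=4),
            seq_len=16,
        )
        assert len(res["per_subject"]) == 2
        assert res["n"] == 2
        for acc in res["per_subject"].values():
            assert 0.0 <= acc <= 1.0

    def test_single_subject_errors(self):
        cfg = SyntheticConfig(n_subjects=1, duration_s=4.0, seed=0)
        with pytest.raises(DataError):
            loocv(simulate_dataset(cfg), tiny_model_cfg(), TrainConfig(epochs=1))


class TestWorkedArithmetic:
    def test_expected_transition_error(self):
        assert expected_transition_error_pct(5, 120, 1.0) == pytest.approx(4.1667, abs=1e-3)

    def test_frame_duration(self):
        assert frame_ms(120.0) == pytest.approx(8.3333, abs=1e-3)
        assert frame_ms_label(120.0) == 8


class TestCertaintyStats:
    def test_quartiles_and_outliers(self):
        vals = np.array([0.1] + [0.8, 0.81, 0.82, 0.83, 0.84, 0.85, 0.86, 0.87])
        s = certainty_stats(vals)
        assert s["n"] == 9
        assert s["n_outliers"] == 1
        assert s["whisker_low"] >= 0.8

    def test_empty(self):
        assert certainty_stats(np.array([])) == {"n": 0}


class TestActivationHeatmap:
    def test_constant_zero_input_gives_zero_map(self, rng):
        net = build_model(tiny_model_cfg(), (20, 14))
        x = np.zeros((1, 3, 20, 14), dtype=np.float32)
        hm = activation_heatmap(net, x)
        assert np.all(hm["map"] == 0.0)

    def test_map_in_unit_interval(self, rng):
        net = build_model(tiny_model_cfg(), (20, 14))
        x = rng.standard_normal((2, 3, 20, 14)).astype(np.float32)
        hm = activation_heatmap(net, x, target_shape=(40, 28))
        assert hm["map"].shape == (40, 28)
        assert hm["map"].min() >= 0.0 and hm["map"].max() <= 1.0
        assert hm["grid"].max() == pytest.approx(1.0)

    def test_empty_input_errors(self):
        net = build_model(tiny_model_cfg(), (20, 14))
        with pytest.raises(DataError):
            activation_heatmap(net, np.zeros((0, 3, 20, 14), dtype=np.float32))

    def test_save_png_and_csv(self, rng, tmp_path):
        from gaitphase.evaluation import save_heatmap

        net = build_model(tiny_model_cfg(), (20, 14))
        x = rng.standard_normal((1, 3, 20, 14)).astype(np.float32)
        hm = activation_heatmap(net, x)
        save_heatmap(hm, tmp_path / "hm.png", tmp_path / "hm.csv")
        assert (tmp_path / "hm.png").stat().st_size > 0
        grid = np.loadtxt(tmp_path / "hm.csv", delimiter=",")
        np.testing.assert_allclose(grid, hm["grid"], atol=1e-6)


class TestInformativeSensorAttribution:
    def test_informative_sensor_gets_high_mass(self):
        """Train on data where one sensor carries the phase signal and the
        rest carry scaled noise; its columns must receive above-average mass
        and the peak must land within one sensor of it (the pooled grid is
        too coarse for an exact assignment)."""
        from gaitphase.pipeline import prepare_subject, run_split
        from gaitphase.types import CHANNELS, SENSOR_LOCATIONS
        from gaitphase.windowing import windows_to_tensors

        cfg = SyntheticConfig(n_subjects=3, duration_s=12.0, noise_sd_imu=0.02, seed=7)
        dataset = simulate_dataset(cfg)
        r = np.random.default_rng(99)
        informative, nc = 4, len(CHANNELS)
        for imu, _, _ in dataset:
            sig_sd = imu.samples[:, informative * nc : (informative + 1) * nc].std()
            for s in range(len(SENSOR_LOCATIONS)):
                if s == informative:
                    continue
                imu.samples[:, s * nc : (s + 1) * nc] = r.normal(
                    0, 0.3 * sig_sd, size=(imu.n_frames, nc)
                )
        wspec = WindowSpec(window_len=30, shift=4)
        res = run_split(
            dataset,
            unseen_subject="subject_02",
            model_cfg=ModelConfigSmall(),
            train_cfg=TrainConfig(epochs=5, batch_size=4, seed=0),
            window_spec=wspec,
            seq_len=32,
            split_seed=0,
            use_truth_labels=True,
        )
        chunks = prepare_subject(
            dataset[2][0], dataset[2][1], window_spec=wspec, seq_len=32,
            truth_labels=dataset[2][2],
        )
        X, _, _ = windows_to_tensors(chunks, wspec)
        hm = activation_heatmap(res["net"], X, target_shape=(30, 70))
        per_sensor = hm["map"].mean(axis=0).reshape(10, 7).mean(axis=1)
        others = np.delete(per_sensor, informative)
        assert per_sensor[informative] > others.mean()
        assert abs(int(np.argmax(per_sensor)) - informative) <= 1


def ModelConfigSmall():
    return tiny_model_cfg(conv_filters=(4, 4, 8, 8, 8, 8), dense_units=(32, 16),
                          lstm_units=None)
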