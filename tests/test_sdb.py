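"""DAP detection, desaturation coupling, features and classifier tests."""

import numpy as np
import pytest

from sleepglove import heart, sdb
from sleepglove.config import SdbConfig
from sleepglove.sdb import DapEvent, DesatEvent, Envelope


class TestAmplitudeEnvelope:
    def test_constant_train_ratio_near_one(self, clean_pulses):
        z, pulses = clean_pulses
        env = sdb.amplitude_envelope(z, pulses)
        ratio = env.env[env.valid] / env.baseline[env.valid]
        assert np.percentile(np.abs(ratio - 1.0), 90) < 0.25

    def test_envelope_invariant_to_dc_offset(self, clean_pulses):
        z, pulses = clean_pulses
        a = sdb.amplitude_envelope(z, pulses)
        b = sdb.amplitude_envelope(z + 1000.0, pulses)
        np.testing.assert_allclose(a.env, b.env, atol=1e-9)

    def test_injected_drop_reaches_half_baseline(self, event_night_analysis):
        d = event_night_analysis
        env = d["env"]
        e0 = d["events"][0]  # depth 0.6 apnea
        sel = (env.t >= e0.onset_s + 2) & (env.t <= e0.end_s - 2)
        ratio = env.env[sel] / env.baseline[sel]
        assert ratio.min() < 0.55


def _flat_envelope(n=2400, dt=0.25):
    t = np.arange(n) * dt
    env = np.ones(n)
    return t, env


class TestDetectDap:
    def test_constant_envelope_has_no_events(self):
        t, env = _flat_envelope()
        e = Envelope(t, env, np.ones_like(env), np.ones_like(env, bool))
        assert sdb.detect_dap(e) == []

    def test_rectangular_drop_detected_with_depth(self):
        t, env = _flat_envelope()
        env[400:460] = 0.5                      # 15 s drop at t=100
        e = Envelope(t, env, np.ones_like(env), np.ones_like(env, bool))
        events = sdb.detect_dap(e)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(100.0, abs=1.0)
        assert events[0].duration_s == pytest.approx(15.0, abs=1.0)
        assert events[0].depth == pytest.approx(0.5, abs=0.02)

    def test_nearby_drops_merged(self):
        t, env = _flat_envelope()
        env[400:440] = 0.4
        env[448:488] = 0.4                      # 2 s gap < merge_gap 5 s
        e = Envelope(t, env, np.ones_like(env), np.ones_like(env, bool))
        assert len(sdb.detect_dap(e)) == 1

    def test_short_drop_ignored(self):
        t, env = _flat_envelope()
        env[400:420] = 0.4                      # 5 s < min_dur 10 s
        e = Envelope(t, env, np.ones_like(env), np.ones_like(env, bool))
        assert sdb.detect_dap(e) == []

    def test_count_monotone_in_depth_threshold(self):
        rng = np.random.default_rng(0)
        t = np.arange(4800) * 0.25
        env = 1.0 + 0.05 * rng.normal(size=len(t))
        for s, depth in ((400, 0.5), (1200, 0.35), (2400, 0.25), (3600, 0.6)):
            env[s : s + 60] = 1.0 - depth
        e = Envelope(t, env, np.ones_like(env), np.ones_like(env, bool))
        counts = [len(sdb.detect_dap(e, SdbConfig(depth_threshold=th)))
                  for th in (0.2, 0.3, 0.4, 0.55)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDetectDesaturation:
    def test_four_point_dip_detected(self):
        spo2 = np.full(600, 97.0)
        spo2[300:310] = 93.0
        events = sdb.detect_desaturation(spo2)
        assert len(events) == 1
        assert events[0].drop_percent == pytest.approx(4.0)
        assert events[0].onset_s == pytest.approx(300.0)

    def test_constant_channel_has_no_events(self):
        assert sdb.detect_desaturation(np.full(600, 97.0)) == []

    def test_two_point_dip_below_criterion(self):
        spo2 = np.full(600, 97.0)
        spo2[300:310] = 95.0
        assert sdb.detect_desaturation(spo2) == []

    def test_all_artifact_channel_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert sdb.detect_desaturation(np.full(120, 37.0)) == []


class TestCoupling:
    @pytest.mark.parametrize("desat_onset, expected", [
        (110.0, "apneic_hypopneic"),   # inside [100, 120]
        (130.0, "control"),            # outside the 20 s window
        (95.0, "control"),             # before the DAP
    ])
    def test_left_centered_window(self, desat_onset, expected):
        daps = [DapEvent(onset_s=100.0, duration_s=15.0, depth=0.5)]
        desats = [DesatEvent(desat_onset, desat_onset + 5, 4.0)]
        out = sdb.couple_dap_desat(daps, desats)
        assert out[0].label == expected

    def test_no_desats_forces_all_control(self, event_night_analysis):
        daps = [DapEvent(d.onset_s, d.duration_s, d.depth)
                for d in event_night_analysis["daps"]]
        out = sdb.couple_dap_desat(daps, [])
        assert all(d.label == "control" for d in out)


class TestMinuteLabels:
    def test_event_spanning_two_minutes_flags_both(self):
        daps = [DapEvent(onset_s=655.0, duration_s=15.0, depth=0.5,
                         label="apneic_hypopneic")]
        flags, ahi = sdb.minute_labels(daps, 60)
        assert flags[10] and flags[11] and flags.sum() == 2
        assert ahi == pytest.approx(1.0)

    def test_no_events_all_clear(self):
        flags, ahi = sdb.minute_labels([], 60)
        assert not flags.any() and ahi == 0.0

    def test_control_events_do_not_flag(self):
        daps = [DapEvent(onset_s=100.0, duration_s=15.0, depth=0.5,
                         label="control")]
        flags, _ = sdb.minute_labels(daps, 10)
        assert not flags.any()


class TestFeatures:
    def test_vector_has_37_finite_features_and_is_deterministic(
            self, event_night_analysis):
        d = event_night_analysis
        dap = d["daps"][0]
        v1 = sdb.extract_features(d["z"], d["stream"].spo2, d["pulses"],
                                  d["env"], dap)
        v2 = sdb.extract_features(d["z"], d["stream"].spo2, d["pulses"],
                                  d["env"], dap)
        assert v1.shape == (37,) and np.all(np.isfinite(v1))
        np.testing.assert_array_equal(v1, v2)
        assert len(sdb.FEATURE_NAMES) == 37

    def test_window_truncated_at_edge_excluded(self, event_night_analysis):
        d = event_night_analysis
        edge = DapEvent(onset_s=5.0, duration_s=15.0, depth=0.5)
        assert sdb.extract_features(d["z"], d["stream"].spo2, d["pulses"],
                                    d["env"], edge) is None

    def test_prv_features_invariant_to_amplitude_scaling(
            self, event_night_analysis):
        """Times and SpO2 drive 29 features; only morphology follows scale."""
        d = event_night_analysis
        dap = d["daps"][2]
        v1 = sdb.extract_features(d["z"], d["stream"].spo2, d["pulses"],
                                  d["env"], dap)
        env2 = Envelope(d["env"].t, 3.0 * d["env"].env,
                        3.0 * d["env"].baseline, d["env"].valid)
        v2 = sdb.extract_features(d["z"], d["stream"].spo2, d["pulses"],
                                  env2, dap)
        morph = [sdb.FEATURE_NAMES.index(n) for n in sdb.FEATURE_NAMES
                 if n.startswith("dap_")]
        keep = [i for i in range(37) if i not in morph]
        np.testing.assert_allclose(v1[keep], v2[keep], rtol=1e-9)
        # baseline level scales with the envelope, ratios do not
        i_base = sdb.FEATURE_NAMES.index("dap_baseline_level")
        assert v2[i_base] == pytest.approx(3.0 * v1[i_base])


class TestClassifier:
    def test_separable_gaussians_classified(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.normal(size=(2 * n, 37))
        X[n:, :5] += 3.0                     # 3 s.d. shift in 5 features
        y = np.array(["CA"] * n + ["OA"] * n)
        rep = sdb.cross_validate_pairwise(X, y, seed=0)
        assert rep["C-O"]["acc"] >= 0.9

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(1)
        n = 100
        X = rng.normal(size=(2 * n, 37))
        X[n:, :5] += 3.0
        y = rng.permutation(np.array(["CA"] * n + ["OA"] * n))
        rep = sdb.cross_validate_pairwise(X, y, seed=0)
        assert abs(rep["C-O"]["acc"] - 0.5) <= 0.1

    def test_feature_scaling_does_not_change_predictions(self):
        rng = np.random.default_rng(2)
        n = 40
        X = rng.normal(size=(2 * n, 37))
        X[n:, :5] += 3.0
        y = np.array([0] * n + [1] * n)
        a = sdb.make_classifier(seed=0).fit(X, y).predict(X)
        b = sdb.make_classifier(seed=0).fit(2.0 * X, y).predict(2.0 * X)
        np.testing.assert_array_equal(a, b)

    def test_missing_class_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 37))
        y = np.array(["CA"] * 30)
        with pytest.warns(UserWarning):
            rep = sdb.cross_validate_pairwise(X, y, seed=0)
        assert rep == {}


class TestEndToEndRecovery:
    def test_injected_event_recall_and_precision(self, event_night_analysis):
        d = event_night_analysis
        events, daps = d["events"], d["daps"]
        tol = 10.0
        tp = sum(1 for e in events
                 if any(abs(dp.onset_s - e.onset_s) < tol for dp in daps))
        fp = sum(1 for dp in daps
                 if not any(abs(dp.onset_s - e.onset_s) < tol for e in events))
        assert tp / len(events) >= 0.9
        assert (len(daps) - fp) / len(daps) >= 0.9

    def test_oa_vs_ca_contrast_separates(self, event_night_analysis):
        """The post-event sympathetic surge must be recoverable by the SVM."""
        d = event_night_analysis
        rep = sdb.cross_validate_pairwise(d["X"], d["y"], seed=0)
        assert rep["C-O"]["acc"] >= 0.8
        assert rep["C-O"]["auc"] >= 0.8
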