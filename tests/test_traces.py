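"""ΔF/F, transient detection and responsiveness classification."""

import numpy as np
import pytest

import v1sense as v
from v1sense.protocol import StimulusProtocol
from v1sense.traces import baseline_sd


def kernel_transient(n_frames, peak_frame, amp, f=20.4, tau=1.0):
    t = np.arange(n_frames) / f
    x = np.zeros(n_frames)
    sel = t >= t[peak_frame]
    x[sel] = amp * np.exp(-(t[sel] - t[peak_frame]) / tau)
    return x


class TestExtractRoiTraces:
    def test_uniform_frames_give_constant_traces(self):
        movie = np.full((5, 16, 16), 7.0)
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        ts = v.extract_roi_traces(movie, [mask], f=20.4)
        np.testing.assert_allclose(ts.F[0], 7.0)

    def test_checkerboard_mask_averages(self):
        movie = np.zeros((3, 8, 8))
        movie[:, ::2, :] = 4.0  # half the mask rows at 2v, half at 0
        mask = np.ones((8, 8), bool)
        ts = v.extract_roi_traces(movie, [mask], f=20.4)
        np.testing.assert_allclose(ts.F[0], 2.0)

    def test_round_trip_through_movie(self):
        pop = v.make_uniform_population(4, seed=0)
        cfg = v.SimConfig(T=2.0, noise_sd=0.0)
        truth = v.simulate_activity(pop, None, cfg, seed=0)
        ts = v.render_traces(truth, cfg, seed=0)
        rois = v.disc_rois(pop.positions, shape=(128, 128))
        movie = v.render_movie(ts, rois)
        out = v.extract_roi_traces(movie, rois, f=cfg.f)
        np.testing.assert_allclose(out.F, ts.F, atol=1e-4)

    def test_empty_mask_names_roi(self):
        movie = np.zeros((2, 8, 8))
        with pytest.raises(ValueError, match="ROI 1"):
            v.extract_roi_traces(
                movie, [np.ones((8, 8), bool), np.zeros((8, 8), bool)], f=20.4
            )


class TestComputeDff:
    def test_constant_trace_zero_dff(self):
        ts = v.compute_dff(v.TraceSet(F=np.full((1, 50), 100.0), f=20.4))
        np.testing.assert_allclose(ts.dff, 0.0)

    def test_simple_ratio(self):
        F = np.full((1, 101), 100.0)
        F[0, 70:] = 110.0  # minority of frames high: median stays 100
        ts = v.compute_dff(v.TraceSet(F=F, f=20.4))
        assert ts.dff[0, 80] == pytest.approx(0.1)

    def test_generator_amplitude_preserved(self):
        gt = v.GroundTruth([np.array([100])], {}, [], n_frames=400, f=20.4)
        cfg = v.SimConfig(T=400 / 20.4, amp=0.25, noise_sd=0.0)
        ts = v.compute_dff(v.render_traces(gt, cfg))
        assert ts.dff[0].max() == pytest.approx(0.25, rel=1e-6)

    def test_prestim_mean_baseline(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        F = np.full((1, n_frames), 80.0)
        ts = v.compute_dff(
            v.TraceSet(F=F, f=20.4), baseline_mode="prestim-mean", protocol=protocol
        )
        np.testing.assert_allclose(ts.dff, 0.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            v.compute_dff(v.TraceSet(F=np.zeros((1, 50)), f=20.4))


class TestDetectTransients:
    def test_clear_transient_detected_once_near_peak(self, rng):
        x = kernel_transient(500, 200, amp=0.1) + rng.normal(0, 0.02, 500)
        ts = v.TraceSet(F=np.ones((1, 500)), f=20.4)
        ts.dff = x[None, :]
        ev = v.detect_transients(ts)
        peaks = np.flatnonzero(ev.B[0])
        assert len(peaks) == 1
        assert abs(peaks[0] - 200) <= 10

    def test_subthreshold_transient_ignored(self, rng):
        x = kernel_transient(500, 200, amp=0.02) + rng.normal(0, 0.02, 500)
        ts = v.TraceSet(F=np.ones((1, 500)), f=20.4)
        ts.dff = x[None, :]
        assert v.detect_transients(ts).B.sum() == 0

    def test_zero_variance_trace_rejected(self):
        ts = v.TraceSet(F=np.ones((1, 50)), f=20.4)
        ts.dff = np.zeros((1, 50))
        with pytest.raises(ValueError, match="zero-variance"):
            v.detect_transients(ts)

    def test_scale_invariance_of_events(self, rng):
        # dF/F cancels any positive gain applied to raw fluorescence
        gt = v.GroundTruth(
            [np.sort(rng.choice(2000, 20, replace=False))], {}, [],
            n_frames=2000, f=20.4,
        )
        cfg = v.SimConfig(T=2000 / 20.4, amp=0.15, noise_sd=0.02)
        base = v.render_traces(gt, cfg, seed=8)
        ev1 = v.detect_transients(v.compute_dff(base))
        scaled = v.TraceSet(F=base.F * 3.7, f=base.f)
        ev2 = v.detect_transients(v.compute_dff(scaled))
        np.testing.assert_array_equal(ev1.B, ev2.B)

    def test_recall_and_precision_on_ground_truth(self):
        cfg = v.SimConfig(T=1000.0, bg_rate=0.1, amp=0.12, noise_sd=0.02)
        pop = v.make_uniform_population(1, seed=1)
        truth = v.simulate_activity(pop, None, cfg, seed=1)
        ts = v.compute_dff(v.render_traces(truth, cfg, seed=1))
        det = np.flatnonzero(v.detect_transients(ts).B[0])
        true = truth.spike_frames[0]
        tol = int(0.5 * cfg.f)
        recall = np.mean([np.abs(det - t).min() <= tol for t in true])
        precision = np.mean([np.abs(true - d).min() <= tol for d in det])
        assert recall >= 0.9
        assert precision >= 0.95


def test_baseline_sd_recovers_noise_floor(rng):
    x = rng.normal(0, 0.02, 5000)
    x[::100] += 0.3  # sparse transient-like outliers
    assert baseline_sd(x)[0] == pytest.approx(0.02, rel=0.1)


class TestClassifyResponsive:
    @staticmethod
    def _events(frames, n_frames, f=20.4):
        B = np.zeros((1, n_frames), np.uint8)
        B[0, frames] = 1
        return v.EventTrainSet(B=B, f=f)

    def test_event_inside_window_is_responsive(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        onset = protocol.trials("S1")[0]
        ev = self._events([int((onset + 1.0) * 20.4)], n_frames)
        table = v.classify_responsive(ev, protocol)
        assert table.responded["S1"][0, 0]

    def test_events_only_during_isi_not_responsive(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        frames = [int((onset + 5.0) * 20.4) for onset in protocol.onsets]
        table = v.classify_responsive(self._events(frames, n_frames), protocol)
        assert table.probability.to_numpy().sum() == 0

    def test_probability_counts_trials(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        onsets = protocol.trials("S4")
        frames = [int((onsets[i] + 0.5) * 20.4) for i in (0, 2)]  # trials 1 and 3 of 5
        table = v.classify_responsive(self._events(frames, n_frames), protocol)
        assert table.probability.loc[0, "S4"] == pytest.approx(0.4)

    def test_percent_invariant_to_neuron_and_trial_order(self, wt_session, protocol):
        table = wt_session["table"]
        ev = wt_session["events"]
        perm = np.random.default_rng(0).permutation(ev.n_neurons)
        shuffled = v.EventTrainSet(B=ev.B[perm], f=ev.f)
        t2 = v.classify_responsive(shuffled, protocol)
        for lab in table.labels:
            assert t2.percent_responsive(lab) == pytest.approx(
                table.percent_responsive(lab)
            )


class TestResponseAmplitude:
    def test_single_transient_amplitude(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        onset = protocol.trials("S1")[0]
        peak = int((onset + 1.0) * 20.4)
        dff = kernel_transient(n_frames, peak, amp=0.1)[None, :]
        ts = v.TraceSet(F=np.ones((1, n_frames)), f=20.4)
        ts.dff = dff
        B = np.zeros((1, n_frames), np.uint8)
        B[0, peak] = 1
        table = v.classify_responsive(v.EventTrainSet(B=B, f=20.4), protocol)
        amp = v.response_amplitude(ts, protocol, table)
        assert amp.loc[0, "S1"] == pytest.approx(0.1)

    def test_mean_over_responsive_trials(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        onsets = protocol.trials("S4")
        p1, p2 = int((onsets[0] + 1) * 20.4), int((onsets[1] + 1) * 20.4)
        dff = (
            kernel_transient(n_frames, p1, 0.1) + kernel_transient(n_frames, p2, 0.3)
        )[None, :]
        ts = v.TraceSet(F=np.ones((1, n_frames)), f=20.4)
        ts.dff = dff
        B = np.zeros((1, n_frames), np.uint8)
        B[0, [p1, p2]] = 1
        table = v.classify_responsive(v.EventTrainSet(B=B, f=20.4), protocol)
        amp = v.response_amplitude(ts, protocol, table)
        # second trial's peak includes the (decayed) tail of nothing: exact mean
        assert amp.loc[0, "S4"] == pytest.approx(0.2, abs=1e-6)

    def test_never_responsive_flagged_nan(self, protocol):
        n_frames = int(np.ceil(protocol.span * 20.4))
        ts = v.TraceSet(F=np.ones((1, n_frames)), f=20.4)
        ts.dff = np.zeros((1, n_frames))
        B = np.zeros((1, n_frames), np.uint8)
        table = v.classify_responsive(v.EventTrainSet(B=B, f=20.4), protocol)
        amp = v.response_amplitude(ts, protocol, table)
        assert np.isnan(amp.loc[0, "S1"])


class TestNai:
    def test_ratio(self):
        # 15% vs 30% responsive -> 0.5
        tbl = _table(pct_s1=15.0, pct_s4=30.0)
        assert v.compute_nai(tbl) == pytest.approx(0.5)
        assert _table(20.0, 20.0).nai() == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            v.compute_nai(_table(10.0, 0.0))

    def test_wt_like_simulation_brackets_ratio(self, wt_session):
        # p = 0.10 vs 0.35 -> NAI near 10/35
        nai = wt_session["table"].nai()
        assert 0.1 < nai < 0.6


def _table(pct_s1, pct_s4, n=200, trials=5):
    """Response table with exact percent-responsive values."""
    import pandas as pd

    responded = {}
    for lab, pct in (("S1", pct_s1), ("S4", pct_s4)):
        k = int(round(pct / 100 * n * trials))
        flat = np.zeros(n * trials, bool)
        flat[:k] = True
        responded[lab] = flat.reshape(n, trials)
    prob = pd.DataFrame({lab: r.mean(axis=1) for lab, r in responded.items()})
    return v.ResponseTable(responded=responded, probability=prob)
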