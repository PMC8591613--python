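"""Interference-suppression cascade and epoching."""

import numpy as np
import pytest

from opmpipe import preprocess, synthetic
from opmpipe.containers import Recording
from opmpipe.preprocess import (
    default_spectral_targets, detect_artefact_segments, downsample,
    epoch_and_baseline, equalize_trials, filter_zero_phase,
    homogeneous_field_correction, regress_motion, spectral_interpolation,
)


def _recording(data, rate=1000.0, axes=None, events=()):
    data = np.atleast_2d(np.asarray(data, float))
    n_ch = data.shape[0]
    if axes is None:
        rng = np.random.default_rng(0)
        axes = rng.normal(size=(n_ch, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return Recording(data, rate, [f"ch{i}" for i in range(n_ch)],
                     np.zeros((n_ch, 3)), axes, events=list(events))


def _array_recording(array, data, rate=1000.0, events=()):
    return Recording(np.asarray(data, float), rate, list(array.channel_names),
                     array.channel_positions(), array.channel_axes(),
                     events=list(events))


# --------------------------------------------------------------------------- #
# Downsampling
# --------------------------------------------------------------------------- #

class TestDownsample:
    def test_6000_to_1000(self):
        rec = _recording(np.random.default_rng(1).normal(size=(3, 60000)),
                         rate=6000.0, events=[("tone", 6000)])
        out = downsample(rec, 1000.0)
        assert out.rate == 1000.0
        assert out.n_samples == 10000
        assert out.events == [("tone", 1000)]

    def test_identity_at_same_rate(self):
        rec = _recording(np.ones((2, 100)))
        out = downsample(rec, 1000.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_alias_suppression(self):
        """A 700 Hz tone at 6000 Hz must not fold into the 1000 Hz output."""
        t = np.arange(60000) / 6000.0
        rec = _recording(np.sin(2 * np.pi * 700.0 * t), rate=6000.0)
        out = downsample(rec, 1000.0)
        assert np.abs(out.data[0, 500:-500]).max() < 0.01

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            downsample(_recording(np.ones((1, 10))), 2000.0)


# --------------------------------------------------------------------------- #
# Motion regression
# --------------------------------------------------------------------------- #

class TestRegressMotion:
    def _regressors(self, n, rate=1000.0, seed=4):
        from scipy.signal import butter, sosfiltfilt
        rng = np.random.default_rng(seed)
        sos = butter(4, 1.0, fs=rate, output="sos")
        return sosfiltfilt(sos, rng.normal(size=(6, n)), axis=1)

    def test_exact_linear_artefact_removed(self):
        n = 30000
        X = self._regressors(n)
        rec = _recording(3.0 * X[0] + 0.5 * X[3])
        out, table = regress_motion(rec, X)
        assert np.sqrt((out.data ** 2).mean()) < 1e-10 * np.sqrt((rec.data ** 2).mean())

    def test_orthogonal_channel_untouched(self):
        n = 20000
        X = self._regressors(n)
        rng = np.random.default_rng(9)
        y = rng.normal(size=n)
        # orthogonalise against [1, X] in every window the regression uses
        win, hop = 10000, 5000
        for s in [0, 5000, 10000]:
            A = np.column_stack([np.ones(win), X[:, s:s + win].T])
            yw = y[s:s + win]
            y[s:s + win] = yw - A @ np.linalg.lstsq(A, yw, rcond=None)[0]
        # iterate once more: overlapping windows interact
        for _ in range(200):
            changed = 0.0
            for s in [0, 5000, 10000]:
                A = np.column_stack([np.ones(win), X[:, s:s + win].T])
                beta = np.linalg.lstsq(A, y[s:s + win], rcond=None)[0]
                changed = max(changed, np.abs(A @ beta).max())
                y[s:s + win] -= A @ beta
            if changed < 1e-14:
                break
        rec = _recording(y)
        out, _ = regress_motion(rec, X)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-10 * np.abs(y).max())

    def test_window_count_formula(self):
        n = 300000  # 300 s at 1000 Hz
        X = self._regressors(n)
        rec = _recording(np.random.default_rng(2).normal(size=n))
        _, table = regress_motion(rec, X, window_s=10.0, overlap_frac=0.5)
        assert len(table) == 59

    def test_still_window_flagged_and_harmless(self):
        """Constant regressors (still run): motion betas zeroed, channel
        passes through up to its mean."""
        n = 20000
        X = np.zeros((6, n))
        y = np.random.default_rng(3).normal(size=n)
        out, table = regress_motion(_recording(y), X)
        assert table.rank_deficient.all()
        # only the slowly varying windowed mean is removed; no noise injected
        resid = out.data[0] - (y - y.mean())
        assert resid.std() < 0.05 * y.std()
        assert np.corrcoef(out.data[0], y)[0, 1] > 0.999

    def test_output_continuous_across_windows(self):
        n = 25000
        X = self._regressors(n)
        y = 2.0 * X[1] + np.random.default_rng(1).normal(size=n)
        out, _ = regress_motion(_recording(y), X)
        assert np.abs(np.diff(out.data[0])).max() < 10 * np.abs(np.diff(y)).max()


# --------------------------------------------------------------------------- #
# Homogeneous field correction
# --------------------------------------------------------------------------- #

class TestHFC:
    def test_uniform_field_removed_exactly(self, array):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(3, 2000)) * 1e-9
        data = array.channel_axes() @ u
        rec = _array_recording(array, data)
        out, removed = homogeneous_field_correction(rec)
        assert np.abs(out.data).max() < 1e-12 * np.abs(data).max()
        np.testing.assert_allclose(removed, u, atol=1e-20)

    def test_single_sample_uniform_recovery(self, array):
        u = np.array([[1e-9], [0.0], [0.0]])
        rec = _array_recording(array, array.channel_axes() @ u)
        _, removed = homogeneous_field_correction(rec)
        np.testing.assert_allclose(removed, u, atol=1e-22)

    def test_dipolar_signal_mostly_retained(self, array, head_model):
        """A dipolar topography projects weakly onto the uniform-field basis
        of a whole-head dual-axis array: the retained energy, computed as
        ||(I - A pinv(A)) y||^2 / ||y||^2 on this geometry, is ~0.88-0.92
        per hemisphere."""
        from opmpipe.forward import lead_field
        for src in synthetic.bilateral_auditory_sources():
            L = lead_field(head_model, array, src.position)
            y = L @ src.moment_orientation
            rec = _array_recording(array, y[:, None])
            out, _ = homogeneous_field_correction(rec)
            retained = (out.data ** 2).sum() / (y ** 2).sum()
            assert retained >= 0.85

    def test_rank_deficient_axes_rejected(self):
        axes = np.tile([1.0, 0.0, 0.0], (5, 1))
        rec = _recording(np.ones((5, 10)), axes=axes)
        with pytest.raises(ValueError, match="uniform field"):
            homogeneous_field_correction(rec)


# --------------------------------------------------------------------------- #
# Spectral interpolation
# --------------------------------------------------------------------------- #

class TestSpectralInterpolation:
    def test_white_noise_psd_preserved_off_target(self):
        from scipy.signal import welch
        rng = np.random.default_rng(6)
        rec = _recording(rng.normal(size=60000))
        out = spectral_interpolation(rec, targets=[50.0])
        f, p_in = welch(rec.data[0], fs=1000.0, nperseg=4096)
        _, p_out = welch(out.data[0], fs=1000.0, nperseg=4096)
        off = (f > 5) & (np.abs(f - 50.0) > 3)
        ratio = p_out[off].sum() / p_in[off].sum()
        assert ratio == pytest.approx(1.0, abs=0.10)

    def test_strong_line_flattened_to_flank_level(self):
        from scipy.signal import welch
        rng = np.random.default_rng(7)
        t = np.arange(120000) / 1000.0
        noise = rng.normal(size=t.size)
        rec = _recording(noise + 100.0 * np.sin(2 * np.pi * 50.0 * t))
        out = spectral_interpolation(rec, targets=[50.0])
        f, p = welch(out.data[0], fs=1000.0, nperseg=8192)
        at = p[np.abs(f - 50.0) <= 0.5].mean()
        flank = p[((f >= 48) & (f <= 49)) | ((f >= 51) & (f <= 52))].mean()
        assert abs(10 * np.log10(at / flank)) < 3.0

    def test_default_target_list(self):
        targets = default_spectral_targets(1000.0)
        assert set(targets) == {50.0, 100.0, 150.0, 200.0, 250.0, 300.0,
                                350.0, 400.0, 450.0, 120.0, 83.0}

    def test_target_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            spectral_interpolation(_recording(np.ones(1000)), targets=[600.0])

    def test_output_real_and_same_length(self):
        rec = _recording(np.random.default_rng(1).normal(size=12345))
        out = spectral_interpolation(rec, targets=[50.0, 120.0, 83.0])
        assert out.data.shape == rec.data.shape
        assert np.isrealobj(out.data)


# --------------------------------------------------------------------------- #
# Zero-phase filtering
# --------------------------------------------------------------------------- #

class TestFilterZeroPhase:
    def test_dc_removed_by_highpass(self):
        rec = _recording(np.full(20000, 5.0))
        out = filter_zero_phase(rec, "highpass", 2.0, 5)
        assert np.abs(out.data.mean()) < 1e-6 * 5.0

    def test_symmetric_bump_peak_unmoved_by_lowpass(self):
        from scipy.ndimage import gaussian_filter1d
        sig = np.zeros(4001)
        sig[2000] = 1.0
        sig = gaussian_filter1d(sig, 30)
        out = filter_zero_phase(_recording(sig), "lowpass", 40.0, 6)
        assert int(np.argmax(out.data[0])) == 2000

    def test_6Hz_preserved_by_2Hz_highpass(self):
        t = np.arange(40000) / 1000.0
        rec = _recording(np.sin(2 * np.pi * 6.0 * t))
        out = filter_zero_phase(rec, "highpass", 2.0, 5)
        mid = out.data[0, 5000:-5000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_zero_phase(_recording(np.ones(100)), "lowpass", 600.0, 4)


# --------------------------------------------------------------------------- #
# Artefact detection
# --------------------------------------------------------------------------- #

class TestArtefactDetection:
    def test_constant_data_unflagged(self):
        rec = _recording(np.zeros((4, 30000)))
        assert detect_artefact_segments(rec) == []

    def test_field_change_rule(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 1e-13, size=(4, 60000))
        ramp = np.linspace(0, 200e-12, 5000)
        data[2, 25000:30000] += ramp          # 200 pT ramp inside chunk 5
        rec = _recording(data)
        bad = detect_artefact_segments(rec)
        flagged = [(s, e) for s, e, r in bad if "field_change" in r]
        assert (25.0, 30.0) in flagged

    def test_step_rule_across_channels(self):
        rng = np.random.default_rng(9)
        data = rng.normal(0, 1e-13, size=(6, 60000))
        data[:, 42000:] += 150e-12            # simultaneous step on all channels
        rec = _recording(data)
        bad = detect_artefact_segments(rec)
        reasons = {r for s, e, r in bad if s <= 42.0 < e}
        assert any("step" in r or "field_change" in r for r in reasons)
        step_only = detect_artefact_segments(
            _recording(data), range_thresh=1.0)  # disable rule (i)
        assert any("step" in r for _, _, r in step_only)

    def test_hf_noise_rule(self):
        rng = np.random.default_rng(10)
        data = rng.normal(0, 1e-14, size=(4, 60000))
        t = np.arange(5000) / 1000.0
        data[1, 30000:35000] += 5e-13 * np.sin(2 * np.pi * 180.0 * t)
        rec = _recording(data)
        bad = detect_artefact_segments(rec, range_thresh=1.0)
        assert any("hf_noise" in r and s == 30.0 for s, e, r in bad)


# --------------------------------------------------------------------------- #
# Epoching
# --------------------------------------------------------------------------- #

class TestEpoching:
    def _rec_with_events(self, n=20000, onsets=(1000, 2000, 3000)):
        rng = np.random.default_rng(11)
        return _recording(rng.normal(size=(3, n)),
                          events=[("tone", s) for s in onsets])

    def test_epoch_length_700_samples(self):
        ep = epoch_and_baseline(self._rec_with_events())
        assert ep.data.shape[2] == 700
        assert ep.times[0] == pytest.approx(-0.2)

    def test_baseline_mean_zero(self):
        ep = epoch_and_baseline(self._rec_with_events())
        sel = (ep.times >= -0.1) & (ep.times < 0.0)
        means = ep.data[:, :, sel].mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-15)

    def test_trial_overlapping_bad_segment_rejected(self):
        rec = self._rec_with_events()
        rec.bad_segments = [(0.9, 1.1, "field_change")]
        ep = epoch_and_baseline(rec)
        assert ep.n_trials == 2
        row = ep.provenance[ep.provenance.onset_sample == 1000].iloc[0]
        assert not row.kept and row.reason == "bad_segment"

    def test_edge_event_dropped(self):
        rec = self._rec_with_events(onsets=(100, 2000, 19900))
        ep = epoch_and_baseline(rec)
        assert ep.n_trials == 1
        assert (ep.provenance[~ep.provenance.kept].reason == "edge").all()


class TestEqualizeTrials:
    def _epochs(self, n_trials, seed=0):
        rng = np.random.default_rng(seed)
        rec = _recording(rng.normal(size=(2, 1000 * (n_trials + 2))),
                         events=[("tone", 1000 * (i + 1)) for i in range(n_trials)])
        return epoch_and_baseline(rec)

    def test_subsample_to_525(self):
        eps = equalize_trials([self._epochs(560)], n=525, seed=1)
        assert eps[0].n_trials == 525

    def test_identity_when_exact(self):
        ep = self._epochs(30)
        out = equalize_trials([ep], n=30, seed=1)[0]
        np.testing.assert_array_equal(out.onsets, ep.onsets)

    def test_seed_determinism(self):
        a = equalize_trials([self._epochs(60)], n=40, seed=5)[0]
        b = equalize_trials([self._epochs(60)], n=40, seed=5)[0]
        np.testing.assert_array_equal(a.onsets, b.onsets)

    def test_shortfall_error(self):
        with pytest.raises(ValueError, match="good trials"):
            equalize_trials([self._epochs(10)], n=525, seed=0)


# --------------------------------------------------------------------------- #
# Cascade properties
# --------------------------------------------------------------------------- #

def test_stages_commute_with_positive_scaling(array):
    """Every linear stage commutes with channel-wise positive scaling."""
    rng = np.random.default_rng(12)
    data = rng.normal(size=(90, 8000)) * 1e-12
    rec = _array_recording(array, data)
    scale = 3.7
    X = rng.normal(size=(6, 8000))
    for fn in (lambda r: regress_motion(r, X)[0],
               lambda r: homogeneous_field_correction(r)[0],
               lambda r: spectral_interpolation(r, targets=[50.0]),
               lambda r: filter_zero_phase(r, "highpass", 2.0, 5)):
        out1 = fn(rec).data * scale
        out2 = fn(_array_recording(array, data * scale)).data
        np.testing.assert_allclose(out1, out2, rtol=1e-9, atol=1e-20)


def test_history_records_full_parameterisation(array):
    rng = np.random.default_rng(13)
    rec = _array_recording(array, rng.normal(size=(90, 6000)) * 1e-12)
    out = filter_zero_phase(rec, "highpass", 2.0, 5)
    out = spectral_interpolation(out, targets=[50.0])
    out, _ = homogeneous_field_correction(out)
    stages = [h["stage"] for h in out.history]
    assert stages == ["filter_highpass", "spectral_interpolation", "hfc"]
    # replaying the recorded history from the raw data is bit-identical
    replay = rec
    for h in out.history:
        if h["stage"] == "filter_highpass":
            replay = filter_zero_phase(replay, "highpass", h["cutoff"], h["order"])
        elif h["stage"] == "spectral_interpolation":
            replay = spectral_interpolation(replay, targets=h["targets"],
                                            halfwidth=h["halfwidth"],
                                            neighbour=h["neighbour"])
        elif h["stage"] == "hfc":
            replay, _ = homogeneous_field_correction(replay)
    np.testing.assert_array_equal(replay.data, out.data)
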