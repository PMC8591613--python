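"""Sensor-level interference suppression and epoching.

The cascade, in pipeline order: downsample to 1000 Hz; windowed multiple
linear regression of the data on the six rigid-body pose regressors
(10 s windows, 50% overlap, cosine cross-fade recombination); homogeneous
field correction (per-sample removal of the best-fitting spatially uniform
field using the channel orientations); spectral interpolation of mains
harmonics and camera-system lines (50 Hz harmonics, 120 Hz, 83 Hz);
zero-phase 2 Hz high-pass (order 5); automated artefact-segment detection
in 5 s chunks (100 pT field-change rule plus high-frequency and step
rules); zero-phase 40 Hz low-pass (order 6); epoching to (-0.2, 0.5) s
with (-0.1, 0) s baseline.

Motion regression is switchable per condition: on still recordings the
pose regressors carry mostly tracking noise, and regressing them can inject
rather than remove interference, so still presets run with it disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochedData, Recording


# --------------------------------------------------------------------------- #
# Downsampling
# --------------------------------------------------------------------------- #

def downsample(rec: Recording, target: float = 1000.0) -> Recording:
    """Anti-alias low-pass and decimate to ``target`` Hz; events are remapped
    to the nearest new sample."""
    if target > rec.rate:
        raise ValueError("upsampling is not supported")
    if target == rec.rate:
        return rec.with_data(rec.data, "downsample", target=target)
    from fractions import Fraction
    frac = Fraction(target / rec.rate).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    out = rec.with_data(data, "downsample", target=target)
    out.rate = target
    out.events = [(lbl, int(round(s * target / rec.rate))) for lbl, s in rec.events]
    out.bad_segments = list(rec.bad_segments)
    return out


# --------------------------------------------------------------------------- #
# Windowed motion regression
# --------------------------------------------------------------------------- #

def _window_starts(n: int, win: int, hop: int) -> list[int]:
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if not starts:
        return [0]
    if starts[-1] + win < n:
        starts.append(n - win)
    return starts


def regress_motion(rec: Recording, regressors: np.ndarray, window_s: float = 10.0,
                   overlap_frac: float = 0.5) -> tuple[Recording, pd.DataFrame]:
    """Windowed ordinary least squares of every channel on the pose.

    Per overlapping window each channel is regressed on
    ``[intercept, X, Y, Z, pitch, yaw, roll]`` and the fitted part
    subtracted; windows are recombined with a cosine-tapered cross-fade
    normalised to unit total weight so the residual is continuous.  A
    rank-deficient window (e.g. a still run, where a pose regressor is
    constant) keeps its motion betas at zero - intercept only - and is
    flagged, preventing tracking noise from being injected into still data.

    Returns the residual recording and a per-window table with R^2.
    """
    regressors = np.asarray(regressors, float)
    if regressors.shape[1] != rec.n_samples:
        raise ValueError("regressors must be aligned to the recording grid")
    n = rec.n_samples
    win = min(n, int(round(window_s * rec.rate)))
    hop = max(1, int(round(win * (1.0 - overlap_frac))))
    starts = _window_starts(n, win, hop)
    taper = np.hanning(win) if len(starts) > 1 else np.ones(win)
    taper = np.maximum(taper, 1e-6)

    fitted = np.zeros_like(rec.data)
    weight = np.zeros(n)
    rows = []
    for s in starts:
        e = s + win
        Xw = regressors[:, s:e].T                      # (win, 6)
        keep = Xw.std(axis=0) > 1e-12 * (np.abs(Xw).max(axis=0) + 1e-300)
        deficient = not keep.all()
        A = np.column_stack([np.ones(win), Xw[:, keep]])
        Y = rec.data[:, s:e].T                         # (win, n_ch)
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
        pred = A @ beta
        resid = Y - pred
        ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        ss_res = (resid ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        fitted[:, s:e] += (pred.T * taper[None, :])
        weight[s:e] += taper
        rows.append({"start_s": s / rec.rate, "end_s": e / rec.rate,
                     "rank_deficient": deficient,
                     "mean_r2": float(np.nanmean(r2))})
    fitted /= weight[None, :]
    out = rec.with_data(rec.data - fitted, "regress_motion",
                        window_s=window_s, overlap_frac=overlap_frac)
    return out, pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Homogeneous field correction
# --------------------------------------------------------------------------- #

def homogeneous_field_correction(rec: Recording) -> tuple[Recording, np.ndarray]:
    """Remove the best-fitting spatially uniform field per sample.

    The model matrix A (channels x 3) holds the channel unit sensitive
    axes; the uniform field u(t) = pinv(A) y(t) is estimated and A u(t)
    subtracted sample by sample.  Returns the cleaned recording and the
    removed 3 x n uniform-field series (Tesla).
    """
    A = rec.channel_axes
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("channel axes span fewer than 3 directions: "
                         "cannot estimate a uniform field")
    pinvA = np.linalg.pinv(A)
    u = pinvA @ rec.data                       # (3, n)
    cleaned = rec.data - A @ u
    out = rec.with_data(cleaned, "hfc")
    return out, u


# --------------------------------------------------------------------------- #
# Spectral interpolation
# --------------------------------------------------------------------------- #

def default_spectral_targets(rate: float) -> list[float]:
    """Mains harmonics (50, 100, ... up to 500 Hz) plus the 120 Hz camera
    line and its 83 Hz alias, restricted to below Nyquist."""
    nyq = rate / 2.0
    targets = [f for f in np.arange(50.0, 501.0, 50.0) if f < nyq]
    targets += [f for f in (120.0, 83.0) if f < nyq]
    return targets


def spectral_interpolation(rec: Recording, targets=None, halfwidth: float = 0.5,
                           neighbour: float = 1.0) -> Recording:
    """Replace narrowband spectral peaks by locally interpolated amplitude.

    Per channel the real FFT amplitude in ``target +/- halfwidth`` is
    replaced by the mean amplitude of the flanking bands
    (``+/- halfwidth .. +/- (halfwidth + neighbour)``) while phases are
    kept, avoiding the ringing of time-domain notch filters.
    """
    if targets is None:
        targets = default_spectral_targets(rec.rate)
    nyq = rec.rate / 2.0
    if any(t >= nyq for t in targets):
        raise ValueError("spectral targets must lie below Nyquist")
    n = rec.n_samples
    Y = np.fft.rfft(rec.data, axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / rec.rate)
    amp = np.abs(Y)
    for t in sorted(targets):
        band = np.abs(freqs - t) <= halfwidth
        flank = (np.abs(freqs - t) > halfwidth) & (np.abs(freqs - t) <= halfwidth + neighbour)
        if not band.any() or not flank.any():
            continue
        target_amp = amp[:, flank].mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(amp[:, band] > 0, target_amp / amp[:, band], 0.0)
        Y[:, band] *= scale
    data = np.fft.irfft(Y, n=n, axis=1)
    return rec.with_data(data, "spectral_interpolation", targets=list(targets),
                         halfwidth=halfwidth, neighbour=neighbour)


# --------------------------------------------------------------------------- #
# Zero-phase filtering
# --------------------------------------------------------------------------- #

def filter_zero_phase(rec: Recording, kind: str, cutoff: float, order: int) -> Recording:
    """Forward-backward Butterworth high- or low-pass (no phase shift)."""
    nyq = rec.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    btype = {"highpass": "highpass", "lowpass": "lowpass"}[kind]
    sos = signal.butter(order, cutoff, btype=btype, fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(data, f"filter_{kind}", cutoff=cutoff, order=order)


# --------------------------------------------------------------------------- #
# Artefact-segment detection
# --------------------------------------------------------------------------- #

def _robust_z(values: np.ndarray, axis=0) -> np.ndarray:
    med = np.median(values, axis=axis, keepdims=True)
    mad = np.median(np.abs(values - med), axis=axis, keepdims=True)
    scale = 1.4826 * mad
    scale = np.where(scale > 0, scale, np.inf)
    return (values - med) / scale


def detect_artefact_segments(rec: Recording, chunk_s: float = 5.0,
                             range_thresh: float = 100e-12,
                             hf_band: tuple | None = None, hf_z: float = 5.0,
                             step_z: float = 5.0) -> list:
    """Automated stand-in for visual artefact inspection in 5 s chunks.

    A chunk is flagged when (i) any channel's field change (max - min over
    the chunk) exceeds ``range_thresh`` (default 100 pT); (ii) any
    channel's high-band envelope is a > ``hf_z`` robust z-score outlier
    against that channel's record median (intermittent high-frequency
    noise); or (iii) the chunk's largest cross-channel median absolute
    first difference is a > ``step_z`` outlier (simultaneous steps across
    channels).  Returns (start_s, end_s, reason) tuples and records them on
    the recording.
    """
    n = rec.n_samples
    chunk = int(round(chunk_s * rec.rate))
    n_chunks = max(1, n // chunk)
    nyq = rec.rate / 2.0
    if hf_band is None:
        hf_band = (100.0, nyq)
    hf_lo, hf_hi = min(hf_band[0], 0.8 * nyq), min(hf_band[1], 0.99 * nyq)
    if hf_hi > hf_lo:
        sos = signal.butter(4, [hf_lo, hf_hi], btype="bandpass", fs=rec.rate,
                            output="sos")
        hf_env = np.abs(signal.sosfiltfilt(sos, rec.data, axis=1))
    else:
        hf_env = np.zeros_like(rec.data)
    step_series = np.median(np.abs(np.diff(rec.data, axis=1)), axis=0)

    chunk_range = np.empty((n_chunks, rec.n_channels))
    chunk_hf = np.empty((n_chunks, rec.n_channels))
    chunk_step = np.empty(n_chunks)
    for c in range(n_chunks):
        a, b = c * chunk, min(n, (c + 1) * chunk)
        seg = rec.data[:, a:b]
        chunk_range[c] = seg.max(axis=1) - seg.min(axis=1)
        chunk_hf[c] = hf_env[:, a:b].mean(axis=1)
        chunk_step[c] = step_series[a:max(a + 1, b - 1)].max()

    z_hf = _robust_z(chunk_hf, axis=0)
    z_step = _robust_z(chunk_step, axis=0)
    bad = []
    for c in range(n_chunks):
        reasons = []
        if (chunk_range[c] > range_thresh).any():
            reasons.append("field_change")
        if (z_hf[c] > hf_z).any():
            reasons.append("hf_noise")
        if z_step[c] > step_z:
            reasons.append("step")
        if reasons:
            bad.append((c * chunk / rec.rate, min(n, (c + 1) * chunk) / rec.rate,
                        "+".join(reasons)))
    rec.bad_segments = list(rec.bad_segments) + bad
    return bad


# --------------------------------------------------------------------------- #
# Epoching
# --------------------------------------------------------------------------- #

def epoch_and_baseline(rec: Recording, events=None, window=(-0.2, 0.5),
                       baseline=(-0.1, 0.0)) -> EpochedData:
    """Epoch around stimulus onsets and baseline-correct.

    Epoch windows are half-open ``[onset + window[0], onset + window[1])``.
    Trials overlapping any bad segment, or too close to the record edge,
    are dropped with a reason in the provenance table.  The per-channel
    mean of the ``baseline`` interval (default the 0.1 s before onset) is
    subtracted from every kept trial.
    """
    if events is None:
        events = rec.events
    pre = int(round(-window[0] * rec.rate))
    post = int(round(window[1] * rec.rate))
    n_samp = pre + post
    times = (np.arange(n_samp) - pre) / rec.rate
    b0 = pre + int(round(baseline[0] * rec.rate))
    b1 = pre + int(round(baseline[1] * rec.rate))

    kept, rows = [], []
    for lbl, s in events:
        t0 = (s - pre) / rec.rate
        t1 = (s + post) / rec.rate
        if s - pre < 0 or s + post > rec.n_samples:
            rows.append({"onset_sample": s, "kept": False, "reason": "edge"})
            continue
        overlaps = any(t0 < seg_end and t1 > seg_start
                       for seg_start, seg_end, _ in rec.bad_segments)
        if overlaps:
            rows.append({"onset_sample": s, "kept": False, "reason": "bad_segment"})
            continue
        kept.append(s)
        rows.append({"onset_sample": s, "kept": True, "reason": ""})

    data = np.empty((len(kept), rec.n_channels, n_samp))
    for i, s in enumerate(kept):
        trial = rec.data[:, s - pre:s + post]
        data[i] = trial - trial[:, b0:b1].mean(axis=1, keepdims=True)
    return EpochedData(data, times, rec.rate, np.asarray(kept, int),
                       window=window, baseline=baseline,
                       provenance=pd.DataFrame(rows),
                       channel_names=rec.channel_names,
                       channel_positions=rec.channel_positions,
                       channel_axes=rec.channel_axes)


def equalize_trials(epochs_list: list[EpochedData], n: int = 525,
                    seed: int = 0) -> list[EpochedData]:
    """Uniform random subsample of ``n`` good trials per condition, without
    replacement, deterministic per seed; ensures equitable power across
    conditions.  When a condition already has exactly ``n`` trials it is
    returned with its ordering intact."""
    rng = np.random.default_rng(seed)
    out = []
    for ep in epochs_list:
        if ep.n_trials < n:
            raise ValueError(f"condition has only {ep.n_trials} good trials, "
                             f"need {n}")
        if ep.n_trials == n:
            out.append(ep)
            continue
        idx = np.sort(rng.choice(ep.n_trials, size=n, replace=False))
        out.append(ep.subset(idx))
    return out


# --------------------------------------------------------------------------- #
# Stage diagnostics
# --------------------------------------------------------------------------- #

def per_trial_max_field_change(rec: Recording, onsets_s: np.ndarray,
                               trial_s: float = 0.5) -> np.ndarray:
    """Per trial: the largest field change (max - min over the trial window)
    across channels, in Tesla.  The stage-wise mean of this quantity is the
    main artefact-magnitude diagnostic."""
    vals = []
    for t in np.asarray(onsets_s, float):
        a = int(round(t * rec.rate))
        b = min(rec.n_samples, a + int(round(trial_s * rec.rate)))
        if b - a < 2 or a < 0:
            continue
        seg = rec.data[:, a:b]
        vals.append((seg.max(axis=1) - seg.min(axis=1)).max())
    return np.asarray(vals)
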