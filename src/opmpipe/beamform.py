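"""LCMV beamforming with symmetric dipole pairs, NAI mapping, ROI virtual
channels, pointwise statistics and PSD diagnostics.

Auditory stimulation evokes highly correlated, near-simultaneous activity
in the two auditory cortices; a conventional single-dipole LCMV scan
suppresses such correlated pairs.  The scanning unit here is therefore the
symmetric dipole pair: the unit-gain constraint is imposed jointly on the
6 columns [L(i) | L(mirror(i))], which keeps correlated bilateral sources
visible while preserving the spatial-filtering interference suppression
of the beamformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import eigh as scipy_eigh

from .containers import EpochedData
from .forward import LeadField, SourceGrid


# --------------------------------------------------------------------------- #
# Covariance
# --------------------------------------------------------------------------- #

@dataclass
class Covariance:
    """Sensor covariance from unaveraged single-trial data (Tesla^2)."""

    C: np.ndarray
    window: tuple = (0.0, 0.5)
    n_trials: int = 0
    n_samples: int = 0
    rank_deficient: bool = False


def covariance(epochs: EpochedData, window=(0.0, 0.5),
               demean: bool = True) -> Covariance:
    """Covariance over the post-stimulus window.

    C = mean over trials and window samples of the outer product of the
    channel vectors, demeaned per trial over the window by default.
    ``demean=False`` keeps the trial-locked evoked mean in the second
    moment, which is what the narrow active-window power of the NAI needs
    (the trials are already baseline-corrected, and demeaning a window
    narrower than the evoked deflection would subtract most of it).
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    sel = (epochs.times >= window[0]) & (epochs.times < window[1])
    if not sel.any():
        raise ValueError("covariance window lies outside the epoch")
    X = epochs.data[:, :, sel]                       # (trials, ch, samp)
    if demean:
        X = X - X.mean(axis=2, keepdims=True)
    n_tr, n_ch, n_s = X.shape
    flat = X.transpose(1, 0, 2).reshape(n_ch, -1)
    C = flat @ flat.T / flat.shape[1]
    C = 0.5 * (C + C.T)
    return Covariance(C, window, n_tr, n_s,
                      rank_deficient=(n_tr * n_s < n_ch))


# --------------------------------------------------------------------------- #
# Weights
# --------------------------------------------------------------------------- #

@dataclass
class BeamformerConfig:
    """``lambda_percent`` scales the diagonal loading:
    C_reg = C + (lambda_percent / 100) * (trace(C) / n_channels) * I."""

    lambda_percent: float = 0.1
    sweep: list = field(default_factory=list)

    def __post_init__(self):
        if self.lambda_percent < 0:
            raise ValueError("lambda_percent must be non-negative")


def regularized(C: Covariance, cfg: BeamformerConfig) -> np.ndarray:
    n_ch = C.C.shape[0]
    return C.C + (cfg.lambda_percent / 100.0) * (np.trace(C.C) / n_ch) * np.eye(n_ch)


def truncated_inverse(Cr: np.ndarray, rel_tol: float = 1e-4) -> tuple[np.ndarray, float]:
    """Rank-truncated inverse of the regularised covariance.

    Spatial projection stages (homogeneous field correction removes exactly
    3 field components) leave the sensor covariance rank-deficient; a plain
    inverse lets the minimum-variance filter escape into the empty
    subspace, which corrupts source power and noise estimates everywhere.
    Eigendirections below ``rel_tol`` x the largest eigenvalue are
    therefore excluded from the inverse (the filter then lives entirely in
    the data subspace), and the projected-noise reference sigma0^2 is the
    smallest *retained* eigenvalue.

    Returns (C_inv, sigma0_squared).
    """
    vals, vecs = np.linalg.eigh(Cr)
    keep = vals > rel_tol * vals.max()
    inv_vals = np.where(keep, 1.0 / np.where(keep, vals, 1.0), 0.0)
    Ci = (vecs * inv_vals) @ vecs.T
    sigma0 = float(vals[keep].min())
    return Ci, sigma0


def lcmv_weights(C: Covariance, L: np.ndarray,
                 cfg: BeamformerConfig | None = None,
                 C_reg_inv: np.ndarray | None = None,
                 info: dict | None = None) -> np.ndarray:
    """LCMV spatial filter W = (L' Cr^-1 L)^-1 L' Cr^-1 (k x channels).

    Satisfies the unit-gain constraint W L = I_k; a singular k x k Gram
    matrix falls back to the pseudo-inverse, flagged via
    ``info["pinv_used"]`` when a dict is supplied.  ``C_reg_inv`` may be
    passed in to amortise the channel-space inverse across grid points.
    """
    if not np.all(np.isfinite(C.C)):
        raise ValueError("covariance contains non-finite entries")
    if C_reg_inv is None:
        Cr = regularized(C, cfg if cfg is not None else BeamformerConfig())
        C_reg_inv, _ = truncated_inverse(Cr)
    CiL = C_reg_inv @ L                          # (ch, k)
    G = L.T @ CiL                                # (k, k)
    pinv_used = False
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        W = np.linalg.pinv(G) @ CiL.T
        pinv_used = True
    else:
        W = np.linalg.solve(G, CiL.T)
    if info is not None:
        info["pinv_used"] = pinv_used
    return W


# --------------------------------------------------------------------------- #
# NAI map
# --------------------------------------------------------------------------- #

@dataclass
class SourceMap:
    """Neural activity index per grid point for a post-stimulus window."""

    grid: SourceGrid
    nai: np.ndarray
    window: tuple = (0.08, 0.12)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.grid.points[:, 0],
                             "y": self.grid.points[:, 1],
                             "z": self.grid.points[:, 2],
                             "NAI": self.nai})

    def peak_point(self) -> np.ndarray:
        return self.grid.points[int(np.argmax(self.nai))]

    def focality(self, threshold: float = 0.75) -> float:
        """Fraction of grid points at or above ``threshold`` x max NAI
        (larger = less focal)."""
        return float(np.mean(self.nai >= threshold * self.nai.max()))


def nai_map(epochs: EpochedData, lf: LeadField, cfg: BeamformerConfig,
            window=(0.08, 0.12), cov_window=(0.0, 0.5),
            paired: bool = True, reduce_rank: int | None = 2,
            use_average: bool = True, combine: str = "max") -> SourceMap:
    """Whole-volume neural activity index with symmetric-pair scanning.

    Weights come from the covariance of the unaveraged single-trial data
    over ``cov_window``.  Per pair: source power = trace(W C_win W'), with
    C_win the second moment of the evoked (trial-averaged,
    baseline-corrected) response over the stated window - averaging
    attenuates everything that is not trial-locked by 1/n_trials, so
    residual movement artefact does not masquerade as deep sources
    (``use_average=False`` falls back to the unaveraged window
    covariance).  The projected-noise reference is sigma0^2 trace(W W')
    with sigma0^2 the smallest retained eigenvalue of the regularised
    covariance.

    ``combine`` sets how the k filter orientations are collapsed:
    ``"max"`` (default) is the dominant-orientation index, the largest
    generalised eigenvalue of (W C_win W', sigma0^2 W W'), which stops
    weak moment orientations from diluting the contrast; ``"trace"`` is
    the plain ratio trace(W C_win W') / (sigma0^2 trace(W W')).  Both
    members of a pair receive the pair's NAI, so the map is
    mirror-symmetric under paired scanning.
    """
    C = covariance(epochs, cov_window)
    if use_average:
        sel = (epochs.times >= window[0]) & (epochs.times < window[1])
        if not sel.any():
            raise ValueError("NAI window lies outside the epoch")
        M = epochs.average()[:, sel]
        Cw = Covariance(M @ M.T / sel.sum(), window, epochs.n_trials, int(sel.sum()))
    else:
        Cw = covariance(epochs, window, demean=False)
    Cr = regularized(C, cfg)
    Ci, sigma0 = truncated_inverse(Cr)
    grid = lf.grid
    nai = np.full(grid.n_points, np.nan)
    for i in range(grid.n_points):
        j = grid.pair_index[i]
        if paired and j < i:
            continue
        L = (lf.pair_lead_field(i, reduce_rank) if paired
             else lf.point_lead_field(i, reduce_rank))
        W = lcmv_weights(C, L, cfg, C_reg_inv=Ci)
        A = W @ Cw.C @ W.T
        B = sigma0 * (W @ W.T)
        trB = float(np.trace(B))
        # a magnetically silent point (e.g. the sphere centre) has W = 0
        if trB <= 0 or not np.all(np.isfinite(B)):
            val = 0.0
        elif combine == "trace":
            val = float(np.trace(A)) / trB
        else:
            jitter = 1e-12 * trB / B.shape[0] * np.eye(B.shape[0])
            try:
                val = float(scipy_eigh(A, B + jitter, eigvals_only=True)[-1])
            except np.linalg.LinAlgError:
                val = float(np.trace(A)) / trB
        nai[i] = val
        if paired:
            nai[j] = val
    return SourceMap(grid, nai, window)


# --------------------------------------------------------------------------- #
# ROI virtual channel
# --------------------------------------------------------------------------- #

@dataclass
class VirtualChannel:
    """Source-space trial series from an ROI spatial filter (arbitrary
    amplitude units; deliberately un-normalised)."""

    trials: np.ndarray        # (n_trials, n_samples)
    times: np.ndarray
    rate: float
    weights: np.ndarray       # (n_channels,)

    @property
    def average(self) -> np.ndarray:
        return self.trials.mean(axis=0)

    def pointwise_t(self):
        return pointwise_t(self)


def roi_virtual_channel(roi_indices, lf: LeadField, C: Covariance,
                        epochs: EpochedData, cfg: BeamformerConfig | None = None,
                        paired: bool = True, reduce_rank: int | None = 2,
                        polarity_window=(0.08, 0.12),
                        pca_on: str = "FCF") -> VirtualChannel:
    """Single ROI time-course by PCA over the concatenated grid-point filters.

    All LCMV filters of the ROI grid points are stacked row-wise into F;
    the principal eigenvector v of M = F C F' (or of F C when
    ``pca_on="FC"``) defines the spatial filter w = v' F, which is applied
    to the single-trial sensor data.  Polarity is fixed so the average
    series peaks positive inside ``polarity_window``, making the output
    invariant to a global sensor sign flip.
    """
    roi_indices = np.atleast_1d(np.asarray(roi_indices, int))
    if roi_indices.size == 0:
        raise ValueError("ROI is empty")
    if cfg is None:
        cfg = BeamformerConfig()
    if not np.any(np.abs(C.C) > 0):
        raise ValueError("zero covariance")
    Ci, _ = truncated_inverse(regularized(C, cfg))
    rows = []
    for i in roi_indices:
        L = (lf.pair_lead_field(i, reduce_rank) if paired
             else lf.point_lead_field(i, reduce_rank))
        rows.append(lcmv_weights(C, L, cfg, C_reg_inv=Ci))
    F = np.vstack(rows)                              # (k_total, ch)
    if pca_on == "FCF":
        M = F @ C.C @ F.T
        vals, vecs = np.linalg.eigh(M)
        v = vecs[:, -1]
    elif pca_on == "FC":
        # PCA of the non-symmetric F C: principal left singular vector
        U, s, Vt = np.linalg.svd(F @ C.C, full_matrices=False)
        v = U[:, 0]
    else:
        raise ValueError("pca_on must be 'FCF' or 'FC'")
    w = v @ F                                        # (ch,)
    trials = np.einsum("c,tcs->ts", w, epochs.data)
    avg = trials.mean(axis=0)
    sel = (epochs.times >= polarity_window[0]) & (epochs.times < polarity_window[1])
    if sel.any() and avg[sel].max() < -avg[sel].min():
        w = -w
        trials = -trials
        avg = -avg
    # reporting convention: unit M100 peak.  The PCA eigenvector scale is
    # arbitrary and differs between conditions; scaling w so the average
    # series peaks at 1 inside the polarity window makes amplitudes and
    # PSDs comparable across runs.  t statistics and correlations are
    # invariant under this scaling.
    peak = np.abs(avg[sel]).max() if sel.any() else np.abs(avg).max()
    if peak > 0:
        w = w / peak
        trials = trials / peak
    return VirtualChannel(trials, epochs.times.copy(), epochs.rate, w)


def pointwise_t(vc: VirtualChannel):
    """One-sample t across trials at each time point; df = n - 1.

    Samples with zero variance across trials report signed infinity and are
    flagged in the returned mask.
    """
    n = vc.trials.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    mean = vc.trials.mean(axis=0)
    sd = vc.trials.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    return t, n - 1, zero_var


# --------------------------------------------------------------------------- #
# PSD diagnostics
# --------------------------------------------------------------------------- #

def psd(series: np.ndarray, rate: float, band=(2.0, 10.0),
        segment_s: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Averaged-periodogram (Welch) PSD restricted to a reporting band.

    Hann-tapered segments of ``segment_s`` seconds at 50% overlap; units
    Tesla^2/Hz for sensor series.
    """
    series = np.asarray(series, float)
    if band[1] > rate / 2.0:
        raise ValueError("band extends above Nyquist")
    nper = min(series.shape[-1], int(round(segment_s * rate)))
    if series.shape[-1] <= nper // 2:
        raise ValueError("series shorter than one segment")
    freqs, power = signal.welch(series, fs=rate, nperseg=nper,
                                noverlap=nper // 2, window="hann", axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return freqs[sel], power[..., sel]


def band_power_db(series: np.ndarray, rate: float, band=(2.0, 10.0)) -> float:
    """Mean in-band PSD in dB (10 log10), a scalar interference summary."""
    _, p = psd(series, rate, band)
    return float(10.0 * np.log10(np.mean(p)))


def masked_band_power_db(series: np.ndarray, rate: float, bad_segments,
                         band=(2.0, 10.0), segment_s: float = 2.0) -> float:
    """In-band PSD excluding artefact-flagged stretches.

    ``bad_segments`` is the recording's (start_s, end_s, reason) list; the
    PSD is the duration-weighted average of Welch estimates over the good
    stretches long enough to hold at least one segment.  This matches how
    interference diagnostics treat rejected data: flagged chunks are
    excluded everywhere, not just from epoching.
    """
    series = np.atleast_2d(np.asarray(series, float))
    n = series.shape[-1]
    good = np.ones(n, bool)
    for s, e, *_ in bad_segments:
        good[int(s * rate):int(np.ceil(e * rate))] = False
    edges = np.flatnonzero(np.diff(np.concatenate([[0], good.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]
    nper = int(round(segment_s * rate))
    powers, weights = [], []
    for a, b in zip(starts, ends):
        if b - a < nper:
            continue
        _, p = psd(series[..., a:b], rate, band, segment_s)
        powers.append(np.mean(p))
        weights.append(b - a)
    if not powers:
        raise ValueError("no good stretch long enough for one PSD segment")
    return float(10.0 * np.log10(np.average(powers, weights=weights)))
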