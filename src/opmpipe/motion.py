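"""Motion-capture processing: gap interpolation, filtering, rigid-body
solving, kinematic summaries and synchronisation with the magnetometer data.

The processing order follows optical-tracking practice for head tracking at
120 Hz: fill occlusion gaps (pattern-based where >= 3 markers of the rigid
body are visible, cubic spline for short remaining gaps up to 100 samples,
then pattern-based again), low-pass the marker trajectories at 2 Hz with a
4th-order zero-phase Butterworth to remove marker vibration, then solve the
6-DOF rigid body per frame by orthogonal Procrustes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .containers import MarkerTrajectories, Recording, RigidBodyTrajectory
from .transforms import euler_to_matrix, is_collinear, kabsch, matrix_to_euler


# --------------------------------------------------------------------------- #
# Gap interpolation
# --------------------------------------------------------------------------- #

@dataclass
class GapReport:
    """Frames that could not be filled, as (marker, start_frame, end_frame)."""

    unresolved: list = field(default_factory=list)

    @property
    def n_unresolved_frames(self) -> int:
        return sum(e - s for _, s, e in self.unresolved)


def _pattern_fill(pos: np.ndarray, template: np.ndarray) -> None:
    """In-place: for frames with >= 3 visible markers, solve the pose from
    the visible subset and place occluded markers from the rigid template."""
    missing = np.isnan(pos).any(axis=2)
    frames = np.nonzero(missing.any(axis=1))[0]
    for f in frames:
        vis = ~missing[f]
        if vis.sum() < 3 or is_collinear(template[vis]):
            continue
        R, t = kabsch(template[vis], pos[f, vis])
        pos[f, ~vis] = template[~vis] @ R.T + t


def _gap_runs(mask: np.ndarray):
    """Yield (start, end) index pairs of consecutive-True runs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return
    splits = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    yield from zip(starts, ends)


def interpolate_gaps(markers: MarkerTrajectories, template: np.ndarray,
                     max_spline_gap: int = 100,
                     spline_flank: int = 24) -> tuple[MarkerTrajectories, GapReport]:
    """Three-pass occlusion filling.

    1. Pattern-based: frames with >= 3 visible markers get their occluded
       markers placed from the rigid template via the pose solved on the
       visible subset.
    2. Cubic spline per marker and coordinate, for remaining gaps of at most
       ``max_spline_gap`` samples with valid data on both sides; the spline
       is fitted to ``spline_flank`` samples flanking each side, so it
       passes exactly through the gap-edge samples.
    3. Pattern-based again (spline output may have restored enough markers).

    Gaps that touch the record boundary are never extrapolated; anything
    still missing is listed in the returned :class:`GapReport`.
    """
    template = np.asarray(template, float)
    out = markers.copy()
    pos = out.positions
    _pattern_fill(pos, template)

    # pass 2: per-marker cubic spline over short interior gaps
    n = pos.shape[0]
    for m in range(pos.shape[1]):
        miss = np.isnan(pos[:, m]).any(axis=1)
        for s, e in _gap_runs(miss):
            if e - s > max_spline_gap or s == 0 or e == n:
                continue
            lo = max(0, s - spline_flank)
            hi = min(n, e + spline_flank)
            support = np.concatenate([np.arange(lo, s), np.arange(e, hi)])
            support = support[~np.isnan(pos[support, m]).any(axis=1)]
            if (support < s).sum() < 2 or (support >= e).sum() < 2:
                continue
            cs = CubicSpline(support, pos[support, m], axis=0)
            pos[s:e, m] = cs(np.arange(s, e))

    _pattern_fill(pos, template)

    report = GapReport()
    miss = np.isnan(pos).any(axis=2)
    for m in range(pos.shape[1]):
        for s, e in _gap_runs(miss[:, m]):
            report.unresolved.append((m, int(s), int(e)))
    return out, report


# --------------------------------------------------------------------------- #
# Filtering
# --------------------------------------------------------------------------- #

def filter_trajectory(obj, cutoff: float = 2.0, order: int = 4):
    """Zero-phase (forward-backward) Butterworth low-pass, applied to every
    marker coordinate or every pose degree of freedom.

    Raises if missing samples remain: interpolate gaps first.
    """
    if isinstance(obj, MarkerTrajectories):
        if np.isnan(obj.positions).any():
            raise ValueError("missing samples remain: interpolate gaps before filtering")
        sos = signal.butter(order, cutoff, btype="low", fs=obj.rate, output="sos")
        out = obj.copy()
        flat = out.positions.reshape(out.n_frames, -1)
        out.positions = signal.sosfiltfilt(sos, flat, axis=0).reshape(out.positions.shape)
        return out
    if isinstance(obj, RigidBodyTrajectory):
        if np.isnan(obj.translation).any() or np.isnan(obj.rotation).any():
            raise ValueError("missing samples remain: interpolate gaps before filtering")
        sos = signal.butter(order, cutoff, btype="low", fs=obj.rate, output="sos")
        out = obj.copy()
        out.translation = signal.sosfiltfilt(sos, out.translation, axis=0)
        out.rotation = signal.sosfiltfilt(sos, out.rotation, axis=0)
        return out
    raise TypeError("expected MarkerTrajectories or RigidBodyTrajectory")


# --------------------------------------------------------------------------- #
# Rigid-body solve
# --------------------------------------------------------------------------- #

def solve_rigid_body(markers: MarkerTrajectories, template: np.ndarray,
                     condition_threshold: float = 1e-6) -> RigidBodyTrajectory:
    """Per-frame least-squares rigid transform from the template to the
    observed markers, with proper rotations enforced and Euler angles
    (pitch, yaw, roll; intrinsic yaw->pitch->roll) unwrapped over time.

    Frames whose visible configuration is near-collinear are flagged via an
    ``ill_conditioned`` attribute on the returned trajectory.
    """
    template = np.asarray(template, float)
    if np.isnan(markers.positions).any():
        raise ValueError("markers contain gaps: interpolate first")
    n = markers.n_frames
    Rs = np.empty((n, 3, 3))
    ts = np.empty((n, 3))
    ill = np.zeros(n, bool)
    centred = template - template.mean(axis=0)
    svals = np.linalg.svd(centred, compute_uv=False)
    base_cond = svals[1] / max(svals[0], 1e-300)
    for f in range(n):
        R, t = kabsch(template, markers.positions[f])
        Rs[f], ts[f] = R, t
        ill[f] = base_cond < condition_threshold
    rot = _continuous_euler(Rs)
    traj = RigidBodyTrajectory(markers.time.copy(), ts, rot, markers.rate)
    traj.ill_conditioned = ill
    return traj


def _continuous_euler(Rs: np.ndarray) -> np.ndarray:
    """Branch-aware continuous Euler angles (pitch, yaw, roll, degrees).

    The principal Tait-Bryan decomposition confines pitch to [-90, 90];
    a head pitching through -90 deg makes the principal yaw and roll flip
    by 180 deg, which a per-angle unwrap turns into runaway excursions.
    Every rotation has a second decomposition (yaw+180, 180-pitch,
    roll+180); per frame the branch (with each angle shifted by multiples
    of 360) closest to the previous frame is kept, so the series follows
    the physical motion across the gimbal."""
    p, y, r = matrix_to_euler(Rs, degrees=True)
    n = p.size
    out = np.empty((n, 3))
    out[0] = p[0], y[0], r[0]
    for f in range(1, n):
        best = None
        for cand in ((p[f], y[f], r[f]),
                     (180.0 - p[f], y[f] + 180.0, r[f] + 180.0)):
            adj = [a - 360.0 * np.round((a - prev) / 360.0)
                   for a, prev in zip(cand, out[f - 1])]
            cost = sum(abs(a - prev) for a, prev in zip(adj, out[f - 1]))
            if best is None or cost < best[0]:
                best = (cost, adj)
        out[f] = best[1]
    return out


def flag_jumps(traj: RigidBodyTrajectory, translation_step: float = 0.05,
               rotation_step: float = 20.0) -> np.ndarray:
    """Automatic stand-in for visual inspection: frames whose pose jumps by
    more than ``translation_step`` metres or ``rotation_step`` degrees from
    the previous frame."""
    dt = np.linalg.norm(np.diff(traj.translation, axis=0), axis=1)
    dr = np.abs(np.diff(traj.rotation, axis=0)).max(axis=1)
    flags = np.zeros(traj.n_frames, bool)
    flags[1:] = (dt > translation_step) | (dr > rotation_step)
    return flags


# --------------------------------------------------------------------------- #
# Kinematics
# --------------------------------------------------------------------------- #

@dataclass
class KinematicsSummary:
    """Per-DOF ranges, 50-bin histograms, and per-trial displacement."""

    dof_names: tuple = ("X", "Y", "Z", "pitch", "yaw", "roll")
    dof_range: np.ndarray = None            # (6,) max - min per DOF
    histograms: dict = None                 # name -> (counts, bin_edges)
    trial_distance: np.ndarray = None       # (n_trials,) metres
    mean_trial_distance: float = 0.0
    excluded_windows: list = None

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ranges = pd.DataFrame({"dof": self.dof_names, "range": self.dof_range})
        trials = pd.DataFrame({"trial": np.arange(self.trial_distance.size),
                               "max_distance_m": self.trial_distance})
        return ranges, trials


def kinematics_summary(pose: RigidBodyTrajectory, trial_windows,
                       n_bins: int = 50) -> KinematicsSummary:
    """Summarise head kinematics.

    Per-trial distance is the maximal Euclidean displacement of the
    translation vector relative to the trial's first sample, so still data
    gives exactly zero.  Empty windows are excluded with notice.
    """
    dof = pose.dof_matrix()
    rng_ = dof.max(axis=0) - dof.min(axis=0)
    hists = {}
    for d, name in enumerate(("X", "Y", "Z", "pitch", "yaw", "roll")):
        counts, edges = np.histogram(dof[:, d], bins=n_bins)
        hists[name] = (counts, edges)
    distances = []
    excluded = []
    for (t0, t1) in trial_windows:
        sel = (pose.time >= t0) & (pose.time < t1)
        if not sel.any():
            excluded.append((t0, t1))
            continue
        tr = pose.translation[sel]
        distances.append(np.linalg.norm(tr - tr[0], axis=1).max())
    distances = np.asarray(distances)
    return KinematicsSummary(
        dof_range=rng_, histograms=hists, trial_distance=distances,
        mean_trial_distance=float(distances.mean()) if distances.size else 0.0,
        excluded_windows=excluded)


def trial_windows_from_events(onsets_s: np.ndarray, length: float = 0.5):
    return [(float(t), float(t) + length) for t in np.asarray(onsets_s, float)]


# --------------------------------------------------------------------------- #
# Synchronisation
# --------------------------------------------------------------------------- #

def synchronize(pose: RigidBodyTrajectory, rec: Recording) -> np.ndarray:
    """Up-sample the 6-DOF pose onto the recording's sample grid by linear
    interpolation; returns the 6 x n_samples regressor matrix ordered
    X, Y, Z, pitch, yaw, roll."""
    t_rec = rec.times
    if t_rec[0] > pose.time[-1] or t_rec[-1] < pose.time[0]:
        raise ValueError("pose and recording time ranges do not overlap")
    dof = pose.dof_matrix()
    out = np.empty((6, t_rec.size))
    for d in range(6):
        out[d] = np.interp(t_rec, pose.time, dof[:, d])
    return out
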