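"""Ground-truth-annotated simulation of wearable-magnetometer recordings.

Emulates a 45-sensor dual-axis OPM array (90 channels) worn during large
continuous head movement inside a shielded room with a remnant static field
of nano-Tesla scale.  The measured signal per channel is

    y_c(t) = a_c(t) . B_room(p_c(t)) + neural_c(t) + line(t) + white noise

where ``p_c(t)`` and ``a_c(t)`` are the channel position and sensitive axis
transported by the head pose (sensors move with the head), the room field
is affine in position (constant gradient tensor), and the neural term is
the motion-invariant forward projection of trial-locked dipole sources in
the head frame.

The remnant field of a real shielded room is nonlinear in position; the
affine model is the minimal one that produces motion artefacts of the right
magnitude and leaves the regression stage partially - not perfectly -
effective when rotations are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import MarkerTrajectories, Recording, RigidBodyTrajectory, SensorArray
from .forward import HeadModel, lead_field
from .transforms import euler_to_matrix, is_collinear


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #

@dataclass
class RoomFieldModel:
    """Affine remnant-field model: B(p) = B0 + G @ (p - origin).

    ``B0`` is the field at the room origin (default magnitude 1.5 nT, the
    scale achievable at the centre of a degaussed shielded room); ``G`` is
    the spatial gradient tensor in Tesla per metre, chosen so that a 10 cm
    displacement along the steepest direction changes the measured field by
    100-1000 pT.
    """

    B0: np.ndarray = field(default_factory=lambda: np.array([1.0e-9, 0.8e-9, 0.6e-9]))
    G: np.ndarray = field(default_factory=lambda: np.diag([3e-9, 2e-9, 3e-9]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.B0 = np.asarray(self.B0, float)
        self.G = np.asarray(self.G, float)
        self.origin = np.asarray(self.origin, float)


def room_field_at(model: RoomFieldModel, position: np.ndarray) -> np.ndarray:
    """Field (Tesla) at ``position``; affine in position, equals B0 at the
    origin.  Accepts a single point (3,) or a stack (..., 3)."""
    position = np.asarray(position, float)
    return model.B0 + (position - model.origin) @ model.G.T


@dataclass
class DipoleSource:
    """Current dipole in the head frame with a trial-locked waveform (A.m)."""

    position: np.ndarray
    moment_orientation: np.ndarray
    waveform: np.ndarray | None = None
    trial_locked: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        m = np.asarray(self.moment_orientation, float)
        n = np.linalg.norm(m)
        if n == 0:
            raise ValueError("moment orientation must be non-zero")
        self.moment_orientation = m / n


@dataclass
class StimulusTrain:
    """Regular tone train: 70 ms tones at a fixed 0.5 s inter-stimulus
    interval (~570 tones in a full-length run)."""

    onsets: np.ndarray
    tone_duration: float = 0.070
    isi: float = 0.5

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, float)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_tones(self) -> int:
        return self.onsets.size

    @classmethod
    def regular(cls, duration: float, isi: float = 0.5, start: float = 1.0,
                margin: float = 0.8, tone_duration: float = 0.070) -> "StimulusTrain":
        onsets = np.arange(start, duration - margin, isi)
        return cls(onsets, tone_duration=tone_duration, isi=isi)


@dataclass
class NoiseModel:
    """Sensor noise: white density (T/sqrt(Hz)), narrowband line components
    (frequency Hz, amplitude Tesla) and the hardware clip limit."""

    white_density: float = 15e-15
    line_components: list = field(default_factory=list)
    clip_limit: float = 5.56e-9
    clip_enabled: bool = False

    def __post_init__(self):
        if self.white_density < 0 or any(a < 0 for _, a in self.line_components):
            raise ValueError("noise densities and amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """What the simulator knows: source waveforms, the artefact it injected,
    the clean neural projection and the event list."""

    source_waveforms: np.ndarray      # (n_sources, n_samples) A.m
    neural: np.ndarray                # (n_ch, n_samples) Tesla
    artefact: np.ndarray              # (n_ch, n_samples) Tesla
    events: list                      # (label, sample)
    evoked_template: np.ndarray       # (n_samples_epoch,) single-trial waveform
    evoked_times: np.ndarray          # matching time axis, s re stimulus


# --------------------------------------------------------------------------- #
# Sensor array
# --------------------------------------------------------------------------- #

def make_sensor_array(n_sensors: int = 45, head_radius: float = 0.09,
                      seed: int = 0, standoff: float = 0.0065) -> SensorArray:
    """Quasi-uniform dual-axis array on the upper scalp hemisphere.

    Sensor cells sit at ``head_radius + standoff`` from the sphere centre on
    a Fibonacci lattice covering polar angles up to ~115 deg (whole-head
    coverage down past the ears).  Per sensor, axis 0 is radial (along the
    position vector) and axis 1 tangential with a seed-deterministic
    azimuthal rotation.
    """
    if head_radius <= 0:
        raise ValueError("head_radius must be positive")
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    rng = np.random.default_rng(seed)
    r = head_radius + standoff
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n_sensors)
    # cos(theta) from 1 (vertex) down to cos(115 deg): upper hemisphere + rim
    cmin = np.cos(np.deg2rad(115.0))
    costheta = 1.0 - (1.0 - cmin) * (i + 0.5) / n_sensors
    sintheta = np.sqrt(1.0 - costheta ** 2)
    phi = golden * i
    # Y is up in the head frame
    positions = r * np.column_stack([sintheta * np.cos(phi), costheta,
                                     sintheta * np.sin(phi)])
    radial = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    # tangential axis: random in-plane direction, deterministic per seed
    axes = np.empty((n_sensors, 2, 3))
    for k in range(n_sensors):
        ref = np.array([1.0, 0.0, 0.0])
        if abs(radial[k] @ ref) > 0.9:
            ref = np.array([0.0, 0.0, 1.0])
        t1 = np.cross(radial[k], ref)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(radial[k], t1)
        ang = rng.uniform(0, 2 * np.pi)
        axes[k, 0] = radial[k]
        axes[k, 1] = np.cos(ang) * t1 + np.sin(ang) * t2
    names = []
    for k in range(n_sensors):
        names += [f"S{k + 1:02d}-RAD", f"S{k + 1:02d}-TAN"]
    return SensorArray(positions, axes, names)


# --------------------------------------------------------------------------- #
# Motion
# --------------------------------------------------------------------------- #

def simulate_motion(duration: float, rate: float = 120.0,
                    translation_range=(1.0, 0.5, 1.15),
                    rotation_range=(110.0, 150.0, 180.0),
                    smoothness_cutoff: float = 1.0,
                    seed: int = 0,
                    constant_velocity=None) -> RigidBodyTrajectory:
    """Band-limited smooth random 6-DOF pose series starting at the identity.

    Each degree of freedom is low-pass-filtered Gaussian noise (zero-phase
    Butterworth at ``smoothness_cutoff``) rescaled so its realised range
    equals the requested range, then shifted to start at zero, giving
    approximately symmetric excursion histograms about the start pose.
    Ranges are (X, Y, Z) metres and (pitch, yaw, roll) degrees; the
    defaults emulate the large-movement condition (head excursions around
    1 m and rotations well above 100 degrees over a run).

    ``constant_velocity`` (3-vector, m/s) overrides the translations with a
    straight constant-speed path, for kinematic calibration checks.
    """
    if rate <= 2 * smoothness_cutoff:
        raise ValueError("rate must exceed twice the smoothness cutoff")
    n = int(round(duration * rate))
    time = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    ranges = np.concatenate([np.asarray(translation_range, float),
                             np.asarray(rotation_range, float)])
    sos = signal.butter(4, smoothness_cutoff, btype="low", fs=rate, output="sos")
    dofs = np.zeros((n, 6))
    for d in range(6):
        x = rng.standard_normal(n)
        if ranges[d] == 0:
            continue
        x = signal.sosfiltfilt(sos, x)
        span = x.max() - x.min()
        if span > 0:
            x = x * (ranges[d] / span)
        dofs[:, d] = x - x[0]
    if constant_velocity is not None:
        v = np.asarray(constant_velocity, float)
        dofs[:, :3] = time[:, None] * v[None, :]
        dofs[:, 3:] = 0.0
    return RigidBodyTrajectory(time, dofs[:, :3], dofs[:, 3:], rate)


def simulate_markers(traj: RigidBodyTrajectory, layout: np.ndarray,
                     occlusion=(0.0, 0.029, 1.24), seed: int = 0) -> MarkerTrajectories:
    """Apply the pose series to a rigid marker layout and occlude samples.

    ``occlusion`` is (fraction, mean_gap_s, max_gap_s); gaps are drawn
    independently per marker with exponentially distributed durations
    (clipped at the maximum) until the requested occluded fraction is
    reached.  The default fraction 0 yields gap-free output.
    """
    layout = np.asarray(layout, float)
    if layout.shape[0] < 3 or is_collinear(layout):
        raise ValueError("marker layout must contain >= 3 non-collinear points")
    frac, mean_s, max_s = occlusion
    n = traj.n_frames
    R = euler_to_matrix(traj.rotation[:, 0], traj.rotation[:, 1], traj.rotation[:, 2])
    pos = np.einsum("nij,mj->nmi", R, layout) + traj.translation[:, None, :]
    if frac > 0:
        rng = np.random.default_rng(seed)
        mean_n = max(1, mean_s * traj.rate)
        max_n = max(1, int(round(max_s * traj.rate)))
        for m in range(layout.shape[0]):
            occluded = np.zeros(n, bool)
            target = frac * n
            attempts = 0
            while occluded.sum() < target and attempts < 50 * n:
                attempts += 1
                length = int(min(max_n, max(1, round(rng.exponential(mean_n)))))
                if length >= n:
                    continue
                start = int(rng.integers(0, n - length))
                if occluded[start:start + length].any():
                    continue
                occluded[start:start + length] = True
            pos[occluded, m, :] = np.nan
    return MarkerTrajectories(traj.time.copy(), pos, traj.rate)


def default_marker_layout(scale: float = 0.12, seed: int = 7) -> np.ndarray:
    """Six-marker rigid layout on the scanner-cast, metres, head frame."""
    rng = np.random.default_rng(seed)
    base = np.array([
        [0.00, 0.11, 0.05],
        [0.06, 0.09, -0.03],
        [-0.06, 0.09, -0.03],
        [0.05, 0.05, 0.09],
        [-0.05, 0.05, 0.09],
        [0.00, 0.12, -0.06],
    ])
    jitter = rng.uniform(-0.005, 0.005, size=base.shape)
    return base * (scale / 0.12) + jitter


# --------------------------------------------------------------------------- #
# Evoked waveform
# --------------------------------------------------------------------------- #

#: default auditory evoked components: (latency s, width s, amplitude A.m, sign)
#: M50 small positive, M100 largest negative, M200 positive.
DEFAULT_EVOKED_COMPONENTS = (
    (0.050, 0.012, 0.35, +1.0),
    (0.100, 0.018, 1.00, -1.0),
    (0.200, 0.030, 0.55, +1.0),
)


def evoked_waveform(t: np.ndarray, components=DEFAULT_EVOKED_COMPONENTS,
                    peak_moment: float = 7e-9) -> np.ndarray:
    """Trial-locked evoked source waveform: a causal sum of Gaussian-windowed
    deflections (A.m) at the canonical ~50/100/200 ms latencies with
    alternating sign and the 100 ms deflection largest.

    ``peak_moment`` scales the relative amplitudes; the default 7 nA.m puts
    the strongest sensor-level deflection of the default bilateral sources
    in the 50-150 fT range after forward projection.
    """
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    for latency, width, amp, sgn in components:
        if width <= 0:
            raise ValueError("component widths must be positive")
        out += sgn * amp * np.exp(-0.5 * ((t - latency) / width) ** 2)
    out *= peak_moment
    return np.where(t < 0, 0.0, out)


def bilateral_auditory_sources(depth: float = 0.054,
                               y: float = 0.0, z: float = 0.005) -> list[DipoleSource]:
    """Mirror-symmetric dipole pair at auditory-cortex-like lateral positions,
    tangentially oriented (the radial component is silent in a sphere)."""
    left = DipoleSource(np.array([-depth, y, z]), np.array([0.0, 1.0, 0.0]))
    right = DipoleSource(np.array([depth, y, z]), np.array([0.0, 1.0, 0.0]))
    return [left, right]


# --------------------------------------------------------------------------- #
# Recording synthesis
# --------------------------------------------------------------------------- #

DEFAULT_LINE_COMPONENTS = [(50.0, 3e-12), (100.0, 1e-12), (150.0, 0.8e-12),
                           (120.0, 1.5e-12), (83.0, 1e-12)]


def _pose_at(traj: RigidBodyTrajectory, times: np.ndarray):
    """Linear-interpolated pose (R, T) on an arbitrary time grid."""
    dof = np.empty((times.size, 6))
    for d in range(3):
        dof[:, d] = np.interp(times, traj.time, traj.translation[:, d])
        dof[:, 3 + d] = np.interp(times, traj.time, traj.rotation[:, d])
    R = euler_to_matrix(dof[:, 3], dof[:, 4], dof[:, 5])
    return R, dof[:, :3]


def simulate_recording(array: SensorArray, traj: RigidBodyTrajectory,
                       room: RoomFieldModel, sources: list[DipoleSource],
                       stim: StimulusTrain, noise: NoiseModel,
                       head_model: HeadModel | None = None,
                       rate: float = 1000.0, seed: int = 0,
                       head_position=(0.0, 0.0, 0.0),
                       evoked_components=DEFAULT_EVOKED_COMPONENTS,
                       peak_moment: float = 7e-9) -> tuple[Recording, GroundTruth]:
    """Synthesise a recording with full ground truth.

    ``head_position`` places the head-frame origin in the room (standing
    conditions put it away from the room centre where the remnant-field
    gradient is steeper).  The neural term is computed in the head frame and
    is motion-invariant; the artefact term moves the channel positions and
    axes through the room field with the pose.
    """
    if head_model is None:
        head_model = HeadModel()
    if noise.line_components and rate < 2 * max(f for f, _ in noise.line_components):
        raise ValueError("rate must be at least twice the highest line frequency")
    duration = traj.time[-1] + 1.0 / traj.rate
    n = int(round(duration * rate))
    times = np.arange(n) / rate
    n_ch = array.n_channels
    ss = np.random.SeedSequence(seed)
    rng_noise, rng_line = [np.random.default_rng(s) for s in ss.spawn(2)]

    # --- neural term (head frame, motion invariant) ------------------------ #
    epoch_t = np.arange(int(round(0.5 * rate))) / rate
    template = evoked_waveform(epoch_t, components=evoked_components,
                               peak_moment=peak_moment)
    onset_samples = np.round(stim.onsets * rate).astype(int)
    source_waveforms = np.zeros((len(sources), n))
    neural = np.zeros((n_ch, n))
    for k, src in enumerate(sources):
        w = np.zeros(n)
        for s0 in onset_samples:
            s1 = min(n, s0 + template.size)
            if s0 < n:
                w[s0:s1] += template[:s1 - s0]
        source_waveforms[k] = w
        L = lead_field(head_model, array, src.position)
        neural += np.outer(L @ src.moment_orientation, w)

    # --- movement artefact ------------------------------------------------- #
    ch_pos = array.channel_positions()
    ch_ax = array.channel_axes()
    head0 = np.asarray(head_position, float)
    artefact = np.empty((n_ch, n))
    chunk = 20000
    for a in range(0, n, chunk):
        b = min(n, a + chunk)
        R, T = _pose_at(traj, times[a:b])
        p = head0 + T[:, None, :] + np.einsum("nij,cj->nci", R, ch_pos)
        ax = np.einsum("nij,cj->nci", R, ch_ax)
        B = room_field_at(room, p)
        artefact[:, a:b] = np.einsum("nci,nci->nc", ax, B).T

    # --- line noise and white noise ---------------------------------------- #
    data = neural + artefact
    # line interference enters as a spatially uniform oscillating field with
    # a fixed random direction per component, projected on the channel axes
    for f, amp in noise.line_components:
        phase = rng_line.uniform(0, 2 * np.pi)
        direction = rng_line.normal(size=3)
        direction /= np.linalg.norm(direction)
        gains = ch_ax @ direction
        data += np.outer(gains * amp, np.sin(2 * np.pi * f * times + phase))
    if noise.white_density > 0:
        sigma = noise.white_density * np.sqrt(rate / 2.0)
        data = data + rng_noise.normal(0.0, sigma, size=(n_ch, n))

    gain_flags = np.array(["ok"] * n_ch)
    if noise.clip_enabled:
        clipped = np.abs(data) > noise.clip_limit
        frac = clipped.mean()
        if frac > 0.5:
            warnings.warn(f"{100 * frac:.1f}% of samples exceed the sensor "
                          "dynamic range and were clipped")
        gain_flags[clipped.any(axis=1)] = "clipped"
        data = np.clip(data, -noise.clip_limit, noise.clip_limit)

    events = [("tone", int(s)) for s in onset_samples if 0 <= s < n]
    rec = Recording(data, rate, list(array.channel_names), ch_pos, ch_ax,
                    events=events,
                    history=[{"stage": "simulate", "seed": seed, "rate": rate}])
    gt = GroundTruth(source_waveforms, neural, artefact, events,
                     evoked_template=template, evoked_times=epoch_t)
    return rec, gt
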