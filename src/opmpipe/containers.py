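"""Core data containers: recordings, sensor arrays, trajectories, epochs.

Magnetic quantities are stored in Tesla throughout; positions in metres;
angles in degrees.  Reporting helpers convert to fT / pT for display.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


# --------------------------------------------------------------------------- #
# Sensor geometry
# --------------------------------------------------------------------------- #

@dataclass
class SensorArray:
    """Dual-axis magnetometer array in head coordinates.

    Each sensor contributes two channels: one sensitive axis radial to the
    head (along the position vector from the sphere centre) and one
    tangential.  The default 45-sensor array therefore yields 90 channels.

    Attributes
    ----------
    positions : (n_sensors, 3) float
        Sensor cell centres, metres, head frame.
    axes : (n_sensors, 2, 3) float
        Unit sensitive axes per sensor: ``axes[:, 0]`` radial,
        ``axes[:, 1]`` tangential.
    channel_names : list of str, length 2 * n_sensors
    gain_flags : (2 * n_sensors,) str array, "ok" or "clipped"
    """

    positions: np.ndarray
    axes: np.ndarray
    channel_names: list[str]
    gain_flags: np.ndarray = None
    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.axes = np.asarray(self.axes, float)
        if self.gain_flags is None:
            self.gain_flags = np.array(["ok"] * (2 * self.n_sensors))
        norms = np.linalg.norm(self.axes, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensitive axes must have unit norm")
        dots = np.einsum("ij,ij->i", self.axes[:, 0], self.axes[:, 1])
        if not np.allclose(dots, 0.0, atol=1e-9):
            raise ValueError("the two axes of a sensor must be orthogonal")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return 2 * self.n_sensors

    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3) position of each channel (sensor position, twice)."""
        return np.repeat(self.positions, 2, axis=0)

    def channel_axes(self) -> np.ndarray:
        """(n_channels, 3) unit sensitive axis of each channel."""
        return self.axes.reshape(-1, 3)


# --------------------------------------------------------------------------- #
# Motion containers
# --------------------------------------------------------------------------- #

@dataclass
class RigidBodyTrajectory:
    """6-DOF pose series: translation (X, Y, Z) metres and rotation
    (pitch, yaw, roll) degrees, unwrapped over time."""

    time: np.ndarray
    translation: np.ndarray  # (n, 3)
    rotation: np.ndarray     # (n, 3) pitch, yaw, roll, degrees
    rate: float

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.translation = np.asarray(self.translation, float)
        self.rotation = np.asarray(self.rotation, float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def dof_matrix(self) -> np.ndarray:
        """(n, 6) matrix ordered X, Y, Z, pitch, yaw, roll."""
        return np.hstack([self.translation, self.rotation])

    def copy(self) -> "RigidBodyTrajectory":
        return RigidBodyTrajectory(self.time.copy(), self.translation.copy(),
                                   self.rotation.copy(), self.rate)


@dataclass
class MarkerTrajectories:
    """Optical-tracker marker positions with occlusion gaps as NaN."""

    time: np.ndarray          # (n,) seconds
    positions: np.ndarray     # (n, n_markers, 3) metres, NaN when occluded
    rate: float = 120.0

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.positions = np.asarray(self.positions, float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """(n, n_markers) boolean, True where the marker is occluded."""
        return np.isnan(self.positions).any(axis=2)

    def occluded_fraction(self) -> float:
        return float(self.mask.mean())

    def copy(self) -> "MarkerTrajectories":
        return MarkerTrajectories(self.time.copy(), self.positions.copy(), self.rate)

    # -- optical-tracker CSV dialect ---------------------------------------- #

    def to_csv(self, path) -> None:
        """Write the tabular export: frame, time_s, then per-marker X, Y, Z
        columns with blank cells for occluded samples."""
        cols = {"frame": np.arange(self.n_frames), "time_s": self.time}
        for m in range(self.n_markers):
            for j, ax in enumerate("XYZ"):
                cols[f"marker{m + 1}_{ax}"] = self.positions[:, m, j]
        pd.DataFrame(cols).to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "MarkerTrajectories":
        df = pd.read_csv(path)
        time = df["time_s"].to_numpy(float)
        marker_cols = [c for c in df.columns if c.startswith("marker")]
        n_markers = len(marker_cols) // 3
        pos = np.empty((len(df), n_markers, 3))
        for m in range(n_markers):
            for j, ax in enumerate("XYZ"):
                pos[:, m, j] = pd.to_numeric(df[f"marker{m + 1}_{ax}"],
                                             errors="coerce").to_numpy(float)
        rate = 1.0 / np.median(np.diff(time)) if time.size > 1 else 120.0
        return cls(time, pos, float(round(rate, 6)))


# --------------------------------------------------------------------------- #
# Recording
# --------------------------------------------------------------------------- #

@dataclass
class Recording:
    """Multichannel magnetometer recording (channels x samples, Tesla).

    ``history`` is an append-only list of ``{"stage": name, **params}``
    dicts recording every processing step applied; ``bad_segments`` holds
    ``(start_s, end_s, reason)`` tuples.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    channel_positions: np.ndarray   # (n_ch, 3) head frame
    channel_axes: np.ndarray        # (n_ch, 3) unit sensitive axes, head frame
    events: list = field(default_factory=list)   # (label, sample) tuples
    history: list = field(default_factory=list)
    bad_segments: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.channel_positions = np.asarray(self.channel_positions, float)
        self.channel_axes = np.asarray(self.channel_axes, float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def event_samples(self, label: str | None = None) -> np.ndarray:
        return np.array([s for (lbl, s) in self.events
                         if label is None or lbl == label], dtype=int)

    def with_data(self, data: np.ndarray, stage: str, **params) -> "Recording":
        """Return a copy carrying new data and an extended history."""
        new = copy.copy(self)
        new.data = np.asarray(data, float)
        new.events = list(self.events)
        new.bad_segments = list(self.bad_segments)
        new.history = self.history + [{"stage": stage, **params}]
        return new

    # -- HDF5 container ------------------------------------------------------ #

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, dtype="float64")
            f.create_dataset("rate", data=float(self.rate))
            ch = f.create_group("channels")
            ch.create_dataset("name", data=np.array(self.channel_names, dtype="S32"))
            ch.create_dataset("position", data=self.channel_positions)
            ch.create_dataset("axis", data=self.channel_axes)
            ev = f.create_group("events")
            labels = [lbl for lbl, _ in self.events]
            samples = [s for _, s in self.events]
            ev.create_dataset("name", data=np.array(labels, dtype="S32"))
            ev.create_dataset("sample", data=np.array(samples, dtype="int64"))
            f.attrs["history"] = repr(self.history)

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            rate = float(f["rate"][()])
            names = [n.decode() for n in f["channels/name"][()]]
            pos = f["channels/position"][()]
            axes = f["channels/axis"][()]
            labels = [n.decode() for n in f["events/name"][()]]
            samples = f["events/sample"][()]
            history = eval(f.attrs.get("history", "[]"))  # noqa: S307 - own format
        events = list(zip(labels, [int(s) for s in samples]))
        return cls(data, rate, names, pos, axes, events=events, history=history)


# --------------------------------------------------------------------------- #
# Epochs
# --------------------------------------------------------------------------- #

@dataclass
class EpochedData:
    """Trials x channels x samples around stimulus onsets.

    ``provenance`` is a DataFrame with one row per *event* (kept or not):
    columns onset_sample, kept, reason.
    """

    data: np.ndarray               # (n_trials, n_ch, n_samples)
    times: np.ndarray              # (n_samples,) seconds relative to onset
    rate: float
    onsets: np.ndarray             # (n_trials,) onset samples of kept trials
    window: tuple = (-0.2, 0.5)
    baseline: tuple = (-0.1, 0.0)
    provenance: pd.DataFrame | None = None
    channel_names: list[str] | None = None
    channel_positions: np.ndarray | None = None
    channel_axes: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def average(self) -> np.ndarray:
        """(n_ch, n_samples) trial-average evoked response."""
        return self.data.mean(axis=0)

    def subset(self, idx: np.ndarray) -> "EpochedData":
        new = dataclasses.replace(self, data=self.data[idx], onsets=self.onsets[idx])
        return new
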