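"""Forward modelling: spherical conductor, symmetric source grid, lead fields.

The conductor is the analytic homogeneous sphere (Sarvas solution for the
magnetic field of a current dipole in a spherically symmetric conductor).
It shares the key structural property of realistic single-shell models --
radially oriented dipoles are magnetically silent outside the conductor --
while being exactly specified and dependency-free.  The lead-field entry
point accepts alternative backends through the same call signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SensorArray

MU0_OVER_4PI = 1e-7  # Tesla metre / Ampere


@dataclass
class HeadModel:
    """Homogeneous conducting sphere: centre (metres, head frame) and radius."""

    centre: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.09

    def __post_init__(self):
        self.centre = np.asarray(self.centre, float)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class SourceGrid:
    """Volumetric dipole grid with mid-sagittal mirror pairing.

    ``pair_index[i]`` is the index of point i's mirror across the plane
    x = centre_x; points on the plane are their own mirror.  The pairing
    is an involution by construction.
    """

    points: np.ndarray              # (m, 3) metres
    resolution: float
    pair_index: np.ndarray          # (m,) int
    mirror_x: float
    roi_masks: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def on_plane(self, i: int) -> bool:
        return self.pair_index[i] == i

    def add_roi(self, name: str, centre, radius: float) -> np.ndarray:
        """Define a spherical region of interest; returns its boolean mask."""
        centre = np.asarray(centre, float)
        mask = np.linalg.norm(self.points - centre, axis=1) <= radius
        self.roi_masks[name] = mask
        return mask


def make_grid(model: HeadModel, resolution: float = 0.005,
              clip_fraction: float = 0.9) -> SourceGrid:
    """Axis-aligned lattice clipped to ``|p - centre| < clip_fraction * radius``.

    The lattice passes through the sphere centre, so x coordinates come in
    exact +/- pairs about the mirror plane x = centre_x and every point has
    an exact mirror partner in the grid.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rmax = clip_fraction * model.radius
    nstep = int(np.floor(rmax / resolution))
    if nstep < 0 or rmax <= 0:
        raise ValueError("empty grid: resolution too coarse for the head model")
    offsets = np.arange(-nstep, nstep + 1) * resolution
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.linalg.norm(pts, axis=1) < rmax
    pts = pts[keep] + model.centre
    if pts.shape[0] == 0:
        raise ValueError("empty grid: resolution too coarse for the head model")

    # integer lattice coordinates make the mirror lookup exact
    idx = np.round((pts - model.centre) / resolution).astype(int)
    lookup = {tuple(row): i for i, row in enumerate(idx)}
    pair = np.empty(pts.shape[0], dtype=int)
    for i, row in enumerate(idx):
        pair[i] = lookup[(-row[0], row[1], row[2])]
    return SourceGrid(pts, resolution, pair, float(model.centre[0]))


def _sarvas(r: np.ndarray, r0: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Magnetic field of current dipole q at r0 inside a conducting sphere,
    evaluated at external points r.  All positions relative to the sphere
    centre; r is (n, 3), returns (n, 3) Tesla."""
    a = r - r0                                    # (n, 3)
    an = np.linalg.norm(a, axis=1)                # |r - r0|
    rn = np.linalg.norm(r, axis=1)                # |r|
    ar = np.einsum("ij,ij->i", a, r)
    F = an * (rn * an + rn ** 2 - r0 @ r.T)
    gradF = ((an ** 2 / rn + ar / an + 2 * an + 2 * rn)[:, None] * r
             - (an + 2 * rn + ar / an)[:, None] * r0[None, :])
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (F[:, None] * qxr0[None, :]
                                          - (r @ qxr0)[:, None] * gradF)
    return B


def lead_field(model: HeadModel, array: SensorArray, p: np.ndarray) -> np.ndarray:
    """Channels x 3 gain matrix for a dipole at head-frame position ``p``.

    Column j is the field projected onto each channel's sensitive axis for a
    unit (1 A.m) dipole moment along head-frame axis j.  A dipole at the
    sphere centre, or any radially oriented moment, produces zero output.
    """
    p = np.asarray(p, float)
    r0 = p - model.centre
    if np.linalg.norm(r0) >= model.radius:
        raise ValueError("dipole position must lie strictly inside the sphere")
    ch_pos = array.channel_positions() - model.centre
    ch_ax = array.channel_axes()
    if np.any(np.linalg.norm(ch_pos, axis=1) <= model.radius):
        raise ValueError("sensors must lie outside the conductor sphere")
    L = np.empty((ch_pos.shape[0], 3))
    eye = np.eye(3)
    for j in range(3):
        B = _sarvas(ch_pos, r0, eye[j])
        L[:, j] = np.einsum("ij,ij->i", B, ch_ax)
    return L


@dataclass
class LeadField:
    """Lead fields for every grid point: ``gains[i]`` is channels x 3."""

    grid: SourceGrid
    gains: np.ndarray          # (m, n_channels, 3)

    @classmethod
    def compute(cls, model: HeadModel, array: SensorArray,
                grid: SourceGrid) -> "LeadField":
        gains = np.empty((grid.n_points, array.n_channels, 3))
        for i, p in enumerate(grid.points):
            gains[i] = lead_field(model, array, p)
        return cls(grid, gains)

    def point_lead_field(self, i: int, reduce_rank: int | None = None) -> np.ndarray:
        """Channels x 3 gain matrix, optionally rank-reduced.

        In a spherical conductor the radially oriented moment is silent, so
        the 3-column gain matrix is effectively rank 2; ``reduce_rank=2``
        keeps the two strongest singular directions (the moment subspace
        the sensors can actually see), which stops the near-silent
        orientation from dominating unit-gain filter norms.
        """
        L = self.gains[i]
        if reduce_rank is None or reduce_rank >= 3:
            return L
        U, s, Vt = np.linalg.svd(L, full_matrices=False)
        return U[:, :reduce_rank] * s[:reduce_rank]

    def pair_lead_field(self, i: int, reduce_rank: int | None = None) -> np.ndarray:
        """Concatenation [L(i) | L(mirror(i))] (channels x 6, or x 4 when
        rank-reduced); collapses to the single block for points on the
        mirror plane."""
        j = self.grid.pair_index[i]
        if j == i:
            return self.point_lead_field(i, reduce_rank)
        return np.hstack([self.point_lead_field(i, reduce_rank),
                          self.point_lead_field(j, reduce_rank)])

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("leadfield", data=self.gains)
            f.create_dataset("grid/points", data=self.grid.points)
            f.create_dataset("grid/pair_index", data=self.grid.pair_index)
            f.create_dataset("grid/resolution", data=self.grid.resolution)
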