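"""Flatmap extraction: normals, velocity sheets, label transfer, masks.

All geometry is in mm, velocities in m/s, wall shear stress in Pa. A flatmap
is a (n_U, n_V, C) array aligned to the quad template grid together with a
boolean validity mask; masked nodes are ignored by every loss and metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .geometry import QuadSurface

logger = logging.getLogger(__name__)

# Inward distances (mm) at which training velocity sheets are extracted.
TRAINING_SHEET_DISTANCES = (0.3, 0.5, 0.6, 0.8, 1.0, 2.0)
# Sheets used at MRI resolution.
MRI_SHEET_DISTANCES = (1.0, 2.0)
# Longitudinal rings next to the inlet excluded from training/metrics.
INLET_EXCLUDE = 3


@dataclass
class Flatmap:
    """(n_U, n_V, C) values on the template grid with a validity mask."""

    values: np.ndarray
    mask: np.ndarray
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} != grid shape {self.values.shape[:2]}"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    def magnitude(self) -> np.ndarray:
        """Euclidean norm over channels, zeroed at masked nodes."""
        mag = np.linalg.norm(self.values, axis=2)
        return np.where(self.mask, mag, 0.0)


@dataclass
class VelocitySheet:
    """Velocity flatmap sampled at a fixed inward-normal distance (mm)."""

    flatmap: Flatmap
    distance: float

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("sheet distance must be positive (no-slip wall is not sampled)")


class VelocitySource:
    """Queryable velocity field. Subclasses return (values, covered) pairs."""

    venc: float = 1.5

    def sample(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class AnalyticSource(VelocitySource):
    """Wraps a callable field ``f(points (N,3) mm) -> (N,3) m/s``."""

    def __init__(self, func, venc: float = 1.5):
        self.func = func
        self.venc = venc

    def sample(self, points):
        v = np.asarray(self.func(points), dtype=float)
        return v, np.ones(len(points), dtype=bool)


class GridSource(VelocitySource):
    """Uniform (possibly anisotropic) voxel grid, trilinear interpolation.

    ``values``: (nx, ny, nz, 3) m/s; ``spacing``: per-axis mm; ``origin``:
    position of voxel (0,0,0) center in mm.
    """

    def __init__(self, values, spacing, origin=(0.0, 0.0, 0.0), venc: float = 1.5):
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[3] != 3:
            raise ValueError("grid values must have shape (nx, ny, nz, 3)")
        self.spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(origin, dtype=float)
        self.venc = venc
        axes = [
            self.origin[k] + self.spacing[k] * np.arange(self.values.shape[k])
            for k in range(3)
        ]
        self._interp = RegularGridInterpolator(
            axes, self.values, method="linear", bounds_error=False, fill_value=np.nan
        )

    def sample(self, points):
        v = self._interp(points)
        covered = np.all(np.isfinite(v), axis=1)
        if not covered.all():
            logger.warning("%d sheet points fall outside the velocity grid", int((~covered).sum()))
        v = np.where(covered[:, None], v, 0.0)
        return v, covered


class PointCloudSource(VelocitySource):
    """Scattered velocity samples; inverse-distance weighting of k neighbors
    within a cutoff radius (mm)."""

    def __init__(self, points, velocities, k: int = 8, radius: float = 5.0, venc: float = 1.5):
        self.points = np.asarray(points, dtype=float).reshape(-1, 3)
        self.velocities = np.asarray(velocities, dtype=float).reshape(-1, 3)
        if len(self.points) != len(self.velocities):
            raise ValueError("points and velocities must pair up")
        self.k = k
        self.radius = radius
        self.venc = venc
        self._tree = cKDTree(self.points)

    def sample(self, query):
        query = np.asarray(query, dtype=float)
        k = min(self.k, len(self.points))
        d, idx = self._tree.query(query, k=k)
        d = np.atleast_2d(d.reshape(len(query), -1))
        idx = np.atleast_2d(idx.reshape(len(query), -1))
        within = d <= self.radius
        covered = within.any(axis=1)
        # exact hits take the sample value directly
        w = np.where(within, 1.0 / np.maximum(d, 1e-12), 0.0)
        exact = d < 1e-12
        has_exact = exact.any(axis=1)
        w[has_exact] = exact[has_exact].astype(float)
        wsum = w.sum(axis=1, keepdims=True)
        wsum[wsum == 0] = 1.0
        v = np.einsum("qk,qkc->qc", w / wsum, self.velocities[idx])
        v = np.where(covered[:, None], v, 0.0)
        return v, covered


def inward_normals(surface: QuadSurface) -> Flatmap:
    """Unit normals pointing into the lumen (toward the local ring centroid).

    Normals come from the cross product of circumferential and longitudinal
    tangents (central differences, periodic in U); nodes with degenerate
    neighborhoods are masked invalid.
    """
    nodes = surface.nodes
    t_u = np.roll(nodes, -1, axis=0) - np.roll(nodes, 1, axis=0)
    t_v = np.empty_like(nodes)
    t_v[:, 1:-1] = nodes[:, 2:] - nodes[:, :-2]
    t_v[:, 0] = nodes[:, 1] - nodes[:, 0]
    t_v[:, -1] = nodes[:, -1] - nodes[:, -2]
    n = np.cross(t_u, t_v)
    norm = np.linalg.norm(n, axis=2)
    valid = norm > 1e-12
    n = np.where(valid[:, :, None], n / np.maximum(norm, 1e-12)[:, :, None], 0.0)
    # orient toward the ring centroid
    centroid = nodes.mean(axis=0, keepdims=True)
    flip = np.sum(n * (centroid - nodes), axis=2) < 0
    n[flip] *= -1.0
    return Flatmap(n, valid, channel_names=("nx", "ny", "nz"))


def sample_velocity_sheet(
    src: VelocitySource,
    surface: QuadSurface,
    distance: float,
    normals: Flatmap | None = None,
) -> VelocitySheet:
    """Velocities at ``node + d * inward_normal`` for every template node."""
    if distance <= 0:
        raise ValueError("inward distance must be positive")
    if normals is None:
        normals = inward_normals(surface)
    pts = surface.nodes + distance * normals.values
    v, covered = src.sample(pts.reshape(-1, 3))
    mask = normals.mask & covered.reshape(surface.shape)
    fm = Flatmap(v.reshape(surface.n_u, surface.n_v, 3), mask, ("vx", "vy", "vz"))
    return VelocitySheet(fm, distance)


def inner_coordinates(surface: QuadSurface, distance: float, normals: Flatmap | None = None) -> Flatmap:
    """Coordinates of the inner surface offset ``distance`` mm along the inward normal."""
    if normals is None:
        normals = inward_normals(surface)
    pts = surface.nodes + distance * normals.values
    return Flatmap(pts, normals.mask.copy(), ("x", "y", "z"))


def transfer_wss_labels(
    src_points: np.ndarray,
    src_wss: np.ndarray,
    surface: QuadSurface,
    radius: float = 5.0,
) -> Flatmap:
    """Nearest-neighbor WSS label transfer with a search radius (mm).

    Each template node takes the WSS vector of its nearest source point; nodes
    farther than ``radius`` from every source point are masked invalid.
    """
    src_points = np.asarray(src_points, dtype=float).reshape(-1, 3)
    src_wss = np.asarray(src_wss, dtype=float).reshape(-1, 3)
    if src_points.size == 0:
        raise ValueError("empty source point set")
    tree = cKDTree(src_points)
    d, idx = tree.query(surface.points())
    mask = (d <= radius).reshape(surface.shape)
    values = src_wss[idx].reshape(surface.n_u, surface.n_v, 3)
    values[~mask] = 0.0
    return Flatmap(values, mask, ("wss_x", "wss_y", "wss_z"))


def build_branch_mask(
    surface: QuadSurface,
    branch_ostia: list[tuple[np.ndarray, float]] | None = None,
    exclude_inlet: int = INLET_EXCLUDE,
) -> np.ndarray:
    """Validity mask excluding branch ostia zones and the inlet rings.

    ``branch_ostia`` is a list of (center (3,), zone_radius mm); nodes strictly
    inside a zone are invalid (a node exactly on the boundary stays valid).
    The first ``exclude_inlet`` longitudinal rings are invalid, mirroring the
    exclusion of inlet boundary values during training.
    """
    mask = np.ones(surface.shape, dtype=bool)
    mask[:, :exclude_inlet] = False
    if branch_ostia:
        for center, zone in branch_ostia:
            d = np.linalg.norm(surface.nodes - np.asarray(center, dtype=float), axis=2)
            mask &= ~(d < zone)
    return mask


def assemble_input(
    wall: Flatmap,
    inner1: Flatmap,
    inner2: Flatmap,
    sheet1: VelocitySheet,
    sheet2: VelocitySheet,
    extra_mask: np.ndarray | None = None,
) -> Flatmap:
    """Stack the 15-channel network input.

    Channel order: wall coordinates (x0,y0,z0), inner coordinates at d1 and d2
    (x1..z1, x2..z2), then the two velocity sheets (vx1..vz1, vx2..vz2), with
    the first sheet strictly closer to the wall. The output mask is the AND of
    all component masks (and ``extra_mask`` if given).
    """
    if sheet1.distance >= sheet2.distance:
        raise ValueError(
            f"sheet distances must satisfy d1 < d2, got {sheet1.distance} >= {sheet2.distance}"
        )
    parts = [wall, inner1, inner2, sheet1.flatmap, sheet2.flatmap]
    for p in parts:
        if p.shape != wall.shape or p.n_channels != 3:
            raise ValueError("all inputs must be 3-channel flatmaps on the same grid")
    values = np.concatenate([p.values for p in parts], axis=2)
    mask = np.logical_and.reduce([p.mask for p in parts])
    if extra_mask is not None:
        mask = mask & extra_mask
    names = (
        "x0", "y0", "z0", "x1", "y1", "z1", "x2", "y2", "z2",
        "vx1", "vy1", "vz1", "vx2", "vy2", "vz2",
    )
    return Flatmap(values, mask, names)
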