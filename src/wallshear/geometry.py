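"""Structured quad templates for tubular vessel walls.

A vessel wall is represented as a quadrilateral grid that is periodic in the
circumferential direction (U) and open in the longitudinal direction (V).
Unwrapping this grid yields the 2D "flatmap" used throughout the package.
The working template is 48 x 93 (U x V); a coarse 12 x 24 version paired with
midpoint subdivision matrices speeds up point-set registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

FINE_N_U = 48
FINE_N_V = 93
COARSE_N_U = 12
COARSE_N_V = 24


@dataclass
class QuadSurface:
    """Grid of 3D nodes (mm) forming a structured quad surface.

    ``nodes`` has shape (n_U, n_V, 3). ``periodic_u`` marks the circumferential
    axis as closed: faces wrap from row n_U-1 back to row 0.
    """

    nodes: np.ndarray
    periodic_u: bool = True

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 3:
            raise ValueError(f"nodes must have shape (n_U, n_V, 3), got {self.nodes.shape}")
        if self.n_u < 3 or self.n_v < 2:
            raise ValueError(f"grid too small: {self.nodes.shape[:2]}")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("surface nodes must be finite")

    @property
    def n_u(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_v(self) -> int:
        return self.nodes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_u, self.n_v)

    def points(self) -> np.ndarray:
        """All nodes as an (n_U * n_V, 3) point cloud."""
        return self.nodes.reshape(-1, 3)

    def with_nodes(self, nodes: np.ndarray) -> "QuadSurface":
        return QuadSurface(nodes, periodic_u=self.periodic_u)

    def quad_faces(self) -> np.ndarray:
        """Vertex-index quads (flat indexing u * n_V + v), wrapping in U."""
        nu, nv = self.shape
        u = np.arange(nu) if self.periodic_u else np.arange(nu - 1)
        v = np.arange(nv - 1)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        un = (uu + 1) % nu
        i00 = uu * nv + vv
        i10 = un * nv + vv
        i11 = un * nv + vv + 1
        i01 = uu * nv + vv + 1
        return np.stack([i00, i10, i11, i01], axis=-1).reshape(-1, 4)


@dataclass
class SubdivisionMatrices:
    """Linear midpoint-subdivision operators for a quad grid.

    ``s_u`` maps n_U rows to 2*n_U rows (periodic); ``s_v`` maps n_V columns to
    2*n_V - 1 columns (open, endpoint-interpolating). Both are row-stochastic:
    every refined node is a convex combination of coarse nodes.
    """

    s_u: np.ndarray
    s_v: np.ndarray

    @property
    def in_shape(self) -> tuple[int, int]:
        return (self.s_u.shape[1], self.s_v.shape[1])

    @property
    def out_shape(self) -> tuple[int, int]:
        return (self.s_u.shape[0], self.s_v.shape[0])


def build_subdivision_matrices(n_u: int, n_v: int) -> SubdivisionMatrices:
    """Midpoint subdivision matrices for an (n_u, n_v) periodic-U quad grid."""
    s_u = np.zeros((2 * n_u, n_u))
    for i in range(n_u):
        s_u[2 * i, i] = 1.0
        s_u[2 * i + 1, i] = 0.5
        s_u[2 * i + 1, (i + 1) % n_u] = 0.5
    s_v = np.zeros((2 * n_v - 1, n_v))
    for j in range(n_v):
        s_v[2 * j, j] = 1.0
    for j in range(n_v - 1):
        s_v[2 * j + 1, j] = 0.5
        s_v[2 * j + 1, j + 1] = 0.5
    return SubdivisionMatrices(s_u=s_u, s_v=s_v)


def subdivide(surface: QuadSurface, mats: SubdivisionMatrices) -> QuadSurface:
    """Refine a quad grid: (n_U, n_V) -> (2 n_U, 2 n_V - 1)."""
    if surface.shape != mats.in_shape:
        raise ValueError(
            f"surface shape {surface.shape} does not match subdivision input {mats.in_shape}"
        )
    refined = np.einsum("au,uvc->avc", mats.s_u, surface.nodes)
    refined = np.einsum("bv,avc->abc", mats.s_v, refined)
    return surface.with_nodes(refined)


def _resample_centerline(centerline: np.ndarray, n_stations: int) -> np.ndarray:
    """Arclength-uniform resampling of a polyline to ``n_stations`` points."""
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    if np.any(seg <= 1e-12):
        raise ValueError("degenerate centerline: repeated points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n_stations)
    return np.stack([np.interp(target, s, centerline[:, k]) for k in range(3)], axis=1)


def _transport_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing (parallel transport) frames along a curve.

    Returns per-station orthonormal vectors (e1, e2) spanning the plane normal
    to the local tangent; avoids the twisting a fixed reference axis causes.
    """
    n = len(tangents)
    e1 = np.zeros((n, 3))
    e2 = np.zeros((n, 3))
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1[0] = ref - np.dot(ref, t0) * t0
    e1[0] /= np.linalg.norm(e1[0])
    e2[0] = np.cross(t0, e1[0])
    for i in range(1, n):
        # rotate the previous frame by the minimal rotation t_{i-1} -> t_i
        a, b = tangents[i - 1], tangents[i]
        c = np.cross(a, b)
        sc = np.linalg.norm(c)
        if sc < 1e-12:
            e1[i], e2[i] = e1[i - 1], e2[i - 1]
            continue
        axis = c / sc
        cos = np.clip(np.dot(a, b), -1.0, 1.0)
        sin = sc
        for src, dst in ((e1, e1), (e2, e2)):
            v = src[i - 1]
            dst[i] = (
                v * cos + np.cross(axis, v) * sin + axis * np.dot(axis, v) * (1 - cos)
            )
        e1[i] -= np.dot(e1[i], b) * b
        e1[i] /= np.linalg.norm(e1[i])
        e2[i] = np.cross(b, e1[i])
    return e1, e2


def build_coarse_template(
    n_u: int = COARSE_N_U,
    n_v: int = COARSE_N_V,
    centerline: np.ndarray | None = None,
    radius_profile: np.ndarray | float = 10.0,
) -> QuadSurface:
    """Procedural tube template over a centerline.

    Parameters
    ----------
    n_u, n_v
        Grid size (circumferential, longitudinal).
    centerline
        (n_stations, 3) polyline in mm, ``n_stations >= n_v``; defaults to a
        straight z-axis segment of length 4 * n_v mm.
    radius_profile
        Scalar radius in mm, or per-station radii (resampled to n_v).

    Ring ``v`` lies in the plane normal to the centerline at station ``v``;
    the U=0 generator line is the template cut-line.
    """
    if centerline is None:
        centerline = np.stack(
            [np.zeros(n_v), np.zeros(n_v), np.linspace(0.0, 4.0 * n_v, n_v)], axis=1
        )
    centerline = np.asarray(centerline, dtype=float)
    if centerline.ndim != 2 or centerline.shape[1] != 3:
        raise ValueError("centerline must be (n_stations, 3)")
    if len(centerline) < n_v:
        raise ValueError(f"centerline needs >= {n_v} stations, got {len(centerline)}")
    stations = _resample_centerline(centerline, n_v)

    radii = np.asarray(radius_profile, dtype=float)
    if radii.ndim == 0:
        radii = np.full(n_v, float(radii))
    elif len(radii) != n_v:
        s_in = np.linspace(0.0, 1.0, len(radii))
        s_out = np.linspace(0.0, 1.0, n_v)
        radii = np.interp(s_out, s_in, radii)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")

    tangents = np.gradient(stations, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    e1, e2 = _transport_frames(tangents)

    theta = 2.0 * np.pi * np.arange(n_u) / n_u
    nodes = (
        stations[None, :, :]
        + radii[None, :, None]
        * (
            np.cos(theta)[:, None, None] * e1[None, :, :]
            + np.sin(theta)[:, None, None] * e2[None, :, :]
        )
    )
    return QuadSurface(nodes, periodic_u=True)


def build_fine_template(
    centerline: np.ndarray | None = None,
    radius_profile: np.ndarray | float = 10.0,
) -> QuadSurface:
    """48 x 93 template built directly (no registration)."""
    return build_coarse_template(FINE_N_U, FINE_N_V, centerline, radius_profile)


def surface_distance(registered: QuadSurface, target_points: np.ndarray) -> np.ndarray:
    """Per-node nearest-point distance (mm) to a target point cloud.

    Returns an (n_U, n_V) array; summarize as mean +/- SD over valid nodes to
    report registration accuracy.
    """
    target_points = np.asarray(target_points, dtype=float)
    if target_points.size == 0:
        raise ValueError("empty target point set")
    tree = cKDTree(target_points.reshape(-1, 3))
    d, _ = tree.query(registered.points())
    return d.reshape(registered.shape)
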