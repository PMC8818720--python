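"""Coherent Point Drift registration (rigid, affine, deformable).

EM point-set registration following Myronenko & Song: the source set Y is a
GMM whose centroids are moved onto the target set X. The deformable stage
displaces Y by G W, where G is a Gaussian kernel of width ``beta`` and the
motion-coherence weight ``alpha`` penalizes non-smooth displacement fields.

Used to drape the quad template over a segmented vessel wall: rigid -> affine
-> deformable on the coarse template, two subdivision passes, then a second
deformable pass on the fine grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import QuadSurface, SubdivisionMatrices, subdivide

logger = logging.getLogger(__name__)


@dataclass
class CPDConfig:
    """Settings for one registration stage.

    ``alpha`` trades data fit against deformation smoothness; ``beta`` (mm) is
    the width of the Gaussian smoothing kernel. Both only matter for the
    deformable stage.
    """

    alpha: float = 3.0
    beta: float = 15.0
    stage: str = "deformable"
    max_iters: int = 100
    tolerance: float = 1e-5
    outlier_weight: float = 0.0
    # warm-start GMM variance (mm^2); None uses the mean pairwise distance
    # init. Later pipeline stages pass the previous stage's converged value:
    # re-initializing to the (huge) default can re-flatten the posteriors and
    # drive an already-aligned source toward the collapsed fixed point.
    sigma2_init: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.stage not in ("rigid", "affine", "deformable"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class CPDResult:
    points: np.ndarray  # transformed source
    sigma2: float
    n_iters: int
    rotation: np.ndarray | None = None  # rigid
    translation: np.ndarray | None = None  # rigid/affine
    linear: np.ndarray | None = None  # affine map B
    coefficients: np.ndarray | None = None  # deformable W


def _init_sigma2(x: np.ndarray, y: np.ndarray) -> float:
    m, d = y.shape
    n = x.shape[0]
    diff2 = (
        n * np.sum(y * y)
        + m * np.sum(x * x)
        - 2.0 * np.sum(x, axis=0) @ np.sum(y, axis=0)
    )
    return diff2 / (d * m * n)


def _posterior(x: np.ndarray, ty: np.ndarray, sigma2: float, w: float) -> np.ndarray:
    """E-step responsibilities P (M x N)."""
    m, d = ty.shape
    n = x.shape[0]
    dist2 = (
        np.sum(ty * ty, axis=1)[:, None]
        + np.sum(x * x, axis=1)[None, :]
        - 2.0 * ty @ x.T
    )
    p = np.exp(-dist2 / (2.0 * sigma2))
    c = (2.0 * np.pi * sigma2) ** (d / 2.0) * w / (1.0 - w) * m / n if w > 0 else 0.0
    denom = p.sum(axis=0) + c
    denom[denom < 1e-300] = 1e-300
    return p / denom[None, :]


def gaussian_kernel(y: np.ndarray, beta: float, y2: np.ndarray | None = None) -> np.ndarray:
    if y2 is None:
        y2 = y
    dist2 = (
        np.sum(y * y, axis=1)[:, None]
        + np.sum(y2 * y2, axis=1)[None, :]
        - 2.0 * y @ y2.T
    )
    return np.exp(-dist2 / (2.0 * beta**2))


def register_cpd(source: np.ndarray, target: np.ndarray, config: CPDConfig) -> CPDResult:
    """Register ``source`` onto ``target`` with the configured stage.

    Returns the moved source points plus the fitted transform parameters.
    """
    y = np.asarray(source, dtype=float).reshape(-1, 3)
    x = np.asarray(target, dtype=float).reshape(-1, 3)
    if y.size == 0 or x.size == 0:
        raise ValueError("point sets must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("point sets must be finite")
    if config.stage == "affine":
        xc = x - x.mean(axis=0)
        if x.shape[0] < 4 or np.linalg.matrix_rank(xc, tol=1e-9) < 3:
            raise ValueError("affine stage needs >= 4 non-coplanar target points")
    if config.stage == "rigid":
        return _register_rigid(y, x, config)
    if config.stage == "affine":
        return _register_affine(y, x, config)
    return _register_deformable(y, x, config)


def _register_rigid(y: np.ndarray, x: np.ndarray, cfg: CPDConfig) -> CPDResult:
    m, d = y.shape
    n = x.shape[0]
    sigma2 = cfg.sigma2_init if cfg.sigma2_init is not None else _init_sigma2(x, y)
    rot = np.eye(d)
    t = np.zeros(d)
    prev = np.inf
    it = 0
    for it in range(1, cfg.max_iters + 1):
        ty = y @ rot.T + t
        p = _posterior(x, ty, sigma2, cfg.outlier_weight)
        np_sum = p.sum()
        mu_x = (p @ x).sum(axis=0) / np_sum
        mu_y = (p.sum(axis=1) @ y) / np_sum
        xh = x - mu_x
        yh = y - mu_y
        a = xh.T @ (p.T @ yh)
        u, _, vt = np.linalg.svd(a)
        c = np.eye(d)
        c[-1, -1] = np.linalg.det(u @ vt)
        rot = u @ c @ vt
        t = mu_x - rot @ mu_y
        # pure rotation + translation (scale fixed at 1)
        tr_arb = np.trace(a.T @ rot)
        xpx = np.sum(p.sum(axis=0) * np.sum(xh * xh, axis=1))
        ypy = np.sum(p.sum(axis=1) * np.sum(yh * yh, axis=1))
        sigma2 = max((xpx - 2.0 * tr_arb + ypy) / (np_sum * d), 1e-12)
        if abs(prev - sigma2) < cfg.tolerance:
            break
        prev = sigma2
    return CPDResult(points=y @ rot.T + t, sigma2=sigma2, n_iters=it, rotation=rot, translation=t)


def _register_affine(y: np.ndarray, x: np.ndarray, cfg: CPDConfig) -> CPDResult:
    m, d = y.shape
    sigma2 = cfg.sigma2_init if cfg.sigma2_init is not None else _init_sigma2(x, y)
    b = np.eye(d)
    t = np.zeros(d)
    prev = np.inf
    it = 0
    for it in range(1, cfg.max_iters + 1):
        ty = y @ b.T + t
        p = _posterior(x, ty, sigma2, cfg.outlier_weight)
        np_sum = p.sum()
        mu_x = (p @ x).sum(axis=0) / np_sum
        mu_y = (p.sum(axis=1) @ y) / np_sum
        xh = x - mu_x
        yh = y - mu_y
        a = xh.T @ (p.T @ yh)
        ypy_mat = yh.T @ (p.sum(axis=1)[:, None] * yh)
        b = a @ np.linalg.inv(ypy_mat)
        t = mu_x - b @ mu_y
        xpx = np.sum(p.sum(axis=0) * np.sum(xh * xh, axis=1))
        sigma2 = max((xpx - np.trace(a @ b.T)) / (np_sum * d), 1e-12)
        if abs(prev - sigma2) < cfg.tolerance:
            break
        prev = sigma2
    return CPDResult(points=y @ b.T + t, sigma2=sigma2, n_iters=it, linear=b, translation=t)


def _register_deformable(y: np.ndarray, x: np.ndarray, cfg: CPDConfig) -> CPDResult:
    m, d = y.shape
    sigma2 = cfg.sigma2_init if cfg.sigma2_init is not None else _init_sigma2(x, y)
    g = gaussian_kernel(y, cfg.beta)
    w = np.zeros((m, d))
    prev = np.inf
    it = 0
    for it in range(1, cfg.max_iters + 1):
        ty = y + g @ w
        p = _posterior(x, ty, sigma2, cfg.outlier_weight)
        p1 = p.sum(axis=1)
        np_sum = p1.sum()
        px = p @ x
        a = g * p1[:, None] + cfg.alpha * sigma2 * np.eye(m)
        w = np.linalg.solve(a, px - p1[:, None] * y)
        ty = y + g @ w
        xpx = np.sum(p.sum(axis=0) * np.sum(x * x, axis=1))
        trpxy = np.sum(px * ty)
        typty = np.sum(p1 * np.sum(ty * ty, axis=1))
        sigma2 = max((xpx - 2.0 * trpxy + typty) / (np_sum * d), 1e-12)
        if abs(prev - sigma2) < cfg.tolerance:
            break
        prev = sigma2
    return CPDResult(points=y + g @ w, sigma2=sigma2, n_iters=it, coefficients=w)


def register_pipeline(
    coarse: QuadSurface,
    mats: SubdivisionMatrices,
    target_points: np.ndarray,
    alpha1: float = 3.0,
    beta1: float = 15.0,
    alpha2: float = 3.0,
    beta2: float = 7.0,
    skip_coarse: bool = False,
    max_iters_coarse: int = 60,
    max_iters_fine: int = 15,
    tolerance: float = 1e-5,
) -> QuadSurface:
    """Two-stage template-to-target registration.

    Rigid -> affine -> deformable (alpha1, beta1) on the coarse grid, two
    subdivision passes to the fine grid, then a second deformable refinement
    (alpha2, beta2). With ``skip_coarse`` the three stages run directly on the
    already-fine template (``coarse`` is then the fine surface and ``mats`` is
    ignored). Grid topology (U, V ordering) is preserved throughout.
    """
    target_points = np.asarray(target_points, dtype=float).reshape(-1, 3)
    sigma2 = [None]  # carried across stages so posteriors stay sharp

    def _run(surface: QuadSurface, stage: str, alpha: float, beta: float, iters: int) -> QuadSurface:
        cfg = CPDConfig(alpha=alpha, beta=beta, stage=stage, max_iters=iters,
                        tolerance=tolerance, sigma2_init=sigma2[0])
        res = register_cpd(surface.points(), target_points, cfg)
        sigma2[0] = res.sigma2
        logger.debug("CPD %s stage: %d iters, sigma2=%.3g", stage, res.n_iters, res.sigma2)
        return surface.with_nodes(res.points.reshape(surface.nodes.shape))

    if skip_coarse:
        surf = _run(coarse, "rigid", alpha1, beta1, max_iters_coarse)
        surf = _run(surf, "affine", alpha1, beta1, max_iters_coarse)
        surf = _run(surf, "deformable", alpha2, beta2, max_iters_fine)
        return surf

    surf = _run(coarse, "rigid", alpha1, beta1, max_iters_coarse)
    surf = _run(surf, "affine", alpha1, beta1, max_iters_coarse)
    surf = _run(surf, "deformable", alpha1, beta1, max_iters_coarse)
    mid = subdivide(surf, mats)
    from .geometry import build_subdivision_matrices

    mats2 = build_subdivision_matrices(*mid.shape)
    fine = subdivide(mid, mats2)
    fine = _run(fine, "deformable", alpha2, beta2, max_iters_fine)
    return fine
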