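"""Analytic synthetic-flow fixtures: tube geometries, laminar velocity
fields with pulsatile modulation, closed-form wall shear stress labels,
voxelization to MRI-like grids, and venc-scaled Gaussian noise.

These stand in for high-resolution CFD as the source of training and
ground-truth data. On a straight tube of radius R (mm) carrying a Poiseuille
profile with centerline velocity Vmax (m/s), the wall shear stress is exactly

    tau_w = 2 * mu * Vmax / R        (R converted to meters)

which makes every label testable against a closed form. Tapered tubes use the
local-cross-section (quasi-1D) version of the same formula with the local
radius and mass-conserving local Vmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flatmap import (
    AnalyticSource,
    Flatmap,
    GridSource,
    build_branch_mask,
    inner_coordinates,
    inward_normals,
    sample_velocity_sheet,
    TRAINING_SHEET_DISTANCES,
)
from .geometry import QuadSurface, build_fine_template

MM = 1e-3  # mm -> m


def raised_cosine_waveform(
    t_ms: np.ndarray,
    period_ms: float = 800.0,
    systole_ms: float = 300.0,
    baseline: float = 0.25,
) -> np.ndarray:
    """Periodic scale s(t) >= 0: raised-cosine systolic pulse on a baseline.

    ``baseline`` is the diastolic fraction of peak flow; the pulse spans
    ``systole_ms`` at the start of the cycle and peaks at s = 1.
    """
    t = np.asarray(t_ms, dtype=float) % period_ms
    s = np.full_like(t, baseline)
    in_pulse = t < systole_ms
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * t[in_pulse] / systole_ms))
    s[in_pulse] = baseline + (1.0 - baseline) * pulse
    return s


@dataclass
class FlowModel:
    """Physical and acquisition parameters of one synthetic flow case.

    mu: dynamic viscosity (Pa s); rho: density (kg/m^3); venc: velocity
    encoding limit (m/s); R: tube radius (mm); Vmax_peak: peak-systole
    centerline velocity (m/s); period: cycle length T (ms).
    """

    mu: float = 4e-3
    rho: float = 1060.0
    venc: float = 1.5
    R: float = 10.0
    Vmax_peak: float = 1.0
    period: float = 800.0
    systole: float = 300.0
    baseline: float = 0.25
    taper_amplitude: float = 0.0  # fractional radius modulation along the tube
    taper_cycles: float = 1.0
    length: float = 372.0  # mm; 93 stations at 4 mm

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.period <= 0 or self.R <= 0:
            raise ValueError("mu, period, and R must be positive")

    def waveform(self, t_ms) -> np.ndarray:
        return raised_cosine_waveform(
            t_ms, period_ms=self.period, systole_ms=self.systole, baseline=self.baseline
        )

    def radius_at(self, z_mm) -> np.ndarray:
        """Local radius R(z) (mm); sinusoidal taper along the axis."""
        z = np.asarray(z_mm, dtype=float)
        return self.R * (
            1.0
            + self.taper_amplitude
            * np.sin(2.0 * np.pi * self.taper_cycles * z / self.length)
        )

    def vmax_at(self, z_mm, t_ms: float) -> np.ndarray:
        """Local centerline velocity (m/s); flow-rate conserving: Vmax ~ R^-2."""
        s = float(self.waveform(np.asarray([t_ms]))[0])
        r = self.radius_at(z_mm)
        return s * self.Vmax_peak * (self.R / r) ** 2

    def wall_wss(self, z_mm, t_ms: float) -> np.ndarray:
        """Analytic wall WSS magnitude (Pa): 2 mu Vmax(z,t) / R(z)."""
        r_m = self.radius_at(z_mm) * MM
        return 2.0 * self.mu * self.vmax_at(z_mm, t_ms) / r_m


def poiseuille_field(model: FlowModel, t_ms: float) -> AnalyticSource:
    """Analytic velocity source for a z-axis tube at time ``t_ms``.

    u_z(r, z, t) = Vmax(z, t) * (1 - r^2 / R(z)^2) inside the lumen, zero
    outside. With zero taper this is exact Poiseuille flow with wall shear
    2 mu Vmax / R; with taper it is the per-cross-section laminar profile.
    """

    def func(points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        r = np.hypot(points[:, 0], points[:, 1])
        rad = model.radius_at(points[:, 2])
        vmax = model.vmax_at(points[:, 2], t_ms)
        uz = np.where(r <= rad, vmax * (1.0 - (r / rad) ** 2), 0.0)
        v = np.zeros_like(points)
        v[:, 2] = uz
        return v

    return AnalyticSource(func, venc=model.venc)


def power_law_field(model: FlowModel, t_ms: float, exponent: float = 9.0) -> AnalyticSource:
    """Blunt (plug-like) profile u_z = Vmax (1 - (r/R)^n); wall shear is
    n mu Vmax / R, steeper near the wall than the parabolic profile."""

    def func(points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        r = np.hypot(points[:, 0], points[:, 1])
        rad = model.radius_at(points[:, 2])
        vmax = model.vmax_at(points[:, 2], t_ms)
        uz = np.where(r <= rad, vmax * (1.0 - (r / rad) ** exponent), 0.0)
        v = np.zeros_like(points)
        v[:, 2] = uz
        return v

    return AnalyticSource(func, venc=model.venc)


def power_law_wall_wss(model: FlowModel, z_mm, t_ms: float, exponent: float = 9.0) -> np.ndarray:
    r_m = model.radius_at(z_mm) * MM
    return exponent * model.mu * model.vmax_at(z_mm, t_ms) / r_m


def oscillating_wss_series(
    reversal_fraction: float,
    n_frames: int = 200,
    period_ms: float = 1024.0,
    magnitude: float = 1.0,
    axis=(1.0, 0.0, 0.0),
    grid_shape: tuple[int, int] = (4, 8),
):
    """WSS series whose direction flips 180 degrees for a fraction of the cycle.

    Sign changes sit midway between frames so the trapezoidal vector integral
    equals the ideal square-wave value exactly; the closed-form OSI is then
    0.5 * reversal_fraction / 0.5 ... i.e. OSI = reversal_fraction when the
    magnitudes are equal (0 -> 0, 0.5 -> full reversal).

    Returns (frames, times_ms): a list of 3-channel Flatmaps and their times.
    To make the trapezoid rule land exactly on the square-wave integrals, the
    number of intervals n satisfies: positive samples a+1, negative n-a, with
    (2a + 1 - n)/n = 1 - 2 f. Frame counts are adjusted to the nearest count
    that admits an integer a.
    """
    if not 0.0 <= reversal_fraction <= 0.5:
        raise ValueError("reversal fraction must be in [0, 0.5]")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    n_int = n_frames - 1
    signs = np.ones(n_frames)
    if reversal_fraction > 0.0:
        # last positive sample index a chosen so that
        # trapz(sign) / trapz(|sign|) = (2a + 1 - n_int) / n_int = 1 - 2f
        a_exact = ((1.0 - 2.0 * reversal_fraction) * n_int + n_int - 1.0) / 2.0
        a = int(round(a_exact))
        a = min(max(a, 0), n_int - 1)
        signs[a + 1 :] = -1.0
    times = np.linspace(0.0, period_ms, n_frames)
    frames = []
    mask = np.ones(grid_shape, dtype=bool)
    for s in signs:
        vec = magnitude * s * axis
        values = np.broadcast_to(vec, grid_shape + (3,)).copy()
        frames.append(Flatmap(values, mask, ("wss_x", "wss_y", "wss_z")))
    return frames, times


@dataclass
class GridSpec:
    """Synthetic-MRI sampling: isotropic spacing dx (mm), frame spacing dt
    (ms), and Gaussian noise SD as a fraction of venc."""

    dx: float = 2.4
    dt: float = 40.0
    noise_sd_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.noise_sd_frac < 0:
            raise ValueError("noise SD fraction must be >= 0")


def voxelize(
    src: AnalyticSource,
    spec: GridSpec,
    bbox: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | None = None,
) -> GridSource:
    """Sample an analytic field onto a uniform voxel grid and add noise.

    Voxel centers start at ``bbox[0]``; values outside the lumen are zero by
    construction of the analytic fields. Noise is N(0, (noise_sd_frac*venc)^2)
    per velocity component over the whole grid.
    """
    lo = np.asarray(bbox[0], dtype=float)
    hi = np.asarray(bbox[1], dtype=float)
    if np.any(hi - lo <= 0):
        raise ValueError("degenerate bounding box")
    counts = np.maximum(np.ceil((hi - lo) / spec.dx).astype(int) + 1, 2)
    axes = [lo[k] + spec.dx * np.arange(counts[k]) for k in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    v, _ = src.sample(pts)
    values = v.reshape(*counts, 3)
    if spec.noise_sd_frac > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        sd = spec.noise_sd_frac * src.venc
        values = values + rng.normal(0.0, sd, size=values.shape)
    return GridSource(values, spacing=spec.dx, origin=lo, venc=src.venc)


@dataclass
class FlowSample:
    """One geometry at one time frame: network inputs plus exact labels."""

    surface: QuadSurface
    wall: Flatmap
    inner: dict  # distance (mm) -> Flatmap of inner coordinates
    sheets: dict  # distance (mm) -> VelocitySheet
    label: Flatmap  # 3-channel WSS (Pa)
    mask: np.ndarray
    time_ms: float
    model: FlowModel


@dataclass
class FlowCase:
    """One geometry over a cardiac cycle."""

    model: FlowModel
    surface: QuadSurface
    frames: list  # of FlowSample
    times: np.ndarray


def _tube_surface(model: FlowModel) -> QuadSurface:
    z = np.linspace(0.0, model.length, 93)
    centerline = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
    return build_fine_template(centerline, model.radius_at(z))


def analytic_wss_label(model: FlowModel, surface: QuadSurface, t_ms: float) -> Flatmap:
    """Exact WSS vectors on the template: magnitude 2 mu Vmax(z)/R(z), directed
    along the flow (+z), tangential to the wall."""
    z = surface.nodes[:, :, 2]
    mag = model.wall_wss(z, t_ms)
    values = np.zeros(surface.shape + (3,))
    values[:, :, 2] = mag
    return Flatmap(values, np.ones(surface.shape, dtype=bool), ("wss_x", "wss_y", "wss_z"))


def make_case(
    model: FlowModel,
    times_ms: np.ndarray,
    sheet_distances=TRAINING_SHEET_DISTANCES,
    source_factory=poiseuille_field,
    grid_spec: GridSpec | None = None,
    rng: np.random.Generator | None = None,
) -> FlowCase:
    """Build surface, inner coordinate flatmaps, velocity sheets at all
    requested distances, and exact WSS labels for every frame.

    With ``grid_spec`` the analytic field is first voxelized (synthetic MRI)
    and sheets are interpolated from the grid; otherwise sheets are sampled
    from the analytic field directly (CFD-point-cloud analogue).
    """
    surface = _tube_surface(model)
    normals = inward_normals(surface)
    wall = Flatmap(surface.nodes.copy(), normals.mask.copy(), ("x", "y", "z"))
    mask = build_branch_mask(surface)
    inner = {d: inner_coordinates(surface, d, normals) for d in sheet_distances}
    frames = []
    times_ms = np.asarray(times_ms, dtype=float)
    for t in times_ms:
        src = source_factory(model, t)
        if grid_spec is not None:
            pts = surface.points()
            lo = pts.min(axis=0) - 2.0 * grid_spec.dx
            hi = pts.max(axis=0) + 2.0 * grid_spec.dx
            src = voxelize(src, grid_spec, (lo, hi), rng=rng)
        sheets = {
            d: sample_velocity_sheet(src, surface, d, normals) for d in sheet_distances
        }
        label = analytic_wss_label(model, surface, t)
        frames.append(
            FlowSample(
                surface=surface,
                wall=wall,
                inner=inner,
                sheets=sheets,
                label=label,
                mask=mask & normals.mask,
                time_ms=float(t),
                model=model,
            )
        )
    return FlowCase(model=model, surface=surface, frames=frames, times=times_ms)


def cycle_sample_times(model: FlowModel, n_systole: int = 6, n_diastole: int = 3) -> np.ndarray:
    """Frame times (ms) covering one cycle, denser through systole.

    Systole carries the full dynamic range of the waveform (including the
    peak at half the systolic interval); diastole is near-constant, so few
    frames are spent there.
    """
    sys_t = np.linspace(0.0, model.systole, n_systole, endpoint=False)
    dia_t = np.linspace(model.systole, model.period, n_diastole, endpoint=False)
    return np.concatenate([sys_t, dia_t])


def make_dataset(
    n_geometries: int = 8,
    seed: int = 0,
    n_frames: int | None = None,
    radius_range=(8.0, 12.0),
    vmax_range=(0.8, 1.4),
    taper_range=(0.08, 0.18),
    sheet_distances=TRAINING_SHEET_DISTANCES,
    n_val: int = 1,
    n_test: int = 1,
) -> dict:
    """Generate a train/val/test split of tapered-tube flow cases.

    Geometries vary radius, taper, and peak velocity; the split is by
    geometry so no surface is shared between subsets. Labels are exact
    analytic WSS at every frame.
    """
    if n_geometries < n_val + n_test + 1:
        raise ValueError("need at least one training geometry")
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_geometries):
        model = FlowModel(
            R=rng.uniform(*radius_range),
            Vmax_peak=rng.uniform(*vmax_range),
            taper_amplitude=rng.uniform(*taper_range),
            taper_cycles=rng.uniform(0.75, 1.5),
        )
        if n_frames is None:
            times = cycle_sample_times(model)
        else:
            times = np.linspace(0.0, model.period, n_frames, endpoint=False)
        cases.append(make_case(model, times, sheet_distances))
    return {
        "train": cases[: n_geometries - n_val - n_test],
        "val": cases[n_geometries - n_val - n_test : n_geometries - n_test],
        "test": cases[n_geometries - n_test :],
    }
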