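"""Hemodynamic evaluation metrics.

Per-frame agreement (MAE on WSS magnitude, relative error against the peak
reference WSS, Pearson pattern correlation), cycle-integrated maps (TAWSS,
OSI via the trapezoidal rule), and agreement statistics (ICC(A,1),
Bland-Altman limits, ordinary least squares). All map-level metrics ignore
masked nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .flatmap import Flatmap


@dataclass
class WSSSeries:
    """Time-ordered 3-channel WSS flatmaps spanning one cardiac cycle.

    ``times`` in ms, strictly increasing; all frames share the mask.
    """

    frames: list
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a WSS series needs at least 2 frames")
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times must pair up")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        m0 = self.frames[0].mask
        for f in self.frames[1:]:
            if f.mask.shape != m0.shape:
                raise ValueError("frames must share a grid")

    @property
    def mask(self) -> np.ndarray:
        m = self.frames[0].mask.copy()
        for f in self.frames[1:]:
            m &= f.mask
        return m

    def stack(self) -> np.ndarray:
        """(n_t, n_U, n_V, 3) array of WSS vectors."""
        return np.stack([f.values for f in self.frames], axis=0)


def tawss(series: WSSSeries) -> Flatmap:
    """Time-averaged WSS magnitude (Pa): (1/T) integral |wss| dt, trapezoidal."""
    w = series.stack()
    mag = np.linalg.norm(w, axis=3)
    t = series.times
    span = t[-1] - t[0]
    avg = np.trapezoid(mag, t, axis=0) / span
    return Flatmap(avg[:, :, None], series.mask, ("tawss",))


def osi(series: WSSSeries) -> Flatmap:
    """Oscillatory shear index in [0, 0.5].

    0.5 * (1 - |integral wss dt| / integral |wss| dt); 0 for a constant
    direction, 0.5 for an equal-magnitude 180-degree reversal over half the
    cycle. Nodes whose magnitude integral vanishes are masked.
    """
    w = series.stack()
    t = series.times
    vec_int = np.trapezoid(w, t, axis=0)  # (nU, nV, 3)
    mag_int = np.trapezoid(np.linalg.norm(w, axis=3), t, axis=0)
    valid = series.mask & (mag_int > 0)
    ratio = np.zeros_like(mag_int)
    ratio[valid] = np.linalg.norm(vec_int, axis=2)[valid] / mag_int[valid]
    # |integral| <= integral of magnitudes, so OSI lies in [0, 0.5]; clip
    # the one-ulp excursions floating point can produce at the endpoints
    values = np.clip(0.5 * (1.0 - ratio), 0.0, 0.5)
    values[~valid] = 0.0
    return Flatmap(values[:, :, None], valid, ("osi",))


def frame_errors(pred: Flatmap, ref: Flatmap) -> dict:
    """Per-frame magnitude agreement over jointly valid nodes.

    mae: mean |dmag| (Pa); rel_error: mean |dmag| / max(ref mag) * 100 (%);
    pearson: correlation of the magnitude images (None when the reference is
    spatially constant).
    """
    mask = pred.mask & ref.mask
    if mask.sum() < 2:
        raise ValueError("need at least 2 jointly valid nodes")
    pm = np.linalg.norm(pred.values, axis=2)[mask]
    rm = np.linalg.norm(ref.values, axis=2)[mask]
    diff = np.abs(pm - rm)
    mae = float(diff.mean())
    peak = float(rm.max())
    rel = float(diff.mean() / peak * 100.0) if peak > 0 else float("nan")
    if np.ptp(rm) == 0:
        pearson = None
    else:
        pearson = float(stats.pearsonr(pm, rm)[0])
    return {"mae": mae, "rel_error": rel, "pearson": pearson}


def icc_a1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): single-measure absolute agreement, two-way model.

    McGraw & Wong: (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n) with
    k = 2 raters and n subjects.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    data = np.stack([x, y], axis=1)  # n subjects x k raters
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: no variance in either rater")
    return float((msr - mse) / denom)


def bland_altman(x: np.ndarray, y: np.ndarray) -> dict:
    """Bias and 95% limits of agreement of y - x."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired values")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def linreg(x: np.ndarray, y: np.ndarray) -> dict:
    """Ordinary least squares y = k x + b; returns slope, intercept, R^2."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }


def evaluate_series(pred: WSSSeries, ref: WSSSeries) -> dict:
    """Full comparison of two WSS series on the same grid.

    Per-frame MAE / relative error / Pearson, plus TAWSS and OSI agreement
    (ICC, Bland-Altman, OLS) over jointly valid nodes.
    """
    per_frame = [frame_errors(p, r) for p, r in zip(pred.frames, ref.frames)]
    t_pred, t_ref = tawss(pred), tawss(ref)
    o_pred, o_ref = osi(pred), osi(ref)
    mask = t_pred.mask & t_ref.mask
    tp, tr = t_pred.values[mask, 0], t_ref.values[mask, 0]
    omask = o_pred.mask & o_ref.mask
    op, orf = o_pred.values[omask, 0], o_ref.values[omask, 0]
    out = {
        "per_frame": per_frame,
        "mae_mean": float(np.mean([f["mae"] for f in per_frame])),
        "rel_error_mean": float(np.mean([f["rel_error"] for f in per_frame])),
        "pearson_mean": float(
            np.mean([f["pearson"] for f in per_frame if f["pearson"] is not None])
        ),
        "tawss": {
            "icc_a1": icc_a1(tr, tp),
            "bland_altman": bland_altman(tr, tp),
            "linreg": linreg(tr, tp),
        },
    }
    if np.ptp(orf) > 0:
        out["osi"] = {
            "bland_altman": bland_altman(orf, op),
            "linreg": linreg(orf, op),
        }
    return out
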