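"""Translational and rotational diffusion estimation.

Translational coefficients come from the Einstein relation for lateral
Brownian motion, MSD(lag) = 4 D lag, fitted by weighted least squares
with a free intercept over an intermediate lag window (default 10-50%
of the maximum lag: short lags carry localisation-scale artefacts,
long lags too few origin pairs). Rotational coefficients come from the
planar-rotor orientation autocorrelation C(lag) = <cos(dtheta)> =
exp(-Dr lag), fitted log-linearly where C >= 0.3.

Diffusion is stored in nm^2/us; 1 nm^2/us == 1e-8 cm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import BoxSpec
from .trajectory import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "msd",
    "fit_diffusion",
    "rotational_acf",
    "convert_units",
    "replica_aggregate",
]

_UNIT_TO_NM2_US = {
    "nm2/us": 1.0,
    "cm2/s": 1e8,
    "1e-8cm2/s": 1.0,
    "1e-9cm2/s": 0.1,
}


@dataclass
class MSDCurve:
    """Time- and ensemble-averaged mean squared lateral displacement."""

    lags: np.ndarray  # us
    values: np.ndarray  # nm^2
    n_samples: np.ndarray  # origin x particle pairs per lag


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient with fit window and error, unit-safe."""

    D: float  # nm^2/us
    error: float  # nm^2/us
    window: tuple[float, float]  # lag range used, us
    method: str  # 'translational' | 'rotational'
    n_replicas: int = 1

    def in_units(self, unit: str) -> float:
        return convert_units(self.D, "nm2/us", unit)


def _check_unwrapped(positions: np.ndarray, box: BoxSpec) -> None:
    steps = np.abs(np.diff(positions, axis=0))
    L = box.in_plane_lengths
    if steps.size and np.any(steps > 0.75 * L):
        raise ValueError(
            "trajectory looks wrapped (frame-to-frame jumps near the box length); "
            "unwrap it before computing MSDs"
        )


def msd(traj: Trajectory, selection: np.ndarray | None = None,
        lag_frames: np.ndarray | None = None, origin_stride: int = 1) -> MSDCurve:
    """Lateral MSD averaged over all origins and selected particles.

    The trajectory must hold continuous (unwrapped) coordinates.
    ``lag_frames`` defaults to every lag up to half the run length.
    """
    if traj.n_frames < 2:
        raise ValueError("need >= 2 frames")
    idx = np.arange(traj.n_particles) if selection is None else np.asarray(selection)
    pos = traj.positions[:, idx, :]
    _check_unwrapped(pos, traj.box)
    F = traj.n_frames
    if lag_frames is None:
        lag_frames = np.arange(1, F // 2 + 1)
    lag_frames = np.asarray(lag_frames, dtype=int)
    if np.any(lag_frames < 1) or np.any(lag_frames > F - 1):
        raise ValueError("lag frames must lie in [1, n_frames - 1]")
    values = np.empty(lag_frames.size)
    counts = np.empty(lag_frames.size, dtype=int)
    for k, lag in enumerate(lag_frames):
        disp = pos[lag:] - pos[:-lag]
        disp = disp[::origin_stride]
        sq = (disp**2).sum(axis=-1)
        values[k] = sq.mean()
        counts[k] = sq.size
    lags = traj.times[lag_frames] - traj.times[0]
    return MSDCurve(lags=lags, values=values, n_samples=counts)


def fit_diffusion(curve: MSDCurve, window: tuple[float, float] | None = None,
                  block_error: float | None = None) -> DiffusionEstimate:
    """Fit MSD = 4 D lag + b by weighted least squares (weights = samples).

    Default window keeps lags within 10-50% of the maximum lag. The
    returned error is the fit SE of the slope/4, combined in quadrature
    with ``block_error`` when given.
    """
    if window is None:
        lag_max = curve.lags.max()
        window = (0.1 * lag_max, 0.5 * lag_max)
    sel = (curve.lags >= window[0]) & (curve.lags <= window[1])
    if sel.sum() < 4:
        raise ValueError(f"fit window {window} contains {int(sel.sum())} lags; need >= 4")
    x, y, w = curve.lags[sel], curve.values[sel], curve.n_samples[sel].astype(float)
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    XtW = X.T @ W
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    resid = y - X @ beta
    dof = max(len(x) - 2, 1)
    # weights enter as relative variances: Var(y_i) = sigma^2 / w_i
    s2 = float(resid @ (w * resid)) / dof
    se_slope = float(np.sqrt(s2 * cov[0, 0]))
    slope = float(beta[0])
    if slope < 0:
        warnings.warn("negative MSD slope; reporting D = 0", stacklevel=2)
        D = 0.0
    else:
        D = slope / 4.0
    err = se_slope / 4.0
    if block_error is not None:
        err = float(np.hypot(err, block_error))
    return DiffusionEstimate(D=D, error=err, window=(float(window[0]), float(window[1])),
                             method="translational")


def rotational_acf(traj: Trajectory, selection: np.ndarray | None = None,
                   lag_frames: np.ndarray | None = None,
                   fit_floor: float = 0.3) -> tuple[np.ndarray, np.ndarray, DiffusionEstimate]:
    """Orientation autocorrelation and the rotational diffusion coefficient.

    C(lag) = <cos(theta(t+lag) - theta(t))>; for a free planar rotor
    C = exp(-Dr lag) exactly, so Dr comes from a log-linear fit over the
    well-conditioned region C in [fit_floor, 1).
    """
    if traj.orientations is None:
        raise ValueError("trajectory has no orientation angles")
    idx = traj.receptor_indices if selection is None else np.asarray(selection)
    theta = traj.orientations[:, idx]
    if np.isnan(theta).all():
        raise ValueError("selection has no orientation data")
    F = traj.n_frames
    if lag_frames is None:
        lag_frames = np.arange(1, F // 2 + 1)
    lag_frames = np.asarray(lag_frames, dtype=int)
    C = np.empty(lag_frames.size)
    for k, lag in enumerate(lag_frames):
        d = theta[lag:] - theta[:-lag]
        C[k] = np.nanmean(np.cos(d))
    lags = traj.times[lag_frames] - traj.times[0]
    usable = C >= fit_floor
    if usable.sum() < 2:
        raise ValueError(
            f"autocorrelation drops below {fit_floor} too fast; Dr unidentifiable "
            "at this frame spacing"
        )
    x, y = lags[usable], np.log(C[usable])
    A = np.column_stack([x, np.ones_like(x)])
    beta, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dr = max(-float(beta[0]), 0.0)
    if len(x) > 2:
        resid = y - A @ beta
        s2 = float(resid @ resid) / (len(x) - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        se = float(np.sqrt(cov[0, 0]))
    else:
        se = 0.0
    est = DiffusionEstimate(D=dr, error=se, window=(float(x.min()), float(x.max())),
                            method="rotational")
    return lags, C, est


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert diffusion coefficients between nm^2/us and cm^2/s scales."""
    try:
        a = _UNIT_TO_NM2_US[from_unit]
        b = _UNIT_TO_NM2_US[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown unit {exc.args[0]!r}; known: {sorted(_UNIT_TO_NM2_US)}"
        ) from None
    return value * a / b


def replica_aggregate(estimates: list[DiffusionEstimate]) -> DiffusionEstimate:
    """Unweighted mean over replicas; SEM when n >= 3, else propagated errors."""
    if not estimates:
        raise ValueError("need at least one estimate")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        raise ValueError(f"mixed estimate kinds: {sorted(methods)}")
    vals = np.array([e.D for e in estimates])
    n = len(vals)
    mean = float(vals.mean())
    if n >= 3:
        err = float(vals.std(ddof=1) / np.sqrt(n))
    elif n == 1:
        err = estimates[0].error
    else:
        err = float(np.sqrt(np.sum([e.error**2 for e in estimates])) / n)
    windows = np.array([e.window for e in estimates])
    return DiffusionEstimate(
        D=mean, error=err,
        window=(float(windows[:, 0].min()), float(windows[:, 1].max())),
        method=estimates[0].method, n_replicas=n,
    )
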