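"""BRET saturation-curve analysis.

Bioluminescence resonance energy transfer titrations probe receptor
oligomerisation in cells: the acceptor (YFP) level is titrated at fixed
donor (Rluc), and the BRET ratio (fluorescence over luminescence,
reported x1000 in mBU) either saturates hyperbolically (specific
interaction) or grows quasi-linearly (nonspecific bystander transfer).

The saturation model is

    BRET(x) = BRETmax * x / (BRET50 + x)

with x the acceptor expression proxy; BRETmax is the plateau and BRET50
the acceptor level giving half of it. Hyperbolic vs linear(-through-
origin) is decided by an extra-sum-of-squares F test. Condition effects
on fitted parameters are assessed with a paired two-sided t test across
independent experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BRETTitration",
    "SaturationFit",
    "bret_ratio",
    "fit_saturation",
    "select_model",
    "compare_conditions",
    "synthesize_titration",
]


@dataclass
class BRETTitration:
    """Titration points: acceptor proxy x vs BRET ratio y (mBU)."""

    x: np.ndarray  # acceptor expression proxy (AU)
    y: np.ndarray  # BRET ratio, mBU
    condition: str = ""
    replicate: int = 0
    construct_pair: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have matching shapes")
        if np.any(self.y < 0):
            raise ValueError("BRET ratios must be >= 0")

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.x).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y_mBU": self.y,
                             "condition": self.condition,
                             "replicate": self.replicate})


@dataclass
class SaturationFit:
    """Hyperbolic (or fallback linear) fit of one titration."""

    bret_max: float  # mBU (hyperbolic) or slope (linear fallback)
    bret50: float  # AU; NaN for the linear model
    se_bret_max: float
    se_bret50: float
    residual_variance: float
    model: str  # 'hyperbolic' | 'linear'
    converged: bool = True
    n_points: int = 0
    details: dict = field(default_factory=dict)


def bret_ratio(fluorescence, luminescence, background: tuple[float, float] = (0.0, 0.0)):
    """Background-corrected BRET ratio in mBU: 1000 (F - F_bg)/(L - L_bg)."""
    f = np.asarray(fluorescence, dtype=float)
    lum = np.asarray(luminescence, dtype=float)
    f_bg, l_bg = background
    corrected_l = lum - l_bg
    if np.any(corrected_l <= 0):
        raise ValueError("corrected luminescence must be positive in every well")
    out = 1000.0 * (f - f_bg) / corrected_l
    return float(out) if out.ndim == 0 else out


def _hyperbola(x, bmax, b50):
    return bmax * x / (b50 + x)


def fit_saturation(titration: BRETTitration, multistart: int = 5) -> SaturationFit:
    """Nonlinear least-squares fit of the saturation hyperbola.

    Positivity is enforced through bounds; several starting points are
    tried and the best sum of squares kept. On non-convergence the fit
    falls back to the linear (bystander) model, flagged in ``model``.
    """
    x, y = titration.x, titration.y
    if titration.n_levels < 4:
        raise ValueError(f"need >= 4 distinct acceptor levels, got {titration.n_levels}")
    ymax = float(y.max()) if y.max() > 0 else 1.0
    xmed = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    starts = [(ymax, xmed), (2 * ymax, xmed / 2), (1.5 * ymax, 2 * xmed),
              (ymax / 2, xmed), (3 * ymax, xmed)][:multistart]
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _hyperbola, x, y, p0=p0,
                bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        ss = float(np.sum((y - _hyperbola(x, *popt)) ** 2))
        if best is None or ss < best[2]:
            best = (popt, pcov, ss)
    n = len(x)
    if best is None:
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        s2 = float(resid @ resid) / max(n - 1, 1)
        se = float(np.sqrt(s2 / np.sum(x * x)))
        return SaturationFit(bret_max=slope, bret50=np.nan, se_bret_max=se,
                             se_bret50=np.nan, residual_variance=s2,
                             model="linear", converged=False, n_points=n)
    popt, pcov, ss = best
    s2 = ss / max(n - 2, 1)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return SaturationFit(
        bret_max=float(popt[0]), bret50=float(popt[1]),
        se_bret_max=float(se[0]), se_bret50=float(se[1]),
        residual_variance=s2, model="hyperbolic", n_points=n,
        details={"ss": ss},
    )


def select_model(titration: BRETTitration, alpha: float = 0.05) -> dict:
    """Hyperbolic vs linear-through-origin by extra-sum-of-squares F test.

    The 1-parameter proportional model is nested in spirit (a hyperbola
    far from saturation); the F statistic compares its residual sum of
    squares against the 2-parameter hyperbola.
    """
    x, y = titration.x, titration.y
    if titration.n_levels <= 2:
        raise ValueError("degenerate design: need > 2 distinct acceptor levels")
    n = len(x)
    slope = float(np.sum(x * y) / np.sum(x * x)) if np.any(x != 0) else 0.0
    ss_lin = float(np.sum((y - slope * x) ** 2))
    hyp = fit_saturation(titration)
    if hyp.model != "hyperbolic":
        return {"model": "linear", "F": np.nan, "p": np.nan, "slope": slope,
                "flag": "hyperbolic fit failed"}
    ss_hyp = hyp.details["ss"]
    df_extra, df_resid = 1, n - 2
    flag = None
    if ss_hyp <= 0:
        model, F, p = "hyperbolic", np.inf, 0.0
    else:
        F = (ss_lin - ss_hyp) / df_extra / (ss_hyp / df_resid)
        p = float(stats.f.sf(max(F, 0.0), df_extra, df_resid))
        model = "hyperbolic" if p < alpha else "linear"
    if model == "linear" and abs(slope) * float(np.max(x)) < 1e-9 * max(float(np.max(np.abs(y))), 1.0):
        flag = "uninformative: flat response"
    return {"model": model, "F": float(F), "p": p, "slope": slope,
            "hyperbolic_fit": hyp, "flag": flag}


def compare_conditions(fits_a: list, fits_b: list, parameter: str = "bret_max",
                       confidence: float = 0.95) -> dict:
    """Paired two-sided t test on a fit parameter across experiments.

    ``fits_a`` and ``fits_b`` are equal-length lists of SaturationFit
    (or raw numbers), paired by experiment.
    """
    def extract(fits):
        return np.array([
            getattr(f, parameter) if isinstance(f, SaturationFit) else float(f)
            for f in fits
        ])

    a, b = extract(fits_a), extract(fits_b)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need >= 2 paired experiments")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        # identical pairs: no evidence against the null by convention
        t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf * np.sign(diff.mean()), 0.0)
    else:
        t, p = stats.ttest_rel(a, b)
    sem = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + confidence / 2, n - 1)
    mean_diff = float(diff.mean())
    return {
        "t": float(t), "p": float(p), "df": n - 1,
        "mean_difference": mean_diff,
        "ci": (mean_diff - tcrit * sem, mean_diff + tcrit * sem),
        "n": n, "parameter": parameter,
    }


def synthesize_titration(bret_max: float = 100.0, bret50: float = 0.5,
                         x_levels: np.ndarray | None = None, noise: float = 0.05,
                         replicates: int = 3, mode: str = "specific",
                         seed: int = 0, slope: float | None = None,
                         condition: str = "", replicate_id: int = 0) -> BRETTitration:
    """Generate a synthetic titration: hyperbolic (specific) or linear (bystander).

    ``noise`` is multiplicative Gaussian noise (fractional SD); each x
    level is measured in ``replicates`` wells, mirroring triplicate
    plate layouts. Deterministic per seed.
    """
    if mode not in ("specific", "bystander"):
        raise ValueError("mode must be 'specific' or 'bystander'")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    if x_levels is None:
        x_levels = np.linspace(0.25, 3.7, 8) / 3.7  # acceptor dose range, normalised
    x_levels = np.asarray(x_levels, dtype=float)
    x = np.repeat(x_levels, replicates)
    if mode == "specific":
        y_true = _hyperbola(x, bret_max, bret50)
    else:
        y_true = (slope if slope is not None else bret_max / (bret50 + x_levels.max())) * x
    rng = np.random.default_rng(seed)
    y = y_true * (1.0 + noise * rng.standard_normal(x.size)) if noise > 0 else y_true.copy()
    y = np.clip(y, 0.0, None)
    return BRETTitration(x=x, y=y, condition=condition, replicate=replicate_id,
                         construct_pair="A2A-Rluc/D2-YFP")
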