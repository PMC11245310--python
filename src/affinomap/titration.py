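"""Titration holdup fitting with the partial-activity single-site model.

A titration holdup varies the effective immobilized-bait concentration by
mixing bait-saturated and control resin in different proportions while the
total resin-to-analyte ratio stays constant. Fraction bound follows

    FB(c) = a * c / (c + Kd)

where ``a`` in (0, 1] is the *active fraction*: the part of the prey
population that is binding-competent. a < 1 (partial binding activity) is a
real feature of some preys and is fitted jointly with Kd.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .affinity import kd_to_pk

__all__ = [
    "TitrationCurve",
    "TitrationFit",
    "make_dilution_series",
    "fit_titration",
    "partial_activity_model",
]

KD_BOUNDS = (1e-12, 1e-2)  # molar search window for the fit


@dataclass
class TitrationCurve:
    """Measured (bait concentration, fraction bound) points for one prey."""

    concentrations: np.ndarray  # molar
    fraction_bound: np.ndarray
    label: str = ""
    sd: np.ndarray | None = None  # optional replicate SDs used as weights

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=float)
        if self.concentrations.shape != self.fraction_bound.shape:
            raise ValueError("concentration and fraction_bound lengths differ")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        # raw readouts tolerate noise excursions outside [0, 1]
        if np.any(self.fraction_bound < -0.2) or np.any(self.fraction_bound > 1.2):
            raise ValueError("fraction_bound outside the tolerated raw range [-0.2, 1.2]")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.fraction_bound.shape:
                raise ValueError("sd length differs from fraction_bound")


@dataclass
class TitrationFit:
    """Least-squares estimates of (Kd, active fraction) with standard errors."""

    kd: float  # molar; +inf when no detectable binding
    active_fraction: float
    se_kd: float
    se_active: float
    converged: bool
    no_binding: bool = False

    @property
    def pk(self) -> float:
        return kd_to_pk(self.kd) if math.isfinite(self.kd) else -math.inf


def make_dilution_series(stock_conc: float, proportions) -> np.ndarray:
    """Effective bait concentrations from resin-mixing proportions.

    Mixing a fraction p of bait-saturated resin with (1 - p) control resin at
    constant total resin gives effective bait concentration p * stock.
    """
    props = np.asarray(proportions, dtype=float)
    if np.any(props < 0) or np.any(props > 1):
        raise ValueError("proportions must lie in [0, 1]")
    if stock_conc <= 0:
        raise ValueError("stock concentration must be positive")
    return props * stock_conc


def partial_activity_model(conc, kd: float, active_fraction: float):
    """FB(c) = a * c / (c + Kd)."""
    conc = np.asarray(conc, dtype=float)
    return active_fraction * conc / (conc + kd)


def fit_titration(curve: TitrationCurve, min_signal: float = 0.05) -> TitrationFit:
    """Fit (Kd, a) by least squares on a titration curve.

    Initialization is scale-free: a0 is the largest observed fraction bound
    (clipped into (0, 1]) and Kd0 the concentration whose response is nearest
    a0/2. Standard errors come from the curvature (covariance) at the
    optimum. Curves that never rise above ``min_signal`` are reported as a
    censored no-detectable-binding result instead of a fit.
    """
    conc = curve.concentrations
    fb = curve.fraction_bound
    if np.unique(conc).size < 3:
        raise ValueError("need at least 3 distinct concentrations to fit")
    if float(np.max(fb)) < min_signal:
        return TitrationFit(
            kd=math.inf, active_fraction=0.0, se_kd=math.nan, se_active=math.nan,
            converged=False, no_binding=True,
        )

    a0 = float(np.clip(np.max(fb), 1e-3, 1.0))
    pos = conc[conc > 0]
    half_idx = int(np.argmin(np.abs(fb - a0 / 2.0)))
    kd0 = float(conc[half_idx]) if conc[half_idx] > 0 else float(np.median(pos))
    kd0 = float(np.clip(kd0, *KD_BOUNDS))

    sigma = curve.sd if curve.sd is not None and np.all(curve.sd > 0) else None
    try:
        popt, pcov = curve_fit(
            partial_activity_model,
            conc,
            fb,
            p0=(kd0, a0),
            bounds=([KD_BOUNDS[0], 1e-9], [KD_BOUNDS[1], 1.0]),
            sigma=sigma,
            maxfev=20000,
        )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return TitrationFit(
            kd=kd0, active_fraction=a0, se_kd=math.nan, se_active=math.nan,
            converged=False,
        )
    kd, a = float(popt[0]), float(popt[1])
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (math.nan, math.nan)
    if not (pos.min() <= kd <= pos.max()):
        warnings.warn(
            f"fitted Kd {kd:.3g} M lies outside the titrated concentration range "
            f"[{pos.min():.3g}, {pos.max():.3g}] M; estimate may be poorly constrained",
            stacklevel=2,
        )
    return TitrationFit(
        kd=kd, active_fraction=a,
        se_kd=float(ses[0]), se_active=float(ses[1]),
        converged=converged,
    )
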