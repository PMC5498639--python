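"""Logan and Patlak graphical analysis of tissue TACs.

Both methods linearise the tissue/input relationship after an equilibration
time t*:

* **Logan** (reversible tracers): ordinary least squares of
  ``int_0^t C_T / C_T(t)`` on ``int_0^t Cp / C_T(t)`` over frames with
  mid-time >= t*; the slope estimates the total distribution volume V_T.
* **Patlak** (irreversible uptake): OLS of ``C_T(t)/Cp(t)`` on
  ``int_0^t Cp / Cp(t)``; the slope is the net influx rate Ki (min^-1).

Input integrals accumulate from t = 0 on a merged grid of blood-sample times
and frame mid-times to limit early-time quadrature error.  The parent-
corrected plasma is the default input (``which`` switches to whole blood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DomainError, InsufficientDataError
from .io import BloodSeries, TimeActivityCurve

__all__ = ["GraphicalFit", "logan_vt", "patlak_ki"]


@dataclass
class GraphicalFit:
    method: str  # "Logan" or "Patlak"
    slope: float  # Logan: V_T (dimensionless); Patlak: Ki (min^-1)
    intercept: float
    t_star: float  # minutes
    n_points: int
    r_squared: float
    x: np.ndarray | None = None  # regression coordinates for plotting
    y: np.ndarray | None = None


def _input_on_merged_grid(tac: TimeActivityCurve, blood: BloodSeries, which: str):
    """Cumulative integral of the input at frame mid-times (minutes)."""
    if which == "plasma_corrected":
        if blood.plasma_parent_corrected is None:
            raise DomainError("blood series has no parent-corrected plasma")
        y = blood.plasma_parent_corrected
    elif which == "whole_blood":
        y = blood.whole_blood
    else:
        raise ValueError(which)
    tb = blood.time_min
    mids = tac.schedule.mid_min
    grid = np.unique(np.concatenate([[0.0], tb, mids]))
    vals = np.interp(grid, np.concatenate([[0.0], tb]), np.concatenate([[0.0], y]))
    # flat extension past the last sample (no frames are expected out there
    # for the standard design: last sample at scan end)
    cum = cumulative_trapezoid(vals, grid, initial=0.0)
    cp_mid = np.interp(mids, grid, vals)
    int_cp_mid = np.interp(mids, grid, cum)
    return cp_mid, int_cp_mid


def _tissue_cumint(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative integral of C_T at frame mid-times, from (0, 0)."""
    mids = tac.schedule.mid_min
    t = np.concatenate([[0.0], mids])
    c = np.concatenate([[0.0], tac.activity])
    return cumulative_trapezoid(c, t)[...]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def logan_vt(
    tac: TimeActivityCurve,
    blood: BloodSeries,
    t_star: float = 10.0,
    which: str = "plasma_corrected",
) -> GraphicalFit:
    """Logan graphical V_T with a fixed linearisation start ``t_star`` (min)."""
    return _graphical(tac, blood, t_star, which, method="Logan")


def patlak_ki(
    tac: TimeActivityCurve,
    blood: BloodSeries,
    t_star: float = 20.0,
    which: str = "plasma_corrected",
) -> GraphicalFit:
    """Patlak net-influx slope Ki with a fixed start ``t_star`` (min)."""
    return _graphical(tac, blood, t_star, which, method="Patlak")


def _graphical(tac, blood, t_star, which, method):
    mids = tac.schedule.mid_min
    cp_mid, int_cp_mid = _input_on_merged_grid(tac, blood, which)
    if np.all(cp_mid <= 0):
        raise DomainError("input concentration is identically zero")
    int_ct_mid = _tissue_cumint(tac)
    use = mids >= t_star
    ct = tac.activity

    if method == "Logan":
        denom = ct
    else:
        denom = cp_mid
    bad = use & (denom <= 0)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} frame(s) with zero denominator dropped")
        use &= denom > 0
    if use.sum() < 3:
        raise InsufficientDataError(
            f"only {int(use.sum())} usable frames beyond t* = {t_star} min"
        )

    if method == "Logan":
        x = int_cp_mid[use] / ct[use]
        y = int_ct_mid[use] / ct[use]
    else:
        x = int_cp_mid[use] / cp_mid[use]
        y = ct[use] / cp_mid[use]
    slope, intercept, r2 = _ols(x, y)
    return GraphicalFit(
        method=method,
        slope=slope,
        intercept=intercept,
        t_star=float(t_star),
        n_points=int(use.sum()),
        r_squared=r2,
        x=x,
        y=y,
    )
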