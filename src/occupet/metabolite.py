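"""Population parent-fraction modelling and plasma metabolite correction.

Radiolabelled metabolites accumulate in plasma over the scan, so raw plasma
activity overstates the concentration of intact tracer.  The fraction of
plasma activity that is intact tracer is modelled as an exponential decay to
a plateau,

    f(t) = c + (1 - c) * exp(-k t),        f(0) = 1,

fitted once to samples pooled across animals (a population fit; individual
metabolism varies little for slowly metabolised tracers) and then applied to
each animal's plasma curve:  Cp_parent(t) = Cp(t) * f(t).

The plateau term keeps the form flexible at late times; at c = 0 it reduces
to a plain mono-exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError
from .io import BloodSeries

__all__ = ["ParentFractionModel", "fit_parent_fraction", "correct_plasma"]


@dataclass(frozen=True)
class ParentFractionModel:
    """f(t) = c + (1-c) exp(-k t), t in minutes."""

    plateau: float  # c in [0, 1]
    rate: float  # k in min^-1
    residual_sd: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.plateau <= 1.0):
            raise DomainError("plateau must lie in [0, 1]")
        if self.rate < 0:
            raise DomainError("rate must be >= 0")

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.plateau + (1.0 - self.plateau) * np.exp(-self.rate * t)


def fit_parent_fraction(samples) -> ParentFractionModel:
    """Least-squares fit of the plateau-exponential to pooled samples.

    ``samples`` is an iterable of (time_min, fraction_intact) pairs from all
    animals together.  Requires at least 3 samples with fractions in [0, 1]
    and positive times.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise InsufficientDataError(f"need >= 3 parent-fraction samples, got {len(samples)}")
    t = np.array([s[0] for s in samples], dtype=float)
    f = np.array([s[1] for s in samples], dtype=float)
    if np.any(t <= 0):
        raise DomainError("sample times must be > 0")
    if np.any((f < 0) | (f > 1)):
        raise DomainError("fractions must lie in [0, 1]")

    if np.allclose(f, 1.0):
        warnings.warn("all fractions equal 1; no metabolism detected (k = 0)")
        return ParentFractionModel(plateau=1.0, rate=0.0, residual_sd=0.0)

    def resid(x):
        c, k = x
        return c + (1.0 - c) * np.exp(-k * t) - f

    best = None
    for x0 in ((0.5, 0.05), (0.0, 0.01), (0.8, 0.1), (0.2, 0.005)):
        sol = least_squares(resid, x0, bounds=([0.0, 0.0], [1.0, 10.0]), xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    c, k = best.x
    r = resid(best.x)
    sd = float(np.sqrt(np.mean(r**2)))
    return ParentFractionModel(plateau=float(c), rate=float(k), residual_sd=sd)


def correct_plasma(blood: BloodSeries, model: ParentFractionModel) -> BloodSeries:
    """Apply the parent-fraction model to a plasma curve.

    Fills ``plasma_parent_corrected = plasma * f(t)``; whole blood is left
    untouched.  Refuses to correct a series that was already corrected.
    """
    if blood.parent_corrected_applied:
        raise DomainError("blood series already parent-corrected; refusing to reapply")
    corrected = blood.plasma * model(blood.time_min)
    return BloodSeries(
        sample_time=blood.sample_time.copy(),
        whole_blood=blood.whole_blood.copy(),
        plasma=blood.plasma.copy(),
        plasma_parent_corrected=corrected,
        parent_corrected_applied=True,
    )
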