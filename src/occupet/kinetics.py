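"""One- and two-tissue compartment modelling of tissue TACs.

The measured region signal is modelled as

    C_meas(t) = (1 - Vb) * (h (*) Cp)(t) + Vb * C_wb(t)

where ``Cp`` is the metabolite-corrected (parent) plasma concentration,
``C_wb`` the whole-blood concentration mixed in through the fractional blood
volume ``Vb``, and ``h`` the tissue impulse response.  For the two-tissue
reversible model (2TRCM) with rate constants K1 [ml/min/ml], k2, k3, k4
[min^-1],

    h(t) = phi1 * exp(-theta1 t) + phi2 * exp(-theta2 t)

with theta1, theta2 the roots of theta^2 - (k2+k3+k4) theta + k2 k4 = 0,
phi1 + phi2 = K1 and  ∫h dt = V_T = (K1/k2)(1 + k3/k4).  The one-tissue model
(1TCM) is the k3 = k4 = 0 special case, h(t) = K1 exp(-k2 t).

Frame values are model-curve averages over each frame (the scanner integrates
counts over frames), computed on a fine uniform grid.  Convolution with each
exponential mode is exact for a piecewise-linear input (recursive update per
grid step), so noiseless synthetic data generated by this forward model is
reproduced by an independent stiff ODE integration to high accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError
from .io import BloodSeries, FrameSchedule, StudyConfig, TimeActivityCurve

__all__ = [
    "KineticParams",
    "MacroParams",
    "FitResult",
    "BiExpClearance",
    "impulse_response_2tcm",
    "model_tac",
    "fit_compartment",
    "akaike",
    "derive_macro",
    "fit_biexponential",
    "frame_weights",
    "interpolate_input",
]

_GRID_DT_MIN = 1.0 / 60.0  # 1-s model grid


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Compartment rate constants.  For the 1TCM, k3 = k4 = 0."""

    K1: float  # ml plasma / min / ml tissue
    k2: float  # min^-1
    k3: float = 0.0
    k4: float = 0.0
    Vb: float = 0.0  # fraction of region volume that is blood

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (0.0 <= self.Vb < 1.0):
            raise DomainError("Vb must lie in [0, 1)")


@dataclass(frozen=True)
class MacroParams:
    """Macro-parameters: total distribution volume and binding potential.

    V_T = (K1/k2)(1 + BP_ND),  BP_ND = k3/k4.
    """

    V_T: float
    BP_ND: float

    def __post_init__(self):
        if self.V_T < 0 or self.BP_ND < 0:
            raise DomainError("macro-parameters must be >= 0")


@dataclass
class FitResult:
    model: str  # "1TCM" or "2TRCM"
    params: KineticParams
    macro: MacroParams | None
    stderr: dict = field(default_factory=dict)
    wrss: float = np.nan
    aic: float = np.nan
    r_squared: float = np.nan
    n_frames: int = 0
    converged: bool = False
    near_irreversible: bool = False
    residuals: np.ndarray | None = None


@dataclass
class BiExpClearance:
    """Bi-exponential washout: half-lives in minutes, amplitude shares in %."""

    half_life_fast: float
    half_life_slow: float
    fraction_fast: float
    fraction_slow: float
    degenerate: bool = False  # rates indistinguishable, mono-exponential fit

    def __post_init__(self):
        if self.half_life_fast > self.half_life_slow:
            raise DomainError("fast half-life must not exceed slow half-life")


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def impulse_response_2tcm(params: KineticParams) -> list[tuple[float, float]]:
    """Amplitude/rate pairs [(phi1, theta1), (phi2, theta2)] of the 2TRCM.

    Reduces exactly to the 1TCM form [(K1, k2)] when k3 = 0, and supports the
    irreversible limit k4 = 0 (theta2 = 0, a constant trapping term).
    """
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if k3 == 0.0 and k4 == 0.0:
        return [(K1, k2)]
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:  # impossible for non-negative rates; numeric guard
        disc = 0.0
    d = np.sqrt(disc)
    theta1 = 0.5 * (s + d)
    theta2 = 0.5 * (s - d)
    if theta1 == theta2:
        # degenerate repeated root: treat as single mode (measure zero)
        return [(K1, theta1)]
    phi1 = K1 * (theta1 - k3 - k4) / (theta1 - theta2)
    phi2 = K1 * (k3 + k4 - theta2) / (theta1 - theta2)
    return [(phi1, theta1), (phi2, theta2)]


def expconv(theta: float, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Convolution exp(-theta t) (*) c(t) for piecewise-linear c on grid t.

    Exact for the linear interpolant of ``c`` (recursive closed form per
    segment); handles theta = 0 (running integral) as a limit.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    out = np.zeros_like(c)
    dt = np.diff(t)
    if theta * dt.max() < 1e-12:
        # theta -> 0: plain running integral of c
        out[1:] = np.cumsum(0.5 * (c[1:] + c[:-1]) * dt)
        return out
    e = np.exp(-theta * dt)
    # segment contribution: substitute u = t_{i+1} - s, c(s) = c_{i+1} - b u:
    #   int_0^{dt} (c_{i+1} - b u) e^{-theta u} du = c_{i+1} g0 - b g1
    # with g0 = (1-e)/theta and g1 = int u e^{-theta u} du = (g0 - dt e)/theta
    g0 = -np.expm1(-theta * dt) / theta
    g1 = (g0 - dt * e) / theta
    b = np.diff(c) / dt
    seg = c[1:] * g0 - b * g1
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        from scipy.signal import lfilter

        out[1:] = lfilter([1.0], [1.0, -float(e[0])], seg)
    else:
        for i in range(dt.size):
            out[i + 1] = out[i] * e[i] + seg[i]
    return out


def _tissue_curve(params: KineticParams, t: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Tissue concentration h (*) Cp on the grid (no blood-volume term)."""
    total = np.zeros_like(cp)
    for phi, theta in impulse_response_2tcm(params):
        if phi == 0.0:
            continue
        total = total + phi * expconv(theta, t, cp)
    return total


def frame_average(t: np.ndarray, curve: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a gridded curve over each frame by trapezoid quadrature."""
    start, end = schedule.start_min, schedule.end_min
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (curve[1:] + curve[:-1]) * np.diff(t))])
    cum_at = np.interp(np.concatenate([start, end]), t, cum)
    n = schedule.n_frames
    integ = cum_at[n:] - cum_at[:n]
    return integ / schedule.duration_min


def model_tac(
    params: KineticParams,
    t: np.ndarray,
    cp: np.ndarray,
    schedule: FrameSchedule,
    c_wb: np.ndarray | None = None,
) -> np.ndarray:
    """Frame-averaged model TAC for a gridded parent-plasma input.

    ``t`` is in minutes and must span the schedule; ``c_wb`` (whole blood on
    the same grid) is required when ``params.Vb > 0``.
    """
    tissue = _tissue_curve(params, t, cp)
    if params.Vb > 0:
        if c_wb is None:
            raise DomainError("whole-blood curve required when Vb > 0")
        curve = (1.0 - params.Vb) * tissue + params.Vb * c_wb
    else:
        curve = tissue
    return frame_average(t, curve, schedule)


def interpolate_input(
    blood: BloodSeries, t: np.ndarray, which: str = "plasma_corrected"
) -> np.ndarray:
    """Sampled blood data -> continuous input on the minute grid ``t``.

    Piecewise linear from (0, 0) through the samples; single-exponential tail
    beyond the last sample, rate taken from the last two samples (flat if
    non-decaying).
    """
    ts = blood.time_min
    if which == "plasma_corrected":
        if blood.plasma_parent_corrected is None:
            raise DomainError("blood series has no parent-corrected plasma")
        y = blood.plasma_parent_corrected
    elif which == "plasma":
        y = blood.plasma
    elif which == "whole_blood":
        y = blood.whole_blood
    else:  # pragma: no cover
        raise ValueError(which)
    out = np.interp(t, np.concatenate([[0.0], ts]), np.concatenate([[0.0], y]))
    beyond = t > ts[-1]
    if np.any(beyond):
        if ts.size >= 2 and y[-1] > 0 and y[-2] > y[-1]:
            lam = np.log(y[-2] / y[-1]) / (ts[-1] - ts[-2])
            out[beyond] = y[-1] * np.exp(-lam * (t[beyond] - ts[-1]))
        else:
            out[beyond] = y[-1]
    return out


def frame_weights(schedule: FrameSchedule, decay_constant: float) -> np.ndarray:
    """Default WLS weights: duration * exp(-lambda_phys * t_mid), normalised.

    Inverse of the count-statistics variance heuristic up to a constant.
    """
    w = schedule.duration_min * np.exp(-decay_constant * schedule.mid_min)
    return w / w.mean()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_BOUNDS_LO = {"K1": 1e-4, "k2": 1e-4, "k3": 1e-4, "k4": 1e-4, "Vb": 0.0}
_BOUNDS_HI = {"K1": 5.0, "k2": 5.0, "k3": 5.0, "k4": 5.0, "Vb": 0.3}
_DEFAULT_START = {"K1": 0.1, "k2": 0.3, "k3": 0.2, "k4": 0.1, "Vb": 0.05}


def _grid_for(schedule: FrameSchedule) -> np.ndarray:
    t_end = schedule.end_min[-1]
    n = int(np.ceil(t_end / _GRID_DT_MIN)) + 1
    return np.linspace(0.0, t_end, n)


def fit_compartment(
    tac: TimeActivityCurve,
    blood: BloodSeries,
    model: str = "2TRCM",
    config: StudyConfig | None = None,
    n_multistart: int | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    input_grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Weighted nonlinear least-squares fit of the 1TCM or 2TRCM.

    The parent-corrected plasma drives the compartments; whole blood enters
    only through the (freely estimated) Vb term.  Sampled blood data is
    interpolated (piecewise linear, exponential tail); a caller with a known
    continuous input (synthetic studies) can instead pass ``input_grid`` as
    ``(t_min, cp, c_wb)`` to bypass the interpolation.  ``n_multistart``
    bounded restarts are drawn by log-uniform jitter around the default start
    (fixed ``seed``); the lowest weighted RSS wins.  Non-convergence is
    flagged on the result, never raised.
    """
    config = config or StudyConfig()
    if model not in ("1TCM", "2TRCM"):
        raise ValueError(f"unknown model {model!r}")
    names = ["K1", "k2", "Vb"] if model == "1TCM" else ["K1", "k2", "k3", "k4", "Vb"]
    nms = config.n_multistart if n_multistart is None else n_multistart

    if input_grid is not None:
        t, cp, c_wb = input_grid
    else:
        t = _grid_for(tac.schedule)
        cp = interpolate_input(blood, t, "plasma_corrected")
        c_wb = interpolate_input(blood, t, "whole_blood")
    y = tac.activity
    if weights is None:
        weights = tac.weights
    if weights is None:
        weights = frame_weights(tac.schedule, config.decay_constant)
    sw = np.sqrt(weights)

    def unpack(x):
        kw = dict(zip(names, x))
        return KineticParams(**kw)

    def resid(x):
        p = unpack(x)
        return sw * (model_tac(p, t, cp, tac.schedule, c_wb) - y)

    lo = np.array([_BOUNDS_LO[n] for n in names])
    hi = np.array([_BOUNDS_HI[n] for n in names])
    x0_base = np.array([_DEFAULT_START[n] for n in names])
    rng = np.random.default_rng(seed)

    best = None
    for i in range(max(1, nms)):
        if i == 0:
            x0 = x0_base.copy()
        else:
            jitter = np.exp(rng.uniform(-1.2, 1.2, size=len(names)))
            x0 = x0_base * jitter
            x0[names.index("Vb")] = rng.uniform(0.0, 0.2)
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    result = FitResult(model=model, params=unpack(x0_base), macro=None, n_frames=y.size)
    if best is None:
        result.converged = False
        return result

    params = unpack(best.x)
    res = resid(best.x)
    wrss = float(np.sum(res**2))
    ss_tot = float(np.sum((sw * (y - np.average(y, weights=weights))) ** 2))
    r2 = 1.0 - wrss / ss_tot if ss_tot > 0 else np.nan
    result.params = params
    result.wrss = wrss
    result.r_squared = r2
    result.residuals = res / sw
    result.converged = bool(best.success) or best.status > 0

    # parameter standard errors from the Jacobian at the optimum
    try:
        J = best.jac
        dof = max(y.size - len(names), 1)
        cov = np.linalg.pinv(J.T @ J) * (wrss / dof)
        result.stderr = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except Exception:
        result.stderr = {}

    if model == "2TRCM":
        if params.k4 <= _BOUNDS_LO["k4"] * 1.01:
            result.near_irreversible = True
        if params.k2 > 0 and params.k4 > 0:
            result.macro = derive_macro(params)
    else:
        if params.k2 > 0:
            result.macro = MacroParams(V_T=params.K1 / params.k2, BP_ND=0.0)
    result.aic = akaike(result)
    return result


def akaike(fit: FitResult) -> float:
    """AIC = N ln(WRSS/N) + 2P with P = 3 (1TCM) or 5 (2TRCM)."""
    p = 3 if fit.model == "1TCM" else 5
    n = fit.n_frames
    if fit.wrss <= 0 or not np.isfinite(fit.wrss):
        warnings.warn("zero/invalid WRSS; returning large-negative AIC sentinel")
        return -1e12
    return float(n * np.log(fit.wrss / n) + 2 * p)


def derive_macro(params: KineticParams) -> MacroParams:
    """Exact macro-parameters from rate constants; needs k2 > 0 and k4 > 0."""
    if params.k2 <= 0 or params.k4 <= 0:
        raise DomainError("macro-parameters undefined for k2 = 0 or k4 = 0")
    bp = params.k3 / params.k4
    return MacroParams(V_T=(params.K1 / params.k2) * (1.0 + bp), BP_ND=bp)


# ---------------------------------------------------------------------------
# bi-exponential clearance
# ---------------------------------------------------------------------------

def fit_biexponential(
    tac: TimeActivityCurve, window_min: tuple[float, float] | None = None
) -> BiExpClearance:
    """Fit A_f e^(-a t) + A_s e^(-b t) to the washout phase of a TAC.

    ``window_min`` defaults to (time of peak frame, end of scan); at least 5
    frames must fall inside.  Half-lives are ln2/rate, fractions are amplitude
    shares in percent.  If the two rates land within 5% of each other the fit
    collapses to a mono-exponential and is flagged ``degenerate``.
    """
    mid = tac.schedule.mid_min
    if window_min is None:
        window_min = (float(mid[np.argmax(tac.activity)]), float(mid[-1]))
    sel = (mid >= window_min[0]) & (mid <= window_min[1])
    t, y = mid[sel], tac.activity[sel]
    if t.size < 5:
        raise InsufficientDataError(f"only {t.size} frames in clearance window")
    if np.any(y <= 0):
        raise DomainError("non-positive activity in clearance window")

    t0 = t[0]
    ts = t - t0  # shift so amplitudes refer to window start
    scale = y[0]

    def model(x):
        a1, l1, a2, l2 = x
        return a1 * np.exp(-l1 * ts) + a2 * np.exp(-l2 * ts)

    def resid(x):
        return model(x) - y

    # crude mono-exponential rate for start values
    k0 = max(np.log(y[0] / y[-1]) / max(ts[-1], 1e-9), 1e-4)
    starts = [
        (0.3 * scale, 5 * k0, 0.7 * scale, 0.5 * k0),
        (0.1 * scale, 10 * k0, 0.9 * scale, k0),
        (0.5 * scale, 2 * k0, 0.5 * scale, 0.2 * k0),
        (0.2 * scale, 20 * k0, 0.8 * scale, 0.1 * k0),
    ]
    lo = [0.0, 1e-6, 0.0, 1e-6]
    hi = [10 * scale, 10.0, 10 * scale, 10.0]
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise InsufficientDataError("bi-exponential fit failed from every start")

    a1, l1, a2, l2 = best.x
    if l1 < l2:
        a1, l1, a2, l2 = a2, l2, a1, l1
    if l2 <= 0 or abs(l1 - l2) / l1 < 0.05 or min(a1, a2) < 1e-9 * scale:
        # rates indistinguishable -> mono-exponential
        lnfit = np.polyfit(ts, np.log(y), 1)
        k = max(-lnfit[0], 1e-9)
        hl = float(np.log(2) / k)
        warnings.warn("bi-exponential fit degenerate; reporting mono-exponential")
        return BiExpClearance(hl, hl, 0.0, 100.0, degenerate=True)

    # report amplitudes referred to the window start
    total = a1 + a2
    return BiExpClearance(
        half_life_fast=float(np.log(2) / l1),
        half_life_slow=float(np.log(2) / l2),
        fraction_fast=float(100.0 * a1 / total),
        fraction_slow=float(100.0 * a2 / total),
    )
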