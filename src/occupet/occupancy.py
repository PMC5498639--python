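"""Receptor-occupancy and in vivo ED50 estimation from kinetic endpoints.

Occupancy of the target by a blocking drug is computed from the drop in the
total distribution volume relative to baseline, corrected for the
non-displaceable volume V_ND,

    Occ = (V_T(baseline) - V_T(drug)) / (V_T(baseline) - V_ND) * 100%

or, independently of V_ND, from the binding potential,

    Occ = (BP_ND(baseline) - BP_ND(drug)) / BP_ND(baseline) * 100%.

V_ND is obtained by extrapolating the V_T-versus-dose curve to infinite dose
with a one-site saturation model, and the dose-occupancy relation is fitted
with a Hill model (Emax fixed at 100%) to estimate the ED50.

``run_study`` chains the whole pipeline (metabolite correction, compartment
fits with AIC selection, graphical analysis, occupancy, ED50) over a list of
scans and emits study-level tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .errors import DomainError, InsufficientDataError
from .graphical import logan_vt, patlak_ki
from .io import ScanRecord, StudyConfig, suv
from .kinetics import fit_compartment
from .metabolite import ParentFractionModel, correct_plasma, fit_parent_fraction
from .simulate import default_parent_samples

__all__ = [
    "DoseResponsePoint",
    "VndFit",
    "Ed50Fit",
    "occupancy_from_vt",
    "occupancy_from_bp",
    "fit_vnd",
    "fit_ed50",
    "compare_groups",
    "run_study",
    "StudyReport",
]


@dataclass
class DoseResponsePoint:
    dose: float  # mg/kg
    estimate: float  # per-scan V_T or BP_ND
    occupancy: float  # percent; not clipped
    flagged: bool = False  # occupancy outside [-10, 110]


@dataclass
class VndFit:
    """One-site saturation fit V_T(D) = V_ND + V_S * ID50 / (ID50 + D)."""

    v_nd: float
    v_s: float
    id50: float  # mg/kg
    stderr: dict = field(default_factory=dict)
    r_squared: float = np.nan
    reliable: bool = True  # False when no dose dependence is detectable


@dataclass
class Ed50Fit:
    """Hill fit Occ(D) = 100 D^h / (ED50^h + D^h), Emax fixed at 100%."""

    ed50: float  # mg/kg
    hill: float
    stderr: dict = field(default_factory=dict)
    r_squared: float = np.nan
    p_value: float = np.nan  # regression F-test vs flat model
    model: str = "hill-free-slope"
    converged: bool = True
    reliable: bool = True


# ---------------------------------------------------------------------------
# occupancy formulas
# ---------------------------------------------------------------------------

def occupancy_from_vt(vt_baseline: float, vt_drug: float, v_nd: float) -> float:
    """Percent occupancy from distribution volumes; requires V_T(base) > V_ND."""
    if vt_baseline <= v_nd:
        raise DomainError("V_T(baseline) must exceed V_ND")
    return 100.0 * (vt_baseline - vt_drug) / (vt_baseline - v_nd)


def occupancy_from_bp(bp_baseline: float, bp_drug: float) -> float:
    """Percent occupancy from binding potentials; requires BP(base) > 0."""
    if bp_baseline <= 0:
        raise DomainError("BP_ND(baseline) must be > 0")
    return 100.0 * (bp_baseline - bp_drug) / bp_baseline


# ---------------------------------------------------------------------------
# dose-response fits
# ---------------------------------------------------------------------------

def fit_vnd(doses, vt_values) -> VndFit:
    """Extrapolate V_ND as the infinite-dose asymptote of the V_T-dose curve.

    Needs baseline (dose 0 counts as a point) plus >= 3 distinct positive
    doses with positive V_T.  When the dose dependence is not resolvable
    (V_S consistent with 0) the result is flagged unreliable.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(vt_values, dtype=float)
    if np.unique(d[d > 0]).size < 3:
        raise InsufficientDataError("need >= 3 distinct positive doses")
    if np.any(v <= 0):
        raise DomainError("V_T values must be positive")

    def model(D, v_nd, v_s, id50):
        return v_nd + v_s * id50 / (id50 + D)

    v0 = float(v[np.argmin(d)])
    p0 = [0.25 * v0, 0.75 * v0, max(np.median(d[d > 0]), 1.0)]
    try:
        popt, pcov = curve_fit(
            model,
            d,
            v,
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 1e6]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise InsufficientDataError(f"V_ND fit did not converge: {exc}") from exc
    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    resid = v - model(d, *popt)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    # dose dependence undetectable if V_S's ~95% CI spans zero
    reliable = np.isfinite(perr[1]) and popt[1] - 1.96 * perr[1] > 0
    return VndFit(
        v_nd=float(popt[0]),
        v_s=float(popt[1]),
        id50=float(popt[2]),
        stderr={"v_nd": float(perr[0]), "v_s": float(perr[1]), "id50": float(perr[2])},
        r_squared=r2,
        reliable=bool(reliable),
    )


def fit_ed50(
    doses,
    occupancies,
    fix_hill: bool = False,
    weights_sd=None,
    model: str = "hill",
) -> Ed50Fit:
    """Nonlinear dose-occupancy regression for the in vivo ED50.

    ``model='hill'`` (default) fixes Emax at 100% with a free Hill slope
    (``fix_hill`` pins it at 1), so occupancy at the fitted ED50 is 50% by
    construction.  ``model='emax'`` frees the top instead (h = 1); there the
    ED50 is the dose at half the *fitted* maximum.  ``weights_sd`` enables
    1/SD^2 weighting.  The regression p-value compares the fitted curve
    against a flat (mean) model.
    """
    d = np.asarray(doses, dtype=float)
    occ = np.asarray(occupancies, dtype=float)
    pos = d > 0
    if np.unique(d[pos]).size < 3:
        raise InsufficientDataError("need >= 3 distinct positive doses")
    if np.all(occ <= 0):
        raise DomainError("all occupancies <= 0; nothing to fit")
    sigma = np.asarray(weights_sd, dtype=float) if weights_sd is not None else None

    if model == "emax":
        def curve(D, ed50, emax):
            return emax * D / (ed50 + D)
        p0 = [np.median(d[pos]), 100.0]
        bounds, names = ([1e-6, 1.0], [1e6, 500.0]), ["ed50", "emax"]
        label = "emax-free-top"
    elif fix_hill:
        def curve(D, ed50):
            return 100.0 * D / (ed50 + D)
        p0, bounds, names = [np.median(d[pos])], ([1e-6], [1e6]), ["ed50"]
        label = "hill-fixed-slope"
    else:
        def curve(D, ed50, h):
            Ds = np.maximum(D, 1e-12)
            return 100.0 * Ds**h / (ed50**h + Ds**h)
        p0, bounds, names = [np.median(d[pos]), 1.0], ([1e-6, 0.05], [1e6, 10.0]), ["ed50", "hill"]
        label = "hill-free-slope"
    if sigma is not None:
        label += "-weighted"

    try:
        popt, pcov = curve_fit(
            curve, d, occ, p0=p0, bounds=bounds, sigma=sigma, maxfev=20000
        )
        converged = True
    except RuntimeError:
        return Ed50Fit(ed50=np.nan, hill=np.nan, model=label, converged=False, reliable=False)

    perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    yhat = curve(d, *popt)
    ss_res = float(np.sum((occ - yhat) ** 2))
    ss_tot = float(np.sum((occ - occ.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    # F-test of the fitted curve against the flat model
    p_par = len(popt)
    dof = d.size - 1 - p_par
    if ss_res > 0 and dof > 0 and ss_tot > ss_res:
        F = ((ss_tot - ss_res) / p_par) / (ss_res / dof)
        p_value = float(stats.f.sf(F, p_par, dof))
    elif ss_res == 0:
        p_value = 0.0
    else:
        p_value = np.nan
    ed50 = float(popt[0])
    hill = float(popt[1]) if (model == "hill" and not fix_hill) else 1.0
    return Ed50Fit(
        ed50=ed50,
        hill=hill,
        stderr=dict(zip(names, perr.astype(float))),
        r_squared=r2,
        p_value=p_value,
        model=label,
        converged=converged,
        reliable=bool(np.isnan(p_value) or p_value < 0.05),
    )


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Classical two-sided unpaired equal-variance t-test -> (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    per_scan: pd.DataFrame  # per-scan fitted endpoints
    group_table: pd.DataFrame  # Table-2 style group summary with t-tests
    occupancy_table: pd.DataFrame  # Table-3 style occupancy by dose and method
    vnd: dict  # method -> VndFit
    ed50: dict  # method -> Ed50Fit
    parent_model: ParentFractionModel | None = None
    failures: list = field(default_factory=list)


def _summary(vals):
    vals = np.asarray(vals, dtype=float)
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0


def run_study(
    records: list[ScanRecord],
    config: StudyConfig | None = None,
    parent_samples=None,
    kinetic_models: tuple[str, ...] = ("1TCM", "2TRCM"),
    ed50_fix_hill: bool = False,
) -> StudyReport:
    """End-to-end analysis of a study: metabolite -> kinetics -> graphical ->
    occupancy -> ED50.

    Per-scan failures are collected and the run continues; the report lists
    them.  Occupancy per dose uses the group-mean drug V_T against the
    baseline-mean V_T (separate animals per dose, no within-animal pairing);
    per-scan occupancies against the baseline mean feed the SD columns.
    """
    config = config or StudyConfig()
    parent = fit_parent_fraction(parent_samples or default_parent_samples())

    rows, failures = [], []
    for rec in records:
        try:
            blood = (
                rec.blood
                if rec.blood.parent_corrected_applied
                else correct_plasma(rec.blood, parent)
            )
            row = {
                "subject_id": rec.subject_id,
                "dose_mg_per_kg": rec.drug_dose,
                "group": rec.group,
            }
            _, row["suv_mean"] = suv(
                rec.tac, rec.injected_dose, rec.body_weight, config.suv_window_min
            )
            for model in kinetic_models:
                fit = fit_compartment(rec.tac, blood, model=model, config=config,
                                      seed=config.seed)
                tag = model.lower()
                row[f"aic_{tag}"] = fit.aic
                if model == "2TRCM":
                    ok = fit.converged and not fit.near_irreversible and fit.macro is not None
                    row["fit_2tcm_ok"] = ok
                    if fit.macro is not None:
                        row["vt_2tcm"] = fit.macro.V_T
                        row["bp_2tcm"] = fit.macro.BP_ND
                        row["vb_2tcm"] = fit.params.Vb
            lg = logan_vt(rec.tac, blood, t_star=config.t_star_logan)
            row["vt_logan"] = lg.slope
            row["r2_logan"] = lg.r_squared
            pk = patlak_ki(rec.tac, blood, t_star=config.t_star_patlak)
            row["ki_patlak"] = pk.slope
            row["r2_patlak"] = pk.r_squared
            rows.append(row)
        except Exception as exc:
            failures.append((rec.subject_id, repr(exc)))
    per_scan = pd.DataFrame(rows)
    if per_scan.empty:
        raise InsufficientDataError("every scan failed; nothing to report")

    # ---- group summary (Table-2 style) ------------------------------------
    base = per_scan[per_scan["dose_mg_per_kg"] == 0]
    group_rows = []
    for dose, sub in per_scan.groupby("dose_mg_per_kg"):
        entry = {"dose_mg_per_kg": dose, "n": len(sub)}
        for col in ("suv_mean", "vt_2tcm", "bp_2tcm", "vb_2tcm", "vt_logan"):
            if col not in sub:
                continue
            # flagged compartment fits are excluded from the summaries
            if col.endswith("2tcm") and "fit_2tcm_ok" in sub:
                vals = sub.loc[sub["fit_2tcm_ok"].fillna(False), col]
                base_vals = base.loc[base["fit_2tcm_ok"].fillna(False), col]
            else:
                vals, base_vals = sub[col], base[col]
            if len(vals) == 0:
                continue
            entry[f"{col}_mean"], entry[f"{col}_sd"] = _summary(vals)
            if dose > 0 and len(vals) >= 2 and len(base_vals) >= 2:
                _, p = compare_groups(base_vals, vals)
                entry[f"{col}_p_vs_baseline"] = p
        group_rows.append(entry)
    group_table = pd.DataFrame(group_rows)

    # ---- occupancy and ED50 per method ------------------------------------
    methods = {"vt_2tcm": "vt", "vt_logan": "vt", "bp_2tcm": "bp"}
    vnd_fits: dict = {}
    ed50_fits: dict = {}
    occ_rows = []
    doses_pos = sorted(d for d in per_scan["dose_mg_per_kg"].unique() if d > 0)
    for col, kind in methods.items():
        if col not in per_scan:
            continue
        # 2TRCM endpoints from flagged fits (non-converged or k4 pinned at
        # its bound) are excluded from the dose-response stage
        if col.endswith("2tcm") and "fit_2tcm_ok" in per_scan:
            usable = per_scan[per_scan["fit_2tcm_ok"].fillna(False)]
        else:
            usable = per_scan
        try:
            base_u = usable[usable["dose_mg_per_kg"] == 0]
            base_mean = float(base_u[col].mean())
            if kind == "vt":
                vnd = fit_vnd(usable["dose_mg_per_kg"], usable[col])
                vnd_fits[col] = vnd
                v_nd = vnd.v_nd
            mean_occ, sd_occ = {}, {}
            for dose in doses_pos:
                sub = usable[usable["dose_mg_per_kg"] == dose][col]
                if kind == "vt":
                    per = [occupancy_from_vt(base_mean, v, v_nd) for v in sub]
                    occ_mean = occupancy_from_vt(base_mean, float(sub.mean()), v_nd)
                else:
                    per = [occupancy_from_bp(base_mean, v) for v in sub]
                    occ_mean = occupancy_from_bp(base_mean, float(sub.mean()))
                mean_occ[dose] = occ_mean
                sd_occ[dose] = float(np.std(per, ddof=1)) if len(per) > 1 else 0.0
            ed50_fits[col] = fit_ed50(
                doses_pos, [mean_occ[d] for d in doses_pos], fix_hill=ed50_fix_hill
            )
        except (DomainError, InsufficientDataError) as exc:
            failures.append((f"occupancy[{col}]", repr(exc)))
            continue
        for dose in doses_pos:
            occ_rows.append(
                {
                    "dose_mg_per_kg": dose,
                    "method": col,
                    "occupancy_pct": mean_occ[dose],
                    "occupancy_sd": sd_occ[dose],
                    "flagged": not (-10.0 <= mean_occ[dose] <= 110.0),
                }
            )
    occupancy_table = pd.DataFrame(occ_rows)

    return StudyReport(
        per_scan=per_scan,
        group_table=group_table,
        occupancy_table=occupancy_table,
        vnd=vnd_fits,
        ed50=ed50_fits,
        parent_model=parent,
        failures=failures,
    )
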