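# occupet

Quantification of drug–target engagement with dynamic PET: compartmental and
graphical kinetic modelling of tumour time–activity curves with a
metabolite-corrected arterial input, followed by receptor-occupancy and
in vivo ED50 estimation.

The package implements the analysis chain used in small-animal CXCR4
occupancy studies with a C-11 labelled antagonist tracer, and ships a
synthetic-study generator with known ground truth so every estimator can be
validated by recovery.

## Who this is for

PET pharmacokinetics practitioners and method developers who need a tested,
scriptable implementation of:

* **Compartment models** — one-tissue (1TCM) and two-tissue reversible
  (2TRCM) models fitted to frame-averaged tissue curves by bounded,
  multistart weighted least squares with the fractional blood volume
  `Vb` free:

  `C_meas(t) = (1 − Vb) · (h ⊛ Cp)(t) + Vb · C_wb(t)`,
  `h(t) = φ₁e^(−θ₁t) + φ₂e^(−θ₂t)`,

  with macro-parameters `V_T = (K1/k2)(1 + BP_ND)` and `BP_ND = k3/k4`, and
  1TCM/2TRCM selection by AIC = N·ln(WRSS/N) + 2P.
* **Graphical analysis** — Logan (slope = V_T, t* = 10 min) and Patlak
  (slope = Ki, t* = 20 min) regressions with explicit t* handling and R²
  diagnostics.
* **Metabolite correction** — a population parent-fraction model
  `f(t) = c + (1 − c)e^(−kt)` applied to plasma inputs.
* **Occupancy inference** —
  `Occ = (V_T(base) − V_T(drug)) / (V_T(base) − V_ND) · 100%` and
  `Occ = (BP(base) − BP(drug)) / BP(base) · 100%`, with V_ND extrapolated
  from the V_T-versus-dose curve and the ED50 from a Hill/Emax regression.
* **Synthetic studies** — a 21-frame, 60-min acquisition with 15 arterial
  samples, bolus-shaped plasma input, slow tracer metabolism, and
  Emax-shaped dose-dependent blockade of specific binding (drug scales k3).

## Worked example

```python
import occupet as op

records, answer_key = op.generate_study(seed=42)   # 6 baseline + 5 dose groups of 3
report = op.run_study(records)                     # metabolite -> kinetics -> graphical -> occupancy

base = report.group_table[report.group_table.dose_mg_per_kg == 0].iloc[0]
print(f"baseline V_T  = {base['vt_2tcm_mean']:.2f} ± {base['vt_2tcm_sd']:.2f}")
print(f"baseline BP_ND = {base['bp_2tcm_mean']:.2f} ± {base['bp_2tcm_sd']:.2f}")
fit = report.ed50["vt_2tcm"]
print(f"ED50 = {fit.ed50:.1f} mg/kg (Hill slope {fit.hill:.2f})")
```

prints

```
baseline V_T  = 0.84 ± 0.01
baseline BP_ND = 1.38 ± 0.33
ED50 = 12.7 mg/kg (Hill slope 1.01)
```

The generating truth for this cohort is V_T = 0.87, BP_ND = 1.85 and
ED50 = 12.7 mg/kg.  V_T and the dose–response are recovered closely (the
~3% V_T shortfall is the sparse-arterial-sampling bias discussed in
`docs/methods.md`); BP_ND scatters much more because it requires resolving
k3 and k4 jointly — which is exactly why the V_T-based occupancy route is
the dependable one, while `report.ed50["bp_2tcm"]` comes back flagged
unreliable.  `answer_key` holds the per-scan true rate constants and
occupancies for direct comparison.

## Analysis scripts

The numbered drivers under `analysis/` run the study end to end and write
tables under `results/`:

```bash
python analysis/01_simulate_study.py          # cohort + ground-truth answer key
python analysis/02_metabolite_correction.py   # population parent-fraction fit
python analysis/03_fit_kinetics.py            # 1TCM vs 2TRCM, AIC, group table
python analysis/04_graphical_analysis.py      # Logan / Patlak slopes and R²
python analysis/05_occupancy_ed50.py          # occupancy, V_ND, ED50
```

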