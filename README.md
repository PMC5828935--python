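# uadyn

Semi-mechanistic exposure-response modelling of uric acid disposition and
urate-lowering therapy.

Hyperuricemia — serum uric acid above the ~6.8 mg/dL solubility limit —
drives gout and is treated either by inhibiting uric acid production
(xanthine oxidase inhibitors: allopurinol/oxypurinol, febuxostat) or by
increasing its renal fractional excretion (uricosurics such as the URAT1
inhibitor lesinurad). `uadyn` is for pharmacometricians and clinical
pharmacologists who want to simulate, estimate and plan such interventions
quantitatively: it answers questions like *"how much production inhibition
does this patient need to halve their serum urate, given their GFR and
fractional excretion — and how much less if a uricosuric is added?"*

## The model

A single serum compartment with amount S_UA (mg), production rate k_P
(mg/h), intestinal clearance CL_I (L/h) and renal excretion through
glomerular filtration (GFR) with fractional escape F_E from tubular
reabsorption:

```
dS_UA/dt = k_P − CL_I·[S]_UA − GFR·F_E·[S]_UA ,   [S]_UA = S_UA / V_UA
dU_UA/dt = GFR·F_E·[S]_UA
```

At steady state `[S]_UA = k_P / (CL_I + GFR·F_E)`, with the inverse
relations `k_P,0 = [S]_UA·CL_I + X_UA` and `F_E,0 = X_UA/([S]_UA·GFR)`
used to back-calculate a patient's baseline physiology from serum
concentration and 24-h urine excretion. Drug effects are saturable:
a production inhibitor scales `k_P` by `1 − R_max·C/(C+P50)`, a
reabsorption inhibitor adds `F_max·C/(C+P50)` to `F_E`. Observations
carry combined additive + proportional residual error
`y = f + sqrt(a² + (b·f)²)·ε`.

Modules: `core` (state equations, steady states, unit plumbing,
Cockcroft-Gault), `drugs` (Emax effect models, PK stand-in, splines),
`simulate` (LSODA time courses with urine-interval accounting),
`estimate` (maximum-likelihood fitting with asymptotic SEs and adequacy
diagnostics), `qualify` (renal-impairment and hyperuricemic-cohort
prediction procedures), `nomogram` (steady-state treatment-planning
grids), `synth` (seeded virtual populations and trials), `io`/`cli`
(tidy CSV dialect and the `uadyn` command-line tool).

## Worked example

The reference patient: baseline serum urate 12 mg/dL, GFR 60 mL/min,
baseline fractional excretion 0.03, intestinal clearance 0.27 L/h.

```python
from uadyn import NomogramSpec, required_inhibition, urine_excretion_at

spec = NomogramSpec(sua_base_mg_dl=12, gfr_ml_min=60, fe0=0.03, cl_i=0.27)
for d_fe in (0.0, 0.05):
    req = required_inhibition(0.5, d_fe, spec)
    urine, pct = urine_excretion_at(req, d_fe, spec)
    print(f"dFE={d_fe:4.2f}: inhibition {100*req:4.1f}%  "
          f"urine {urine:6.1f} mg/24h ({pct:+5.1f}%)")
```

prints

```
dFE=0.00: inhibition 50.0%  urine  155.5 mg/24h (-50.0%)
dFE=0.05: inhibition 26.2%  urine  414.7 mg/24h (+33.3%)
```

To halve this patient's serum urate, a xanthine oxidase inhibitor alone
must cut production by 50%; adding a uricosuric that raises fractional
excretion by 0.05 (roughly lesinurad 200 mg/day) drops the requirement to
26%, at the cost of a 33% higher urinary urate load — the quantity to
check against nephrolithiasis risk. The same objects drive full time-course
simulation (`run_simulation`), trial generation (`uadyn synth`), model
fitting (`uadyn fit`) and the qualification procedures; see
`examples/config.yaml` for a configuration covering every command and
`docs/methods.md` for the science and the numerical choices.

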