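# icgpbpk

A physiologically based pharmacokinetic (PBPK) model of indocyanine green
(ICG) liver function testing, with in-silico cirrhosis and hepatectomy,
non-compartmental PK analysis, transporter-parameter calibration, and a
model-based pipeline for classifying survival after partial hepatectomy.

ICG is an inert anionic dye that is confined to plasma, taken up exclusively
by the liver and excreted unchanged into the bile. Clinicians quantify liver
function from its plasma disappearance: the elimination rate constant
*k*<sub>el</sub> (reported as the plasma disappearance rate,
PDR = 100·*k*<sub>el</sub>, %/min), the retention ratio
R15 = *c*(15 min)/*c*<sub>max</sub>, clearance
CL = *V*<sub>d</sub>·*k*<sub>el</sub> and half-life
*t*<sub>1/2</sub> = ln 2/*k*<sub>el</sub>. This package is aimed at
modellers and hepatobiliary researchers who want to ask mechanistic
questions of these routine measurements: how do portosystemic shunting,
parenchymal loss and liver resection move the ICG parameters, and can the
model's prediction of *postoperative* R15 — obtained from preoperative R15
and the planned resection rate alone — classify surgical risk better than
the preoperative measurement by itself?

## Model

A whole-body compartmental ODE model connects venous blood, lung, arterial
blood, the gastrointestinal tract (feeding the portal vein), the liver and a
pooled rest compartment through the systemic circulation. Flow conservation
holds by construction (*Q*<sub>CO</sub> = *Q*<sub>lu</sub> =
*Q*<sub>h</sub> + *Q*<sub>re</sub>, *Q*<sub>h</sub> = *Q*<sub>ha</sub> +
*Q*<sub>po</sub>). In the liver, sinusoidal uptake and canalicular excretion
are irreversible Michaelis–Menten transport steps scaled by functional liver
volume (uptake competitively inhibited by plasma bilirubin); bile-to-feces
transit is first order. Disease and surgery enter through four scenario
parameters:

- `f_shunts` — fraction of hepatic blood bypassing the liver tissue,
- `f_tissue_loss` — fraction of functional parenchyma lost,
- `f_cirrhosis` — composite severity, setting both in lockstep
  (Child–Turcotte–Pugh classes map to 0.0 / 0.41 / 0.70 / 0.82),
- `resection_rate` — fraction of liver volume removed surgically
  (`f_bloodflow` separately emulates intraoperative trial clamping).

The map from measured preoperative R15 to cirrhosis degree is logarithmic,
*f*<sub>cirrhosis</sub> = *a*·ln(*b*·R15) + *c*, fitted to the model's own
R15-vs-cirrhosis scan.

## Worked example

```python
import numpy as np
from icgpbpk import (ModelParameters, standard_bolus, simulate,
                     default_grid, pk_parameters)

params = ModelParameters()                      # healthy 75 kg reference
tc = simulate(params, standard_bolus(0.5), default_grid(60.0, 0.1))
res = pk_parameters(tc)
print(f"PDR  = {res.pdr:.1f} %/min")
print(f"R15  = {res.r15_percent:.1f} %")
print(f"CL   = {res.cl_ml_min:.0f} ml/min")
print(f"t1/2 = {res.t_half:.1f} min")

cirrhotic = ModelParameters(scenario=params.scenario.with_cirrhosis(0.70))
res_c = pk_parameters(simulate(cirrhotic, standard_bolus(0.5),
                               default_grid(60.0, 0.1)))
print(f"moderate cirrhosis: PDR = {res_c.pdr:.1f} %/min, "
      f"R15 = {res_c.r15_percent:.1f} %")
```

prints

```
PDR  = 18.3 %/min
R15  = 4.5 %
CL   = 624 ml/min
t1/2 = 3.8 min
moderate cirrhosis: PDR = 5.3 %/min, R15 = 30.6 %
```

A healthy subject clears the dye fast (R15 < 10%, the usual clinical
threshold for safe major resection); moderate cirrhosis slows elimination
more than threefold and retains ~31% of the peak concentration at 15 min.

The survival-classification pipeline on a synthetic 141-patient cohort:

```python
from icgpbpk import (CohortGeneratorConfig, R15Surface, generate,
                     run_scan, fit_map_coefficients, build_features, evaluate)

surface = R15Surface.compute()                  # R15 over (cirrhosis, resection)
scan = run_scan("f_cirrhosis", np.arange(0.0, 0.91, 0.05))
coeffs = fit_map_coefficients(scan)             # a ~ 0.37
cohort, truth = generate(CohortGeneratorConfig(seed=1), surface)
X, y = build_features(cohort, "PBPK1", coeffs=coeffs, surface=surface)
m = evaluate(X, y, seed=1)
print(f"PBPK1 ROC AUC = {m.full['roc_auc']:.3f} "
      f"(CV {m.cv_mean['roc_auc']:.3f} ± {m.cv_sd['roc_auc']:.3f})")
```

prints `PBPK1 ROC AUC = 0.929 (CV 0.920 ± 0.060)` — the model-predicted
postoperative R15 separates survivors from non-survivors well, while the
preoperative measurement alone (`"Data1A"`) does markedly worse.

There is also a CLI: `icgpbpk simulate|nca|scan|fit|cohort|classify --help`.

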