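# Methods

## Model structure

Indocyanine green (ICG) is modeled as a single species, measured in mmole,
distributed over the plasma spaces of a whole-body circulation: venous
blood, lung capillary blood, arterial blood, gastrointestinal capillary
blood, portal vein, liver sinusoidal blood, hepatic vein, and a pooled
"rest" compartment standing in for all organs that do not eliminate the
dye. Two non-vascular pools complete the system: liver tissue
(hepatocytes) and bile, with a cumulative feces sink. The model is a plain
ODE system without transport delays.

Because ICG is protein-bound and confined to plasma, each compartment's
distribution volume is its blood volume times (1 − HCT) with hematocrit
HCT = 0.51. Convective exchange between compartments is irreversible:
the flux out of compartment *i* is *Q<sub>i</sub>* · *C<sub>i</sub>*, with
*C<sub>i</sub>* the plasma concentration and *Q<sub>i</sub>* the full
volumetric blood flow through the compartment. An alternative formulation
multiplies the flows by (1 − HCT) as well ("plasma flow"); we tested both
and kept the blood-flow form: it reproduces healthy plasma disappearance
rates of ~18–21 %/min and healthy R15 of ~4–5%, where the plasma-flow form
halves effective hepatic delivery and predicts a clinically implausible
healthy PDR of ~11 %/min and R15 of ~13%. Physically, the blood-flow form
corresponds to treating each compartment's plasma as well mixed with the
plasma stream passing through it at the volumetric blood flow rate.

Flows derive from cardiac output *Q*<sub>CO</sub> = COBW · BW
(0.83 ml/s/kg · 75 kg = 3.735 l/min) through fractional flows: hepatic
venous flow *Q*<sub>h</sub> = 0.255 · *Q*<sub>CO</sub>, portal flow
*Q*<sub>po</sub> = 0.19 · *Q*<sub>CO</sub>, hepatic artery
*Q*<sub>ha</sub> = *Q*<sub>h</sub> − *Q*<sub>po</sub>, rest flow
*Q*<sub>re</sub> = *Q*<sub>CO</sub> − *Q*<sub>h</sub>. The identities
*Q*<sub>CO</sub> = *Q*<sub>lu</sub> = *Q*<sub>h</sub> + *Q*<sub>re</sub>
and *Q*<sub>h</sub> = *Q*<sub>ha</sub> + *Q*<sub>po</sub> hold exactly for
every admissible scenario. The rest compartment's blood volume closes the
volume budget: Fblood · (BW · 1 l/kg − explicitly modeled organ volumes),
treating body density as 1 kg/l — the one volume not fixed by the
parameter table.

## Hepatic elimination

Three serial transport steps, all scaled by functional liver tissue
volume *V*<sub>li</sub> = FVli · BW · (1 − Fblood) ·
(1 − f_tissue_loss) · (1 − resection_rate):

1. **Sinusoidal uptake** (OATP1B3): irreversible Michaelis–Menten in the
   liver plasma concentration, Vmax = 0.037 mmole/min/l liver,
   Km = 0.0217 mM, competitively inhibited by plasma bilirubin
   (Km scaled by 1 + bil/ki_bil, ki_bil = 0.02 mM). Default plasma
   bilirubin is 0.007 mM, the middle of the healthy reference range
   (0.005–0.015 mM); the inhibition form is assumed competitive, the
   standard mechanism for transporter substrates sharing a carrier.
2. **Canalicular excretion**: irreversible Michaelis–Menten in the
   hepatocyte concentration, Vmax = 0.000944 mmole/min/l liver,
   Km = 0.0124 mM.
3. **Bile-to-feces transit**: first order in the bile amount,
   k = 0.000114 /min, scaled by the functional-liver fraction so that all
   transport capacity shrinks with the working organ.

With these constants, uptake — not excretion — controls the plasma
disappearance on the 15–30 min horizon; bile acts as a slow depot. The
model deliberately describes only the first, monoexponential phase of ICG
elimination on which all clinical parameters are defined; the slow
terminal phase is out of scope.

## Disease and surgery scenarios

**Cirrhosis** combines two mechanisms varied in lockstep via
`f_cirrhosis`: a fraction `f_shunts` of both the arterial and portal
streams bypasses the liver tissue directly into the hepatic vein
(intrahepatic shunting; the split ratio between the two streams is taken
equal, since no separate ratio is established), and a fraction
`f_tissue_loss` of parenchyma is removed. Child–Turcotte–Pugh classes map
onto composite degrees 0.0 (control), 0.41 (A), 0.70 (B), 0.82 (C).

**Hepatectomy** (`resection_rate`) removes liver tissue *and* the liver's
vascular volume but leaves hepatic inflow unchanged — immediately after
resection the remnant is hyperperfused. **Trial clamping** is emulated
separately by `f_bloodflow`, which scales hepatic inflow with the
difference rerouted to the rest compartment (cardiac output preserved).
Comparing matched clamping and resection fractions reproduces the strong
concordance between intraoperative clamped and postoperative measurements
(paired PDR correlation > 0.99 in our scans).

## Dosing and integration

Dosing protocols are ordered lists of bolus and infusion events; a bolus
is a constant-rate input over the injection duration (default 5 s), so the
ODE system is event-free within dosing segments and the cumulative input
is exactly the resolved dose. mg/kg doses resolve against body weight;
mg convert to mmole via the ICG molar mass 774.96 g/mole.

Integration uses LSODA with rtol 1e-8 and atol 1e-10 mmole, restarted at
every dosing breakpoint; the default output grid is 0–120 min at 0.1 min
(scans use a 60 min horizon, which covers the R20 sample and the kel
window with margin). A bookkeeping state tracks cumulative input, making
the mass balance |administered − (system + feces)|/administered a direct
diagnostic; it stays below 1e-6 (typically 1e-12) at all output times.
Uncertainty envelopes perturb each parameter individually by ±25% and
report pointwise mean, SD, min and max over all runs plus the base run;
physical constants (molar mass) and dosing-related quantities (injection
time, doses) are never varied.

## Non-compartmental analysis

kel is the negative slope of a log-linear least-squares fit over a
configurable window, by default 5–15 min after dose start — early enough
to sit in the monoexponential phase that clinical PDR measurements use,
late enough to avoid the mixing transient. PDR = 100·kel,
t½ = ln 2/kel, AUC∞ = trapezoid + c_last/kel, Vd = D/(AUC∞·kel),
CL = Vd·kel, R15 = c(15)/c_max with c_max the maximum of the *sampled*
curve (not the back-extrapolated intercept, matching clinical practice).
All internal identities (t½·kel = ln 2, CL = Vd·kel) hold exactly by
construction; on dense monoexponential input every output matches the
closed form to < 0.5%.

## Calibration

The five transporter parameters are fitted by weighted least squares,

F = Σ_k w_k · [Σ_i (w_ik·(y_ik − m_ik))²] / n_k,

with study weights w_k proportional to subject counts, per-point weights
w_ik = 1/SD when errors are available (else 1), and n_k the number of
points in block k — a per-block mean of squared weighted residuals, which
keeps densely and sparsely sampled studies comparable. Optimization is
bounded multi-start local least squares in log10-parameter space (the
parameters are positive scale quantities); start points are drawn
log-uniformly within bounds spanning ×0.01–×100 around the reference
values, and the seed is mandatory, making results reproducible. Per-start
dispersion is reported as an identifiability diagnostic — the (Vmax, Km)
pairs are strongly correlated along ridges, so curve recovery is the
meaningful criterion, not per-parameter recovery. A built-in synthetic
calibration corpus (two bolus doses, one infusion, one biliary-excretion
block, multiplicative noise) supports recovery experiments; with 5% noise
and 25 starts the refit reproduces noise-free venous curves to well under
5%.

## Cirrhosis map and survival classification

Scanning `f_cirrhosis` over [0, 0.9] with the standard 0.5 mg/kg bolus
and regressing f on ln R15 yields the logarithmic map
f = a·ln(b·R15) + c. Only the slope a and the effective intercept
a·ln b + c are identifiable from such a fit (b and c trade off along a
ridge), so fitted coefficients are reported with b = 1. Our model yields
a ≈ 0.37. Estimates are clamped to [0, 0.9]; healthy subjects map to 0.

The classification pipeline builds five feature sets — preoperative R15
(Data1A); preoperative R15 × future liver remnant (Data1B); preoperative
R15 + resection rate (Data2); model-predicted postoperative R15 (PBPK1);
estimated cirrhosis degree + resection rate (PBPK2) — and trains a
C-support vector classifier (polynomial kernel, degree 3, C = 1, kernel
scale from feature variance, no class reweighting) on standardized
features, with non-survival as the positive class. The kernel offset is
set to 1 (inhomogeneous polynomial): including lower-order terms makes the
hypothesis spaces nest across feature sets, so a classifier given an
additional feature can always express the smaller model's solution.
Evaluation follows 200 ShuffleSplit iterations at a 75/25 train/test
ratio; confusion-matrix metrics and ROC AUC (from the continuous decision
score) are aggregated as mean ± SD next to a full-dataset fit. Splits with
single-class test sets are skipped and counted. A cutoff scan thresholds a
single feature directly and locates the balanced-accuracy optimum.

## Synthetic cohort generator

No patient-level data ships with the package; the generator emulates the
structure the classification analysis assumes for a hepatectomy cohort of
141 patients. Per patient: a latent cirrhosis degree f ~ 0.9·Beta(1.2,
1.54); a resection rate ~ Uniform(0.05, 0.75) (independent of f — real
surgical planning correlates the two, a simplification to note); true
pre- and postoperative R15 from the PBPK model (via a precomputed bilinear
surface over a 0.05 × 0.05 grid of cirrhosis × resection, avoiding ~10⁵
ODE solves per cohort); measured preoperative R15 = truth × lognormal
noise with CV 0.10; death ~ Bernoulli(logistic((postop R15 − 0.35)/0.07)).
The 0.35 anchor is the retention cutoff at which balanced accuracy of the
single-feature classifier peaks; the beta shape was calibrated once, by
deterministic quadrature against the death model, so the expected
non-survivor fraction equals the reference composition 32/141 ≈ 0.227.
Driving death through *true postoperative* R15 makes the model-predicted
postoperative R15 the Bayes-optimal single feature — the generator encodes
the causal structure under which comparing the five classifiers is
meaningful.

What passing tests on this cohort do **not** show: real preoperative
R15/outcome associations are far weaker than the generator's (real
measurement error, comorbidities and surgical factors are absent), so
absolute AUC values here overstate clinical performance; only the
*ordering* of the feature sets — model-informed ≥ two-feature data ≥
single-feature data — is the meaningful, and tested, property.

## Numerical choices and limitations

- Integrator tolerances (1e-8/1e-10) are chosen so the conservation check
  is meaningful; calibration runs relax to 1e-6/1e-9 and evaluate the
  model only at data times.
- Scan inversion uses piecewise-linear monotone interpolation and refuses
  values outside the attainable range rather than extrapolating.
- The extraction ratio uses the flow-weighted arterial/portal inflow mix
  as denominator; it is reported as 0 where inflow is 0.
- Degenerate inputs (zero dose, zero liver volume at full tissue loss)
  produce zero rates, not NaNs; concentrations in empty compartments are
  defined as 0.
- Problem sizes in the shipped experiments (60-min scan horizons, 19-point
  scan grids, 25-start recovery, 20-seed cohort sweeps) are the package's
  default study conditions; all are configurable.
- Known limitations: no terminal slow elimination phase, no enterohepatic
  recirculation (ICG undergoes none), no renal elimination, no transit
  delays (compensated by a cardiac output at the lower physiological end),
  and a single reference physiology (75 kg, male-typical volumes) unless
  overridden.
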