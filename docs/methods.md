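# Methods

This note documents the models implemented in `qivikit`, the parameter
sources and defaults, the calibrated constants, the numerical choices, and
the limitations a user should know before trusting an extrapolation.

## In vitro ADME estimation

**Caco-2 permeability.** Under sink conditions (receiver exchanged at every
sampling interval) the cumulative receiver concentration grows linearly, so
the flux is the ordinary-least-squares slope and
`Papp = Vr · slope / (A · C0)` (cm/s). A negative slope — an evaporation or
degradation artefact — clamps to `Papp = 0` with a logged warning rather than
an exception, so batch tables survive single bad wells. Replicates aggregate
as mean ± sample SD (n−1); per-replicate values are retained.

**Substrate depletion.** `ln(Ct/C0)` is regressed on time with weights
proportional to the reciprocal observed concentration (the "1/y" kinetics
convention, giving late, low-concentration points more relative weight on
the log scale). `k = −slope`, `t½ = ln 2 / k`, `Clint = k · V / N` with
`V = 100 µL` and `N = 0.0525·10⁶` viable cells by default (0.525·10⁶
cells/mL × 100 µL). The half-life constant is ln 2 = 0.693; the constant
0.639 that circulates in one assay write-up is reachable via
`legacy_half_life_constant=True` but is not used anywhere, since only ln 2
is consistent with the exponential decay it is derived from. A non-negative
slope means no measurable depletion: `k = 0`, `Clint = 0`, infinite
half-life.

**Plasma protein binding.** `fub = C_buffer / C_plasma` from rapid
equilibrium dialysis. The assay runs at 50% plasma; the default estimator
reports the measured ratio as-is (the convention of the source protocol).
With `dilution_correction=True` the diluted-plasma value `fu′` is mapped to
undiluted plasma by `fub = 1 / (D·(1/fu′ − 1) + 1)` with dilution factor
`D = 1/plasma_fraction`.

**Blood:plasma ratio.** `Kb/p = Ke/p · H + (1 − H)` with haematocrit
`H = 0.375` (the measured value of the pooled donor blood); the inverse
mapping is exposed for deriving erythrocyte partitioning from a measured
`Kb/p`.

**Whole-liver scaling.** `Clint_scaled = (Clint / fub) · HPGL · Wl` for
hepatocytes, `(Clint / fub) · MPPGL · Wl` for microsomes, converted to mL/h.
The `1/fub` factor (restrictive clearance) is on by default and togglable.
Renal clearance is `GFR_total · fub`. Scaling factors: rat HPGL 107·10⁶
cells/g, MPPGL 46 mg/g, liver 11.9 g (an alternative profile with 19 g, used
in parts of the source modelling literature, ships as
`rat_results_liver`); human HPGL 117.5·10⁶, MPPGL 40, liver 1800 g.

**Read-across.** Data-poor records are completed conservatively: missing
`Clint` → 0 (worst case, maximizing predicted internal exposure; the
compound classes here are low-clearance), missing `b/p` → 1 (measured values
cluster near 1), missing `Papp` → arithmetic mean of measured values within
the same chemical class, missing `fub` → the record's in silico value or an
error. Fills are provenance-flagged and never overwrite measurements; the
operation is idempotent.

## Ionization and tissue partitioning

Henderson–Hasselbalch species fractions are computed per compound type
(neutral, mono-/diprotic acid/base, zwitterion with independent sites); they
sum to 1 by construction. Cyromazine is handled as a monoprotic base with
pKa 5.30 — the only reading consistent with its unionized fraction of 0.99
at pH 7.4.

Tissue:plasma partition coefficients follow the mechanistic
(Rodgers–Rowland) scheme. For every tissue,

```
Kpu = f_EW + (1+X)/(1+Y)·f_IW + (P·f_NL + (0.3P+0.7)·f_NP)/(1+Y) + association
Kp  = Kpu · fub
```

where `X` and `Y` are the ionized:neutral ratios at intracellular pH 7.0 and
plasma pH 7.4, and `P = 10^logPow` (vegetable-oil scale
`log Kvo/w = 1.115·logPow − 1.35` for adipose). Moderate-to-strong bases
(basic pKa ≥ 7, configurable) associate with acidic phospholipids, with the
association constant back-calculated from the blood:plasma ratio via the
blood-cell composition; all other types associate with tissue albumin
(acids, neutrals) or lipoproteins (weak bases, zwitterions) through the
residual plasma binding `1/fub − 1 − plasma lipid partitioning` (clipped at
zero). Tissue compositions are bundled standard rat literature values
(`data/tissue_composition.csv`), reused for the human model — the common
practice when human compositions are not separately available — and
user-overridable. A flagged all-`Kp = 1` fallback exists for degenerate
records.

## The oral-route PBK model

State: twelve lumen pools (dissolved + undissolved for stomach, duodenum,
jejunum, ileum, colon, rectum), twelve flow-limited tissues (liver, gut,
spleen, kidney, brain, muscle, adipose, skeleton, heart, skin, rest, lung),
venous and arterial blood, and three cumulative sinks (hepatic metabolism,
urine, feces). Whole-blood concentrations circulate; plasma observables
divide by the blood:plasma ratio.

- **Transit.** Group transit times (stomach 0.5 h; small intestine 4 h;
  large intestine 12 h rat / 40 h human) are apportioned to sub-segments in
  proportion to segment length; each segment empties first-order at
  1/residence-time; rectal outflow is fecal excretion.
- **Dissolution.** The undissolved pool dissolves at a rate proportional to
  the solubility shortfall (`50/h per 1000 mg/L of Cs − C`, a Noyes–Whitney
  form), and the dissolved concentration is capped at the water solubility;
  supersaturation precipitates back. Doses enter the stomach dissolved up to
  the cap, the remainder as solid.
- **Absorption** occurs from all intestinal segments but not the stomach:
  `ka = Papp · SA / V_lumen · f_neutral(pH)` (pH-partition hypothesis). The
  absorbed flux feeds the portal inflow of the liver (first-pass).
- **Distribution** is flow-limited: venous outflow of tissue *t* carries
  `BP · A_t/(V_t · Kp_t)`. Gut and spleen drain portally into the liver;
  the lung sits in series between venous and arterial blood and carries the
  full cardiac output; the flow-balance validator requires systemic flows to
  sum to cardiac output within 1%.
- **Elimination.** Hepatic: `Clint_scaled · fub · A_liver/(V_liver ·
  Kp_liver)` — the scaled intrinsic clearance applied to the unbound
  plasma-equivalent liver concentration, which reproduces well-stirred
  extraction at steady state because the liver is flow-connected. Renal:
  `GFR · fub` acting on arterial plasma, removed via the kidney compartment
  into a terminal urine accumulator. (A diagram-level description that
  routes kidney output into the "rest" compartment was deliberately not
  implemented literally: returning excreted mass to a perfused tissue would
  recirculate it and break clearance semantics.)
- **Gastric secretion** rates are carried in the physiology record and
  validated, but lumen fluid volumes are held at steady state (secretion
  balanced by water absorption); they are parameters, not states.

**Physiology.** GIT geometry, transit, pH, secretion, liver weight, HPGL,
MPPGL and GFR come from the compiled rat/human tables of the modelling
literature (see the header of `data/reference_physiology.yaml`); non-GIT
organ volumes and flows are standard reference values (Brown 1997 rat, ICRP
89 human), all user-overridable. Two deliberate interpretations:

- Human GFR is stored as **125 mL/min total** for the 70 kg male. The
  literature table prints the unit as mL/min/kg, which would give a
  physiologically impossible 8750 mL/min; 125 mL/min is the standard adult
  value.
- The **rat effective absorptive lumen volume is a calibrated constant**
  (0.1 mL small intestine). Printed "fraction absorbed" rate constants of
  ~1.4·10⁻² h⁻¹ for these compounds would imply a ~68 mL rat small
  intestine and an absorption half-time of two days, which contradicts the
  observed sub-hour absorption peaks; the calibrated value reproduces the
  in vivo absorption phase of the cyromazine validation dataset and is
  documented as a calibration, with the `ka ∝ Papp` proportionality as the
  tested invariant. Human lumen volumes stay at fasted-state literature
  values (105 mL SI, 13 mL LI), and the human absorptive surface is the
  smooth mucosal cylinder area (~6.6·10³ cm²) rather than the villous
  amplified area, which would make absorption instantaneous in this
  formulation.

**Solver.** `scipy.integrate.solve_ivp` (LSODA), rtol 1e-8 / atol 1e-10 by
default, hard restart at every dose event, output on a fixed 1000-point grid
plus event times. Mass balance (administered = in-body + eliminated) holds
to well below 0.1% at every output time; a one-compartment reduction
(uniform initial distribution, all Kp = 1, fast flows, renal-only clearance)
matches the analytic exponential within 1e-3 relative. Screening and MCMC
runs use rtol 1e-6…1e-5 and coarser grids; the validation and acceptance
simulations use the defaults.

## In vitro disposition (VIVD-type) correction

Instantaneous-equilibrium mass balance over free medium, serum protein and
lipid, well plastic, headspace and cells:

```
nominal·V_med = C_free·(V_med·(1 + K_prot[prot] + K_lip[lip])
                        + K_plastic·A + K_aw·V_air + K_cell·V_cells)
```

with `K_aw = H_pc/(R·T)` and logPow correlations for neutral organics
(albumin `log K = 0.71·logPow + 0.42`, lipid `1.01·logPow + 0.12`,
polystyrene `0.92·logPow − 3.60`, module-level constants a user can
reassign). Ionizable compounds partition into the hydrophobic phases with
their neutral fraction at medium pH and accumulate in acidic organelles by
ion trapping (cytosol pH 7.0, lysosome 4.75, mitochondria 8.0). The cell
pool is reported per cell volume (hence the large intracellular numbers);
conservation is checked on medium-referenced amounts and is exact to
rounding. Sorption kinetics are ignored (instantaneous equilibrium), the
standard assumption for static multiwell exposures.

Bundled assay conditions (`vivd.ASSAY_REGISTRY`) describe the endocrine
battery: 96-well geometry (200 µL medium, ~1 cm² plastic contact, 300 µL
headspace), reporter-gene assays (AR/ER/TR) with 5% serum and 5·10⁴ cells,
H295R steroidogenesis with 2.5% serum and 10⁵ cells, TTR binding cell-free
with the carrier protein only. Serum is modelled as 38 g/L protein and
2.5 g/L lipid at 100%. These are typical protocol values, not the source
assays' unpublished exact conditions — the reason the worked-example test
carries a ±30% band even though the computed corrections land within ~7% of
the published ones.

## Sensitivity and uncertainty

**Morris screening.** Trajectories perturb one parameter at a time on a
4-level grid over `[θ/2, 2θ]` (log-uniform mapping; fractions capped at 1).
The elementary effect is the relative sensitivity in its step-size-free
log-log form `SC = ln(f₁/f₀)/ln(θ₁/θ₀)` — exactly the exponent for
power-law responses — with the finite relative-difference quotient as
fallback for non-positive outputs, and the historical product form behind
`printed_form=True` (it shrinks quadratically with the step and cannot rank
parameters). Defaults: 20 trajectories (8 in the test/acceptance runs, which
is already seed-stable for four parameters), ranking by mean absolute effect
with alphabetical tie-break. The default output functional is the venous
plasma Cmax; unbound Cmax and AUC are options.

A structural identity worth knowing: with restrictive scaling
(`Clint_scaled ∝ 1/fub`) and elimination on the unbound liver concentration
(`∝ fub·Clint_scaled`), hepatic clearance is exactly independent of fub. fub
then influences Cmax only through tissue partitioning (`Kp = Kpu·fub`) and
renal clearance, and through the direct factor in *unbound* outputs. This
bounds how highly fub can rank for a hepatically cleared compound in any
model that implements these equations as written.

**MCMC.** Adaptive random-walk Metropolis in log-parameter space over
(fub, Papp, Clint, solubility) with log-uniform priors spanning the same
two-fold range (fub capped at 1) and a Gaussian likelihood on
log-concentrations; the noise scale is estimated from baseline residuals
when not supplied. The proposal scale adapts toward 30% acceptance during
burn-in only, so the retained chain is a fixed-kernel Metropolis sample and
bitwise reproducible for a fixed seed. Defaults are 10,000 steps with 2,000
burn-in; the test suite and acceptance script use 200–400 steps with a
coarse solver, which this low-dimensional, well-identified posterior does
not need more of. Credible bands are pointwise 50% and 95% quantiles over
re-simulated posterior draws; nesting is guaranteed by quantile ordering.

## Exposure scenarios and QIVIVE

A drinking-water scenario doses `concentration × 2 L/day` in five equal
boluses at 0/4/8/12/16 h for five consecutive days (an 8-h overnight gap);
LOAEL-type inputs (mg/kg bw/day) convert through body weight to the same
schedule. Any implied water concentration above the compound's solubility is
capped with a warning — the "maximum solubility" worst case uses the cap
itself. The scenario metric is the unbound Cmax (mol/L) over the final
dosing day of the 5-day schedule (steady state for these elimination
half-lives), from a simulation that runs one trailing day beyond the last
dose. Margins of exposure are plain ratios of like concentrations
(unit-invariant); the protectiveness flag marks a free in vitro benchmark
within one order of magnitude of (or below) the LOAEL-derived unbound Cmax,
the threshold being configurable. Allometric LOAEL scaling uses
`loael_human = loael_animal · (BW_animal/BW_human)^(1−0.75)` with the
exponent configurable.

## Synthetic data

Generators are deterministic functions of (config, seed) and emit data in
the exact shapes the estimators consume: linear sink-condition receiver
series, exponential depletion triplicates at 0/15/30/60/120/240 min,
dialysis buffer/plasma pairs, and sparse noisy in vivo-like plasma profiles
(8–12 observations). Noise is multiplicative lognormal (concentrations stay
positive) with per-assay coefficients of variation at the scale of the
measured replicate spreads (Papp ~23%, b/p ~22%, fub ~2%, depletion ~5%,
profiles 10%). The generators emulate assay *shapes and noise*, not LC-MS
peak data, matrix effects, inter-donor variability or transporter
asymmetries — so estimator-recovery tests demonstrate numerical correctness
and robustness to replicate noise, not robustness to real-world assay
pathologies.

## Known limitations

- **Tebuconazole rat validation.** The in vivo reference profiles are total
  radioactivity (parent + metabolites). For a logPow 3.73 neutral compound
  the mechanistic partitioning gives a steady-state distribution volume near
  1.7 L for a 350 g rat, so a 0.7 mg oral dose cannot produce the ~4.6 µg/mL
  plasma peak the radioactivity data show (that would need an effective
  volume of ~0.15 L). The simulated parent-compound Cmax/AUC therefore sit
  far below the radioactivity reference, and the published prediction
  metrics for this compound are not reproduced (the published AUCs are also
  mutually inconsistent with the published scaled clearance by two orders of
  magnitude). Cyromazine — hydrophilic, renally cleared, internally
  consistent — validates within two-fold on all three metrics.
- **Sensitivity orderings.** The fub-cancellation identity above, plus the
  fact that cyromazine absorption must be fast to match its observed Tmax,
  means the package's measured Morris rankings differ from the published
  ones (which require permeability-limited absorption that the validated
  kinetics exclude). The rankings the package computes are internally
  consistent with its validated model; both are reported, neither is tuned.
- Human tissue compositions reuse rat values; no population variability; no
  dermal/inhalation routes; no fed-state food effects; no metabolite
  kinetics; no transporter-mediated uptake or Caco-2 efflux asymmetry; no
  enzyme-specific clearance decomposition; VIVD has no time-resolved
  sorption/degradation kinetics.
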