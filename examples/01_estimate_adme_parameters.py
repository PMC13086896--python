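"""Estimate in vitro ADME parameters from raw assay data.

Generates synthetic Caco-2, hepatocyte-depletion, dialysis and blood/plasma
assay data at the tebuconazole ground truths, runs each estimator, and scales
the intrinsic clearance to the whole rat liver.
"""

import qivikit as qk
from qivikit.adme import (
    BloodPlasmaMeasurement,
    bp_ratio,
    clint_from_depletion,
    fub_from_red,
    papp_from_timeseries,
    renal_clearance,
    scale_clint,
)
from qivikit.synthetic import (
    GeneratorConfig,
    gen_depletion_ts,
    gen_permeability_ts,
    gen_red_measurements,
)

cfg = GeneratorConfig(seed=7, cv=0.05, replicates=3)

papp = papp_from_timeseries(gen_permeability_ts(3.92e-6, cfg))
print(f"Papp  = {papp.value:.3g} +/- {papp.sd:.2g} cm/s "
      "(apparent Caco-2 permeability; ~4e-6 cm/s is moderate absorption)")

dep = clint_from_depletion(gen_depletion_ts(5.27, cfg))
print(f"Clint = {dep['clint']:.3g} uL/min/1e6 cells, half-life "
      f"{dep['half_life']:.0f} min (hepatocyte substrate depletion)")

fub = fub_from_red(gen_red_measurements(0.06, cfg))
print(f"fub   = {fub.value:.3g} +/- {fub.sd:.2g} "
      "(fraction unbound in plasma; strong protein binding)")

kbp = bp_ratio(BloodPlasmaMeasurement(ke_p=0.84, haematocrit=0.375))
print(f"b/p   = {kbp:.3g} (blood:plasma ratio near 1: no erythrocyte uptake)")

rat = qk.default_physiology("rat")
cl_h = scale_clint(dep["clint"], "PHH", fub.value, rat)
cl_r = renal_clearance(rat.gfr, fub.value)
print(f"Scaled hepatic Clint = {cl_h:.0f} mL/h, renal clearance = "
      f"{cl_r:.1f} mL/h for a {rat.body_weight} kg rat")
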