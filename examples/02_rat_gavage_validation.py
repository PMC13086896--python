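"""Simulate single oral gavage doses in the rat and compare with in vivo data.

Runs the bottom-up PBK model for tebuconazole (2 mg/kg) and cyromazine
(3 mg/kg) and reports Cmax/Tmax/AUC next to the in vivo reference metrics
(total radioactivity), with prediction factors (predicted/observed; a factor
within 0.5-2 is the usual two-fold acceptance band for PBK models).
"""

import qivikit as qk
from qivikit.pbk import build_model, prediction_factor, simulate, summarize
from qivikit.records import DoseEvent, DosingSchedule

rat = qk.default_physiology("rat")

for rec in (qk.TEBUCONAZOLE, qk.CYROMAZINE):
    ref = qk.INVIVO_RAT[rec.name]
    dose = ref["dose_mg_per_kg"] * rat.body_weight
    model = build_model(rec, rat)
    schedule = DosingSchedule(events=[DoseEvent(time=0.0, amount=dose)],
                              duration=48.0)
    ts = simulate(model, schedule, 48.0)
    pred = summarize(ts, rec.fub, mw=rec.mw)
    obs = ref["summary"]
    f = prediction_factor(pred, obs)
    print(f"{rec.name} ({ref['dose_mg_per_kg']} mg/kg gavage, {dose:.2f} mg):")
    print(f"  Cmax {pred.cmax:8.3g} ug/mL  vs in vivo {obs.cmax:6.3g} "
          f"(factor {f['cmax_factor']:.2f}, two-fold: {f['cmax_within_twofold']})")
    print(f"  Tmax {pred.tmax:8.3g} h      vs in vivo {obs.tmax:6.3g} "
          f"(factor {f['tmax_factor']:.2f}, two-fold: {f['tmax_within_twofold']})")
    print(f"  AUC  {pred.auc:8.3g} ug/mL*h vs in vivo {obs.auc:6.3g} "
          f"(factor {f['auc_factor']:.2f})")
    print(f"  mass balance residual: {ts.mass_balance_residual().max():.2e}")
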