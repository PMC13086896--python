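# Reference physiology for the bottom-up PBK model, version 1.
#
# GIT geometry, transit, secretion, liver weight, HPGL/MPPGL and GFR follow the
# compiled rodent/human tables of the modelling literature (McConnell 2008 rat GI;
# Vdoviakova 2016 rat intestinal anatomy; ICRP Publication 89 organ masses;
# Katayama 1984 rat GFR; Levey 1999 human GFR; Musther 2014 scaling factors).
# Non-GIT organ volumes and blood flows are standard reference values after
# Brown et al. 1997 (rat) and ICRP 89 (human male, 70 kg), expressed for a
# 0.35 kg rat and a 70 kg human. Every value is overridable by user config.
#
# Units: body_weight kg; volumes L (GIT lumen mL); flows L/h; liver_weight g;
# hpgl 1e6 cells/g; mppgl mg/g; gfr mL/min (total); transit h; secretion mL/h;
# surface areas cm2 (effective smooth absorptive area used by the model --
# the printed villous/anatomical values are kept under `anatomy`).
#
# `si_lumen_volume_total` is a calibrated constant: the effective absorptive
# fluid volume of the small intestine, set so that simulated oral profiles of
# the two reference compounds reproduce the in vivo absorption phase. It is
# deliberately below the total resident water because only the free mucosal
# fluid participates in absorption.

rat:
  species: rat
  body_weight: 0.35
  blood_volume: 0.02
  haematocrit: 0.46
  cardiac_output: 5.70
  liver_weight: 11.9
  hpgl: 107.0
  mppgl: 46.0
  gfr: 3.36          # 9.6 mL/min/kg * 0.35 kg
  gfr_per_kg: 9.6
  git_transit: {stomach: 0.5, small_intestine: 4.0, large_intestine: 12.0}
  si_lumen_volume_total: 0.1
  li_lumen_volume_total: 0.5
  compartments:
    - {name: liver,    volume: 0.0119,  blood_flow: 0.1197}   # arterial inflow only
    - {name: gut,      volume: 0.0095,  blood_flow: 0.7467}   # portal, drains to liver
    - {name: spleen,   volume: 0.0007,  blood_flow: 0.0570}   # portal, drains to liver
    - {name: kidney,   volume: 0.0026,  blood_flow: 0.8037}
    - {name: brain,    volume: 0.0020,  blood_flow: 0.1140}
    - {name: muscle,   volume: 0.1414,  blood_flow: 1.5846}
    - {name: adipose,  volume: 0.0245,  blood_flow: 0.3990}
    - {name: skeleton, volume: 0.0256,  blood_flow: 0.6954}
    - {name: heart,    volume: 0.0012,  blood_flow: 0.2793}
    - {name: skin,     volume: 0.0665,  blood_flow: 0.3306}
    - {name: rest,     volume: 0.0420,  blood_flow: 0.5700}
    - {name: lung,     volume: 0.0018,  blood_flow: 5.70}     # in series, carries CO
  git_segments:
    - {name: stomach,  volume_fasted: 3.40, ph_fasted: 3.90, surface_area: 0.0,
       transit_time: 0.5, secretion_rate: 1.5}
    - {name: duodenum, volume_fasted: 0.00674, ph_fasted: 5.89, surface_area: 4.571,
       transit_time: 0.2694, secretion_rate: 0.2559}
    - {name: jejunum,  volume_fasted: 0.0707, ph_fasted: 6.01, surface_area: 48.00,
       transit_time: 2.8283, secretion_rate: 2.6869}
    - {name: ileum,    volume_fasted: 0.02256, ph_fasted: 6.13, surface_area: 15.31,
       transit_time: 0.9024, secretion_rate: 0.8572}
    - {name: colon,    volume_fasted: 0.4423, ph_fasted: 5.64, surface_area: 23.94,
       transit_time: 10.615, secretion_rate: 0.0}
    - {name: rectum,   volume_fasted: 0.0577, ph_fasted: 6.00, surface_area: 3.12,
       transit_time: 1.385, secretion_rate: 0.0}
  anatomy:
    si_length_cm: 148.5
    li_length_cm: 26.0
    si_surface_area_cm2: 67.88
    li_surface_area_cm2: 27.06
    si_diameter_cm: [0.25, 0.50]
    li_diameter_cm: [1.0, 0.30]
    stomach_volume_fasted_mL: 3.40
    stomach_ph_fasted: 3.90
    si_ph_range: [5.89, 6.13]
    li_ph_range: [5.64, 6.00]
    secretion_mL_per_h: {stomach: 1.5, small_intestine: 3.8, large_intestine: 0.0}

rat_results_liver:
  # Alternative profile: 19 g liver used in parts of the source modelling
  # literature for a 350 g Sprague Dawley rat.
  inherit: rat
  liver_weight: 19.0
  compartments_override:
    liver: {volume: 0.0190}

human:
  species: human
  body_weight: 70.0
  blood_volume: 5.30
  haematocrit: 0.375
  cardiac_output: 390.0
  liver_weight: 1800.0
  hpgl: 117.5
  mppgl: 40.0
  gfr: 125.0          # mL/min total for a 70 kg male
  gfr_per_kg: null
  git_transit: {stomach: 0.5, small_intestine: 4.0, large_intestine: 40.0}
  si_lumen_volume_total: 105.0
  li_lumen_volume_total: 13.0
  compartments:
    - {name: liver,    volume: 1.80,   blood_flow: 25.35}
    - {name: gut,      volume: 1.20,   blood_flow: 62.40}
    - {name: spleen,   volume: 0.18,   blood_flow: 11.70}
    - {name: kidney,   volume: 0.31,   blood_flow: 74.10}
    - {name: brain,    volume: 1.45,   blood_flow: 46.80}
    - {name: muscle,   volume: 29.0,   blood_flow: 66.30}
    - {name: adipose,  volume: 15.0,   blood_flow: 19.50}
    - {name: skeleton, volume: 10.5,   blood_flow: 19.50}
    - {name: heart,    volume: 0.33,   blood_flow: 15.60}
    - {name: skin,     volume: 3.30,   blood_flow: 22.62}
    - {name: rest,     volume: 0.93,   blood_flow: 26.13}
    - {name: lung,     volume: 0.53,   blood_flow: 390.0}
  git_segments:
    - {name: stomach,  volume_fasted: 47.0,  ph_fasted: 1.90, surface_area: 0.0,
       transit_time: 0.5, secretion_rate: 133.33}
    - {name: duodenum, volume_fasted: 3.75,  ph_fasted: 6.12, surface_area: 235.7,
       transit_time: 0.1429, secretion_rate: 5.878}
    - {name: jejunum,  volume_fasted: 39.0,  ph_fasted: 6.80, surface_area: 2451.4,
       transit_time: 1.4857, secretion_rate: 61.13}
    - {name: ileum,    volume_fasted: 62.25, ph_fasted: 7.42, surface_area: 3912.9,
       transit_time: 2.3714, secretion_rate: 97.57}
    - {name: colon,    volume_fasted: 10.64, ph_fasted: 6.30, surface_area: 1414.0,
       transit_time: 32.73, secretion_rate: 2.5}
    - {name: rectum,   volume_fasted: 2.36,  ph_fasted: 7.00, surface_area: 314.0,
       transit_time: 7.27, secretion_rate: 0.0}
  anatomy:
    si_length_cm: 700.0
    li_length_cm: 110.0
    si_surface_area_cm2: 2.0e+6   # villous; model uses smooth mucosal area
    li_surface_area_cm2: 3460.0
    si_diameter_cm: [4.0, 2.40]
    li_diameter_cm: [6.0, 4.0]
    stomach_volume_fasted_mL: 47.0
    stomach_ph_fasted: 1.90
    si_ph_range: [6.12, 7.42]
    li_ph_range: [6.30, 7.00]
    secretion_mL_per_h: {stomach: 133.33, small_intestine: 164.58, large_intestine: 2.5}
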