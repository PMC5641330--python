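# Rat whole-body physiology, 0.25 kg reference animal.
# Volumes/flows: Brown et al. 1997 compilations, rounded for internal
# consistency (volumes sum to 250 mL; systemic flows <= cardiac output).
# Tissue composition fractions: Poulin & Theil 2002 (rat values where
# published; human values otherwise -- the fractions differ little).
# qh, liver weight and MPPGL are the compound study's anchored values.
# asf_kappa_per_cm: species absorption scale of the surrogate ASF model,
# calibrated once against the reported simulated oral exposure of the bundled
# compound (docs/methods.md) and then frozen.
species: rat
reference_body_weight_kg: 0.25
cardiac_output_ml_min: 80.0
qh_ml_min_kg: 70.0
liver_weight_per_kg: 40.0
mppgl: 45.0
asf_kappa_per_cm: 0.054
venous_blood_ml: 11.3
arterial_blood_ml: 4.9
plasma_composition: {f_water: 0.96, f_neutral_lipid: 0.00147, f_phospholipid: 0.00083}
tissues:
  # liver flow is the hepatic ARTERY; artery (3.9) + gut (13.0) + spleen (0.6)
  # = 17.5 mL/min = qh * 0.25 kg.
  - {name: lung,    volume_ml: 1.5,   flow_ml_min: 80.0, f_water: 0.79,  f_neutral_lipid: 0.0122, f_phospholipid: 0.0093, source: "Brown1997/PoulinTheil2002"}
  - {name: adipose, volume_ml: 19.0,  flow_ml_min: 1.6,  f_water: 0.12,  f_neutral_lipid: 0.853,  f_phospholipid: 0.0016, source: "Brown1997/PoulinTheil2002"}
  - {name: bone,    volume_ml: 15.0,  flow_ml_min: 2.5,  f_water: 0.446, f_neutral_lipid: 0.0273, f_phospholipid: 0.0027, source: "Brown1997/PoulinTheil2002"}
  - {name: brain,   volume_ml: 1.43,  flow_ml_min: 1.3,  f_water: 0.788, f_neutral_lipid: 0.0392, f_phospholipid: 0.0533, source: "Brown1997/PoulinTheil2002"}
  - {name: gut,     volume_ml: 11.3,  flow_ml_min: 13.0, f_water: 0.749, f_neutral_lipid: 0.0292, f_phospholipid: 0.0138, source: "Brown1997/PoulinTheil2002"}
  - {name: heart,   volume_ml: 0.83,  flow_ml_min: 3.9,  f_water: 0.779, f_neutral_lipid: 0.014,  f_phospholipid: 0.0118, source: "Brown1997/PoulinTheil2002"}
  - {name: kidney,  volume_ml: 1.83,  flow_ml_min: 9.2,  f_water: 0.771, f_neutral_lipid: 0.0123, f_phospholipid: 0.0284, source: "Brown1997/PoulinTheil2002"}
  - {name: liver,   volume_ml: 10.0,  flow_ml_min: 3.9,  f_water: 0.705, f_neutral_lipid: 0.0138, f_phospholipid: 0.0303, source: "study anchor 40 g/kg; PoulinTheil2002"}
  - {name: muscle,  volume_ml: 101.0, flow_ml_min: 22.0, f_water: 0.756, f_neutral_lipid: 0.01,   f_phospholipid: 0.009,  source: "Brown1997/PoulinTheil2002"}
  - {name: skin,    volume_ml: 40.0,  flow_ml_min: 5.0,  f_water: 0.651, f_neutral_lipid: 0.0239, f_phospholipid: 0.0111, source: "Brown1997/PoulinTheil2002"}
  - {name: spleen,  volume_ml: 0.5,   flow_ml_min: 0.6,  f_water: 0.771, f_neutral_lipid: 0.0077, f_phospholipid: 0.0136, source: "Brown1997/PoulinTheil2002"}
  - {name: rest,    volume_ml: 31.41, flow_ml_min: 17.0, f_water: 0.756, f_neutral_lipid: 0.01,   f_phospholipid: 0.009,  source: "balance; muscle-like composition"}
gi_compartments:
  # Fasted rat GI chain; small-intestinal transit totals ~1.35 h.  Stomach
  # transit is formulation-dependent and overridden at simulation time.
  - {name: stomach,   radius_cm: 0.40,  length_cm: 3.0,  volume_ml: 1.25, transit_h: 0.25, ph: 3.0, bile_salt_mM: 0.08, sa_amplification: 0.0, source: "fasted defaults"}
  - {name: duodenum,  radius_cm: 0.175, length_cm: 8.0,  volume_ml: 0.31, transit_h: 0.13, ph: 6.0, bile_salt_mM: 8.0,  sa_amplification: 4.0, source: "fasted defaults"}
  - {name: jejunum1,  radius_cm: 0.175, length_cm: 19.0, volume_ml: 0.73, transit_h: 0.28, ph: 6.2, bile_salt_mM: 6.0,  sa_amplification: 2.0, source: "fasted defaults"}
  - {name: jejunum2,  radius_cm: 0.170, length_cm: 19.0, volume_ml: 0.69, transit_h: 0.25, ph: 6.4, bile_salt_mM: 5.0,  sa_amplification: 0.8, source: "fasted defaults"}
  - {name: ileum1,    radius_cm: 0.165, length_cm: 19.0, volume_ml: 0.65, transit_h: 0.25, ph: 6.6, bile_salt_mM: 4.0,  sa_amplification: 0.3, source: "fasted defaults"}
  - {name: ileum2,    radius_cm: 0.160, length_cm: 19.0, volume_ml: 0.61, transit_h: 0.23, ph: 6.9, bile_salt_mM: 3.0,  sa_amplification: 0.12, source: "fasted defaults"}
  - {name: ileum3,    radius_cm: 0.155, length_cm: 19.0, volume_ml: 0.57, transit_h: 0.21, ph: 7.4, bile_salt_mM: 2.5,  sa_amplification: 0.05, source: "fasted defaults"}
  - {name: caecum,    radius_cm: 0.90,  length_cm: 4.0,  volume_ml: 2.0,  transit_h: 2.5,  ph: 6.2, bile_salt_mM: 1.0,  sa_amplification: 0.3, source: "fasted defaults"}
  - {name: asc_colon, radius_cm: 0.50,  length_cm: 10.0, volume_ml: 1.5,  transit_h: 4.0,  ph: 6.6, bile_salt_mM: 0.5,  sa_amplification: 0.3, source: "fasted defaults"}
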