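# Human whole-body physiology, 70 kg adult male reference.
# Volumes/flows: standard compilations (Davies & Morris 1993; Brown et al. 1997,
# ICRP 89), rounded so that volumes sum to 70 L and systemic flows to the
# cardiac output.  Tissue water/lipid fractions: Poulin & Theil 2002 (human).
# qh, liver weight and MPPGL are the compound study's anchored values.
# asf_kappa_per_cm is this package's species absorption scale: calibrated once
# against the reported simulated oral exposure of the bundled compound
# (see docs/methods.md) and then frozen.
species: human
reference_body_weight_kg: 70.0
cardiac_output_ml_min: 5600.0
qh_ml_min_kg: 20.0
liver_weight_per_kg: 21.0
mppgl: 45.0
asf_kappa_per_cm: 0.338
venous_blood_ml: 3640.0
arterial_blood_ml: 1560.0
plasma_composition: {f_water: 0.96, f_neutral_lipid: 0.00224, f_phospholipid: 0.00147}
tissues:
  # liver flow is the hepatic ARTERY; portal inflow = gut + spleen flows.
  # artery (423) + gut (900) + spleen (77) = 1400 = qh * 70 kg.
  - {name: lung,    volume_ml: 530.0,   flow_ml_min: 5600.0, f_water: 0.811, f_neutral_lipid: 0.0030, f_phospholipid: 0.0090, source: "Davies1993/PoulinTheil2002"}
  - {name: adipose, volume_ml: 12000.0, flow_ml_min: 260.0,  f_water: 0.18,  f_neutral_lipid: 0.79,   f_phospholipid: 0.0020, source: "Davies1993/PoulinTheil2002"}
  - {name: bone,    volume_ml: 8500.0,  flow_ml_min: 250.0,  f_water: 0.439, f_neutral_lipid: 0.074,  f_phospholipid: 0.0011, source: "Brown1997/PoulinTheil2002"}
  - {name: brain,   volume_ml: 1450.0,  flow_ml_min: 700.0,  f_water: 0.77,  f_neutral_lipid: 0.051,  f_phospholipid: 0.0565, source: "Davies1993/PoulinTheil2002"}
  - {name: gut,     volume_ml: 1100.0,  flow_ml_min: 900.0,  f_water: 0.718, f_neutral_lipid: 0.0487, f_phospholipid: 0.0163, source: "Davies1993/PoulinTheil2002"}
  - {name: heart,   volume_ml: 330.0,   flow_ml_min: 240.0,  f_water: 0.758, f_neutral_lipid: 0.0115, f_phospholipid: 0.0166, source: "Davies1993/PoulinTheil2002"}
  - {name: kidney,  volume_ml: 310.0,   flow_ml_min: 1100.0, f_water: 0.783, f_neutral_lipid: 0.0207, f_phospholipid: 0.0162, source: "Davies1993/PoulinTheil2002"}
  - {name: liver,   volume_ml: 1470.0,  flow_ml_min: 423.0,  f_water: 0.751, f_neutral_lipid: 0.0348, f_phospholipid: 0.0252, source: "study anchor 21 g/kg; PoulinTheil2002"}
  - {name: muscle,  volume_ml: 29000.0, flow_ml_min: 750.0,  f_water: 0.76,  f_neutral_lipid: 0.0238, f_phospholipid: 0.0072, source: "Davies1993/PoulinTheil2002"}
  - {name: skin,    volume_ml: 3400.0,  flow_ml_min: 300.0,  f_water: 0.718, f_neutral_lipid: 0.0284, f_phospholipid: 0.0111, source: "Brown1997/PoulinTheil2002"}
  - {name: spleen,  volume_ml: 180.0,   flow_ml_min: 77.0,   f_water: 0.788, f_neutral_lipid: 0.0201, f_phospholipid: 0.0198, source: "Davies1993/PoulinTheil2002"}
  - {name: rest,    volume_ml: 6530.0,  flow_ml_min: 600.0,  f_water: 0.76,  f_neutral_lipid: 0.0238, f_phospholipid: 0.0072, source: "balance; muscle-like composition"}
gi_compartments:
  # Fasted-state geometry/transit (ACAT-style 9-compartment chain); fluid
  # volumes ~40% of the cylindrical volume in the small intestine.  Stomach
  # transit is formulation-dependent and overridden at simulation time.
  # sa_amplification: relative absorptive-effectiveness weight of the
  # surrogate ASF model (villous amplification x proximal bias of micelle-
  # mediated uptake for high-logD compounds), declining steeply distally.
  - {name: stomach,   radius_cm: 10.0, length_cm: 20.0,  volume_ml: 46.0,  transit_h: 0.25,  ph: 1.3, bile_salt_mM: 0.08, sa_amplification: 0.0, source: "fasted defaults"}
  - {name: duodenum,  radius_cm: 1.53, length_cm: 14.0,  volume_ml: 42.0,  transit_h: 0.26,  ph: 6.0, bile_salt_mM: 2.8,  sa_amplification: 4.0, source: "fasted defaults"}
  - {name: jejunum1,  radius_cm: 1.45, length_cm: 58.0,  volume_ml: 154.0, transit_h: 0.95,  ph: 6.2, bile_salt_mM: 2.2,  sa_amplification: 0.8, source: "fasted defaults"}
  - {name: jejunum2,  radius_cm: 1.32, length_cm: 58.0,  volume_ml: 127.0, transit_h: 0.74,  ph: 6.4, bile_salt_mM: 1.8,  sa_amplification: 0.15, source: "fasted defaults"}
  - {name: ileum1,    radius_cm: 1.18, length_cm: 58.0,  volume_ml: 101.0, transit_h: 0.58,  ph: 6.6, bile_salt_mM: 1.5,  sa_amplification: 0.03, source: "fasted defaults"}
  - {name: ileum2,    radius_cm: 1.04, length_cm: 58.0,  volume_ml: 79.0,  transit_h: 0.42,  ph: 6.9, bile_salt_mM: 1.2,  sa_amplification: 0.01, source: "fasted defaults"}
  - {name: ileum3,    radius_cm: 0.85, length_cm: 58.0,  volume_ml: 53.0,  transit_h: 0.29,  ph: 7.4, bile_salt_mM: 1.0,  sa_amplification: 0.005, source: "fasted defaults"}
  - {name: caecum,    radius_cm: 3.39, length_cm: 13.8,  volume_ml: 50.0,  transit_h: 4.39,  ph: 6.4, bile_salt_mM: 0.5,  sa_amplification: 0.3, source: "fasted defaults"}
  - {name: asc_colon, radius_cm: 2.41, length_cm: 28.5,  volume_ml: 52.0,  transit_h: 13.1,  ph: 6.8, bile_salt_mM: 0.2,  sa_amplification: 0.3, source: "fasted defaults"}
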