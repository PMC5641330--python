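# pbpkpd

Whole-body physiologically based pharmacokinetic / pharmacodynamic (PBPK/PD)
modeling of **buagafuran**, a lipophilic anxiolytic agarofuran derivative,
built for the question its developers faced after phase I: *what oral dose
should go into efficacy trials?*  The package is aimed at DMPK modelers who
want the full animal-to-human chain — in vitro assay calculators, IVIVE
clearance, oral absorption, whole-body disposition, brain-driven
pharmacodynamics and regimen simulation — as open, tested Python instead of
a proprietary GUI.

## What it implements

- **Oral absorption**: a nine-compartment compartmental absorption and
  transit (ACAT-style) gut — stomach through ascending colon — with
  first-order transit, Nernst–Brunner dissolution, bile-salt solubilization,
  first-order precipitation, and permeability-driven uptake scaled by
  per-compartment absorption scale factors `ASF_n = C1 · w_n · κ` (C1–C4
  exposed for optimization; formulation-dependent gastric emptying, 0.1 h
  suspension / 1 h capsule).
- **Disposition**: perfusion-limited tissues with blood-referenced driving
  force `C_out = (A/V)·Rb/Kp`; Poulin–Theil homogeneous Kp from tissue
  composition with the optimized brain override (Kp = 6.7); hepatic-only
  elimination enforcing the well-stirred clearance exactly
  (`F_hepatic = 1 − CLhep/Qh`); renal clearance 0.
- **IVIVE**: microsomal depletion → `CLint(app) = k/M` →
  `CLint = CLint(app)·MPPGL·liver weight` → well-stirred
  `CLhep = fub·Qh·CLint / (Qh + fub·CLint)`, used as the initial guess that
  observed data refine (reference CLhep 36.8 rat / 11.7 human mL/min/kg).
- **Pharmacodynamics**: direct-link sigmoid Emax on brain concentration,
  `E = E0 + Emax·C^γ/(EC50^γ + C^γ)` (E0 = 0.63, EC50 = 10.6 ng/mL,
  γ = 2.5), with fixed-baseline fitting, R²/AIC reporting and
  non-identifiability flags.
- **Analysis tools**: WinNonlin-style NCA (Cmax/Tmax/AUC/MRT/λz), one-at-a-
  time parameter sensitivity analysis, joint bounded least-squares
  refinement across datasets, synthetic-data generators with known ground
  truth, and multiple-dose regimen comparison (`30mg t.i.d. x7d` grammar).

## Worked example

```bash
python examples/01_simulate_human_single_dose.py
```

```
fraction absorbed      0.194
plasma Cmax            15.47 ng/mL at 1.49 h
plasma AUC0-48h        67.4 ng*h/mL
plasma AUC0-inf        67.6 ng*h/mL
brain Cmax             100.6 ng/mL (Kp brain 6.7)
mass-balance error     5.2e-15 (relative)
```

A 30 mg capsule in a 70 kg adult: ~19% of the dose crosses the gut wall
(permeability/efflux-limited — the compound is a P-gp substrate), 58% of
that is lost to hepatic first pass, and the surviving ~2 mg produces a
~15 ng/mL plasma peak 1.5 h after dosing.  Brain exposure runs ~6.7× plasma.

The dose-selection logic itself:

```bash
python examples/05_dose_regimen_selection.py
```

```
        regimen  daily_dose_mg  brain_cmax_ss  brain_cmin_ss  brain_cavg_ss  fraction_above_threshold  avg_effect
30mg t.i.d. x7d          90.00         108.94          13.42          56.61                      1.00        2.49
60mg b.i.d. x7d         120.00         208.45           9.17          75.48                      0.92        2.35
```

At steady state, 30 mg three-times-daily keeps brain levels above the
EC50 (10.6 ng/mL) for the whole day; doubling the unit dose to 60 mg
twice-daily nearly doubles the brain peak yet buys no additional average
effect — both regimens sit on the Emax plateau — which is the case for
30 mg t.i.d. as the candidate therapeutic regimen.

Other examples: `02` IVIVE clearance chain, `03` tissue partition table and
Vss, `04` EPM Emax fitting on synthetic behavioral data, `06` sensitivity
analysis and clearance refitting.  A thin CLI mirrors the library
(`pbpkpd simulate|nca|ivive|kp|pdfit|pdsim|psa|fit|synth|papp|regimen-compare|reproduce`),
writing a JSON run manifest next to every output.

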