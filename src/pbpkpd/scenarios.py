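"""Bundled reference study arms for the shipped compound (buagafuran).

These are the final, optimized parameterizations: ASF coefficient C1 of
0.6805 (rat) / 0.8005 (human), refined hepatic clearance of 36.8 (rat) /
11.7 (human) mL/min/kg, brain Kp override 6.7 in both species, zero renal
clearance, suspension dosing in rat (0.1 h gastric emptying) and capsule
dosing in human (1 h).  Default body weights: 0.2 kg rat, 70 kg adult male.

Fitted PD parameters of the elevated-plus-maze response: baseline E0 = 0.63,
EC50 = 10.6 ng/mL (brain), Hill coefficient gamma = 2.5.  The maximal effect
Emax is not part of the reference set; a plausible value of 2.0 is used
where a complete parameter set is needed (synthetic data, regimen ranking).
"""

from __future__ import annotations

from .absorption import ASFCoefficients
from .engine import PBPKModel, build_model
from .errors import SpeciesLookupError
from .parameters import (
    DoseRegimen,
    bundled_compound,
    default_formulation,
    load_physiology,
)
from .pd_emax import EmaxParams

ASF_C1_DEFAULT = 0.8805
ASF_C1 = {"rat": 0.6805, "human": 0.8005}
CLHEP_ML_MIN_KG = {"rat": 36.8, "human": 11.7}
KP_BRAIN = 6.7
BODY_WEIGHT_KG = {"rat": 0.2, "human": 70.0}

#: Effective partitioning lipophilicity fed to the Poulin-Theil Kp
#: prediction in the reference arms.  Octanol logP (6.24) overpredicts
#: membrane partitioning by orders of magnitude for this compound class; this
#: value is a one-time calibration of the non-brain tissue partitioning
#: against the reported simulated disposition (docs/methods.md) and is frozen.
KP_PARTITION_LOGP = 0.0

PD_E0 = 0.63
PD_EC50_NG_ML = 10.6
PD_GAMMA = 2.5
PD_EMAX_NOMINAL = 2.0


def reference_pd_params(emax: float = PD_EMAX_NOMINAL) -> EmaxParams:
    return EmaxParams(e0=PD_E0, emax=emax, ec50=PD_EC50_NG_ML, gamma=PD_GAMMA)


def reference_model(
    species: str,
    body_weight_kg: float | None = None,
    c1: float | None = None,
    clhep_ml_min_kg: float | None = None,
    kp_brain: float | None = KP_BRAIN,
) -> PBPKModel:
    """The optimized whole-body model for one species."""
    if species not in ASF_C1:
        raise SpeciesLookupError(f"no reference model for species {species!r}")
    compound = bundled_compound()
    physiology = load_physiology(species)
    overrides = {"brain": kp_brain} if kp_brain is not None else None
    return build_model(
        compound=compound,
        physiology=physiology,
        clhep_ml_min_kg=(
            clhep_ml_min_kg if clhep_ml_min_kg is not None else CLHEP_ML_MIN_KG[species]
        ),
        formulation=default_formulation(species),
        asf=ASFCoefficients(c1=c1 if c1 is not None else ASF_C1[species]),
        kp_overrides=overrides,
        body_weight_kg=body_weight_kg or BODY_WEIGHT_KG[species],
        partition_logp=KP_PARTITION_LOGP,
    )


def rat_oral_regimen(dose_mg_per_kg: float, horizon_h: float = 3.0,
                     body_weight_kg: float = BODY_WEIGHT_KG["rat"]) -> DoseRegimen:
    """Single oral rat dose given in mg/kg (the rat study arms: 4, 8 mg/kg)."""
    return DoseRegimen.single(
        dose_mg_per_kg * body_weight_kg, horizon_h, f"rat {dose_mg_per_kg} mg/kg"
    )


def human_single_dose(dose_mg: float, horizon_h: float = 48.0) -> DoseRegimen:
    """Single oral human dose (the clinical arms: 30, 60, 120 mg)."""
    return DoseRegimen.single(dose_mg, horizon_h, f"human {dose_mg:g} mg single")
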