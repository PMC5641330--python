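"""IVIVE of hepatic clearance from microsomal substrate depletion.

Chain: first-order depletion slope k -> apparent intrinsic clearance
CLint(app) = k / M (mL/min/mg microsomal protein) -> whole-liver intrinsic
clearance CLint = CLint(app) * MPPGL * liver-weight-per-kg (mL/min/kg)
-> well-stirred hepatic blood clearance

    CLhep = fub * Qh * (CLint/fuinc) / (Qh + fub * (CLint/fuinc)),
    fub = fup / Rb.

The depletion relation is dimensionally forced to k/M (1/min over mg/mL
gives mL/min/mg).  ``fuinc`` (unbound fraction in the incubation) defaults
to 1 and is exposed for binding corrections.  Renal clearance of the bundled
compound is zero (urinary recovery of parent < 1% of dose).

IVIVE typically underestimates in vivo clearance for compounds with
extra-microsomal (e.g. conjugative or extrahepatic) elimination, so the
pipeline treats CLhep as a user-supplied or fitted parameter and the IVIVE
value as the initial guess only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, PreconditionError


@dataclass
class DepletionFit:
    k_per_min: float
    t_half_min: float
    clint_app_ml_min_mg: float
    r2: float
    depleting: bool  # False when the fitted slope is not a real loss (k <= 0)


@dataclass
class ClearanceParams:
    """Clearance block of a PBPK model (all per kg body weight, blood basis)."""

    clhep_ml_min_kg: float
    clrenal_ml_min_kg: float = 0.0
    clint_ml_min_kg: float | None = None
    fuinc: float = 1.0

    def __post_init__(self):
        if self.clhep_ml_min_kg < 0 or self.clrenal_ml_min_kg < 0:
            raise DomainError("clearances must be >= 0")
        if not 0 < self.fuinc <= 1:
            raise DomainError("fuinc must be in (0, 1]")


def clint_app_from_depletion(
    timepoints_min, concentrations, m_protein_mg_ml: float
) -> DepletionFit:
    """Fit ln(C) vs t by least squares; k is the negated slope.

    Non-depleting data (k <= 0) are returned flagged, not raised: a zero
    slope is a legitimate assay outcome (no measurable metabolism).
    """
    t = np.asarray(timepoints_min, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 3:
        raise PreconditionError("need >= 3 depletion timepoints")
    if np.any(c <= 0):
        raise DomainError("concentrations must be positive for a ln-linear fit")
    if m_protein_mg_ml <= 0:
        raise DomainError("microsomal protein concentration must be > 0")
    lnc = np.log(c)
    slope, intercept = np.polyfit(t, lnc, 1)
    resid = lnc - (slope * t + intercept)
    ss_tot = float(np.sum((lnc - lnc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    k = -float(slope)
    if k <= 1e-10:  # numerically zero slope: no measurable depletion
        return DepletionFit(0.0, np.inf, 0.0, r2, depleting=False)
    return DepletionFit(k, np.log(2) / k, k / m_protein_mg_ml, r2, depleting=True)


def scale_clint(
    clint_app_ml_min_mg: float, mppgl: float, liver_weight_per_kg: float
) -> float:
    """Scale per-mg-protein clearance to whole-liver mL/min/kg body weight."""
    if clint_app_ml_min_mg < 0:
        raise DomainError("clint_app must be >= 0")
    if mppgl <= 0 or liver_weight_per_kg <= 0:
        raise DomainError("scaling constants must be > 0")
    return clint_app_ml_min_mg * mppgl * liver_weight_per_kg


def well_stirred_clhep(
    clint_ml_min_kg: float,
    fup: float,
    rb: float,
    qh_ml_min_kg: float,
    fuinc: float = 1.0,
) -> float:
    """Well-stirred hepatic blood clearance (mL/min/kg); strictly < Qh."""
    if qh_ml_min_kg <= 0:
        raise DomainError("Qh must be > 0")
    if not 0 < fuinc <= 1:
        raise DomainError("fuinc must be in (0, 1]")
    if not 0 < fup <= 1:
        raise DomainError("fup must be in (0, 1]")
    if rb <= 0:
        raise DomainError("Rb must be > 0")
    if clint_ml_min_kg < 0:
        raise DomainError("CLint must be >= 0")
    fub = fup / rb
    clu = clint_ml_min_kg / fuinc
    return fub * qh_ml_min_kg * clu / (qh_ml_min_kg + fub * clu)
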