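"""In vitro assay calculators: Caco-2 permeability, efflux ratio, dialysis fu.

Papp comes from a linear fit of cumulative receiver amount vs time,
``Papp = (dQ/dt) / (A * C0)``.  Runs are only accepted when the linear fit
has correlation R > 0.9 (the study's validity rule).  Because 50 uL of
receiver fluid is replaced at every sampling time, the measured receiver
amount under-reads the true cumulative transport; the withdrawal correction
re-adds the drug removed with earlier samples and is on by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, PreconditionError


@dataclass
class TransportObservation:
    """One directional Caco-2 transport run.

    times in min; receiver amounts in nmol (as sampled); membrane area cm^2;
    donor concentration in uM; sample/receiver volumes in mL.
    """

    direction: str  # "AP->BL" | "BL->AP"
    times_min: np.ndarray
    receiver_amount_nmol: np.ndarray
    membrane_area_cm2: float = 0.6
    initial_conc_um: float = 50.0
    receiver_volume_ml: float = 0.6
    sample_volume_ml: float = 0.05

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.receiver_amount_nmol = np.asarray(self.receiver_amount_nmol, dtype=float)
        if self.direction not in ("AP->BL", "BL->AP"):
            raise DomainError(f"unknown direction {self.direction!r}")
        if self.times_min.shape != self.receiver_amount_nmol.shape:
            raise PreconditionError("times and amounts must align")


@dataclass
class PappResult:
    papp_cm_s: float
    slope_nmol_s: float
    r: float
    corrected: bool


def papp(obs: TransportObservation, withdrawal_correction: bool = True) -> PappResult:
    """Apparent permeability from a transport run, in cm/s.

    The slope dQ/dt (nmol/s) is the least-squares fit of (corrected)
    cumulative receiver amount against time; Papp = slope / (A * C0) with C0
    in nmol/mL so the result is cm/s.  Raises :class:`DomainError` when the
    fit correlation R <= 0.9.
    """
    t = obs.times_min * 60.0  # s
    if t.size < 3:
        raise PreconditionError("need >= 3 sampling times in the linear window")
    q = obs.receiver_amount_nmol.copy()
    if withdrawal_correction and obs.receiver_volume_ml > 0:
        # each earlier draw removed sample_volume/receiver_volume of what was
        # then in the receiver; add those aliquots back cumulatively.
        frac = obs.sample_volume_ml / obs.receiver_volume_ml
        removed = 0.0
        for i in range(q.size):
            q[i] += removed
            removed += frac * obs.receiver_amount_nmol[i]
    slope, intercept = np.polyfit(t, q, 1)
    if np.allclose(q, q[0]):
        # zero transport: slope 0 by construction, R undefined -> Papp 0
        return PappResult(0.0, 0.0, 1.0, withdrawal_correction)
    r = float(np.corrcoef(t, q)[0, 1])
    if not r > 0.9:
        raise DomainError(f"transport run not linear: R = {r:.3f} <= 0.9")
    c0_nmol_ml = obs.initial_conc_um  # 1 uM == 1 nmol/mL
    papp_cm_s = float(slope / (obs.membrane_area_cm2 * c0_nmol_ml))
    return PappResult(papp_cm_s, float(slope), r, withdrawal_correction)


def efflux_ratio(papp_ab_cm_s: float, papp_ba_cm_s: float) -> float:
    """Efflux ratio ER = Papp(BL->AP) / Papp(AP->BL)."""
    if papp_ab_cm_s <= 0:
        raise DomainError("absorptive Papp must be > 0 for an efflux ratio")
    if papp_ba_cm_s < 0:
        raise DomainError("Papp cannot be negative")
    return papp_ba_cm_s / papp_ab_cm_s


def fu_dialysis(conc_buffer: float, conc_plasma: float) -> float:
    """Unbound plasma fraction from equilibrium dialysis: fu = C_buffer/C_plasma.

    Values > 1 (assay noise) are reported clipped to 1 with a warning.
    """
    if conc_buffer < 0 or conc_plasma < 0:
        raise DomainError("concentrations must be non-negative")
    if conc_plasma == 0:
        raise DomainError("plasma concentration must be > 0")
    fu = conc_buffer / conc_plasma
    if fu > 1:
        warnings.warn(f"fu = {fu:.3f} > 1 clipped to 1 (assay noise)", stacklevel=2)
        return 1.0
    return fu
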