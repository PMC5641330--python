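"""Compartmental absorption and transit (ACAT-style) oral absorption.

Nine well-mixed GI compartments (stomach, duodenum, jejunum x2, ileum x3,
caecum, ascending colon) with first-order transit, Nernst-Brunner
dissolution, first-order precipitation of supersaturated excess, and
permeability-driven absorption scaled per compartment by an absorption scale
factor (ASF).

ASF surrogate
-------------
The reference tool's "Opt logD SA/V" ASF law is proprietary; this module
implements a documented surrogate,

    small intestine:  ASF_n = C1 * w_n * kappa * g(logD; C2)
    caecum / colon:   ASF_n = C3 (C4) * w_n * kappa

where ``w_n`` is the relative surface-to-volume ratio of compartment n
(cylindrical 2/R corrected by the shipped villous surface-amplification
profile and normalized to the duodenum), ``kappa`` (1/cm) is the species
absorption scale shipped with the physiology (a one-time calibration of the
surrogate, see docs/methods.md), and ``g(logD; C2) = 10**(-C2*max(logD-3, 0))``
is a monotone lipophilicity attenuation (default C2 = 0: no attenuation).
ASF is linear in C1 by construction, and C1-C4 are exposed for optimization.

The absorption rate from compartment n is  Peff * ASF_n * C_n * V_n, with
Peff from a species-specific log-log Caco-2 correlation.

Dissolution and luminal solubility
----------------------------------
Dissolution follows Nernst-Brunner for monodisperse spheres at the dosed
particle radius (diffusion-layer thickness = particle radius; fixed specific
surface area, i.e. area proportional to undissolved mass).  Luminal
solubility is the aqueous solubility augmented by bile-salt micellar
solubilization with a lipophilicity-derived solubilization ratio
(log10 SR = 2.23 + 0.61 logP), so strongly lipophilic compounds are rarely
solubility-limited in the fasted intestine.  Supersaturated excess
precipitates first-order with the compound's mean precipitation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, PreconditionError, SpeciesLookupError
from .parameters import CompoundRecord, FormulationSpec, SpeciesPhysiology
from .units import S_PER_H, cm_s_to_cm_h

N_GUT = 9
#: gut state layout: undissolved (9), dissolved (9), cumulative absorbed,
#: cumulative transited out of the ascending colon
N_GUT_STATE = 2 * N_GUT + 2
IDX_ABSORBED = 2 * N_GUT
IDX_EXITED = 2 * N_GUT + 1

#: Caco-2 -> effective jejunal permeability power-law (log-log) constants:
#: Peff[cm/s] = A_species * (Papp[cm/s] / 1e-5)**B.  The human/rat ratio of
#: 3.6 follows the classic human:rat Peff proportionality.
PEFF_CORRELATION = {
    "human": {"a_cm_s": 5.0e-5, "b": 0.7},
    "rat": {"a_cm_s": 5.0e-5 / 3.6, "b": 0.7},
}

#: bile-salt solubilization ratio correlation (molar): log10 SR = 2.23 + 0.61 logP
SR_INTERCEPT, SR_SLOPE = 2.23, 0.61

#: upper bound on luminal solubility (mg/mL): the SR correlation extrapolates
#: unphysically beyond logP ~5, and fasted-state micelles cannot carry more
#: drug than roughly their own mass concentration allows
LUMINAL_SOLUBILITY_CAP_MG_ML = 25.0


@dataclass
class ASFCoefficients:
    """ASF scaling coefficients; C1/C2 act on the small intestine, C3/C4 on
    caecum and ascending colon.  Default C1 = 0.8805 (the unoptimized
    reference value the study adjusted per species).  The colon defaults are
    deliberately small: the fasted colon holds little free water and the
    shipped compound is an efflux substrate, so colonic uptake is marginal
    (consistent with near-complete small-intestinal absorption of what gets
    absorbed at all)."""

    c1: float = 0.8805
    c2: float = 0.0
    c3: float = 0.2
    c4: float = 0.05

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3, self.c4) < 0:
            raise DomainError("ASF coefficients must be >= 0")


def peff_from_caco2(papp_caco2_cm_s: float, species: str) -> float:
    """Effective intestinal permeability (cm/s) from a Caco-2 Papp."""
    if papp_caco2_cm_s < 0:
        raise DomainError("Papp must be >= 0")
    try:
        cc = PEFF_CORRELATION[species]
    except KeyError:
        raise SpeciesLookupError(f"no Peff correlation for species {species!r}") from None
    if papp_caco2_cm_s == 0:
        return 0.0
    return cc["a_cm_s"] * (papp_caco2_cm_s / 1e-5) ** cc["b"]


def asf_profile(
    coeffs: ASFCoefficients, logd: float, physiology: SpeciesPhysiology
) -> np.ndarray:
    """Per-compartment absorption scale factors (1/cm); stomach is 0."""
    gi = physiology.gi_compartments
    if len(gi) != N_GUT:
        raise PreconditionError("physiology must have 9 gut compartments")
    duod = gi[1]
    g = 10.0 ** (-coeffs.c2 * max(logd - 3.0, 0.0))
    asf = np.zeros(N_GUT)
    for n, comp in enumerate(gi):
        if n == 0:
            continue  # no gastric absorption
        w = (comp.sa_amplification / duod.sa_amplification) * (
            duod.radius_cm / comp.radius_cm
        )
        if comp.name in ("caecum", "asc_colon"):
            c = coeffs.c3 if comp.name == "caecum" else coeffs.c4
            asf[n] = c * w * physiology.asf_kappa_per_cm
        else:
            asf[n] = coeffs.c1 * w * physiology.asf_kappa_per_cm * g
    return asf


def solubilization_ratio(logp: float) -> float:
    """Micellar solubilization ratio (mol drug per mol bile salt)."""
    return 10.0 ** (SR_INTERCEPT + SR_SLOPE * logp)


def effective_solubility_profile(
    compound: CompoundRecord, physiology: SpeciesPhysiology
) -> np.ndarray:
    """Luminal solubility (mg/mL) per compartment: aqueous + bile-salt term."""
    sr = solubilization_ratio(compound.logp)
    out = np.empty(N_GUT)
    for n, comp in enumerate(physiology.gi_compartments):
        micellar = sr * (comp.bile_salt_mM * 1e-3) * compound.mw  # g/L == mg/mL
        out[n] = min(
            compound.solubility_mg_ml + micellar, LUMINAL_SOLUBILITY_CAP_MG_ML
        )
    return out


def dissolution_rate(
    undissolved_mg: float,
    dissolved_conc_mg_ml: float,
    solubility_mg_ml: float,
    particle_radius_um: float,
    particle_density_g_ml: float,
    diffusion_coeff_1e5_cm2_s: float,
    volume_ml: float,
) -> float:
    """Nernst-Brunner dissolution rate, mg/h (zero at/above saturation).

    rate = 3 D M (Cs - C) / (rho r^2), with the diffusion-layer thickness set
    to the particle radius; surface area is 3 M / (rho r).
    """
    if min(particle_radius_um, particle_density_g_ml, volume_ml) <= 0:
        raise DomainError("particle radius, density and volume must be > 0")
    if undissolved_mg <= 0:
        return 0.0
    driving = solubility_mg_ml - dissolved_conc_mg_ml
    if driving <= 0:
        return 0.0
    d_cm2_h = diffusion_coeff_1e5_cm2_s * 1e-5 * S_PER_H
    r_cm = particle_radius_um * 1e-4
    rho_mg_cm3 = particle_density_g_ml * 1000.0
    return 3.0 * d_cm2_h * undissolved_mg * driving / (rho_mg_cm3 * r_cm**2)


def precipitation_rate(
    dissolved_conc_mg_ml: float,
    solubility_mg_ml: float,
    mean_precip_time_s: float,
    volume_ml: float = 1.0,
) -> float:
    """First-order precipitation of the supersaturated excess, mg/h."""
    if mean_precip_time_s <= 0:
        raise DomainError("mean precipitation time must be > 0")
    excess_conc = dissolved_conc_mg_ml - solubility_mg_ml
    if excess_conc <= 0:
        return 0.0
    return excess_conc * volume_ml * (S_PER_H / mean_precip_time_s)


class GutModel:
    """Pre-assembled right-hand side of the gut subsystem.

    State layout (mg): undissolved[0:9], dissolved[9:18], cumulative absorbed
    [18], cumulative exited [19].  The absorption flux per compartment is
    ``ka_n * dissolved_n`` with ``ka_n = Peff * ASF_n`` (1/h).
    """

    def __init__(
        self,
        compound: CompoundRecord,
        physiology: SpeciesPhysiology,
        formulation: FormulationSpec,
        asf_coeffs: ASFCoefficients | None = None,
        peff_scale: float = 1.0,
    ):
        asf_coeffs = asf_coeffs or ASFCoefficients()
        gi = physiology.gi_compartments
        # logD = logP for a neutral compound (no ionization correction)
        self.asf = asf_profile(asf_coeffs, compound.logp, physiology)
        peff_cm_h = cm_s_to_cm_h(
            peff_from_caco2(compound.papp_caco2_cm_s, physiology.species)
        )
        self.ka = peff_cm_h * self.asf * peff_scale  # 1/h
        self.kt = np.array(
            [
                1.0 / (formulation.stomach_transit_h if n == 0 else gi[n].transit_h)
                for n in range(N_GUT)
            ]
        )
        self.volumes = np.array([c.volume_ml for c in gi])
        self.cs = effective_solubility_profile(compound, physiology)
        d_cm2_h = compound.diffusion_coeff_1e5_cm2_s * 1e-5 * S_PER_H
        r_cm = compound.particle_radius_um * 1e-4
        rho = compound.particle_density_g_ml * 1000.0
        self.kdis = 3.0 * d_cm2_h / (rho * r_cm**2)  # per mg per (mg/mL)
        self.kprec = S_PER_H / compound.mean_precip_time_s  # 1/h

    def rhs(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (d state/dt, absorption flux into the portal vein in mg/h)."""
        und = y[:N_GUT]
        dis = y[N_GUT : 2 * N_GUT]
        conc = dis / self.volumes
        driving = self.cs - conc
        dissolution = np.where(
            (und > 0) & (driving > 0), self.kdis * und * driving, 0.0
        )
        precip = np.where(driving < 0, -driving * self.volumes * self.kprec, 0.0)
        net_dis = dissolution - precip
        absorb = self.ka * dis
        dy = np.empty(N_GUT_STATE)
        d_und = -self.kt * und - net_dis
        d_dis = -self.kt * dis + net_dis - absorb
        # transit chain: compartment n feeds n+1; colon output leaves the body
        d_und[1:] += self.kt[:-1] * und[:-1]
        d_dis[1:] += self.kt[:-1] * dis[:-1]
        dy[:N_GUT] = d_und
        dy[N_GUT : 2 * N_GUT] = d_dis
        dy[IDX_ABSORBED] = absorb.sum()
        dy[IDX_EXITED] = self.kt[-1] * (und[-1] + dis[-1])
        return dy, float(absorb.sum())


def fraction_absorbed(
    compound: CompoundRecord,
    physiology: SpeciesPhysiology,
    formulation: FormulationSpec,
    dose_mg: float,
    asf_coeffs: ASFCoefficients | None = None,
    t_end_h: float = 48.0,
    rtol: float = 1e-8,
) -> float:
    """Fraction of an oral dose absorbed across the gut wall (sink blood).

    Integrates the gut subsystem alone; useful for absorption-only studies
    and property checks.
    """
    from scipy.integrate import solve_ivp

    gut = GutModel(compound, physiology, formulation, asf_coeffs)
    y0 = np.zeros(N_GUT_STATE)
    y0[0] = dose_mg
    sol = solve_ivp(
        lambda t, y: gut.rhs(y)[0],
        (0.0, t_end_h),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=dose_mg * 1e-12 + 1e-15,
    )
    if not sol.success:
        raise DomainError(f"gut integration failed: {sol.message}")
    return float(sol.y[IDX_ABSORBED, -1] / dose_mg) if dose_mg > 0 else 0.0
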