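"""Tissue:plasma partition coefficients (Poulin & Theil, homogeneous model).

For a neutral compound the tissue:plasma ratio is predicted from tissue and
plasma composition:

    Kp = [P*(Vnl_t + 0.3*Vph_t) + (Vw_t + 0.7*Vph_t)]
         / [P*(Vnl_p + 0.3*Vph_p) + (Vw_p + 0.7*Vph_p)] * (fup / fut)

with P = 10**logP (octanol:water), Vnl/Vph/Vw the fractional neutral lipid,
phospholipid and water contents, and the tissue unbound fraction estimated by
the standard convention fut = 1 / (1 + 0.5*(1 - fup)/fup).  Phospholipids are
treated as 30% lipid-like / 70% water-like, hence the 0.3/0.7 weights.

The alternative perfusion-limited Kp scheme that handles ionized species
(Rodgers-Rowland) is deliberately not implemented -- the compound this
package ships is neutral -- but the interface is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DomainError, SpeciesLookupError
from .parameters import CompoundRecord, SpeciesPhysiology


def fut_poulin_theil(fup: float) -> float:
    """Tissue unbound fraction from plasma unbound fraction (standard convention)."""
    if not 0 < fup <= 1:
        raise DomainError("fup must be in (0, 1]")
    return 1.0 / (1.0 + 0.5 * (1.0 - fup) / fup)


def poulin_theil_kp(
    logp: float,
    fup: float,
    tissue_comp: tuple[float, float, float],
    plasma_comp: tuple[float, float, float],
    fut: float | None = None,
) -> float:
    """Homogeneous-model Kp for a neutral compound.

    ``tissue_comp``/``plasma_comp`` are (f_water, f_neutral_lipid,
    f_phospholipid) fractions.
    """
    vw_t, vnl_t, vph_t = tissue_comp
    vw_p, vnl_p, vph_p = plasma_comp
    if vw_t + vnl_t + vph_t <= 0 or vw_p + vnl_p + vph_p <= 0:
        raise DomainError("degenerate all-zero composition")
    p = 10.0**logp
    if fut is None:
        fut = fut_poulin_theil(fup)
    num = p * (vnl_t + 0.3 * vph_t) + (vw_t + 0.7 * vph_t)
    den = p * (vnl_p + 0.3 * vph_p) + (vw_p + 0.7 * vph_p)
    return (num / den) * (fup / fut)


@dataclass
class KpSet:
    """Per-tissue Kp with provenance; overrides win over predictions."""

    kp: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, tissue: str) -> float:
        try:
            return self.kp[tissue]
        except KeyError:
            raise SpeciesLookupError(f"no Kp for tissue {tissue!r}") from None

    def with_override(self, tissue: str, value: float) -> "KpSet":
        if tissue not in self.kp:
            raise SpeciesLookupError(f"override for unknown tissue {tissue!r}")
        if value <= 0:
            raise DomainError("Kp override must be > 0")
        kp = dict(self.kp)
        prov = dict(self.provenance)
        kp[tissue] = value
        prov[tissue] = "optimized"
        return KpSet(kp, prov)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": list(self.kp),
                "kp": [self.kp[t] for t in self.kp],
                "provenance": [self.provenance.get(t, "predicted") for t in self.kp],
            }
        )


def build_kpset(
    compound: CompoundRecord,
    physiology: SpeciesPhysiology,
    overrides: dict[str, float] | None = None,
    partition_logp: float | None = None,
) -> KpSet:
    """Predict Kp for every perfused tissue; apply optimized overrides.

    ``partition_logp`` is the lipophilicity fed to the Kp prediction; it
    defaults to the compound's octanol logP.  For strongly lipophilic
    compounds octanol:water grossly overpredicts membrane/tissue
    partitioning, so the bundled study arms use a calibrated effective
    partitioning lipophilicity instead (see docs/methods.md).

    The bundled study arms also override brain Kp to 6.7 (optimized against
    rat brain data and carried over to human).
    """
    fup = compound.fup(physiology.species)
    logp = compound.logp if partition_logp is None else partition_logp
    plasma = (
        physiology.plasma_composition.f_water,
        physiology.plasma_composition.f_neutral_lipid,
        physiology.plasma_composition.f_phospholipid,
    )
    kp: dict[str, float] = {}
    prov: dict[str, str] = {}
    for t in physiology.tissues:
        kp[t.name] = poulin_theil_kp(
            logp,
            fup,
            (t.f_water, t.f_neutral_lipid, t.f_phospholipid),
            plasma,
        )
        prov[t.name] = "predicted"
    kpset = KpSet(kp, prov)
    for tissue, value in (overrides or {}).items():
        kpset = kpset.with_override(tissue, value)
    return kpset


def vss_l(kpset: KpSet, physiology: SpeciesPhysiology) -> float:
    """Steady-state distribution volume: sum Vt*Kpt + Vplasma, in litres."""
    v = sum(t.volume_ml * kpset[t.name] for t in physiology.tissues)
    v += physiology.venous_blood_ml + physiology.arterial_blood_ml
    return v / 1000.0
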