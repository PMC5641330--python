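"""Typed parameter containers, shipped physiology tables and config I/O.

Configuration dialect
---------------------
Compound and physiology files are human-readable YAML.  Unknown keys are
**errors**, not warnings: silently ignored typos in parameter names are the
dominant failure mode of PBPK configs.  Observed concentration data travel as
CSV with columns ``time_h, conc_ng_ml, matrix, dose, species`` (plus an
optional ``censored`` flag for below-LLOQ records).

Shipped physiology
------------------
Rat and human whole-body tables (tissue volumes, blood flows, lipid/water
composition, GI geometry and transit) are package data with a provenance
column per entry.  Only hepatic blood flow, liver weight and microsomal
protein content are compound-study anchors; the rest are standard published
compilations (Brown et al. 1997; Davies & Morris 1993; Poulin & Theil 2002).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigError, ParseError, RangeError, SpeciesLookupError

SPECIES = ("rat", "human")
MATRICES = ("plasma", "brain")

#: canonical order of the nine gut compartments (stomach -> ascending colon)
GI_ORDER = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "caecum",
    "asc_colon",
)


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=False)


class CompoundRecord(_StrictModel):
    """Physicochemical and in vitro parameters of a compound.

    Units: mw g/mol; solubility mg/mL (intrinsic aqueous, at ``solubility_ref_ph``);
    papp_caco2 cm/s; particle radius um; particle density g/mL; diffusion
    coefficient in 1e-5 cm^2/s; mean precipitation time s.  ``rb`` is the
    blood:plasma concentration ratio, ``fup_by_species`` the unbound plasma
    fraction per species.
    """

    name: str
    mw: float
    logp: float
    solubility_mg_ml: float
    solubility_ref_ph: float = 7.0
    pka_list: list[float] = []
    papp_caco2_cm_s: float
    rb: float
    fup_by_species: dict[str, float]
    particle_radius_um: float
    particle_density_g_ml: float
    diffusion_coeff_1e5_cm2_s: float
    mean_precip_time_s: float

    @model_validator(mode="after")
    def _ranges(self) -> "CompoundRecord":
        if self.mw <= 0:
            raise ValueError("range: mw must be > 0")
        if self.solubility_mg_ml <= 0:
            raise ValueError("range: solubility_mg_ml must be > 0")
        if self.rb <= 0:
            raise ValueError("range: rb must be > 0")
        if self.papp_caco2_cm_s < 0:
            raise ValueError("range: papp_caco2_cm_s must be >= 0")
        if self.particle_radius_um <= 0:
            raise ValueError("range: particle_radius_um must be > 0")
        if self.particle_density_g_ml <= 0:
            raise ValueError("range: particle_density_g_ml must be > 0")
        if self.diffusion_coeff_1e5_cm2_s <= 0:
            raise ValueError("range: diffusion_coeff_1e5_cm2_s must be > 0")
        if self.mean_precip_time_s <= 0:
            raise ValueError("range: mean_precip_time_s must be > 0")
        for sp, fup in self.fup_by_species.items():
            if not 0 < fup <= 1:
                raise ValueError(f"range: fup for {sp!r} must be in (0, 1]")
        if self.pka_list:
            # v1 handles neutral compounds only; ionization is a non-goal.
            raise ValueError("range: pka_list must be empty (neutral compounds only)")
        return self

    def fup(self, species: str) -> float:
        try:
            return self.fup_by_species[species]
        except KeyError:
            raise SpeciesLookupError(f"no fup for species {species!r}") from None


class TissueSpec(_StrictModel):
    """One perfused tissue: volume, blood flow, and lipid/water composition."""

    name: str
    volume_ml: float
    flow_ml_min: float
    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float
    source: str = ""

    @model_validator(mode="after")
    def _ranges(self) -> "TissueSpec":
        if self.volume_ml <= 0 or self.flow_ml_min <= 0:
            raise ValueError(f"range: {self.name}: volume and flow must be > 0")
        for f in (self.f_water, self.f_neutral_lipid, self.f_phospholipid):
            if not 0 <= f <= 1:
                raise ValueError(f"range: {self.name}: composition fractions in [0,1]")
        return self


class GICompartment(_StrictModel):
    """One gut compartment: cylindrical geometry, fluid volume, transit, milieu."""

    name: str
    radius_cm: float
    length_cm: float
    volume_ml: float
    transit_h: float
    ph: float
    bile_salt_mM: float
    sa_amplification: float
    source: str = ""

    @model_validator(mode="after")
    def _ranges(self) -> "GICompartment":
        if min(self.radius_cm, self.length_cm, self.volume_ml, self.transit_h) <= 0:
            raise ValueError(f"range: {self.name}: geometry/transit must be > 0")
        if self.bile_salt_mM < 0 or self.sa_amplification < 0:
            raise ValueError(f"range: {self.name}: bile salt and SA amplification >= 0")
        return self


class PlasmaComposition(_StrictModel):
    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float


class SpeciesPhysiology(_StrictModel):
    """Whole-body physiology of one species at a reference body weight.

    ``tissues`` lists every perfused non-blood compartment (lung included;
    the liver entry's flow is the *hepatic artery* -- portal inflow is the sum
    of gut and spleen flows).  ``asf_kappa_per_cm`` is the species absorption
    scale of the surrogate ASF model (see :mod:`pbpkpd.absorption`).
    """

    species: str
    reference_body_weight_kg: float
    cardiac_output_ml_min: float
    qh_ml_min_kg: float
    liver_weight_per_kg: float
    mppgl: float
    asf_kappa_per_cm: float
    venous_blood_ml: float
    arterial_blood_ml: float
    plasma_composition: PlasmaComposition
    tissues: list[TissueSpec]
    gi_compartments: list[GICompartment]

    @model_validator(mode="after")
    def _invariants(self) -> "SpeciesPhysiology":
        if self.species not in SPECIES:
            raise ValueError(f"range: unknown species {self.species!r}")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("range: duplicate tissue names")
        for required in ("lung", "liver", "gut", "spleen", "brain"):
            if required not in names:
                raise ValueError(f"range: missing required tissue {required!r}")
        gi_names = tuple(g.name for g in self.gi_compartments)
        if gi_names != GI_ORDER:
            raise ValueError(
                f"range: gi_compartments must be the 9 entries {GI_ORDER}, got {gi_names}"
            )
        # lung receives total cardiac output and is excluded from the sum.
        systemic = sum(t.flow_ml_min for t in self.tissues if t.name != "lung")
        if systemic > self.cardiac_output_ml_min * (1 + 1e-9):
            raise ValueError("range: sum of tissue flows exceeds cardiac output")
        qh_abs = self.qh_ml_min_kg * self.reference_body_weight_kg
        portal_plus_artery = sum(
            t.flow_ml_min for t in self.tissues if t.name in ("liver", "gut", "spleen")
        )
        if abs(portal_plus_artery - qh_abs) > 0.02 * qh_abs:
            raise ValueError(
                "range: hepatic artery + portal (gut+spleen) flows must equal "
                f"qh*BW ({qh_abs:.1f} mL/min), got {portal_plus_artery:.1f}"
            )
        return self

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise SpeciesLookupError(f"no tissue {name!r} in {self.species} physiology")

    def scaled_to(self, body_weight_kg: float) -> "SpeciesPhysiology":
        """Linearly rescale volumes and flows to a new body weight.

        Per-kg quantities (qh, liver weight, MPPGL) and GI radii are kept;
        GI fluid volumes scale with weight.
        """
        if body_weight_kg <= 0:
            raise RangeError("body weight must be > 0")
        s = body_weight_kg / self.reference_body_weight_kg
        data = self.model_dump()
        data["reference_body_weight_kg"] = body_weight_kg
        data["cardiac_output_ml_min"] *= s
        data["venous_blood_ml"] *= s
        data["arterial_blood_ml"] *= s
        for t in data["tissues"]:
            t["volume_ml"] *= s
            t["flow_ml_min"] *= s
        for g in data["gi_compartments"]:
            g["volume_ml"] *= s
        return SpeciesPhysiology.model_validate(data)

    @property
    def body_weight_kg(self) -> float:
        return self.reference_body_weight_kg


class FormulationSpec(_StrictModel):
    """Dosage form; its only model effect is the gastric emptying time."""

    dosage_form: str  # "IR suspension" | "IR capsule"
    stomach_transit_h: float
    species: str

    @model_validator(mode="after")
    def _ranges(self) -> "FormulationSpec":
        if self.dosage_form not in ("IR suspension", "IR capsule"):
            raise ValueError(f"range: unknown dosage form {self.dosage_form!r}")
        if self.stomach_transit_h <= 0:
            raise ValueError("range: stomach_transit_h must be > 0")
        if self.species not in SPECIES:
            raise ValueError(f"range: unknown species {self.species!r}")
        return self


#: shipped default gastric emptying per dosage form (h)
STOMACH_TRANSIT_DEFAULT_H = {"IR suspension": 0.1, "IR capsule": 1.0}


def default_formulation(species: str) -> FormulationSpec:
    """Suspension for rat, capsule for human (the bundled study arms)."""
    form = "IR suspension" if species == "rat" else "IR capsule"
    return FormulationSpec(
        dosage_form=form,
        stomach_transit_h=STOMACH_TRANSIT_DEFAULT_H[form],
        species=species,
    )


@dataclass(frozen=True)
class DoseRegimen:
    """A list of (time h, amount mg) dose events and a simulation horizon."""

    doses: tuple[tuple[float, float], ...]
    horizon_h: float
    label: str = ""

    def __post_init__(self):
        times = [t for t, _ in self.doses]
        if any(t < 0 for t in times):
            raise RangeError("dose times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise RangeError("dose times must be strictly increasing")
        if self.doses and self.horizon_h < times[-1]:
            raise RangeError("horizon must cover the last dose time")
        if any(a < 0 for _, a in self.doses):
            raise RangeError("dose amounts must be >= 0")

    @classmethod
    def single(cls, dose_mg: float, horizon_h: float, label: str = "") -> "DoseRegimen":
        return cls(doses=((0.0, dose_mg),), horizon_h=horizon_h, label=label)


@dataclass
class ObservedDataset:
    """Observed concentration-time records (long format) plus a study label.

    ``data`` columns: time_h, conc_ng_ml, matrix, dose, species, censored.
    """

    data: pd.DataFrame
    metadata: str = ""

    REQUIRED = ("time_h", "conc_ng_ml", "matrix", "dose", "species")

    def __post_init__(self):
        df = self.data.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ConfigError(f"observed data missing column {col!r}")
        if "censored" not in df.columns:
            df["censored"] = False
        df = df.sort_values(["matrix", "time_h"], kind="stable").reset_index(drop=True)
        self.data = df

    @property
    def records(self):
        return list(self.data.itertuples(index=False))

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ObservedDataset):
            return NotImplemented
        return self.metadata == other.metadata and self.data.equals(other.data)


# ---------------------------------------------------------------------------
# config I/O


def _validate_into(model_cls, payload: dict, what: str):
    try:
        return model_cls.model_validate(payload)
    except pydantic.ValidationError as err:
        first = err.errors()[0]
        msg = first.get("msg", "")
        loc = ".".join(str(x) for x in first.get("loc", ()))
        if "range:" in msg:
            raise RangeError(f"{what}: {msg.split('range:', 1)[1].strip()}") from None
        if first.get("type") == "extra_forbidden":
            raise ConfigError(f"{what}: unknown key {loc!r}") from None
        if first.get("type") == "missing":
            raise ConfigError(f"{what}: missing mandatory field {loc!r}") from None
        raise ConfigError(f"{what}: field {loc!r}: {msg}") from None


def load_compound(path) -> CompoundRecord:
    """Read a compound YAML config, validating every invariant."""
    with open(path) as fh:
        try:
            payload = yaml.safe_load(fh)
        except yaml.YAMLError as err:
            raise ConfigError(f"{path}: not valid YAML: {err}") from None
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a key-value mapping")
    return _validate_into(CompoundRecord, payload, str(path))


def write_compound(record: CompoundRecord, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(record.model_dump(), fh, sort_keys=False)


def _data_text(fname: str) -> str:
    return (importlib.resources.files("pbpkpd") / "data" / fname).read_text()


def bundled_compound(name: str = "buagafuran") -> CompoundRecord:
    """Load a compound shipped as package data (currently only buagafuran)."""
    try:
        text = _data_text(f"compound_{name}.yaml")
    except FileNotFoundError:
        raise ConfigError(f"no bundled compound {name!r}") from None
    return _validate_into(CompoundRecord, yaml.safe_load(text), f"bundled {name}")


def load_physiology(species: str) -> SpeciesPhysiology:
    """Load the shipped physiology table for ``species`` ("rat" or "human")."""
    if species not in SPECIES:
        raise SpeciesLookupError(
            f"unknown species {species!r}; shipped tables: {SPECIES}"
        )
    payload = yaml.safe_load(_data_text(f"physiology_{species}.yaml"))
    return _validate_into(SpeciesPhysiology, payload, f"physiology {species}")


def read_observations(path) -> ObservedDataset:
    """Read an observations CSV; malformed rows raise :class:`ParseError`."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # header-level failure
        raise ParseError(f"cannot read {path}: {err}") from None
    for col in ObservedDataset.REQUIRED:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            t, c = float(row.time_h), float(row.conc_ng_ml)
        except (TypeError, ValueError):
            raise ParseError("non-numeric time/concentration", line=i) from None
        if t < 0:
            raise ParseError(f"negative time {t}", line=i)
        if c < 0:
            raise ParseError(f"negative concentration {c}", line=i)
        if row.matrix not in MATRICES:
            raise ParseError(f"unknown matrix {row.matrix!r}", line=i)
        if row.species not in SPECIES:
            raise ParseError(f"unknown species {row.species!r}", line=i)
    return ObservedDataset(data=df, metadata=str(path))


def write_observations(dataset: ObservedDataset, path) -> None:
    dataset.data.to_csv(path, index=False)
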