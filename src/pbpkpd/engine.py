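"""Whole-body perfusion-limited PBPK engine.

Structure: the gut chain (see :mod:`pbpkpd.absorption`) feeds absorbed drug
into the portal inflow of the liver; every tissue is flow-limited with
venous-equilibrated outflow ``C_out = (A/V) * Rb / Kp`` (blood-referenced
driving force); venous blood collects all tissue outflows, passes through the
lung, and returns as arterial blood.  Elimination happens only in the liver
(renal clearance is zero for the bundled compound) through an intrinsic-like
blood clearance

    CLu = Qh * CLhep / (Qh - CLhep)

applied to the liver outflow concentration, which makes the systemic blood
clearance exactly the specified well-stirred CLhep and the hepatic first-pass
availability exactly 1 - CLhep/Qh.

Dose events re-initialize the state exactly (the integrator is restarted at
every dose time); mass balance over gut + body + eliminated + exited is
audited at every output time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .absorption import IDX_ABSORBED, IDX_EXITED, N_GUT, N_GUT_STATE, ASFCoefficients, GutModel
from .clearance import ClearanceParams
from .errors import PreconditionError, RangeError, SolverError
from .parameters import (
    CompoundRecord,
    DoseRegimen,
    FormulationSpec,
    SpeciesPhysiology,
)
from .partition import KpSet, build_kpset
from .units import MG_PER_ML_TO_NG_PER_ML, MIN_PER_H


@dataclass
class PBPKModel:
    """A fully parameterized whole-body model for one species/formulation."""

    compound: CompoundRecord
    physiology: SpeciesPhysiology  # already scaled to body_weight
    kpset: KpSet
    clearance: ClearanceParams
    asf: ASFCoefficients
    formulation: FormulationSpec
    body_weight_kg: float

    def __post_init__(self):
        qh = self.physiology.qh_ml_min_kg
        if self.clearance.clhep_ml_min_kg >= qh:
            raise RangeError(
                f"clhep {self.clearance.clhep_ml_min_kg} must be < hepatic blood "
                f"flow {qh} mL/min/kg (well-stirred bound)"
            )
        if self.formulation.species != self.physiology.species:
            raise RangeError("formulation species does not match physiology")

    def replace(self, **kw) -> "PBPKModel":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def build_model(
    compound: CompoundRecord,
    physiology: SpeciesPhysiology,
    clhep_ml_min_kg: float,
    formulation: FormulationSpec,
    asf: ASFCoefficients | None = None,
    kp_overrides: dict[str, float] | None = None,
    body_weight_kg: float | None = None,
    partition_logp: float | None = None,
) -> PBPKModel:
    """Assemble a model, predicting Kp and scaling physiology to body weight."""
    bw = body_weight_kg or physiology.reference_body_weight_kg
    phys = physiology.scaled_to(bw)
    kpset = build_kpset(
        compound, phys, overrides=kp_overrides, partition_logp=partition_logp
    )
    return PBPKModel(
        compound=compound,
        physiology=phys,
        kpset=kpset,
        clearance=ClearanceParams(clhep_ml_min_kg=clhep_ml_min_kg),
        asf=asf or ASFCoefficients(),
        formulation=formulation,
        body_weight_kg=bw,
    )


@dataclass
class PBPKResult:
    """Solved trajectories plus refined peak metrics.

    Concentrations are venous *plasma* (and brain tissue) in ng/mL; tissue
    amounts in mg.  ``mass_balance_error`` is the max relative deviation of
    (gut + body + eliminated + exited) from the administered total.
    """

    times: np.ndarray
    plasma_conc: np.ndarray
    brain_conc: np.ndarray
    tissue_amounts: pd.DataFrame
    gut: pd.DataFrame
    mass_balance_error: float
    cmax_plasma: float
    tmax_plasma: float
    cmax_brain: float
    tmax_brain: float
    fraction_absorbed: float
    _segments: list = field(default_factory=list, repr=False)
    _model: "PBPKModel | None" = field(default=None, repr=False)

    def conc_at(self, times, matrix: str = "plasma") -> np.ndarray:
        """Evaluate the dense solution at arbitrary times (ng/mL)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty(times.shape)
        for i, t in enumerate(times):
            y = _eval_segments(self._segments, t)
            out[i] = _conc_from_state(self._model, y, matrix)
        return out


class _System:
    """Assembled ODE right-hand side for one model."""

    def __init__(self, model: PBPKModel):
        phys = model.physiology
        self.model = model
        self.gut = GutModel(
            model.compound, phys, model.formulation, model.asf
        )
        self.tissues = [t.name for t in phys.tissues]
        nt = len(self.tissues)
        self.nt = nt
        self.i_t0 = N_GUT_STATE
        self.i_ven = N_GUT_STATE + nt
        self.i_art = self.i_ven + 1
        self.i_elim = self.i_ven + 2
        self.n_state = self.i_elim + 1

        self.v = np.array([t.volume_ml for t in phys.tissues])
        self.q = np.array([t.flow_ml_min * MIN_PER_H for t in phys.tissues])
        self.kp = np.array([model.kpset[t.name] for t in phys.tissues])
        self.rb = model.compound.rb
        self.v_ven = phys.venous_blood_ml
        self.v_art = phys.arterial_blood_ml
        self.co = phys.cardiac_output_ml_min * MIN_PER_H

        self.i_lung = self.tissues.index("lung")
        self.i_liver = self.tissues.index("liver")
        self.i_gutw = self.tissues.index("gut")
        self.i_spleen = self.tissues.index("spleen")
        self.i_brain = self.tissues.index("brain")

        clhep = model.clearance.clhep_ml_min_kg * model.body_weight_kg * MIN_PER_H
        qh = (
            self.q[self.i_liver] + self.q[self.i_gutw] + self.q[self.i_spleen]
        )
        self.q_liver_total = qh
        # intrinsic-like blood clearance applied to liver outflow
        self.clu = qh * clhep / (qh - clhep) if clhep > 0 else 0.0
        # systemic arterial distribution; any CO not assigned to a tissue is
        # an arteriovenous shunt straight back to venous blood
        q_sys = self.q.sum() - self.q[self.i_lung]
        self.q_shunt = max(self.co - q_sys, 0.0)
        # outflow coefficient per tissue: C_out = A * rb/(kp*v)
        self.c_out_coef = self.rb / (self.kp * self.v)

    def rhs(self, t, y):
        dy = np.empty(self.n_state)
        gut_dy, r_abs = self.gut.rhs(y[:N_GUT_STATE])
        dy[:N_GUT_STATE] = gut_dy

        a_t = y[self.i_t0 : self.i_t0 + self.nt]
        c_out = a_t * self.c_out_coef
        c_ven = y[self.i_ven] / self.v_ven
        c_art = y[self.i_art] / self.v_art

        d_t = self.q * (c_art - c_out)
        # lung: driven by venous return at total cardiac output
        d_t[self.i_lung] = self.co * (c_ven - c_out[self.i_lung])
        # liver: hepatic artery + portal (gut wall + spleen outflows) +
        # freshly absorbed drug; clearance on the outflow concentration
        portal_in = (
            self.q[self.i_gutw] * c_out[self.i_gutw]
            + self.q[self.i_spleen] * c_out[self.i_spleen]
        )
        d_t[self.i_liver] = (
            self.q[self.i_liver] * c_art
            + portal_in
            + r_abs
            - (self.q_liver_total + self.clu) * c_out[self.i_liver]
        )

        venous_in = (
            sum(
                self.q[i] * c_out[i]
                for i in range(self.nt)
                if i not in (self.i_lung, self.i_liver, self.i_gutw, self.i_spleen)
            )
            + self.q_liver_total * c_out[self.i_liver]
            + self.q_shunt * c_art
        )
        dy[self.i_ven] = venous_in - self.co * c_ven
        dy[self.i_art] = self.co * (c_out[self.i_lung] - c_art)
        dy[self.i_t0 : self.i_t0 + self.nt] = d_t
        dy[self.i_elim] = self.clu * c_out[self.i_liver]
        return dy


def _conc_from_state(model_sys, y, matrix: str) -> float:
    sys = model_sys
    if matrix == "plasma":
        c_blood = y[sys.i_ven] / sys.v_ven
        return c_blood / sys.rb * MG_PER_ML_TO_NG_PER_ML
    if matrix == "brain":
        i = sys.i_t0 + sys.i_brain
        return (
            y[i] / sys.v[sys.i_brain] * MG_PER_ML_TO_NG_PER_ML
        )
    raise PreconditionError(f"unknown matrix {matrix!r}")


def _eval_segments(segments, t: float) -> np.ndarray:
    for t0, t1, sol in segments:
        if t0 <= t <= t1:
            return sol(t)
    t0, t1, sol = segments[-1]
    return sol(min(max(t, t0), t1))


def _refine_peak(segments, sys, grid_t, grid_c, matrix: str) -> tuple[float, float]:
    """Refine (cmax, tmax) around the grid argmax using the dense solution."""
    i = int(np.argmax(grid_c))
    lo = grid_t[max(i - 1, 0)]
    hi = grid_t[min(i + 1, len(grid_t) - 1)]
    ts = np.linspace(lo, hi, 201)
    cs = np.array(
        [_conc_from_state(sys, _eval_segments(segments, t), matrix) for t in ts]
    )
    j = int(np.argmax(cs))
    return float(cs[j]), float(ts[j])


def simulate(
    model: PBPKModel,
    regimen: DoseRegimen,
    grid_dt_h: float = 0.05,
    rtol: float = 1e-9,
    atol_scale: float = 1e-13,
    route: str = "oral",
    initial: str = "empty",
) -> PBPKResult:
    """Integrate the model over a dosing regimen.

    Dose events are handled exactly: the stiff integrator (LSODA) restarts at
    every dose time with the dose added to the stomach (oral) or venous blood
    (iv).  ``initial="equilibrated"`` pre-distributes the first iv dose at
    distribution equilibrium (a degenerate mode used for closed-form
    verification).
    """
    if regimen.doses and regimen.doses[-1][0] > regimen.horizon_h:
        raise PreconditionError("regimen extends beyond horizon")
    sys = _System(model)
    total_dose = sum(a for _, a in regimen.doses)
    atol = max(total_dose, 1e-6) * atol_scale

    y = np.zeros(sys.n_state)
    dose_times = [t for t, _ in regimen.doses]
    bounds = sorted(set(dose_times + [0.0, regimen.horizon_h]))
    if bounds[-1] < regimen.horizon_h:
        bounds.append(regimen.horizon_h)
    dose_at = dict(regimen.doses)

    segments = []
    times_out = [np.array([0.0])]
    # apply dose at t=0 if present
    for k in range(len(bounds) - 1):
        t0, t1 = bounds[k], bounds[k + 1]
        if t0 in dose_at:
            amt = dose_at[t0]
            if route == "oral":
                y[0] += amt  # undissolved drug into the stomach
            elif route == "iv":
                if initial == "equilibrated" and k == 0:
                    c_b = amt / (
                        sys.v_ven
                        + sys.v_art
                        + float(np.sum(sys.kp * sys.v / sys.rb))
                    )
                    y[sys.i_ven] += c_b * sys.v_ven
                    y[sys.i_art] += c_b * sys.v_art
                    y[sys.i_t0 : sys.i_t0 + sys.nt] += (
                        c_b * sys.kp * sys.v / sys.rb
                    )
                else:
                    y[sys.i_ven] += amt
            else:
                raise PreconditionError(f"unknown route {route!r}")
        t_eval = np.arange(t0, t1, grid_dt_h)[1:]
        try:
            sol = solve_ivp(
                sys.rhs,
                (t0, t1),
                y,
                method="LSODA",
                dense_output=True,
                rtol=rtol,
                atol=atol,
            )
        except ValueError:
            # LSODA's dense output occasionally emits duplicate step times on
            # stiff segments; BDF is the robust fallback
            sol = solve_ivp(
                sys.rhs,
                (t0, t1),
                y,
                method="BDF",
                dense_output=True,
                rtol=rtol,
                atol=atol,
            )
        if not sol.success:
            raise SolverError(
                f"integration failed in [{t0}, {t1}]: {sol.message}",
                t_last=float(sol.t[-1]),
                y_last=sol.y[:, -1],
            )
        segments.append((t0, t1, sol.sol))
        times_out.append(np.append(t_eval, t1))
        y = sol.y[:, -1].copy()

    times = np.unique(np.concatenate(times_out))
    states = np.column_stack([_eval_segments(segments, t) for t in times])

    plasma = states[sys.i_ven] / sys.v_ven / sys.rb * MG_PER_ML_TO_NG_PER_ML
    brain = (
        states[sys.i_t0 + sys.i_brain] / sys.v[sys.i_brain] * MG_PER_ML_TO_NG_PER_ML
    )

    # mass balance audit: everything administered so far must be accounted for
    administered = np.array(
        [sum(a for td, a in regimen.doses if td <= t + 1e-12) for t in times]
    )
    gut_drug = states[: 2 * N_GUT].sum(axis=0) + states[IDX_EXITED]
    body = states[sys.i_t0 : sys.i_t0 + sys.nt].sum(axis=0)
    body += states[sys.i_ven] + states[sys.i_art] + states[sys.i_elim]
    with np.errstate(invalid="ignore", divide="ignore"):
        mbe = np.abs(gut_drug + body - administered) / np.where(
            administered > 0, administered, 1.0
        )
    mass_balance_error = float(np.max(mbe)) if administered[-1] > 0 else 0.0

    cmax_p, tmax_p = _refine_peak(segments, sys, times, plasma, "plasma")
    cmax_b, tmax_b = _refine_peak(segments, sys, times, brain, "brain")

    tissue_amounts = pd.DataFrame(
        states[sys.i_t0 : sys.i_t0 + sys.nt].T, index=times, columns=sys.tissues
    )
    gut_cols = (
        [f"undissolved_{g.name}" for g in model.physiology.gi_compartments]
        + [f"dissolved_{g.name}" for g in model.physiology.gi_compartments]
        + ["absorbed", "exited"]
    )
    gut = pd.DataFrame(states[:N_GUT_STATE].T, index=times, columns=gut_cols)
    fa = (
        float(states[IDX_ABSORBED, -1] / administered[-1])
        if route == "oral" and administered[-1] > 0
        else 0.0
    )

    return PBPKResult(
        times=times,
        plasma_conc=plasma,
        brain_conc=brain,
        tissue_amounts=tissue_amounts,
        gut=gut,
        mass_balance_error=mass_balance_error,
        cmax_plasma=cmax_p,
        tmax_plasma=tmax_p,
        cmax_brain=cmax_b,
        tmax_brain=tmax_b,
        fraction_absorbed=fa,
        _segments=segments,
        _model=sys,
    )


@dataclass
class SteadyStateMetrics:
    cmax_ss: float
    cmin_ss: float
    cavg_ss: float
    fraction_above_threshold: float


def steady_state_metrics(
    result: PBPKResult,
    tau_h: float,
    threshold_ng_ml: float,
    matrix: str = "brain",
    n_fine: int = 2001,
) -> SteadyStateMetrics:
    """Cmax/Cmin/Cavg and fraction of the dosing interval above a threshold,
    computed on the last complete interval of a multiple-dose simulation."""
    t_end = float(result.times[-1])
    if t_end < 5 * tau_h:
        raise PreconditionError("simulation must span >= 5 dosing intervals")
    ts = np.linspace(t_end - tau_h, t_end, n_fine)
    cs = result.conc_at(ts, matrix=matrix)
    cavg = float(np.trapezoid(cs, ts) / tau_h)
    return SteadyStateMetrics(
        cmax_ss=float(cs.max()),
        cmin_ss=float(cs.min()),
        cavg_ss=cavg,
        fraction_above_threshold=float(np.mean(cs > threshold_ng_ml)),
    )
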