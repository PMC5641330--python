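"""Whole-body PBPK engine: conservation, limits, closed-form equivalence."""

import numpy as np
import pytest

from pbpkpd import scenarios
from pbpkpd.engine import build_model, simulate, steady_state_metrics
from pbpkpd.errors import PreconditionError, RangeError
from pbpkpd.parameters import (
    DoseRegimen,
    bundled_compound,
    default_formulation,
    load_physiology,
)


def _one_compartment_model(clhep=0.1):
    """All Kp = 1, Rb = 1: the body collapses toward one well-mixed volume."""
    comp = bundled_compound().model_copy(update={"rb": 1.0})
    phys = load_physiology("human")
    m = build_model(comp, phys, clhep_ml_min_kg=clhep,
                    formulation=default_formulation("human"))
    for t in m.kpset.kp:
        m.kpset.kp[t] = 1.0
    return m


def _total_volume_ml(model):
    phys = model.physiology
    return (
        sum(t.volume_ml for t in phys.tissues)
        + phys.venous_blood_ml
        + phys.arterial_blood_ml
    )


def test_zero_dose_gives_zero_concentrations(rat_model):
    reg = DoseRegimen(doses=((0.0, 0.0),), horizon_h=3.0)
    res = simulate(rat_model, reg)
    assert np.all(res.plasma_conc == 0.0)
    assert np.all(res.brain_conc == 0.0)


def test_mass_balance_below_1e6(rat_result_4, human_result_30):
    assert rat_result_4.mass_balance_error < 1e-6
    assert human_result_30.mass_balance_error < 1e-6


def test_iv_bolus_matches_one_compartment_closed_form():
    # equilibrated-start iv bolus with uniform partitioning and elimination
    # slow against inter-tissue flows: C(t) = (D/Vss) * exp(-CL*t/Vss)
    m = _one_compartment_model(clhep=0.1)
    dose = 10.0
    reg = DoseRegimen(doses=((0.0, dose),), horizon_h=12.0)
    res = simulate(m, reg, route="iv", initial="equilibrated", grid_dt_h=0.1)
    v = _total_volume_ml(m)
    cl_ml_h = 0.1 * m.body_weight_kg * 60.0
    closed = dose / v * np.exp(-cl_ml_h * res.times / v) * 1e6
    assert np.max(np.abs(res.plasma_conc - closed) / closed) < 5e-3


def test_multiple_dose_accumulation_matches_superposition():
    # one-compartment limit: trough accumulation = (1-e^(-n*k*tau))/(1-e^(-k*tau))
    m = _one_compartment_model(clhep=0.1)
    v = _total_volume_ml(m)
    k = 0.1 * m.body_weight_kg * 60.0 / v
    tau, n = 8.0, 10
    reg = DoseRegimen(
        doses=tuple((tau * i, 10.0) for i in range(n)), horizon_h=tau * n
    )
    res = simulate(m, reg, route="iv", grid_dt_h=0.1)
    first = res.conc_at([tau - 1e-3])[0]
    last = res.conc_at([tau * n - 1e-3])[0]
    expected = (1 - np.exp(-n * k * tau)) / (1 - np.exp(-k * tau))
    assert last / first == pytest.approx(expected, rel=0.03)


def test_dose_linearity_below_saturation(rat_result_4, rat_result_8):
    # sub-solubility regime: doubling the dose doubles Cmax and AUC
    ratio_cmax = rat_result_8.cmax_plasma / rat_result_4.cmax_plasma
    auc4 = np.trapezoid(rat_result_4.plasma_conc, rat_result_4.times)
    auc8 = np.trapezoid(rat_result_8.plasma_conc, rat_result_8.times)
    assert ratio_cmax == pytest.approx(2.0, rel=1e-3)
    assert auc8 / auc4 == pytest.approx(2.0, rel=1e-3)


def test_solver_tolerance_convergence(rat_model):
    reg = scenarios.rat_oral_regimen(4.0)
    a = simulate(rat_model, reg, grid_dt_h=0.02, rtol=1e-9)
    b = simulate(rat_model, reg, grid_dt_h=0.02, rtol=5e-10)
    auc = lambda r: np.trapezoid(r.plasma_conc, r.times)
    assert abs(a.cmax_plasma / b.cmax_plasma - 1) < 1e-4
    assert abs(auc(a) / auc(b) - 1) < 1e-4


def test_steady_state_tissue_plasma_ratio_equals_kp(rat_model):
    # quasi-infusion (frequent small doses): tissue:plasma ratios converge to
    # the Kp definition (brain carries the optimized override)
    reg = DoseRegimen(
        doses=tuple((0.25 * i, 0.02) for i in range(96)), horizon_h=24.0
    )
    res = simulate(rat_model, reg, grid_dt_h=0.05)
    cp = res.plasma_conc[-1]
    assert res.brain_conc[-1] / cp == pytest.approx(
        rat_model.kpset["brain"], rel=0.05
    )
    v_mus = rat_model.physiology.tissue("muscle").volume_ml
    c_mus = res.tissue_amounts["muscle"].iloc[-1] / v_mus * 1e6
    assert c_mus / cp == pytest.approx(rat_model.kpset["muscle"], rel=0.05)


def test_clearance_must_stay_below_hepatic_flow():
    comp = bundled_compound()
    phys = load_physiology("rat")
    with pytest.raises(RangeError):
        build_model(comp, phys, clhep_ml_min_kg=70.0,
                    formulation=default_formulation("rat"))


class TestSteadyStateMetrics:
    def test_constant_infusion_fraction_one(self):
        m = _one_compartment_model(clhep=0.5)
        reg = DoseRegimen(
            doses=tuple((0.25 * i, 1.0) for i in range(192)), horizon_h=48.0
        )
        res = simulate(m, reg, route="iv", grid_dt_h=0.1)
        ss = steady_state_metrics(res, tau_h=8.0, threshold_ng_ml=1.0,
                                  matrix="plasma")
        assert ss.fraction_above_threshold == 1.0
        assert ss.cmin_ss <= ss.cavg_ss <= ss.cmax_ss

    def test_horizon_too_short_rejected(self, rat_result_4):
        with pytest.raises(PreconditionError):
            steady_state_metrics(rat_result_4, tau_h=8.0, threshold_ng_ml=1.0)


def test_refined_peak_consistent_with_grid(human_result_30):
    grid_max = human_result_30.plasma_conc.max()
    assert human_result_30.cmax_plasma >= grid_max - 1e-12
    assert human_result_30.cmax_plasma == pytest.approx(grid_max, rel=0.01)
    t = human_result_30.tmax_plasma
    assert human_result_30.times[0] <= t <= human_result_30.times[-1]
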