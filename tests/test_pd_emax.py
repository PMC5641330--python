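"""Direct-link sigmoid Emax model: identities, fitting, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpkpd import scenarios
from pbpkpd.pd_emax import EmaxParams, effect_at, fit_emax, pd_profile


@settings(max_examples=50, deadline=None)
@given(
    e0=st.floats(0.0, 5.0),
    emax=st.floats(0.0, 10.0),
    ec50=st.floats(1e-3, 1e3),
    gamma=st.floats(0.1, 8.0),
)
def test_emax_identities(e0, emax, ec50, gamma):
    p = EmaxParams(e0=e0, emax=emax, ec50=ec50, gamma=gamma)
    assert effect_at(p, 0.0) == pytest.approx(e0)
    assert effect_at(p, ec50) == pytest.approx(e0 + emax / 2, rel=1e-9, abs=1e-12)
    c_plateau = ec50 * 10.0 ** (12.0 / gamma)
    assert effect_at(p, c_plateau) == pytest.approx(e0 + emax, rel=1e-6, abs=1e-9)
    # monotone in concentration
    grid = np.geomspace(ec50 / 100, ec50 * 100, 20)
    assert np.all(np.diff(effect_at(p, grid)) >= -1e-12)


def test_noise_free_fit_recovers_parameters():
    truth = EmaxParams(e0=0.63, emax=2.0, ec50=10.6, gamma=2.5)
    conc = np.array([0.5, 2, 5, 8, 12, 20, 40, 80])
    fit = fit_emax(conc, effect_at(truth, conc), fixed_e0=0.63)
    assert fit.params.emax == pytest.approx(truth.emax, rel=1e-6)
    assert fit.params.ec50 == pytest.approx(truth.ec50, rel=1e-6)
    assert fit.params.gamma == pytest.approx(truth.gamma, rel=1e-6)
    assert fit.r2 > 1 - 1e-9
    assert fit.identifiable


def test_fit_scale_equivariance():
    # multiplying concentrations by s multiplies EC50 by s, leaves the rest
    truth = EmaxParams(e0=0.63, emax=2.0, ec50=10.6, gamma=2.5)
    rng = np.random.default_rng(7)
    conc = np.geomspace(1, 80, 10)
    eff = effect_at(truth, conc) + rng.normal(0, 0.02, conc.size)
    f1 = fit_emax(conc, eff, fixed_e0=0.63)
    s = 37.0
    f2 = fit_emax(conc * s, eff, fixed_e0=0.63)
    assert f2.params.ec50 == pytest.approx(f1.params.ec50 * s, rel=1e-4)
    assert f2.params.gamma == pytest.approx(f1.params.gamma, rel=1e-4)
    assert f2.params.emax == pytest.approx(f1.params.emax, rel=1e-4)


def test_linear_data_prefers_linear_model_by_aic():
    rng = np.random.default_rng(11)
    conc = np.linspace(1, 50, 12)
    eff = 0.63 + 0.03 * conc + rng.normal(0, 0.01, conc.size)
    hill = fit_emax(conc, eff, fixed_e0=0.63)
    # linear comparator fitted independently, same AIC convention
    slope, icpt = np.polyfit(conc, eff, 1)
    resid = eff - (slope * conc + icpt)
    n = conc.size
    aic_lin = n * np.log(np.sum(resid**2) / n) + 2 * 2
    assert aic_lin < hill.aic


def test_flat_design_flagged_non_identifiable():
    truth = EmaxParams(e0=0.63, emax=2.0, ec50=10.6, gamma=2.5)
    rng = np.random.default_rng(3)
    conc = np.linspace(0.01, 0.3, 8)  # everything far below EC50
    eff = effect_at(truth, conc) + rng.normal(0, 0.01, conc.size)
    fit = fit_emax(conc, eff, fixed_e0=0.63)
    assert not fit.identifiable
    assert fit.message


class TestPDProfile:
    def test_flat_at_baseline_for_zero_concentration(self, rat_model):
        from pbpkpd.engine import simulate
        from pbpkpd.parameters import DoseRegimen

        res = simulate(rat_model, DoseRegimen(doses=((0.0, 0.0),), horizon_h=1.0))
        prof = pd_profile(scenarios.reference_pd_params(), res)
        assert np.allclose(prof.effect, 0.63)

    def test_monotone_composition(self):
        p = scenarios.reference_pd_params()

        class FakeResult:
            times = np.linspace(0, 1, 20)
            brain_conc = np.linspace(0, 50, 20)

        prof = pd_profile(p, FakeResult())
        assert np.all(np.diff(prof.effect) >= 0)

    def test_effect_peaks_with_brain_concentration(self, rat_result_4):
        prof = pd_profile(scenarios.reference_pd_params(), rat_result_4)
        i_eff = int(np.argmax(prof.effect))
        i_conc = int(np.argmax(prof.driving_conc))
        assert i_eff == i_conc  # direct link, no hysteresis
        # brain peak is early (within the first hour after dosing)
        assert prof.times[i_conc] < 1.0
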