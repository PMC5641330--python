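"""Fit the direct-link sigmoid Emax model to elevated-plus-maze data.

Generates a synthetic EPM study along the simulated rat brain profile
(4 mg/kg oral; sampling 5-180 min; n = 10 per time group) from known
parameters, then recovers EC50 and the Hill coefficient with the baseline
fixed at the vehicle group's 0.63.
"""

from pbpkpd import scenarios
from pbpkpd.engine import simulate
from pbpkpd.pd_emax import fit_emax
from pbpkpd.synthetic import gen_epm_dataset

truth = scenarios.reference_pd_params()  # E0 0.63, Emax 2.0, EC50 10.6, gamma 2.5
rat = scenarios.reference_model("rat")
brain = simulate(rat, scenarios.rat_oral_regimen(4.0), grid_dt_h=0.02)

df = gen_epm_dataset(truth, brain, [5, 10, 15, 30, 60, 90, 120, 180],
                     noise_sd=0.3, seed=7, group_size=10)
groups = df.drop_duplicates("time_min")
fit = fit_emax(groups["conc_ng_ml"], groups["effect_mean"], fixed_e0=0.63)

print(f"true  EC50 {truth.ec50:.1f} ng/mL, gamma {truth.gamma:.1f}")
print(f"fitted EC50 {fit.params.ec50:.2f} ng/mL, gamma {fit.params.gamma:.2f}, "
      f"Emax {fit.params.emax:.2f}")
print(f"R2 {fit.r2:.3f}, AIC {fit.aic:.1f}, identifiable: {fit.identifiable}")

# The rat brain profile spans ~0-36 ng/mL, bracketing the half-maximal
# region around 10.6 ng/mL -- exactly why the design identifies EC50.
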