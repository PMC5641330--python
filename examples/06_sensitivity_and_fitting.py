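"""Parameter sensitivity analysis and refinement against (synthetic) data.

Sweeps the ASF coefficient C1 (the dominant absorption scaler) on the rat
model, then refits hepatic clearance from a noisy synthetic dataset.
"""

from pbpkpd import scenarios
from pbpkpd.engine import simulate
from pbpkpd.fitting import fit_parameters, psa_sweep
from pbpkpd.synthetic import gen_pk_dataset

rat = scenarios.reference_model("rat")
reg = scenarios.rat_oral_regimen(4.0)

psa = psa_sweep(rat, reg, "c1", 0.2, 2.0, n=5)
print("C1 sensitivity (plasma):")
print(psa.metrics.to_string(index=False, float_format="%.3f"))

truth = simulate(rat, reg, grid_dt_h=0.02)
data = gen_pk_dataset(rat, reg, [0.083, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0],
                      cv=0.10, seed=11, result=truth)
fit = fit_parameters(rat, [(reg, data)], free={"clhep": (5.0, 69.0)},
                     n_starts=1, check_identifiability=False)
print(f"\nrefit CLhep: {fit.params['clhep']:.1f} mL/min/kg (true 36.8); "
      f"objective {fit.objective:.4f} (from {fit.objective_initial:.4f})")

# Cmax and AUC rise monotonically with C1 -- absorption scaling is the
# high-leverage uncertainty, which is why the study optimized C1 per species.
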