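# Buagafuran: physicochemical and in vitro input parameters.
# Measured values: Caco-2 Papp, unbound plasma fractions, microsomal CLint.
# In-silico estimates (reported with the compound): logP, aqueous solubility,
# particle properties, blood:plasma ratio, diffusion coefficient.
# The diffusion coefficient is reported as 0.8251 without a power of ten;
# the conventional 1e-5 cm^2/s scale for small molecules in water is assumed.
name: buagafuran
mw: 262.44
logp: 6.24
solubility_mg_ml: 0.00985
solubility_ref_ph: 7.0
pka_list: []
papp_caco2_cm_s: 1.95e-4
rb: 0.73
fup_by_species:
  rat: 0.031
  human: 0.040
particle_radius_um: 5.0
particle_density_g_ml: 1.2
diffusion_coeff_1e5_cm2_s: 0.8251
mean_precip_time_s: 900.0
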