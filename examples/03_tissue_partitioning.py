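"""Tissue:plasma partition coefficients and steady-state volume.

Poulin-Theil homogeneous predictions for every perfused tissue, with the
optimized brain override (6.7) the study carried from rat into human.
"""

from pbpkpd.parameters import bundled_compound, load_physiology
from pbpkpd.partition import build_kpset, vss_l
from pbpkpd import scenarios

compound = bundled_compound()
phys = load_physiology("human")
kpset = build_kpset(
    compound, phys, overrides={"brain": scenarios.KP_BRAIN},
    partition_logp=scenarios.KP_PARTITION_LOGP,
)
print(kpset.to_frame().to_string(index=False, float_format="%.3f"))
print(f"\nVss (sum Vt*Kpt + Vblood): {vss_l(kpset, phys):.1f} L")

# "optimized" provenance marks the brain override; everything else is
# predicted from tissue water/lipid composition and the calibrated effective
# partitioning lipophilicity (see docs/methods.md).
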