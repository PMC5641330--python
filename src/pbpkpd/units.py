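"""Centralized unit conventions and converters.

Package-wide convention (all internal model state and rates):

==============  =======================
quantity        internal unit
==============  =======================
time            hours (h)
amount          milligrams (mg)
concentration   ng/mL for reported plasma/brain levels; mg/mL inside the gut
volume          mL
flow            mL/h (inputs are commonly mL/min and converted here)
permeability    cm/h  (inputs in cm/s)
==============  =======================

Anything that crosses a module boundary in a different unit is converted at
the boundary through these constants, never ad hoc.
"""

MIN_PER_H = 60.0
S_PER_H = 3600.0

MG_PER_ML_TO_NG_PER_ML = 1.0e6

CM_PER_S_TO_CM_PER_H = S_PER_H
CM2_PER_S_TO_CM2_PER_H = S_PER_H


def ml_min_to_ml_h(flow_ml_min: float) -> float:
    """Convert a flow from mL/min to mL/h."""
    return flow_ml_min * MIN_PER_H


def ml_min_kg_to_ml_h(flow_ml_min_kg: float, body_weight_kg: float) -> float:
    """Convert a weight-normalized flow (mL/min/kg) to absolute mL/h."""
    return flow_ml_min_kg * body_weight_kg * MIN_PER_H


def cm_s_to_cm_h(v_cm_s: float) -> float:
    """Convert a velocity/permeability from cm/s to cm/h."""
    return v_cm_s * CM_PER_S_TO_CM_PER_H
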