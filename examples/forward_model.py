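"""Simulate cortex and inner-medulla enhancement curves from the 7-compartment model.

Builds a synthetic plasma AIF on a 1.6 s grid, pushes it through the
seven-compartment kidney model at typical parameter values, and prints
the derived flows and curve summaries.
"""

import numpy as np

from renoperf import (
    AcquisitionSpec,
    GroundTruthCenters,
    derived_flows,
    make_aif,
    seven_comp_tissue,
)

spec = AcquisitionSpec()  # 1.6 s resolution, 7 min, 20 s baseline
aif = make_aif(spec)
params = GroundTruthCenters().centers  # typical renal parameter set

c_cor, c_med = seven_comp_tissue(params, aif)
flows = derived_flows(params)

print(f"cortical perfusion F_cor : {params.f_cor:6.1f} mL/100mL/min")
print(f"tubular flow F_T         : {flows.f_t:6.1f} mL/100mL/min (= E_FF * F_cor)")
print(f"medullary perfusion F_med: {flows.f_med:6.1f} mL/100mL/min (= E_med*(1-E_FF)*F_cor)")
print(f"AIF peak at t = {aif.t[aif.v.argmax()]:.1f} s")
print(f"cortex peak at t = {c_cor.t[c_cor.v.argmax()]:.1f} s "
      f"(vascular first pass, early)")
print(f"medulla peak at t = {c_med.t[c_med.v.argmax()]:.1f} s "
      f"(tubular accumulation, late)")
# The cortex peaks shortly after the AIF because it is dominated by the
# arterial plasma compartment; the medulla enhances late because tracer
# reaches it through the tubular chain and the vasa recta.
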