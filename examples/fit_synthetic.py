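"""Fit the 7-compartment model to one noisy synthetic curve pair.

Generates a dataset at arterial CNR 150, runs the multi-start iterated
fit and compares the recovered flows with the generating ground truth.
"""

from renoperf import (
    AcquisitionSpec,
    FitConfig,
    derived_flows,
    generate_experiment,
    signal_to_contrast,
)
from renoperf.fitting import iterated_fit

spec = AcquisitionSpec()
ds = generate_experiment(n_aifs=1, sets_per_aif=1, cnr=150.0, seed=1)[0]

# measurement convention: baseline-subtracted noisy curves
aif = signal_to_contrast(ds.noisy["aif"], spec)
c_cor = signal_to_contrast(ds.noisy["c_cor"], spec)
c_med = signal_to_contrast(ds.noisy["c_med"], spec)

res = iterated_fit(c_cor, c_med, aif, FitConfig(n_starts=20, rng_seed=1))
true = derived_flows(ds.truth)

print(f"fit status: {res.status} "
      f"({res.n_in_bounds}/{res.n_starts_converged} converged starts in bounds)")
print(f"{'':12s}{'fitted':>10s}{'true':>10s}   (mL/100mL/min)")
print(f"{'F_cor':12s}{res.params.f_cor:10.1f}{ds.truth.f_cor:10.1f}")
print(f"{'F_T':12s}{res.derived.f_t:10.1f}{true.f_t:10.1f}")
print(f"{'F_med':12s}{res.derived.f_med:10.1f}{true.f_med:10.1f}")
print(f"chi-square (data term): {res.chi_square:.3e}")
# F_cor is typically recovered within a few percent; F_med, the hardest
# target, within tens of percent at this noise level.
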