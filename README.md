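# renoperf

Separate measurement of renal **cortical** and **inner-medullary** perfusion
from dynamic contrast-enhanced (DCE) MR renography, via a seven-compartment
tracer-kinetic model fitted jointly to cortex and inner-medulla
enhancement curves.

## Why

The renal medulla operates on the edge of hypoxia and is regulated
separately from the cortex, but no routine non-invasive technique measures
inner-medullary perfusion: arterial spin labeling decays before the tracer
reaches the medulla, and standard renography models either ignore the
cortico-medullary split or cannot express medullary blood flow.  This
package implements a physiologically structured model in which a contrast
bolus entering the cortex either

* gets filtered into the tubular chain — proximal tubules (PT, cortex) →
  loop of Henle (LH, medulla) → distal tubules (DT, cortex) → collecting
  ducts (CD, medulla) — with probability `E_FF` (the filtration fraction), or
* stays vascular and passes either through the medullary vasa recta (VR)
  with probability `E_med` of the unfiltered flow, or directly to the
  venous plasma (PV).

Each compartment X has an exponential residue function
`R_X(t) = exp(−t/MTT_X)` and propagator `H_X = R_X/MTT_X`; chains act by
convolution.  The measured region curves are

```
C_cor = F·[R_PA + (1−E_FF)(1−E_med)·R_PV∗H_PA + (1−E_FF)E_med·R_PV∗H_VR∗H_PA
            + E_FF·R_PT∗H_PA + E_FF·R_DT∗H_LH∗H_PT∗H_PA] ∗ C_A
C_med = F·[(1−E_FF)E_med·R_VR∗H_PA + E_FF·R_LH∗H_PT∗H_PA
            + E_FF·R_CD∗H_DT∗H_LH∗H_PT∗H_PA] ∗ C_A
```

with `C_A` the plasma arterial input function and `F` the cortical plasma
flow.  The ten free parameters (seven MTTs, `F_cor`, `E_med`, `E_FF`) yield
the derived targets

* **tubular flow** (GFR per 100 mL tissue): `F_T = E_FF · F_cor`
* **inner-medullary perfusion**: `F_med = E_med · (1 − E_FF) · F_cor`

Because ten parameters from two curves invite local minima, fitting is an
iterated multi-start procedure: many regularized unconstrained descents
from random initial values inside the physiological ranges, a post-hoc
physiological-bounds filter, and lowest-chi-square selection.

The package also ships the surrounding machinery: synthetic AIF and
curve-set generation at the acquisition's timing and noise level, k-means
segmentation of 4D series into cortex / inner medulla / excluded
partial-volume clusters, a two-compartment filtration comparator model,
and the reliability statistics (CoV, ICC, regression, Bland–Altman).

## Worked example

`python examples/fit_synthetic.py` generates one noisy synthetic
cortex/medulla pair at arterial CNR 150 (1.6 s sampling, 7 min, 20 s
pre-contrast baseline) and runs the 20-start iterated fit:

```
fit status: ok (15/19 converged starts in bounds)
                fitted      true   (mL/100mL/min)
F_cor            244.3     238.4
F_T               70.8      68.4
F_med             79.8      77.7
chi-square (data term): 2.698e-02
```

Cortical perfusion and tubular flow are recovered within a few percent;
inner-medullary perfusion — the hardest target, a small flow inferred from
the cortex→medulla exchange — lands within a few percent here and within
tens of percent in unfavourable noise draws.  The other examples
(`examples/forward_model.py`, `examples/segment_phantom.py`,
`examples/stability_study.py`) demonstrate the forward model, phantom
segmentation and repeat-fit stability, each printing a few annotated
numbers.

A thin CLI wraps the same pipelines:

```bash
renoperf simulate --n-aifs 2 --sets 4 --seed 1 --out sim/
renoperf fit7c --aif sim/ds_000/aif.csv --cortex sim/ds_000/cortex.csv \
         --medulla sim/ds_000/medulla.csv --aif-kind plasma --seed 7 --out fit.json
renoperf stability --data sim/ --seed 7 --n-repeats 10 --out report/
```

Every stochastic command requires `--seed` and writes a manifest (config
hash, seed, versions) that reproduces its outputs bit-identically.

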