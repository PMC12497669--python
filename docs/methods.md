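# Methods

## Model

The kidney parenchyma is modelled as seven well-mixed compartments.
Tracer arrives in the arterial plasma compartment (PA; arterioles plus
glomerular and peritubular capillaries) with plasma flow `F_cor`
(mL/100 mL/min).  Its outflow splits three ways: a fraction `E_FF`
(filtration fraction) is filtered into the tubular chain PT → LH → DT →
CD and leaves as urine; of the unfiltered remainder, a fraction `E_med`
(medullary flow fraction) traverses the vasa recta (VR) before reaching
the venous plasma (PV), the rest drains to PV directly.  Every
compartment is linear and stationary with exponential residue function
`R_X(t) = e^(−t/MTT_X)`; a chain of compartments responds with the
convolution of its members' propagators `H_X = R_X/MTT_X`.  The cortex
signal collects PA + PV + PT + DT, the inner-medulla signal VR + LH + CD;
the fractional volumes multiply and then cancel in these sums, so they
are never represented.  Derived flows:

    F_T   = E_FF · F_cor            (tubular flow = GFR per 100 mL tissue)
    F_med = E_med · (1 − E_FF) · F_cor   (inner-medullary perfusion)

Flows are stated in mL/100 mL/min and used internally as fractional flow
per second (divided by 6000), the conversion dimensional analysis forces
so that flow × time × concentration is a concentration.

Assumptions inherited from the measurement convention: signal change is
proportional to concentration with one shared constant (set to 1 — only
ratios enter the fit); aorta blood concentration converts to plasma by
1/(1 − Hct) with Hct = 0.45; water exchange, T2* saturation, and
small-vessel hematocrit differences are not modelled.  The exponential
vascular response is a simplification; dispersed/delayed input response
functions are out of scope.

A two-compartment filtration model (plasma feeding a tubule,
`C = F_p·R_p∗C_A + F_t·R_t∗H_p∗C_A`) serves as the comparator for the
shared parameters; it is exactly the 7-compartment model restricted to
the PA→PT sub-chain.  Whether the reference implementation carried a
venous term is unknown; this series form is consistent with the
comparator's reported parameters and is documented as an interpretation.

## Numerics

Convolution with an exponential kernel uses the exact recursion for
piecewise-linear inputs (one IIR filter pass per compartment,
unconditionally stable, no step-size bias); it agrees with brute-force
quadrature to <0.1% for dt ≤ MTT/10 and with a stiff ODE integration of
the coupled mass balances to <0.5% of peak.  The AIF grid is the model
grid; no internal resampling.

Fitting minimizes the joint sum of squares over cortex and medulla
(equal weighting — the curves have comparable amplitude and noise) with
Levenberg–Marquardt in a transformed space: log for MTTs and flows,
logit for fractions.  The transform keeps the *unconstrained* descent
away from negative transit times without imposing hard bounds during
optimization; bounds act only as the post-hoc physiological filter.  A
quadratic penalty `λ·Σ(u_k − u_k,init)²` in transformed space
regularizes the descent toward its own starting point; λ is expressed
relative to the data sum of squares.  The default weight is 1e-6:
calibration on noiseless synthetic curves showed that 1e-3 biases
recovered F_cor by several percent and scatters repeated multi-start
runs by 1–2% CoV, whereas at 1e-6 the penalty acts purely as a
conditioner/tie-breaker — noiseless truth is recovered to <1% and
repeated runs of the full procedure agree to ~0.1%, matching the
near-zero repeat variability the procedure is designed to deliver.  The
weight is config-exposed; note that any nonzero weight sets a floor
`O(λ)` on the attainable data chi-square, which matters only for
noiseless degeneracy experiments (run those with weight 0).

The iterated procedure draws `n_starts` (default 100; experiments here
use ≥20) initial vectors uniformly within the physiological ranges
(uniformity is an interpretation — the reference only states "randomly
within physiological ranges"), descends from each, discards solutions
with any parameter outside bounds, and returns the lowest *data*
chi-square among survivors (selection compares fits to data, not
penalties).  Ties resolve to the lowest start index; with seeded
per-start streams the whole procedure is bit-reproducible.  Zero
in-bounds survivors yield status `no_in_bounds_solution` with the best
out-of-bounds candidate attached; all-zero tissue curves short-circuit
to a zero-flow result with status ok.

Physiological bounds (seconds; flows mL/100 mL/min): MTT_PA 0–15,
MTT_PV 1–20, MTT_VR 50–200, tubular MTTs 1–100, F_cor 0–1000, fractions
0–1.  A known tension: noisy data sometimes pull MTT_VR below its 50 s
lower bound, and a 20-start run can then end with no in-bounds
survivor; such failures are recorded and excluded from summary medians
rather than being fatal.  (How the reference procedure reconciled a
fitted vasa-recta MTT mean of ~32 s with the 50 s bound is not
documented; the bounds here are applied strictly.)

## Synthetic data

The generator emulates the acquisition: 1.6 s temporal resolution, 7 min
duration, 20 s pre-contrast baseline, arterial CNR 150.  Because patient
aorta curves are not redistributable, a parametric plasma AIF stands in:
zero baseline, gamma-variate first pass, delayed dispersed recirculation
bump, slow biexponential washout, with ±20% per-subject shape jitter.
Ground-truth parameter sets are drawn per parameter from
Normal(center, 0.20·center), redrawn until inside the bounds (i.e.,
truncated normal).  The center values are not published; the defaults
here are the simulation-fit group means reported for this model
(MTTs 1.5/7.5/60/43/77/29/41 s, F_cor 249, E_med 0.40, E_FF 0.29, with
the vasa-recta center raised from the reported 32 s to 60 s to respect
its lower bound) and are fully configurable — they are an
interpretation, not reported constants.  One noise σ = AIF-peak/CNR is
applied to all three curves (aorta and tissue come from the same
acquisition); whether the reference added noise to the AIF itself is
ambiguous, so `noise.include_aif` (default true) exposes the choice.

What the generator does *not* emulate: respiratory motion, registration
error, coil inhomogeneity, T1/T2* signal nonlinearity, inflow
fluctuation artifacts.  Passing recovery tests on this generator
therefore demonstrates identifiability of the model under its own
assumptions at realistic noise, not robustness to acquisition physics.

The 4D phantom populates a concentric-shell geometry (cortex ring,
thin partial-volume ring, medulla core; ≥50 voxels each) with the model's
region curves; partial-volume voxels mix cortex and medulla with
per-voxel α ~ U(0.2, 0.8).  The default ring proportions keep the
mixing ring ~14% of the foreground.  With a much thicker mixing ring
(~23%), 3-means clustering absorbs the medulla-like half of the mixture
continuum into the medulla cluster; the cluster-*mean* medulla curve is
then both damped and vascularly contaminated, which can collapse fitted
F_med entirely.  This is a structural property of mean-curve extraction
over a mixing continuum — in patients the excluded cluster is largely
outer medulla with genuinely distinct kinetics, not pure numerical
mixtures — and is the main caveat attached to the segmentation
end-to-end contract.

## Segmentation

Voxel time courses are clustered with Lloyd k-means (k = 3, best of
n_init inits, seeded) on baseline-subtracted, per-voxel peak-normalized
curves, so clusters are shape- rather than amplitude-driven (the feature
space is not documented in the reference; this choice is deliberate and
recorded here).  Roles are assigned by kinetics: cortex = earliest
(tie: highest) peak; of the rest, inner medulla = higher late/early
enhancement ratio; the remaining cluster is excluded as partial
volume/outer medulla.  The aorta extractor runs 2-means on raw curves
and keeps the largest connected component of the enhancing cluster — a
deterministic replacement for manual voxel removal.  Label maps use
0 = background, 1 = cortex, 2 = inner medulla, 3 = excluded.

## Statistics

CoV = sample SD (n−1) / mean; undefined for zero mean, reported missing
and excluded from medians.  ICCs come from the two-way ANOVA mean
squares: consistency = (MS_R−MS_E)/(MS_R+(k−1)MS_E); absolute agreement
adds k(MS_C−MS_E)/n to the denominator.  IQRs use linear-interpolation
quantiles.  Regression is OLS with R² the squared Pearson correlation;
Bland–Altman limits are mean difference ± 1.96 SD.  Accuracy IQRs are
taken across curves (one fit per curve), stability CoV across repeats
within a curve.

## Experiment scales

The reference study design is 24 AIFs × 4 curve sets = 96 pairs with 50
fit repetitions of a 100-start procedure.  The packaged experiments and
the acceptance script run a desk-scale version of the same design —
8 curve pairs, 10 repeats, 20-start fits for stability; 24 pairs for the
noisy-accuracy band — chosen so the full pipeline (not a shortcut)
executes in minutes while the medians being tested remain stable; all
counts are arguments, so the full-scale design is one call away.

## Known limitations

* F_med remains the most fragile estimate: individual noisy pairs show
  repeat-CoV outliers up to tens of percent and occasional sign-level
  bias, consistent with the overfitting risk of ten free parameters.
* MTT estimates, especially MTT_VR, are weakly identified (see the
  bounds tension above).
* The two-compartment comparator is fitted to a volume-weighted
  parenchymal mix (default 70% cortex) — the exact curve used by the
  reference is not documented and the choice is exposed.
* Mean-curve extraction over heavy partial-volume mixing biases the
  medulla curve (see above); fitting the excluded cluster with an extra
  mixing parameter is a noted future hook, not implemented.
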