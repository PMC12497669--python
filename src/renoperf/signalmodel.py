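"""Signal ↔ concentration conventions, hematocrit correction and noise.

Contrast-agent concentration is taken proportional to the signal change
over the pre-contrast baseline, with a proportionality constant of 1
shared by all regions (only ratios enter the fit, so the absolute scale
is irrelevant).  The aorta *blood* concentration is converted to plasma
by dividing by (1 − hematocrit).  Noise is injected as i.i.d. Gaussian
samples whose standard deviation is sized so the arterial curve reaches
a prescribed contrast-to-noise ratio (CNR), defined as peak arterial
signal change over baseline standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import Curve

__all__ = [
    "AcquisitionSpec",
    "signal_to_contrast",
    "blood_to_plasma",
    "arterial_cnr",
    "add_noise_to_cnr",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Timing and physiology constants of the dynamic acquisition.

    Defaults match a free-breathing renal DCE protocol: 1.6 s temporal
    resolution, 7 min total acquisition, imaging starting 20 s before
    contrast injection, hematocrit 0.45.
    """

    dt: float = 1.6
    duration: float = 420.0
    baseline_window: float = 20.0
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < 10 * self.dt:
            raise ValueError("duration must cover at least 10 samples")
        if not 0 < self.baseline_window < self.duration:
            raise ValueError("baseline_window must lie in (0, duration)")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must be in (0, 1)")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration / self.dt)) + 1

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def baseline_mask(self, t: np.ndarray) -> np.ndarray:
        """Samples inside the pre-contrast window (time < baseline_window)."""
        return np.asarray(t) < self.baseline_window


def signal_to_contrast(s: Curve, spec: AcquisitionSpec) -> Curve:
    """Baseline-subtracted signal: proportional-concentration convention.

    Subtracts the mean over the pre-contrast window; proportionality
    constant 1, identical for all regions.  Idempotent.
    """
    mask = spec.baseline_mask(s.t)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    return s.with_values(s.v - s.v[mask].mean())


def blood_to_plasma(c_blood: Curve, hct: float) -> Curve:
    """Convert a blood concentration curve to plasma: divide by (1 − hct)."""
    if not 0 < hct < 1:
        raise ValueError(f"hematocrit must be in (0, 1), got {hct}")
    return c_blood.with_values(c_blood.v / (1.0 - hct))


def arterial_cnr(aif_signal: Curve, spec: AcquisitionSpec) -> float:
    """Peak arterial signal change over baseline standard deviation."""
    mask = spec.baseline_mask(aif_signal.t)
    if mask.sum() < 3:
        raise ValueError("baseline window must contain at least 3 samples")
    base = aif_signal.v[mask]
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("baseline standard deviation is zero; CNR undefined")
    return float((aif_signal.v.max() - base.mean()) / sd)


def add_noise_to_cnr(
    curves: dict[str, Curve],
    target_cnr: float,
    rng_seed,
) -> dict[str, Curve]:
    """Add Gaussian noise sized to an arterial CNR target.

    One σ = peak(AIF)/target_cnr is computed from the noiseless ``aif``
    entry and applied independently to every sample of every curve — all
    curves come from the same acquisition, hence one noise level.
    Deterministic given the seed.

    Parameters
    ----------
    curves : dict
        Must contain key ``"aif"``; typically also ``"c_cor"``, ``"c_med"``.
    target_cnr : float
        Desired ratio of noiseless AIF peak to noise σ.
    rng_seed : int or numpy.random.Generator
    """
    if target_cnr <= 0:
        raise ValueError("target_cnr must be > 0")
    if "aif" not in curves:
        raise ValueError("curves must contain an 'aif' entry")
    peak = float(curves["aif"].v.max())
    if peak <= 0:
        raise ValueError("noiseless AIF must have a positive peak")
    sigma = peak / target_cnr
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out = {}
    for name, c in curves.items():
        out[name] = c.with_values(c.v + rng.normal(0.0, sigma, size=c.n))
    return out
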