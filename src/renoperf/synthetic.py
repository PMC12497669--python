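"""Synthetic renal DCE data: AIFs, ground truths, curve sets, phantoms.

Study data are not redistributable, so evaluation runs on synthetic data
that emulates the acquisition: 1.6 s temporal resolution, 7 min duration,
a 20 s pre-contrast baseline, and Gaussian noise sized to an arterial
contrast-to-noise ratio of 150.  A parametric arterial input function
(gamma-variate first pass, dispersed recirculation, slow biexponential
washout) stands in for measured patient aorta curves; per-subject shape
jitter emulates inter-patient AIF variability.

Ground-truth parameter sets are drawn from a normal distribution with a
20% relative standard deviation around configurable center values,
redrawn per parameter until inside the physiological bounds.  The center
defaults are an interpretation: they follow groupwise simulation means
reported for this model (with the vasa recta transit time raised to its
60 s to respect the 50 s lower bound) and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import Curve
from .kinetic import ParameterBounds, SevenCompParams, seven_comp_tissue
from .signalmodel import AcquisitionSpec, add_noise_to_cnr
from .util import rng_stream, stream_seed

__all__ = [
    "AifShape",
    "GroundTruthCenters",
    "SyntheticDataset",
    "Phantom",
    "make_aif",
    "sample_ground_truth",
    "generate_experiment",
    "concentric_geometry",
    "make_phantom",
]


# ---------------------------------------------------------------------------
# arterial input function


@dataclass(frozen=True)
class AifShape:
    """Shape parameters of the parametric plasma AIF.

    ``amplitude`` sets the first-pass peak height (arbitrary units);
    times in seconds.  The recirculation bump is a delayed, broader
    gamma-variate; the washout is a slow biexponential body phase.
    """

    amplitude: float = 1.0
    first_pass_peak_time: float = 8.0
    first_pass_sharpness: float = 3.0
    recirc_delay: float = 22.0
    recirc_peak_time: float = 14.0
    recirc_sharpness: float = 2.0
    recirc_fraction: float = 0.22
    tail_fraction: float = 0.18
    tail_onset: float = 12.0
    tail_fast: float = 90.0
    tail_slow: float = 900.0
    tail_fast_weight: float = 0.5

    def __post_init__(self) -> None:
        for f in (
            "amplitude",
            "first_pass_peak_time",
            "first_pass_sharpness",
            "recirc_peak_time",
            "recirc_sharpness",
            "tail_onset",
            "tail_fast",
            "tail_slow",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        for f in ("recirc_fraction", "tail_fraction", "tail_fast_weight"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must be in [0, 1]")
        if self.recirc_delay < 0:
            raise ValueError("recirc_delay must be >= 0")


def _gamma_variate(tau: np.ndarray, t_peak: float, alpha: float) -> np.ndarray:
    """Normalized gamma-variate: 0 for tau<=0, peak 1 at tau=t_peak."""
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / t_peak
    out[pos] = x**alpha * np.exp(alpha * (1.0 - x))
    return out


def make_aif(
    spec: AcquisitionSpec,
    shape: AifShape | None = None,
    rng_seed: int | None = None,
) -> Curve:
    """Synthetic plasma-concentration AIF on the acquisition grid.

    Exactly zero during the pre-contrast baseline window, then a
    gamma-variate first pass plus a delayed dispersed recirculation bump
    plus a slow biexponential washout.  Strictly nonnegative.  If
    ``rng_seed`` is given, the shape parameters are jittered (±20%
    multiplicative, uniform) to emulate inter-subject variability.
    """
    shape = shape or AifShape()
    if rng_seed is not None:
        rng = rng_stream(rng_seed, "aif-shape")
        jitter = {
            f: getattr(shape, f) * rng.uniform(0.8, 1.2)
            for f in (
                "first_pass_peak_time",
                "first_pass_sharpness",
                "recirc_delay",
                "recirc_peak_time",
                "recirc_fraction",
                "tail_fraction",
            )
        }
        jitter["recirc_fraction"] = min(jitter["recirc_fraction"], 1.0)
        jitter["tail_fraction"] = min(jitter["tail_fraction"], 1.0)
        shape = replace(shape, **jitter)

    t = spec.time_grid()
    tau = t - spec.baseline_window
    first = _gamma_variate(tau, shape.first_pass_peak_time, shape.first_pass_sharpness)
    recirc = shape.recirc_fraction * _gamma_variate(
        tau - shape.recirc_delay, shape.recirc_peak_time, shape.recirc_sharpness
    )
    body = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    body[pos] = (
        shape.tail_fraction
        * (1.0 - np.exp(-tp / shape.tail_onset))
        * (
            shape.tail_fast_weight * np.exp(-tp / shape.tail_fast)
            + (1.0 - shape.tail_fast_weight) * np.exp(-tp / shape.tail_slow)
        )
    )
    v = shape.amplitude * (first + recirc + body)
    return Curve(t, v)


# ---------------------------------------------------------------------------
# ground-truth sampling


@dataclass(frozen=True)
class GroundTruthCenters:
    """Center values for ground-truth sampling, with relative SD.

    Each simulated truth draws every free parameter from
    Normal(center, rel_sd·center), redrawn until within the bounds.
    """

    centers: SevenCompParams = field(
        default_factory=lambda: SevenCompParams(
            mtt_pa=1.5,
            mtt_pv=7.5,
            mtt_vr=60.0,
            mtt_pt=43.0,
            mtt_lh=77.0,
            mtt_dt=29.0,
            mtt_cd=41.0,
            f_cor=249.0,
            e_med=0.40,
            e_ff=0.29,
        )
    )
    rel_sd: float = 0.20
    bounds: ParameterBounds = field(default_factory=ParameterBounds.seven_comp_default)

    def __post_init__(self) -> None:
        if not 0 < self.rel_sd < 1:
            raise ValueError("rel_sd must be in (0, 1)")
        if not self.bounds.contains(self.centers.to_array()):
            raise ValueError("centers must lie within the bounds")


def sample_ground_truth(
    centers: GroundTruthCenters, rng_seed: int | np.random.Generator
) -> SevenCompParams:
    """One ground-truth parameter set.

    Per parameter: Normal(center, rel_sd·center), redrawn until inside
    the physiological bounds (fractions thereby stay in [0, 1]).
    Deterministic given the seed.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else rng_stream(rng_seed, "truth")
    )
    c = centers.centers.to_array()
    lo, hi = centers.bounds.lower, centers.bounds.upper
    out = np.empty_like(c)
    for k in range(len(c)):
        sd = centers.rel_sd * c[k]
        if sd == 0:
            out[k] = c[k]
            continue
        for _ in range(10_000):
            draw = rng.normal(c[k], sd)
            if lo[k] <= draw <= hi[k]:
                out[k] = draw
                break
        else:  # pragma: no cover - bounds always reachable from valid centers
            raise RuntimeError(f"could not draw parameter {k} within bounds")
    return SevenCompParams.from_array(out)


# ---------------------------------------------------------------------------
# curve-set experiment


@dataclass(frozen=True)
class SyntheticDataset:
    """One simulated curve set: AIF, truth, clean and noisy curves."""

    aif: Curve
    truth: SevenCompParams
    clean: tuple[Curve, Curve]
    noisy: dict[str, Curve]
    seed: int
    aif_index: int = 0
    set_index: int = 0

    def regenerate_clean(self) -> tuple[Curve, Curve]:
        """Recompute the clean curves from (truth, aif); must be bit-identical."""
        return seven_comp_tissue(self.truth, self.aif)


def generate_experiment(
    n_aifs: int,
    sets_per_aif: int = 4,
    centers: GroundTruthCenters | None = None,
    cnr: float = 150.0,
    seed: int = 0,
    spec: AcquisitionSpec | None = None,
    include_aif_noise: bool = True,
) -> list[SyntheticDataset]:
    """The simulation design: per AIF, several curve sets with unique truths.

    For each of ``n_aifs`` synthetic AIFs, ``sets_per_aif`` ground-truth
    parameter sets are drawn and forward-modelled to cortex/medulla
    curves; Gaussian noise sized to the arterial CNR target is added to
    every curve (optionally sparing the AIF).  At full study scale
    (24 AIFs × 4 sets) this yields 96 unique curve pairs.
    """
    if n_aifs < 1 or sets_per_aif < 1:
        raise ValueError("counts must be >= 1")
    centers = centers or GroundTruthCenters()
    spec = spec or AcquisitionSpec()
    datasets: list[SyntheticDataset] = []
    for i in range(n_aifs):
        aif = make_aif(spec, rng_seed=stream_seed(seed, "aif", i))
        for j in range(sets_per_aif):
            truth = sample_ground_truth(centers, rng_stream(seed, "truth", i, j))
            c_cor, c_med = seven_comp_tissue(truth, aif)
            noise_seed = stream_seed(seed, "noise", i, j)
            noisy = add_noise_to_cnr(
                {"aif": aif, "c_cor": c_cor, "c_med": c_med},
                cnr,
                rng_stream(seed, "noise", i, j),
            )
            if not include_aif_noise:
                noisy["aif"] = aif
            datasets.append(
                SyntheticDataset(
                    aif=aif,
                    truth=truth,
                    clean=(c_cor, c_med),
                    noisy=noisy,
                    seed=noise_seed,
                    aif_index=i,
                    set_index=j,
                )
            )
    return datasets


# ---------------------------------------------------------------------------
# 4D phantom


@dataclass(frozen=True)
class Phantom:
    """A 4D signal array with ground-truth region labels.

    Labels: 0 background, 1 cortex, 2 inner medulla, 3 partial volume.
    Partial-volume voxels mix the cortex and medulla curves with a
    per-voxel cortical fraction alpha in (0.2, 0.8).
    """

    image4d: np.ndarray
    labels: np.ndarray
    region_curves: dict[str, Curve]
    alphas: np.ndarray
    sigma: float
    seed: int


LABEL_BACKGROUND, LABEL_CORTEX, LABEL_MEDULLA, LABEL_PARTIAL = 0, 1, 2, 3


def concentric_geometry(
    shape: tuple[int, int, int] = (32, 32, 1),
    r_medulla: float = 7.5,
    r_partial: float = 9.0,
    r_cortex: float = 14.0,
) -> np.ndarray:
    """Concentric-shell label map: medulla core, partial-volume ring, cortex ring.

    The default radii keep the mixing ring a thin minority (~14% of
    foreground) so that cluster mean curves stay representative of the
    pure tissues; see the methods note for the behaviour with thicker
    mixing rings.
    """
    if not 0 < r_medulla < r_partial < r_cortex:
        raise ValueError("need 0 < r_medulla < r_partial < r_cortex")
    nx, ny, nz = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    plane = np.full((nx, ny), LABEL_BACKGROUND, dtype=np.int8)
    plane[r < r_cortex] = LABEL_CORTEX
    plane[r < r_partial] = LABEL_PARTIAL
    plane[r < r_medulla] = LABEL_MEDULLA
    return np.repeat(plane[:, :, None], nz, axis=2)


def make_phantom(
    labels: np.ndarray,
    truth: SevenCompParams,
    aif: Curve,
    sigma: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Populate a label geometry with the model's region curves plus noise.

    Cortex voxels carry the cortical curve, medulla voxels the medullary
    curve, partial-volume voxels a per-voxel mixture
    ``alpha·c_cor + (1−alpha)·c_med`` with alpha ~ U(0.2, 0.8);
    background stays at zero.  Gaussian noise of standard deviation
    ``sigma`` is added everywhere.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be a 3D integer array")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    c_cor, c_med = seven_comp_tissue(truth, aif)
    nt = aif.n
    img = np.zeros(labels.shape + (nt,), dtype=float)
    img[labels == LABEL_CORTEX] = c_cor.v
    img[labels == LABEL_MEDULLA] = c_med.v

    rng = rng_stream(seed, "phantom")
    pv_idx = np.argwhere(labels == LABEL_PARTIAL)
    alphas = rng.uniform(0.2, 0.8, size=len(pv_idx))
    for (i, j, k), a in zip(pv_idx, alphas):
        img[i, j, k] = a * c_cor.v + (1.0 - a) * c_med.v

    if sigma > 0:
        img = img + rng.normal(0.0, sigma, size=img.shape)

    return Phantom(
        image4d=img,
        labels=labels.copy(),
        region_curves={"cortex": c_cor, "inner_medulla": c_med, "aif": aif},
        alphas=alphas,
        sigma=float(sigma),
        seed=int(seed),
    )
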