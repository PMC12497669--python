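"""Curve-based k-means segmentation of dynamic renal images.

Cortex and inner medulla have characteristically different enhancement
curves (early sharp vascular first pass vs. delayed, slowly accumulating
tubular enhancement), so voxels can be clustered on their time courses
alone.  Three clusters are formed over the kidney foreground: cortex,
inner medulla, and a partial-volume/outer-medulla cluster that is
excluded from fitting.  Clustering operates on baseline-subtracted,
per-voxel peak-normalized curves so clusters are driven by curve shape,
not amplitude.

A simple aorta extractor is included: 2-means foreground/background on
the curves of an aortic slice, keeping the largest connected component
of the enhancing cluster (a deterministic replacement for manual voxel
editing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .curves import Curve

__all__ = [
    "SegmentationResult",
    "kmeans_curves",
    "assign_roles",
    "region_mean_curve",
    "segment_dynamic",
    "extract_aif",
]

# label-map convention
LABEL_BACKGROUND, LABEL_CORTEX, LABEL_MEDULLA, LABEL_EXCLUDED = 0, 1, 2, 3


@dataclass(frozen=True)
class SegmentationResult:
    """Three-cluster segmentation of a dynamic series.

    ``labels`` uses 0=background, 1=cortex, 2=inner medulla, 3=excluded
    (partial volume / outer medulla).  ``roles`` maps the raw cluster
    indices onto those roles; ``fraction_excluded`` is the excluded share
    of foreground voxels.
    """

    labels: np.ndarray
    cluster_curves: dict[str, Curve]
    roles: dict[str, int]
    fraction_excluded: float


def _normalize_curves(X: np.ndarray, n_baseline: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if n_baseline > 0:
        X = X - X[:, :n_baseline].mean(axis=1, keepdims=True)
    peak = np.abs(X).max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return X / peak


def kmeans_curves(
    X: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    n_baseline: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means over baseline-subtracted, peak-normalized curves.

    Parameters
    ----------
    X : (n_voxels, n_time) array
    n_baseline : number of leading pre-contrast samples for baseline
        subtraction (0 disables it).

    Returns labels (per voxel) and centroids in normalized-feature space;
    best of ``n_init`` initializations by inertia, deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a voxel-by-time matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} voxels, got {X.shape[0]}")
    feats = _normalize_curves(X, n_baseline)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(feats)
    return labels, km.cluster_centers_


def assign_roles(centroids: np.ndarray) -> dict[str, int]:
    """Map 3 cluster centroids onto cortex / inner medulla / excluded.

    Rule (overridable by the caller ignoring this helper): the cortex is
    the cluster with the earliest (tie: highest) first-pass peak; of the
    remaining two, the inner medulla is the one with the higher
    late-to-early enhancement ratio (slow tubular accumulation); the
    last is excluded as partial volume.
    """
    C = np.asarray(centroids, dtype=float)
    if C.shape[0] != 3:
        raise ValueError("exactly 3 centroids required")
    if np.allclose(C, C[0], atol=1e-12):
        raise ValueError("degenerate centroids: all clusters identical")
    nt = C.shape[1]
    peak_idx = C.argmax(axis=1)
    peak_val = C.max(axis=1)
    order = sorted(range(3), key=lambda i: (peak_idx[i], -peak_val[i]))
    cortex = order[0]
    rest = order[1:]
    late = C[:, -max(nt // 4, 1):].mean(axis=1)
    early = peak_val.copy()
    early[early == 0] = 1e-30
    ratio = late / early
    medulla = max(rest, key=lambda i: ratio[i])
    excluded = next(i for i in rest if i != medulla)
    return {"cortex": cortex, "inner_medulla": medulla, "excluded": excluded}


def region_mean_curve(image4d: np.ndarray, mask: np.ndarray, dt: float = 1.0) -> Curve:
    """Per-timepoint arithmetic mean over the mask voxels."""
    image4d = np.asarray(image4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image4d.shape[:-1]:
        raise ValueError("mask shape must match the spatial image shape")
    if not mask.any():
        raise ValueError("mask is empty")
    v = image4d[mask].mean(axis=0)
    return Curve(np.arange(image4d.shape[-1]) * float(dt), v)


def segment_dynamic(
    image4d: np.ndarray,
    foreground: np.ndarray,
    dt: float = 1.0,
    seed: int = 0,
    n_init: int = 10,
    n_baseline: int = 0,
) -> SegmentationResult:
    """Full pipeline: cluster foreground voxel curves, assign roles.

    Produces the label map (1=cortex, 2=inner medulla, 3=excluded), the
    per-role mean curves of the raw (unnormalized) data, and the
    excluded voxel fraction.
    """
    foreground = np.asarray(foreground, dtype=bool)
    X = np.asarray(image4d, dtype=float)[foreground]
    raw_labels, centroids = kmeans_curves(
        X, k=3, seed=seed, n_init=n_init, n_baseline=n_baseline
    )
    roles = assign_roles(centroids)
    labelmap = np.zeros(foreground.shape, dtype=np.int8)
    role_codes = {
        "cortex": LABEL_CORTEX,
        "inner_medulla": LABEL_MEDULLA,
        "excluded": LABEL_EXCLUDED,
    }
    fg_idx = np.argwhere(foreground)
    for role, cluster in roles.items():
        sel = fg_idx[raw_labels == cluster]
        labelmap[sel[:, 0], sel[:, 1], sel[:, 2]] = role_codes[role]
    curves = {
        role: region_mean_curve(image4d, labelmap == code, dt=dt)
        for role, code in role_codes.items()
    }
    frac_excl = float((raw_labels == roles["excluded"]).mean())
    return SegmentationResult(labelmap, curves, roles, frac_excl)


def extract_aif(slice4d: np.ndarray, dt: float = 1.0, seed: int = 0) -> Curve:
    """AIF from an aortic slice: 2-means + largest connected component.

    Voxel curves are split into an enhancing and a background cluster by
    amplitude (raw curves, no normalization — the aorta is the
    high-enhancement structure); isolated enhancing voxels are dropped
    by keeping only the largest connected component of the enhancing
    cluster.
    """
    img = np.asarray(slice4d, dtype=float)
    if img.ndim == 3:  # (x, y, t) -> (x, y, 1, t)
        img = img[:, :, None, :]
    flat = img.reshape(-1, img.shape[-1])
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(flat)
    peaks = km.cluster_centers_.max(axis=1)
    if abs(peaks[0] - peaks[1]) < 1e-12:
        raise ValueError("no enhancing cluster found in aorta slice")
    enhancing = int(np.argmax(peaks))
    mask = (labels == enhancing).reshape(img.shape[:-1])
    comp, n_comp = ndimage.label(mask)
    if n_comp == 0:
        raise ValueError("no enhancing cluster found in aorta slice")
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n_comp + 1))
    keep = comp == (int(np.argmax(sizes)) + 1)
    return region_mean_curve(img, keep, dt=dt)
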