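"""Readers and writers: curve CSVs, dataset directories, NIfTI, manifests.

Curve CSV convention: two columns ``time_s,value``, header required,
UTF-8, rows in time order, full float precision (round-trip bit-stable).
Synthetic datasets serialize to a directory of curve CSVs plus
``truth.json`` and ``meta.json``; phantoms to a 4D NIfTI image, an
integer NIfTI label map and a JSON sidecar.  Every stochastic command
writes a manifest (config hash, seed, versions) so its outputs can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .curves import Curve
from .kinetic import SevenCompParams, derived_flows
from .synthetic import Phantom, SyntheticDataset

__all__ = [
    "read_curve",
    "write_curve",
    "save_dataset",
    "load_dataset",
    "save_phantom",
    "write_json",
    "write_manifest",
]

_HEADER = "time_s,value"


def read_curve(path) -> Curve:
    """Read a Curve from CSV; validates header, order and grid uniformity."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].replace(" ", "")
    if header != _HEADER:
        raise ValueError(
            f"{path}: expected header '{_HEADER}', got '{lines[0]}' "
            "(columns must be exactly time_s and value)"
        )
    t, v = [], []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2:
            raise ValueError(
                f"{path}, line {i}: expected 2 comma-separated fields, got "
                f"{len(parts)} — decimal commas are not supported, use '.'"
            )
        try:
            t.append(float(parts[0]))
            v.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: cannot parse '{ln}': {exc}") from None
    t = np.asarray(t)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3
        raise ValueError(f"{path}, line {bad}: time values must be strictly increasing")
    try:
        return Curve(t, np.asarray(v))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_curve(curve: Curve, path) -> None:
    """Write a Curve as CSV at full float precision (%.17g)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER + "\n")
        for ti, vi in zip(curve.t, curve.v):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


# ---------------------------------------------------------------------------
# datasets


def save_dataset(ds: SyntheticDataset, outdir) -> None:
    """Serialize a SyntheticDataset to a directory.

    ``aif.csv``/``cortex.csv``/``medulla.csv`` hold the noisy measurement
    curves; ``*_clean.csv`` the noiseless versions; ``truth.json`` the
    generating parameters; ``meta.json`` provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_curve(ds.noisy["aif"], outdir / "aif.csv")
    write_curve(ds.noisy["c_cor"], outdir / "cortex.csv")
    write_curve(ds.noisy["c_med"], outdir / "medulla.csv")
    write_curve(ds.aif, outdir / "aif_clean.csv")
    write_curve(ds.clean[0], outdir / "cortex_clean.csv")
    write_curve(ds.clean[1], outdir / "medulla_clean.csv")
    der = derived_flows(ds.truth)
    write_json(
        {"params": ds.truth.to_dict(), "derived": {"f_med": der.f_med, "f_t": der.f_t}},
        outdir / "truth.json",
    )
    write_json(
        {"seed": ds.seed, "aif_index": ds.aif_index, "set_index": ds.set_index},
        outdir / "meta.json",
    )


def load_dataset(indir) -> SyntheticDataset:
    """Load a SyntheticDataset saved by :func:`save_dataset`."""
    indir = Path(indir)
    truth = SevenCompParams(**json.loads((indir / "truth.json").read_text())["params"])
    meta = json.loads((indir / "meta.json").read_text())
    aif = read_curve(indir / "aif_clean.csv")
    clean = (read_curve(indir / "cortex_clean.csv"), read_curve(indir / "medulla_clean.csv"))
    noisy = {
        "aif": read_curve(indir / "aif.csv"),
        "c_cor": read_curve(indir / "cortex.csv"),
        "c_med": read_curve(indir / "medulla.csv"),
    }
    return SyntheticDataset(
        aif=aif,
        truth=truth,
        clean=clean,
        noisy=noisy,
        seed=meta["seed"],
        aif_index=meta["aif_index"],
        set_index=meta["set_index"],
    )


# ---------------------------------------------------------------------------
# NIfTI


def save_phantom(phantom: Phantom, image_path, labels_path, sidecar_path=None) -> None:
    """Write a phantom as 4D NIfTI + integer label map (+ JSON sidecar)."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(phantom.image4d.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), str(labels_path))
    if sidecar_path is not None:
        write_json(
            {
                "sigma": phantom.sigma,
                "seed": phantom.seed,
                "labels": {"background": 0, "cortex": 1, "inner_medulla": 2, "partial_volume": 3},
            },
            sidecar_path,
        )


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


# ---------------------------------------------------------------------------
# JSON + manifests


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, command: str, config: dict, seed: int | None, args: dict) -> None:
    """Provenance record enabling exact re-runs of a stochastic command."""
    import scipy

    from . import __version__

    write_json(
        {
            "command": command,
            "config": config,
            "config_hash": config_hash(config),
            "seed": seed,
            "args": args,
            "versions": {
                "renoperf": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
            },
        },
        path,
    )
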