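"""Network-ready inputs: brain masking, per-slice standardisation, 3-label
ground truth and 64 x 64 training patches.

Brain tissue is everything inside the intracranial volume that is not CSF.
Intensities are standardised per slice over brain-tissue voxels only (zero
mean, unit variance), because non-brain voxels are mostly zero and would bias
a global fit; non-brain voxels are set to 0 afterwards.  Ground truth uses
three labels -- non-brain (0), non-WMH brain tissue (1), WMH (2) -- and patch
sampling is class-aware: a configurable fraction of patches is forced to
contain at least one WMH voxel to fight the extreme label imbalance.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ContractViolation, DegenerateSliceError, ParameterError
from .io import Volume, check_aligned

__all__ = [
    "LABEL_NON_BRAIN",
    "LABEL_TISSUE",
    "LABEL_WMH",
    "TrainingPatch",
    "brain_tissue_mask",
    "normalize_slice",
    "normalize_volume",
    "relabel",
    "extract_training_patches",
    "patches_to_arrays",
    "save_patches",
    "load_patches",
    "slice_dataset",
]

log = logging.getLogger(__name__)

LABEL_NON_BRAIN = 0
LABEL_TISSUE = 1
LABEL_WMH = 2


@dataclass
class TrainingPatch:
    """One multi-channel 64 x 64 (by default) training example.

    ``channels`` is (n_channels, p, p); ``labels`` is (p, p) of {0, 1, 2};
    provenance records (scan id, slice index, top-left origin).
    """

    channels: np.ndarray
    labels: np.ndarray
    scan_id: str
    slice_index: int
    origin: tuple[int, int]


def brain_tissue_mask(icv: Volume, csf: Volume) -> Volume:
    """Brain tissue = ICV and not CSF."""
    check_aligned(icv=icv, csf=csf)
    mask = icv.data.astype(bool) & ~csf.data.astype(bool)
    return Volume(mask.astype(np.uint8), icv.affine.copy())


def normalize_slice(slice_: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Standardise brain-tissue voxels of one slice to zero mean, unit SD.

    Non-brain voxels are set to 0.  Raises :class:`DegenerateSliceError` for
    an empty mask or (near-)zero intensity variance over the brain.
    """
    slice_ = np.asarray(slice_, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if slice_.shape != mask.shape:
        raise ContractViolation("slice and mask shapes differ")
    if not mask.any():
        raise DegenerateSliceError("empty brain mask")
    vals = slice_[mask]
    sd = vals.std()
    if sd < 1e-12:
        raise DegenerateSliceError("zero intensity variance over brain tissue")
    out = np.zeros_like(slice_)
    out[mask] = (vals - vals.mean()) / sd
    return out


def normalize_volume(flair: Volume, brain: Volume) -> Volume:
    """Apply :func:`normalize_slice` slice by slice; degenerate slices (empty
    mask / constant intensity) become all-zero and are logged."""
    check_aligned(flair=flair, brain=brain)
    out = np.zeros(flair.shape, dtype=float)
    for z in range(flair.shape[2]):
        try:
            out[:, :, z] = normalize_slice(
                flair.data[:, :, z], brain.data[:, :, z].astype(bool)
            )
        except DegenerateSliceError as e:
            log.info("slice %d not normalised (%s); zeroed", z, e)
    return Volume(out, flair.affine.copy())


def relabel(wmh_mask: Volume, icv: Volume, csf: Volume) -> Volume:
    """Three-label ground truth: 0 non-brain, 1 brain tissue, 2 WMH.

    WMH claims priority over tissue; a WMH voxel outside the brain-tissue
    region is demoted to its region's label and logged.
    """
    check_aligned(wmh=wmh_mask, icv=icv, csf=csf)
    brain = icv.data.astype(bool) & ~csf.data.astype(bool)
    wmh = wmh_mask.data.astype(bool)
    stray = int((wmh & ~brain).sum())
    if stray:
        log.warning("%d WMH voxels outside brain tissue were demoted", stray)
    labels = np.zeros(wmh.shape, dtype=np.int16)
    labels[brain] = LABEL_TISSUE
    labels[wmh & brain] = LABEL_WMH
    return Volume(labels, icv.affine.copy())


def extract_training_patches(
    channels: Sequence[Volume],
    labels: Volume,
    patch_size: int = 64,
    n_patches: int = 100,
    seed: int = 0,
    wmh_fraction: float = 0.5,
    scan_id: str = "scan",
) -> list[TrainingPatch]:
    """Sample ``n_patches`` patches whose footprint intersects brain tissue.

    A ``wmh_fraction`` share of patches is drawn from origins whose window
    contains at least one WMH voxel (when any exist).  Deterministic for a
    given seed.
    """
    if n_patches == 0:
        return []
    if not channels:
        raise ParameterError("at least one image channel required")
    vols = {f"ch{i}": v for i, v in enumerate(channels)}
    check_aligned(labels=labels, **vols)
    rows, cols, nsl = labels.shape
    p = patch_size
    if p > rows or p > cols:
        raise ParameterError(f"patch size {p} does not fit in-plane shape {rows}x{cols}")

    lab = labels.data
    rng = np.random.default_rng(seed)

    def window_origins(mask2d: np.ndarray) -> np.ndarray:
        # origins whose p x p window contains >= 1 True pixel
        from scipy.ndimage import maximum_filter

        hit = maximum_filter(mask2d.astype(np.uint8), size=p, mode="constant")
        # maximum_filter is centred; shift to top-left-origin indexing
        off = (p - 1) // 2
        valid = hit[off : off + rows - p + 1, off : off + cols - p + 1]
        return np.argwhere(valid > 0)

    brain_orig = {}
    wmh_orig = {}
    for z in range(nsl):
        b = lab[:, :, z] != LABEL_NON_BRAIN
        if b.any():
            o = window_origins(b)
            if len(o):
                brain_orig[z] = o
        w = lab[:, :, z] == LABEL_WMH
        if w.any():
            o = window_origins(w)
            if len(o):
                wmh_orig[z] = o
    if not brain_orig:
        raise ParameterError("no valid patch origin intersects brain tissue")

    n_wmh = int(round(wmh_fraction * n_patches)) if wmh_orig else 0
    if wmh_fraction > 0 and not wmh_orig:
        log.warning("no WMH voxels present; sampling brain-only patches")

    out: list[TrainingPatch] = []
    for i in range(n_patches):
        pool = wmh_orig if i < n_wmh else brain_orig
        zs = list(pool.keys())
        z = zs[rng.integers(len(zs))]
        r, c = pool[z][rng.integers(len(pool[z]))]
        ch = np.stack(
            [np.asarray(v.data, dtype=float)[r : r + p, c : c + p, z] for v in channels]
        )
        out.append(
            TrainingPatch(
                channels=ch,
                labels=lab[r : r + p, c : c + p, z].astype(np.int16),
                scan_id=scan_id,
                slice_index=int(z),
                origin=(int(r), int(c)),
            )
        )
    return out


def patches_to_arrays(patches: Sequence[TrainingPatch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into (N, C, p, p) inputs and (N, p, p) integer targets."""
    X = np.stack([p.channels for p in patches]).astype(np.float64)
    Y = np.stack([p.labels for p in patches]).astype(np.int64)
    return X, Y


def save_patches(patches: Sequence[TrainingPatch], path) -> Path:
    """Serialise a patch set to ``<path>.npz`` plus a JSON manifest."""
    path = Path(path)
    X, Y = patches_to_arrays(patches)
    np.savez_compressed(path.with_suffix(".npz"), channels=X, labels=Y)
    manifest = {
        "n_patches": len(patches),
        "patch_size": int(X.shape[-1]),
        "n_channels": int(X.shape[1]),
        "provenance": [
            {"scan_id": p.scan_id, "slice": p.slice_index, "origin": list(p.origin)}
            for p in patches
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_patches(path) -> list[TrainingPatch]:
    path = Path(path)
    arr = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    out = []
    for i, prov in enumerate(manifest["provenance"]):
        out.append(
            TrainingPatch(
                channels=arr["channels"][i],
                labels=arr["labels"][i],
                scan_id=prov["scan_id"],
                slice_index=prov["slice"],
                origin=tuple(prov["origin"]),
            )
        )
    return out


def slice_dataset(volumes: Sequence[Volume]) -> list[tuple[int, int]]:
    """Enumerate whole-slice items over a set of scans as (scan, slice) pairs.

    Whole slices are the test-time unit: a catalogue of k scans of s slices
    each yields k * s items.
    """
    return [(i, z) for i, v in enumerate(volumes) for z in range(v.shape[2])]
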