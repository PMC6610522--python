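"""LOTS-IM: Limited One-Time Sampling Irregularity Map.

Unsupervised, per-slice texture-anomaly scoring.  Every slice is tiled into
non-overlapping *source* patches at several sizes (1, 2, 4 and 8 pixels); a
set of *target* patches is sampled at random locations fully inside the brain
tissue.  The difference between a source patch ``s`` and a target patch ``t``
is

    difference = theta * |max(s - t)| + (1 - theta) * |mean(s - t)|

with ``max``/``mean`` taken elementwise over ``s - t`` before the absolute
value, exactly in that order.  The *age value* of a source patch is the mean
of its ``top_m`` largest differences against the targets; sources in healthy
tissue score low because plenty of targets resemble them, whereas irregular
(e.g., hyperintense) patches score high against nearly all targets.

Per-size age maps are min-max normalised per slice, up-sampled bilinearly to
slice resolution and Gaussian-smoothed, then blended as a convex combination
(default weights 0.65 / 0.2 / 0.1 / 0.05 for sizes 1 / 2 / 4 / 8).  The blend
is finally penalised by multiplying with the FLAIR intensities -- keeping only
bright irregularities, which is what WMH are -- and min-max normalised
globally over all brain voxels of the volume.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import ContractViolation, DegenerateSliceError, ParameterError
from .io import Volume, check_aligned
from .preprocess import brain_tissue_mask

__all__ = [
    "IAMConfig",
    "PatchSet",
    "IrregularityMap",
    "extract_source_patches",
    "sample_target_patches",
    "patch_difference",
    "age_value",
    "age_grid",
    "compute_age_map",
    "blend_age_maps",
    "penalize_and_normalize",
    "compute_iam",
]

log = logging.getLogger(__name__)

_CHUNK = 4096  # source patches scored per vectorised block


@dataclass(frozen=True)
class IAMConfig:
    """Tunable knobs of the irregularity-map computation.

    ``theta`` balances the peak term against the mean term of the patch
    difference; ``top_m`` is how many of the largest differences are averaged
    into the age value; ``n_targets`` how many target patches are sampled per
    slice and patch size.  ``smoothing_sigma`` of ``None`` uses half the patch
    size (in pixels) at each scale.
    """

    patch_sizes: tuple[int, ...] = (1, 2, 4, 8)
    theta: float = 0.5
    top_m: int = 100
    n_targets: int = 2048
    blend_weights: tuple[float, ...] = (0.65, 0.2, 0.1, 0.05)
    smoothing_sigma: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.theta <= 1:
            raise ParameterError("theta must lie in [0, 1]")
        if self.top_m < 1 or self.n_targets < 1:
            raise ParameterError("top_m and n_targets must be positive")
        sizes = self.patch_sizes
        if any(b <= a for a, b in zip(sizes, sizes[1:])) or any(s < 1 for s in sizes):
            raise ParameterError("patch_sizes must be positive and strictly increasing")
        w = np.asarray(self.blend_weights, dtype=float)
        if len(w) != len(sizes):
            raise ParameterError("one blend weight per patch size required")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("blend weights must be non-negative and sum to 1")

    def sigma_for(self, size: int) -> float:
        return size / 2.0 if self.smoothing_sigma is None else self.smoothing_sigma


@dataclass
class PatchSet:
    """Patches of one role on one slice; `origins` are top-left (row, col)."""

    patches: list[np.ndarray]
    origins: list[tuple[int, int]]
    role: str  # "source" | "target"
    size: int

    def __len__(self):
        return len(self.patches)

    def as_array(self) -> np.ndarray:
        """Stack into (n_patches, size*size); clipped edge patches are
        padded by edge replication so all rows have equal length."""
        n = self.size
        out = np.empty((len(self.patches), n * n), dtype=float)
        for i, p in enumerate(self.patches):
            if p.shape != (n, n):
                p = np.pad(p, ((0, n - p.shape[0]), (0, n - p.shape[1])), mode="edge")
            out[i] = p.ravel()
        return out


@dataclass
class IrregularityMap:
    """Final IAM plus the per-patch-size age maps it was blended from."""

    per_size_maps: dict[int, np.ndarray]
    final_map: np.ndarray


def extract_source_patches(slice_: np.ndarray, size: int) -> PatchSet:
    """Tile the slice into a non-overlapping grid of ``size x size`` patches.

    Every pixel belongs to exactly one patch; edge patches are clipped when
    the slice dimensions are not multiples of ``size``.
    """
    slice_ = np.asarray(slice_)
    rows, cols = slice_.shape
    if size > rows or size > cols:
        raise ParameterError(f"patch size {size} exceeds slice shape {slice_.shape}")
    patches, origins = [], []
    for r in range(0, rows, size):
        for c in range(0, cols, size):
            patches.append(slice_[r : r + size, c : c + size])
            origins.append((r, c))
    return PatchSet(patches, origins, "source", size)


def _valid_target_origins(brain_mask: np.ndarray, size: int) -> np.ndarray:
    """(k, 2) array of origins whose whole window lies inside the mask."""
    mask = np.asarray(brain_mask, dtype=bool)
    if size > mask.shape[0] or size > mask.shape[1]:
        return np.empty((0, 2), dtype=int)
    ok = sliding_window_view(mask, (size, size)).all(axis=(2, 3))
    return np.argwhere(ok)


def sample_target_patches(
    slice_: np.ndarray,
    brain_mask: np.ndarray,
    size: int,
    n_targets: int,
    seed: int | np.random.Generator,
) -> PatchSet:
    """Sample ``n_targets`` patches (with replacement) fully inside the brain.

    Raises
    ------
    DegenerateSliceError
        If no placement keeps the whole patch inside the brain mask; callers
        normally skip such slices.
    """
    slice_ = np.asarray(slice_)
    if slice_.shape != np.shape(brain_mask):
        raise ContractViolation("slice and brain mask shapes differ")
    origins = _valid_target_origins(brain_mask, size)
    if len(origins) == 0:
        raise DegenerateSliceError(
            f"no valid {size}x{size} target placement inside the brain mask"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = origins[rng.integers(0, len(origins), size=n_targets)]
    patches = [slice_[r : r + size, c : c + size] for r, c in picks]
    return PatchSet(patches, [tuple(p) for p in picks], "target", size)


def patch_difference(s: np.ndarray, t: np.ndarray, theta: float) -> float:
    """theta*|max(s-t)| + (1-theta)*|mean(s-t)|, elementwise max/mean first."""
    s, t = np.asarray(s, dtype=float), np.asarray(t, dtype=float)
    if s.shape != t.shape:
        raise ContractViolation(f"patch shapes differ: {s.shape} vs {t.shape}")
    d = s - t
    return float(theta * abs(d.max()) + (1.0 - theta) * abs(d.mean()))


def age_value(differences: Sequence[float], top_m: int) -> float:
    """Mean of the ``min(top_m, len)`` largest difference values."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ContractViolation("age_value needs at least one difference value")
    k = min(int(top_m), d.size)
    return float(np.partition(d, d.size - k)[d.size - k :].mean())


def age_grid(
    slice_: np.ndarray,
    brain_mask: np.ndarray,
    size: int,
    config: IAMConfig,
    targets: PatchSet,
) -> np.ndarray:
    """Raw (un-normalised) age values on the source-patch grid.

    A source patch receives an age value iff it contains at least one
    brain-tissue pixel; all other grid cells stay 0.
    """
    slice_ = np.asarray(slice_, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    sources = extract_source_patches(slice_, size)
    gh = -(-slice_.shape[0] // size)
    gw = -(-slice_.shape[1] // size)
    grid = np.zeros((gh, gw), dtype=float)

    in_brain = np.array(
        [mask[r : r + size, c : c + size].any() for r, c in sources.origins]
    )
    if not in_brain.any() or len(targets) == 0:
        return grid

    S = sources.as_array()[in_brain]
    T = targets.as_array()
    k = min(config.top_m, len(T))
    ages = np.empty(len(S), dtype=float)
    for start in range(0, len(S), _CHUNK):
        blk = S[start : start + _CHUNK]
        d = blk[:, None, :] - T[None, :, :]
        diff = config.theta * np.abs(d.max(axis=2)) + (1 - config.theta) * np.abs(
            d.mean(axis=2)
        )
        part = np.partition(diff, diff.shape[1] - k, axis=1)[:, diff.shape[1] - k :]
        ages[start : start + _CHUNK] = part.mean(axis=1)

    flat_idx = np.flatnonzero(in_brain)
    grid.ravel()[flat_idx] = ages
    return grid


def compute_age_map(
    slice_: np.ndarray,
    brain_mask: np.ndarray,
    size: int,
    config: IAMConfig,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-size age map at slice resolution: age grid -> per-slice min-max
    normalisation -> bilinear up-sampling -> Gaussian smoothing."""
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        log.warning("empty brain mask: returning a zero age map")
        return np.zeros(np.shape(slice_), dtype=float)
    if rng is None:
        rng = config.seed
    targets = sample_target_patches(slice_, mask, size, config.n_targets, rng)
    grid = age_grid(slice_, mask, size, config, targets)

    lo, hi = grid.min(), grid.max()
    grid = (grid - lo) / (hi - lo) if hi > lo else np.zeros_like(grid)

    h, w = np.shape(slice_)
    if grid.shape != (h, w):
        grid = ndimage.zoom(
            grid, (h / grid.shape[0], w / grid.shape[1]), order=1, mode="nearest",
            grid_mode=True,
        )
    sigma = config.sigma_for(size)
    if sigma > 0:
        grid = ndimage.gaussian_filter(grid, sigma=sigma)
    return np.clip(grid, 0.0, 1.0)


def blend_age_maps(maps: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """Pixelwise convex combination of the per-size age maps."""
    w = np.asarray(weights, dtype=float)
    if len(maps) != len(w):
        raise ParameterError("need one weight per map")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ParameterError("blend weights must be non-negative and sum to 1")
    maps = [np.asarray(m, dtype=float) for m in maps]
    for m in maps[1:]:
        if m.shape != maps[0].shape:
            raise ContractViolation("age maps to blend must share a shape")
    out = np.zeros_like(maps[0])
    for wi, m in zip(w, maps):
        out += wi * m
    return out


def penalize_and_normalize(
    blended: np.ndarray, flair: np.ndarray, brain_mask: np.ndarray
) -> np.ndarray:
    """Multiply the blended map by the FLAIR volume (to keep only bright
    irregularities) and min-max normalise jointly over every brain voxel of
    the whole volume; non-brain voxels are exactly 0."""
    blended = np.asarray(blended, dtype=float)
    flair = np.asarray(flair, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if not (blended.shape == flair.shape == mask.shape):
        raise ContractViolation("blended map, FLAIR and mask must share a shape")
    prod = blended * flair
    out = np.zeros_like(prod)
    vals = prod[mask]
    if vals.size == 0:
        log.warning("empty brain mask: zero irregularity map")
        return out
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        log.warning("constant product over the brain: degenerate normalisation, zero map")
        return out
    out[mask] = (prod[mask] - lo) / (hi - lo)
    return out


def compute_iam(
    flair: Volume, icv: Volume, csf: Volume, config: IAMConfig = IAMConfig()
) -> IrregularityMap:
    """Run the full multi-scale pipeline on a volume.

    Per slice and per patch size: sample targets, score sources, normalise,
    up-sample, smooth; blend the four scales; then penalise by FLAIR and
    normalise globally over the brain.  Deterministic given ``config.seed``.
    """
    check_aligned(flair=flair, icv=icv, csf=csf)
    brain = brain_tissue_mask(icv, csf).data.astype(bool)
    data = np.asarray(flair.data, dtype=float)
    nsl = data.shape[2]

    per_size = {s: np.zeros(data.shape, dtype=float) for s in config.patch_sizes}
    for z in range(nsl):
        sl, m = data[:, :, z], brain[:, :, z]
        if not m.any():
            log.info("slice %d has an empty brain mask; zero maps", z)
            continue
        for si, size in enumerate(config.patch_sizes):
            rng = np.random.default_rng([config.seed, z, si])
            try:
                per_size[size][:, :, z] = compute_age_map(sl, m, size, config, rng)
            except DegenerateSliceError:
                log.info("slice %d: no valid %dx%d target patch; zero map", z, size, size)

    blended = blend_age_maps(
        [per_size[s] for s in config.patch_sizes], config.blend_weights
    )
    final = penalize_and_normalize(blended, data, brain)
    return IrregularityMap(per_size_maps=per_size, final_map=final)
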