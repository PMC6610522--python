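"""Synthetic T2-FLAIR-like brain phantoms with ground truth.

The phantom is deliberately minimal rather than anatomically realistic: a
per-slice ellipse of "brain" whose radii shrink toward the first and last
slices (so the stack is roughly ellipsoidal), a thin bright cortical rim,
low-intensity CSF cavities near the centre, and hyperintense ellipsoidal
lesions standing in for white-matter hyperintensities (WMH).  That is exactly
the topology the downstream stages need: an intracranial-volume (ICV) mask, a
CSF mask whose complement within ICV is "brain tissue", and bright lesions on
a darker tissue background, as on real FLAIR.

All randomness flows from a single integer seed through one generator, so a
given :class:`PhantomSpec` always produces a bit-identical bundle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ContractViolation, ParameterError, PlacementError
from .io import Volume

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "phantom_suite"]

log = logging.getLogger(__name__)

LABEL_NON_BRAIN = 0
LABEL_TISSUE = 1
LABEL_WMH = 2

_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic scan.

    The default geometry emulates a 256 x 256 x 35 whole-brain FLAIR stack at
    1 x 1 x 5 mm voxels; tests typically shrink ``shape`` to keep runtimes low.
    ``lesion_contrast`` multiplies the mean normal-tissue intensity, so values
    above 1 make lesions hyperintense as WMH are on T2-FLAIR.
    """

    shape: tuple[int, int, int] = (256, 256, 35)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 5.0)
    lesion_count: int = 8
    lesion_radius_range: tuple[float, float] = (3.0, 8.0)  # mm
    lesion_contrast: float = 1.7
    csf_fraction: float = 0.12
    noise_sd: float | None = None  # default: 5% of the tissue intensity
    seed: int = 0
    tissue_intensity: float = 100.0
    rim_contrast: float = 1.15
    csf_intensity_fraction: float = 0.25

    def __post_init__(self):
        r, c, s = self.shape
        if r < 32 or c < 32:
            raise ParameterError("in-plane dimensions must be >= 32")
        if s < 1:
            raise ParameterError("need at least one slice")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel dimensions must be positive")
        if self.lesion_count < 0:
            raise ParameterError("lesion_count must be >= 0")
        if self.lesion_contrast <= 1:
            raise ParameterError("lesion_contrast must exceed 1 (WMH are hyperintense)")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ParameterError("lesion_radius_range must satisfy 0 < lo <= hi")
        if not (0 < self.csf_fraction < 0.5):
            raise ParameterError("csf_fraction must lie in (0, 0.5)")

    @property
    def effective_noise_sd(self) -> float:
        return 0.05 * self.tissue_intensity if self.noise_sd is None else self.noise_sd


@dataclass
class PhantomBundle:
    """One synthetic scan plus its masks and 3-label ground truth."""

    flair: Volume
    icv: Volume
    csf: Volume
    labels: Volume
    true_wmh_volume: float  # mm^3
    spec: PhantomSpec

    def __post_init__(self):
        icv = self.icv.data.astype(bool)
        csf = self.csf.data.astype(bool)
        if np.any(csf & ~icv):
            raise ContractViolation("CSF mask must be a subset of the ICV mask")


def _radial_field(spec: PhantomSpec) -> np.ndarray:
    """Normalised elliptical radius rho per voxel; the brain is rho <= 1."""
    rows, cols, nsl = spec.shape
    a, b = 0.42 * rows, 0.40 * cols
    rc, cc, zc = (rows - 1) / 2.0, (cols - 1) / 2.0, (nsl - 1) / 2.0
    z = np.arange(nsl)
    # radii shrink toward the first/last slices (ellipsoidal cap profile)
    shrink = np.sqrt(np.clip(1.0 - ((z - zc) / (nsl / 2.0 + 0.5)) ** 2, 0.0, None))
    shrink = np.clip(shrink, 0.2, None)
    r = np.arange(rows)[:, None, None]
    c = np.arange(cols)[None, :, None]
    rho = np.sqrt(
        ((r - rc) / (a * shrink[None, None, :])) ** 2
        + ((c - cc) / (b * shrink[None, None, :])) ** 2
    )
    return rho


def _csf_mask(spec: PhantomSpec, icv: np.ndarray) -> np.ndarray:
    """Two ventricle-like cavities, scaled so CSF makes up roughly
    ``csf_fraction`` of the ICV (binary search on the cavity size)."""
    rows, cols, nsl = spec.shape
    rc, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    r = np.arange(rows)[:, None, None]
    c = np.arange(cols)[None, :, None]
    offsets = (-0.16 * cols, 0.16 * cols)
    target = spec.csf_fraction * icv.sum()

    def cavity(scale):
        m = np.zeros(spec.shape, bool)
        for off in offsets:
            d = ((r - rc) / (scale * rows)) ** 2 + ((c - cc - off) / (0.6 * scale * cols)) ** 2
            m |= d <= 1.0
        return m & icv

    lo_s, hi_s = 0.01, 0.35
    for _ in range(30):
        mid = 0.5 * (lo_s + hi_s)
        if cavity(mid).sum() < target:
            lo_s = mid
        else:
            hi_s = mid
    return cavity(0.5 * (lo_s + hi_s))


def _lesion_footprint(spec: PhantomSpec, center, radius_mm) -> tuple | None:
    """Voxel indices of an ellipsoid of the given mm radius around ``center``,
    or None if it pokes outside the volume."""
    dr, dc, dz = spec.voxel_size
    r0, c0, z0 = center
    er, ec, ez = radius_mm / dr, radius_mm / dc, radius_mm / dz
    ez = max(ez, 0.5)
    # inward rounding: only voxel centres that can fall inside the ellipsoid
    rlo, rhi = int(np.ceil(r0 - er)), int(np.floor(r0 + er))
    clo, chi = int(np.ceil(c0 - ec)), int(np.floor(c0 + ec))
    zlo, zhi = int(np.ceil(z0 - ez)), int(np.floor(z0 + ez))
    rows, cols, nsl = spec.shape
    if rlo < 0 or clo < 0 or zlo < 0 or rhi >= rows or chi >= cols or zhi >= nsl:
        return None
    rr, cc2, zz = np.mgrid[rlo : rhi + 1, clo : chi + 1, zlo : zhi + 1]
    inside = (
        ((rr - r0) / er) ** 2 + ((cc2 - c0) / ec) ** 2 + ((zz - z0) / ez) ** 2
    ) <= 1.0
    if not inside.any():
        return None
    return rr[inside], cc2[inside], zz[inside]


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build one phantom bundle; deterministic for a given spec (incl. seed).

    Raises
    ------
    PlacementError
        If some lesion cannot be placed fully inside brain tissue after
        bounded retries (the error names the lesion index).
    """
    rng = np.random.default_rng(spec.seed)
    rho = _radial_field(spec)
    icv = rho <= 1.0
    rim = icv & (rho > 0.93)
    csf = _csf_mask(spec, icv & ~rim)
    tissue = icv & ~csf

    flair = np.zeros(spec.shape, dtype=np.float64)
    flair[tissue] = spec.tissue_intensity
    flair[rim] = spec.rim_contrast * spec.tissue_intensity
    flair[csf] = spec.csf_intensity_fraction * spec.tissue_intensity

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[tissue] = LABEL_TISSUE

    # lesions: hyperintense relative to the mean over (rim-included) tissue,
    # with a small margin so the contrast bound survives lesion painting
    mean_tissue = flair[tissue].mean() if tissue.any() else spec.tissue_intensity
    lesion_value = 1.01 * spec.lesion_contrast * mean_tissue
    interior = np.argwhere(tissue & (rho < 0.9))
    for i in range(spec.lesion_count):
        radius = rng.uniform(*spec.lesion_radius_range)
        placed = False
        for _ in range(_MAX_PLACEMENT_TRIES):
            center = interior[rng.integers(len(interior))]
            foot = _lesion_footprint(spec, center, radius)
            if foot is None:
                continue
            if tissue[foot].all():
                flair[foot] = lesion_value
                labels[foot] = LABEL_WMH
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place lesion {i} (radius {radius:.1f} mm) inside brain tissue"
            )

    flair = flair + rng.normal(0.0, spec.effective_noise_sd, spec.shape)

    vv = float(np.prod(spec.voxel_size))
    true_volume = float((labels == LABEL_WMH).sum()) * vv
    mk = lambda arr, dt: Volume.from_voxel_size(arr.astype(dt), spec.voxel_size)
    return PhantomBundle(
        flair=mk(flair, np.float64),
        icv=mk(icv, np.uint8),
        csf=mk(csf, np.uint8),
        labels=mk(labels, np.int16),
        true_wmh_volume=true_volume,
        spec=spec,
    )


def phantom_suite(
    groups: Sequence[tuple[float, float]],
    n_per_group: int,
    seed: int,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomBundle]:
    """Generate ``n_per_group`` phantoms per target WMH-volume range (mm^3).

    Ranges are half-open ``[lo, hi)``; an unbounded upper end may be given as
    ``inf``.  Lesion count and radius are adjusted iteratively until the
    realised WMH volume lands inside the requested range.

    Raises
    ------
    ParameterError
        If ranges overlap, or a range is unreachable for the phantom geometry.
    """
    groups = [(float(lo), float(hi)) for lo, hi in groups]
    for lo, hi in groups:
        if not (0 <= lo < hi):
            raise ParameterError(f"invalid range [{lo}, {hi})")
    for (lo1, hi1), (lo2, hi2) in zip(sorted(groups), sorted(groups)[1:]):
        if hi1 > lo2:
            raise ParameterError("target-volume ranges must be non-overlapping")

    base = base_spec if base_spec is not None else PhantomSpec(shape=(128, 128, 9))
    out: list[PhantomBundle] = []
    for gi, (lo, hi) in enumerate(groups):
        target = lo * 1.5 if np.isinf(hi) else 0.5 * (lo + hi)
        for j in range(n_per_group):
            bundle = _generate_in_range(base, lo, hi, target, seed + 97 * gi + j)
            out.append(bundle)
    return out


def _generate_in_range(base, lo, hi, target, seed, max_iter=12):
    radius = 6.0
    per_lesion = 4.0 / 3.0 * np.pi * radius**3
    count = max(1, round(target / per_lesion))
    for _ in range(max_iter):
        spec = replace(
            base,
            seed=seed,
            lesion_count=count,
            lesion_radius_range=(0.8 * radius, 1.2 * radius),
        )
        try:
            bundle = generate_phantom(spec)
        except PlacementError:
            radius *= 0.85
            count = max(1, round(target / (4.0 / 3.0 * np.pi * radius**3)))
            continue
        v = bundle.true_wmh_volume
        if lo <= v < hi and v >= 1:
            return bundle
        if v <= 0:
            count += 1
            continue
        # rescale the lesion radius toward the target volume
        radius *= np.clip((target / v) ** (1.0 / 3.0), 0.7, 1.4)
        if radius < 1.5:
            radius = 1.5
            count = max(1, round(target / (4.0 / 3.0 * np.pi * radius**3)))
    raise ParameterError(
        f"could not reach a WMH volume in [{lo}, {hi}) mm^3 for shape {base.shape}"
    )
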