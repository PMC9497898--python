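"""VOI definition, mu +/- 3 sigma normalization and gray-level discretization.

Two segmentation styles mirror common phantom practice: an axis-aligned cubic
VOI for the printed objects and threshold-based region growing (with border
and apical/basal slice exclusion) for the biological ones. Intensities are
standardized to z = (I - mu)/sigma clipped at +/-3 before binning; gray levels
come from either a fixed bin size (FBS, ceil((I - I_min)/B), B = 0.15
normalized / 50 raw) or a fixed bin number (FBN, D = 64).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .virtual_mr import MRVolume

__all__ = [
    "VOIMask",
    "NormalizationSpec",
    "DiscretizationSpec",
    "DiscreteVOI",
    "cubic_voi",
    "grow_voi",
    "normalize_mu3sigma",
    "discretize_fbs",
    "discretize_fbn",
    "discretize",
]


class DegenerateVOIError(ValueError):
    """VOI has no usable intensity spread (or is empty)."""


@dataclass
class VOIMask:
    mask: np.ndarray  # bool, aligned to its MRVolume
    method: str  # "cubic" | "grown"
    edge_mm: float | None = None

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class NormalizationSpec:
    mu: float
    sigma: float
    clip_k: float = 3.0


@dataclass
class DiscretizationSpec:
    method: str  # "FBS" | "FBN"
    B: float = 0.15  # bin width (FBS); 0.15 normalized, 50 raw
    D: int = 64  # bin number (FBN)
    ibsi_strict: bool = False  # floor((I - I_min)/B) + 1 variant

    @classmethod
    def for_setup(cls, method: str, normalized: bool) -> "DiscretizationSpec":
        if method == "FBS":
            return cls("FBS", B=0.15 if normalized else 50.0)
        return cls("FBN", D=64)


@dataclass
class DiscreteVOI:
    """Integer gray levels (1..G) on a mask, ready for texture matrices."""

    levels: np.ndarray  # int, 0 outside the mask
    mask: np.ndarray
    n_levels: int  # table size G used for matrix indexing
    spec: DiscretizationSpec


def cubic_voi(volume: MRVolume, center_mm, edge_mm: float) -> VOIMask:
    """Axis-aligned cube of the given edge length centered at ``center_mm``."""
    shape = volume.intensities.shape
    half = edge_mm / 2.0
    sl = []
    for c, s in zip(center_mm, shape):
        lo = int(round((c - half) / volume.voxel_mm))
        hi = lo + int(round(edge_mm / volume.voxel_mm))
        if lo < 0 or hi > s:
            raise ValueError("cubic VOI exceeds volume bounds")
        sl.append(slice(lo, hi))
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(sl)] = True
    return VOIMask(mask=mask, method="cubic", edge_mm=edge_mm)


def centered_cubic_voi(volume: MRVolume, edge_mm: float) -> VOIMask:
    """Cube centered on the field of view (printed phantoms are centered)."""
    center = tuple(s * volume.voxel_mm / 2.0 for s in volume.intensities.shape)
    return cubic_voi(volume, center, edge_mm)


def grow_voi(volume: MRVolume, seeds) -> VOIMask:
    """Threshold-based region growing with border-zone and end-slice exclusion.

    Otsu foreground -> largest 26-connected component containing a seed ->
    one-voxel erosion (border-zone exclusion) -> removal of the most apical
    and basal occupied slices (last grid axis).
    """
    from scipy.ndimage import binary_erosion, label
    from skimage.filters import threshold_otsu

    arr = volume.intensities
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise ValueError("at least one seed is required")
    thresh = threshold_otsu(arr)
    fg = arr > thresh
    if not any(fg[s] for s in seeds):
        raise DegenerateVOIError("no seed lies in the foreground")
    lab, _ = label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    keep = {lab[s] for s in seeds if fg[s]}
    comp = np.isin(lab, sorted(keep))
    comp = binary_erosion(comp, np.ones((3, 3, 3), dtype=bool))
    occupied = np.flatnonzero(comp.any(axis=(0, 1)))
    if occupied.size <= 2:
        raise DegenerateVOIError("VOI empty after exclusions")
    comp[:, :, occupied[0]] = False
    comp[:, :, occupied[-1]] = False
    if not comp.any():
        raise DegenerateVOIError("VOI empty after exclusions")
    return VOIMask(mask=comp, method="grown")


def normalize_mu3sigma(
    volume: MRVolume, mask: VOIMask, clip_k: float = 3.0, exclude: bool = False
) -> tuple[np.ndarray, NormalizationSpec]:
    """Standardize VOI intensities to z-scores, limited to +/- ``clip_k``.

    Returns the transformed intensity grid (values outside the mask are left
    untouched and are ignored downstream) and the spec used. ``exclude=True``
    masks out-of-range voxels instead of clipping them (the mask is modified
    in place in that case).
    """
    vals = volume.intensities[mask.mask]
    if vals.size < 2:
        raise DegenerateVOIError("normalization needs at least 2 voxels")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    if sigma == 0:
        raise DegenerateVOIError("zero intensity spread in VOI")
    z = (volume.intensities - mu) / sigma
    out = volume.intensities.astype(np.float64).copy()
    if exclude:
        keep = np.abs(z) <= clip_k
        mask.mask &= keep
        out[mask.mask] = z[mask.mask]
    else:
        out[mask.mask] = np.clip(z[mask.mask], -clip_k, clip_k)
    return out, NormalizationSpec(mu=mu, sigma=sigma, clip_k=clip_k)


def discretize_fbs(
    intensities: np.ndarray, mask: VOIMask, spec: DiscretizationSpec
) -> DiscreteVOI:
    """Fixed-bin-size gray levels: ceil((I - I_min)/B), level 1 at I = I_min."""
    if spec.B <= 0:
        raise ValueError("bin width must be positive")
    vals = intensities[mask.mask]
    if vals.size == 0:
        raise DegenerateVOIError("empty mask")
    imin = vals.min()
    q = (vals - imin) / spec.B
    if spec.ibsi_strict:
        lev = np.floor(q).astype(np.int64) + 1
    else:
        lev = np.maximum(np.ceil(q).astype(np.int64), 1)
    levels = np.zeros(intensities.shape, dtype=np.int64)
    levels[mask.mask] = lev
    return DiscreteVOI(levels=levels, mask=mask.mask,
                       n_levels=int(lev.max()), spec=spec)


def discretize_fbn(
    intensities: np.ndarray, mask: VOIMask, spec: DiscretizationSpec
) -> DiscreteVOI:
    """Fixed-bin-number gray levels: 1 at I_min, else ceil(D (I-I_min)/(I_max-I_min))."""
    if spec.D < 2:
        raise ValueError("bin number must be >= 2")
    vals = intensities[mask.mask]
    if vals.size == 0:
        raise DegenerateVOIError("empty mask")
    imin, imax = vals.min(), vals.max()
    if imax == imin:
        warnings.warn("constant VOI: all gray levels set to 1", RuntimeWarning)
        lev = np.ones(vals.shape, dtype=np.int64)
    else:
        lev = np.ceil(spec.D * (vals - imin) / (imax - imin)).astype(np.int64)
        lev[vals == imin] = 1
        lev = np.clip(lev, 1, spec.D)
    levels = np.zeros(intensities.shape, dtype=np.int64)
    levels[mask.mask] = lev
    return DiscreteVOI(levels=levels, mask=mask.mask, n_levels=int(lev.max()),
                       spec=spec)


def discretize(
    intensities: np.ndarray, mask: VOIMask, spec: DiscretizationSpec
) -> DiscreteVOI:
    if spec.method == "FBS":
        return discretize_fbs(intensities, mask, spec)
    if spec.method == "FBN":
        return discretize_fbn(intensities, mask, spec)
    raise ValueError(f"unknown discretization method {spec.method!r}")
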