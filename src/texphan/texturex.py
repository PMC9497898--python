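"""Gray-level texture matrices (GLCM, GLRLM, GLSZM) and the 45-feature vector.

All three matrix families are computed in 3D on integer gray levels 1..G:

* GLCM: symmetric co-occurrences at Chebyshev distance 1 over the 13 unique
  3D direction offsets, probability-normalized and feature-averaged per
  direction (the common "averaging" aggregation).
* GLRLM: maximal collinear same-level runs per direction, same 13 offsets.
* GLSZM: maximal 26-connected same-level zones, a single matrix.

Feature definitions follow the standard formulations; logarithms are base 2
(entropies in bits). A constant VOI is a legitimate input and returns the
analytic limits (entropy 0, Energy 1, Contrast 0, ...) rather than an error.

The vector also carries five first-order statistics (min, max, mean, median,
voxel count) taken from the pre-discretization intensities, for 45 features
in total: 18 GLCM + 11 GLRLM + 11 GLSZM + 5 histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .voiprep import DiscreteVOI, DiscretizationSpec, VOIMask, discretize, normalize_mu3sigma
from .virtual_mr import MRVolume

__all__ = [
    "DIRECTIONS_3D",
    "TextureMatrix",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "compute_glszm",
    "glszm_features",
    "histogram_stats",
    "extract_all",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "HIST_NAMES",
    "ALL_FEATURE_NAMES",
    "FEATURE_FAMILY",
]

# the 13 unique direction offsets of a 26-neighborhood (one per +/- pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

GLCM_NAMES = [
    "Jmax", "JointAverage", "JointVariance", "JointEntropy",
    "DifferenceAverage", "DifferenceVariance", "DifferenceEntropy",
    "SumAverage", "SumVariance", "SumEntropy", "Energy", "Contrast",
    "Dissimilarity", "Homogeneity", "InverseDifferenceMoment", "Correlation",
    "ClusterShade", "ClusterProminence",
]
GLRLM_NAMES = ["SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE", "SRLGE",
               "SRHGE", "LRLGE", "LRHGE"]
GLSZM_NAMES = ["SAE", "LZE", "GLN_z", "ZSN", "ZP", "LGZE", "HGZE", "SZLGE",
               "SZHGE", "LZLGE", "LZHGE"]
HIST_NAMES = ["min", "max", "mean", "median", "voxel_count"]
ALL_FEATURE_NAMES = GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + HIST_NAMES
assert len(ALL_FEATURE_NAMES) == 45

FEATURE_FAMILY = {
    **{n: "GLCM" for n in GLCM_NAMES},
    **{n: "GLRLM" for n in GLRLM_NAMES},
    **{n: "GLSZM" for n in GLSZM_NAMES},
    **{n: "Histogram" for n in HIST_NAMES},
}


@dataclass
class TextureMatrix:
    kind: str  # "GLCM" | "GLRLM" | "GLSZM"
    matrices: list[np.ndarray]  # one per direction (GLSZM: a single matrix)
    directions: list[tuple[int, int, int]] | None
    n_voxels: int
    normalized: bool = False


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    lv = np.where(mask[sl], levels[sl], 0)
    return lv


def compute_glcm(dvoi: DiscreteVOI, distance: int = 1,
                 directions=DIRECTIONS_3D, symmetric: bool = True) -> TextureMatrix:
    """Per-direction symmetric co-occurrence counts over in-mask voxel pairs."""
    lv = _crop_to_mask(dvoi.levels, dvoi.mask)
    if lv.max() == 0:
        raise ValueError("empty mask")
    G = dvoi.n_levels
    nvox = int((lv > 0).sum())
    mats = []
    for d in directions:
        off = tuple(distance * c for c in d)
        sl_a, sl_b = [], []
        for o, s in zip(off, lv.shape):
            if o >= 0:
                sl_a.append(slice(0, s - o))
                sl_b.append(slice(o, s))
            else:
                sl_a.append(slice(-o, s))
                sl_b.append(slice(0, s + o))
        a = lv[tuple(sl_a)].ravel()
        b = lv[tuple(sl_b)].ravel()
        valid = (a > 0) & (b > 0)
        counts = np.zeros((G, G), dtype=np.int64)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
        if symmetric:
            counts = counts + counts.T
        mats.append(counts)
    return TextureMatrix("GLCM", mats, list(directions), nvox)


def normalize_matrix(m: TextureMatrix) -> TextureMatrix:
    out = []
    for c in m.matrices:
        s = c.sum()
        out.append(c / s if s > 0 else c.astype(float))
    return TextureMatrix(m.kind, out, m.directions, m.n_voxels, normalized=True)


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    G = p.shape[0]
    i = np.arange(1, G + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    nz = p > 0
    pnz = p[nz]
    mu = float((ii * p).sum())  # marginal mean (symmetric matrix)
    var = float(((ii - mu) ** 2 * p).sum())
    k_diff = np.arange(G)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * G + 1)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    pd_nz = p_diff[p_diff > 0]
    ps_nz = p_sum[p_sum > 0]
    corr = 1.0 if var == 0 else float(
        (((ii - mu) * (jj - mu) * p).sum()) / var)
    return {
        "Jmax": float(p.max()),
        "JointAverage": mu,
        "JointVariance": var,
        "JointEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "DifferenceAverage": da,
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "DifferenceEntropy": float(-(pd_nz * np.log2(pd_nz)).sum()),
        "SumAverage": sa,
        "SumVariance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "SumEntropy": float(-(ps_nz * np.log2(ps_nz)).sum()),
        "Energy": float((p ** 2).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Homogeneity": float((p / (1 + np.abs(ii - jj))).sum()),
        "InverseDifferenceMoment": float((p / (1 + (ii - jj) ** 2)).sum()),
        "Correlation": corr,
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
    }


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    """The 18 co-occurrence features, computed per direction then averaged."""
    if not m.normalized:
        m = normalize_matrix(m)
    per_dir = [_glcm_features_single(p) for p in m.matrices if p.sum() > 0]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# --------------------------------------------------------------------------
# Run-length matrix
# --------------------------------------------------------------------------

def _runs_for_direction(lv: np.ndarray, d) -> tuple[np.ndarray, np.ndarray]:
    """Levels and lengths of all maximal runs along direction ``d``.

    Lines are gathered for every start voxel (one whose predecessor along
    ``-d`` falls outside the grid), concatenated with zero separators, and
    run-length encoded in one pass. Level 0 (outside mask) breaks runs and is
    not itself a run.
    """
    shape = np.array(lv.shape)
    d = np.array(d)
    idx = np.indices(lv.shape).reshape(3, -1).T
    prev = idx - d
    is_start = ((prev < 0) | (prev >= shape)).any(axis=1)
    starts = idx[is_start]
    lmax = int(min(
        (shape[k] if d[k] != 0 else np.inf) for k in range(3)))
    t = np.arange(lmax)
    pos = starts[:, None, :] + t[None, :, None] * d  # (S, L, 3)
    inb = ((pos >= 0) & (pos < shape)).all(axis=2)
    vals = np.zeros(pos.shape[:2], dtype=np.int64)
    p = pos[inb]
    vals[inb] = lv[p[:, 0], p[:, 1], p[:, 2]]
    flat = np.concatenate(
        [vals, np.zeros((len(starts), 1), dtype=np.int64)], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    bounds = np.concatenate(([0], change + 1, [len(flat)]))
    lens = np.diff(bounds)
    levs = flat[bounds[:-1]]
    keep = levs > 0
    return levs[keep], lens[keep]


def compute_glrlm(dvoi: DiscreteVOI, directions=DIRECTIONS_3D) -> TextureMatrix:
    """Per-direction maximal-run counts; run-length-weighted sums = voxel count."""
    lv = _crop_to_mask(dvoi.levels, dvoi.mask)
    if lv.max() == 0:
        raise ValueError("empty mask")
    G = dvoi.n_levels
    nvox = int((lv > 0).sum())
    lmax_all = max(lv.shape)
    mats = []
    for d in directions:
        levs, lens = _runs_for_direction(lv, d)
        counts = np.zeros((G, lmax_all), dtype=np.int64)
        np.add.at(counts, (levs - 1, lens - 1), 1)
        mats.append(counts)
    return TextureMatrix("GLRLM", mats, list(directions), nvox)


def _rlm_style_features(counts: np.ndarray, n_voxels: int, names) -> dict[str, float]:
    ns = counts.sum()
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    p = counts / ns
    vals = [
        float((p / j ** 2).sum()),          # short runs/zones emphasis
        float((p * j ** 2).sum()),          # long runs/zones emphasis
        float((counts.sum(axis=1) ** 2).sum() / ns),  # gray-level non-uniformity
        float((counts.sum(axis=0) ** 2).sum() / ns),  # length/size non-uniformity
        float(ns / n_voxels),               # run/zone percentage
        float((p / i ** 2).sum()),
        float((p * i ** 2).sum()),
        float((p / (i ** 2 * j ** 2)).sum()),
        float((p * i ** 2 / j ** 2).sum()),
        float((p * j ** 2 / i ** 2).sum()),
        float((p * i ** 2 * j ** 2).sum()),
    ]
    return dict(zip(names, vals))


def glrlm_features(m: TextureMatrix) -> dict[str, float]:
    """The 11 run-length features, averaged over the 13 directions."""
    per_dir = [_rlm_style_features(c, m.n_voxels, GLRLM_NAMES)
               for c in m.matrices if c.sum() > 0]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# --------------------------------------------------------------------------
# Size-zone matrix
# --------------------------------------------------------------------------

def compute_glszm(dvoi: DiscreteVOI, connectivity: int = 26) -> TextureMatrix:
    """Zones are maximal 26-connected same-level components (single matrix)."""
    from scipy.ndimage import label

    lv = _crop_to_mask(dvoi.levels, dvoi.mask)
    if lv.max() == 0:
        raise ValueError("empty mask")
    G = dvoi.n_levels
    nvox = int((lv > 0).sum())
    structure = np.ones((3, 3, 3), dtype=bool) if connectivity == 26 else None
    zones = []  # (level, size)
    for g in range(1, G + 1):
        binary = lv == g
        if not binary.any():
            continue
        lab, nc = label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    counts = np.zeros((G, max_size), dtype=np.int64)
    for g, s in zones:
        counts[g - 1, s - 1] += 1
    return TextureMatrix("GLSZM", [counts], None, nvox)


def glszm_features(m: TextureMatrix) -> dict[str, float]:
    """The 11 size-zone features from the single zone matrix."""
    return _rlm_style_features(m.matrices[0], m.n_voxels, GLSZM_NAMES)


# --------------------------------------------------------------------------
# First-order statistics and the full vector
# --------------------------------------------------------------------------

def histogram_stats(intensities: np.ndarray, mask: VOIMask) -> dict[str, float]:
    """min/max/mean/median over masked (pre-discretization) intensities + count."""
    vals = intensities[mask.mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "voxel_count": float(vals.size),
    }


def extract_all(
    volume: MRVolume,
    mask: VOIMask,
    discretization: str = "FBS",
    normalize: bool = True,
) -> dict[str, float]:
    """Run the full chain: optional normalization, discretization, 45 features.

    ``discretization`` follows the acquisition setup ("FBS" uses bin width
    0.15 on normalized / 50 on raw intensities; "FBN" uses 64 bins).
    """
    if normalize:
        intens, _ = normalize_mu3sigma(volume, mask)
    else:
        intens = volume.intensities.astype(np.float64)
    spec = DiscretizationSpec.for_setup(discretization, normalized=normalize)
    dvoi = discretize(intens, mask, spec)
    out: dict[str, float] = {}
    out.update(glcm_features(compute_glcm(dvoi)))
    out.update(glrlm_features(compute_glrlm(dvoi)))
    out.update(glszm_features(compute_glszm(dvoi)))
    out.update(histogram_stats(intens, mask))
    assert len(out) == 45
    return out
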