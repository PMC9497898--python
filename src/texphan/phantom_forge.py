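"""Ground-truth voxel phantoms: QR cubes, a Hilbert cube, and biological look-alikes.

Phantoms are labeled 3D grids at a fine isotropic pitch (default 0.25 mm), the
digital equivalent of the two-material fillable objects used in MR radiomics
repeatability studies: white plastic prints (signal-void) immersed in a dilute
NiCl2 solution (bright on T1 and T2).

Grid axis convention: ``labels[x, y, z]`` with world position = index * pitch.
Coronal planes are fixed-``y`` slices; the QR module pattern lives in the
(x, z) plane and is extruded along ``y``, so every coronal slice through the
code region shows the full symbol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import qrcodec

__all__ = [
    "LABEL_AIR",
    "LABEL_PLASTIC",
    "LABEL_SOLUTION",
    "VoxelPhantom",
    "make_qr_phantom",
    "make_hilbert_phantom",
    "make_bio_phantom",
    "rotate_phantom",
    "hilbert_curve_3d",
    "save_phantom",
    "load_phantom",
]

LABEL_AIR = 0
LABEL_PLASTIC = 1
LABEL_SOLUTION = 2
# labels >= 3 are kind-specific tissue classes of the biological phantoms

DEFAULT_PITCH_MM = 0.25
WALL_MM = 2.0  # container wall thickness
QUIET_MODULES = 2  # solution-filled quiet zone inside the container


class PhantomResolutionError(ValueError):
    """Ground-truth pitch too coarse for the requested structure."""


class PhantomGeometryError(ValueError):
    """Requested structure does not fit the container."""


@dataclass
class VoxelPhantom:
    """A labeled material grid plus optional within-class modulation field."""

    name: str
    labels: np.ndarray  # int8/int16, axes (x, y, z)
    pitch_mm: float
    payload: str | None = None
    rng_seed: int | None = None
    modulation: np.ndarray | None = None  # multiplicative, same shape, ~1
    meta: dict = field(default_factory=dict)

    @property
    def dims_mm(self) -> tuple[float, float, float]:
        return tuple(s * self.pitch_mm for s in self.labels.shape)

    def label_set(self) -> set[int]:
        return set(np.unique(self.labels).tolist())


def _grid_shape(dims_mm, pitch_mm):
    return tuple(int(round(d / pitch_mm)) for d in dims_mm)


def _container(shape, pitch_mm, wall_mm=WALL_MM):
    """Plastic box filled with solution."""
    labels = np.full(shape, LABEL_SOLUTION, dtype=np.int16)
    w = max(1, int(round(wall_mm / pitch_mm)))
    labels[:w, :, :] = LABEL_PLASTIC
    labels[-w:, :, :] = LABEL_PLASTIC
    labels[:, :w, :] = LABEL_PLASTIC
    labels[:, -w:, :] = LABEL_PLASTIC
    labels[:, :, :w] = LABEL_PLASTIC
    labels[:, :, -w:] = LABEL_PLASTIC
    return labels, w


def make_qr_phantom(
    text: str,
    outer_dims_mm: tuple[float, float, float] = (50.0, 50.0, 40.0),
    code_height_mm: float = 30.0,
    pitch_mm: float = DEFAULT_PITCH_MM,
    name: str | None = None,
) -> VoxelPhantom:
    """Build a fillable QR-code container phantom.

    ``outer_dims_mm`` is (in-plane width, in-plane width, extrusion height):
    the QR pattern spans the first and second extents in the (x, z) plane and
    is extruded as plastic columns along y to ``code_height_mm``. Module size
    is set by the interior width divided by (modules + 2 * quiet modules), so
    a 29-module symbol in a 50 mm container yields ~1.39 mm modules.
    """
    if not text:
        raise ValueError("payload text must be non-empty")
    wx, wz, height = outer_dims_mm
    if code_height_mm >= height:
        raise PhantomGeometryError("code height must be below the outer height")
    mods = qrcodec.encode_text(text)  # raises QRCapacityError if too long
    n = mods.shape[0]
    interior = min(wx, wz) - 2 * WALL_MM
    module_mm = interior / (n + 2 * QUIET_MODULES)
    if module_mm < 2 * pitch_mm:
        raise PhantomResolutionError(
            f"pitch {pitch_mm} mm too coarse for {module_mm:.2f} mm modules")
    shape = _grid_shape((wx, height, wz), pitch_mm)
    labels, w = _container(shape, pitch_mm)

    # module (i, j) of the symbol -> rows i along z (top of symbol at high z),
    # columns j along +x; dark modules become plastic columns
    x0 = (shape[0] * pitch_mm - n * module_mm) / 2.0
    z0 = (shape[2] * pitch_mm - n * module_mm) / 2.0
    xs = (np.arange(shape[0]) + 0.5) * pitch_mm
    zs = (np.arange(shape[2]) + 0.5) * pitch_mm
    jj = np.floor((xs - x0) / module_mm).astype(int)
    ii = np.floor((zs[::-1] - z0) / module_mm).astype(int)  # symbol row 0 at top
    valid_x = (jj >= 0) & (jj < n)
    valid_z = (ii >= 0) & (ii < n)
    pattern = np.zeros((shape[0], shape[2]), dtype=bool)
    sub = mods[np.clip(ii, 0, n - 1)][:, np.clip(jj, 0, n - 1)]  # (z, x)
    pattern[np.ix_(valid_x, valid_z)] = sub.T[np.ix_(valid_x, valid_z)]
    y_top = w + int(round(code_height_mm / pitch_mm))
    y_top = min(y_top, shape[1] - w)
    region = labels[:, w:y_top, :]
    region[pattern[:, None, :] & (region == LABEL_SOLUTION)] = LABEL_PLASTIC
    phantom = VoxelPhantom(
        name=name or f"qr_{int(min(wx, wz))}mm",
        labels=labels,
        pitch_mm=pitch_mm,
        payload=text,
        meta={
            "modules": n,
            "module_mm": module_mm,
            "code_height_mm": code_height_mm,
            "code_y_range_mm": (w * pitch_mm, y_top * pitch_mm),
        },
    )
    return phantom


def large_qr_phantom(pitch_mm: float = DEFAULT_PITCH_MM) -> VoxelPhantom:
    """The 5x5x4 cm^3 QR container with a 3 cm code height."""
    return make_qr_phantom(
        "UNIDEB MRI Texture Analysis Phantom", (50.0, 50.0, 40.0), 30.0,
        pitch_mm, name="largeQR")


def small_qr_phantom(pitch_mm: float = DEFAULT_PITCH_MM) -> VoxelPhantom:
    """The 4x4x3 cm^3 QR container with a 2 cm code height."""
    return make_qr_phantom(
        "UNIDEB MRI Texture Analysis Phantom", (40.0, 40.0, 30.0), 20.0,
        pitch_mm, name="smallQR")


# --------------------------------------------------------------------------
# Hilbert cube
# --------------------------------------------------------------------------

def hilbert_curve_3d(level: int) -> np.ndarray:
    """Cell centers of the 3D Hilbert curve at the given recursion level.

    Returns an array of shape (8**level, 3) of integer lattice coordinates in
    a (2**level)^3 grid; consecutive entries are face-adjacent (unit steps).
    Uses the Gray-code transpose construction (Skilling 2004).
    """
    if level < 1:
        raise ValueError("recursion level must be >= 1")
    ncells = 8 ** level
    coords = np.empty((ncells, 3), dtype=np.int64)
    b = level
    for h in range(ncells):
        # distribute the index bits over the 3 transposed axes (MSB first)
        x = [0, 0, 0]
        for bit in range(3 * b):
            axis = bit % 3
            x[axis] |= ((h >> (3 * b - 1 - bit)) & 1) << (b - 1 - bit // 3)
        # undo the skew (inverse of the transpose encoding)
        n = 2 << (b - 1)
        t = x[2] >> 1
        for i in range(2, 0, -1):
            x[i] ^= x[i - 1]
        x[0] ^= t
        q = 2
        while q != n:
            p = q - 1
            for i in range(2, -1, -1):
                if x[i] & q:
                    x[0] ^= p
                else:
                    t = (x[0] ^ x[i]) & p
                    x[0] ^= t
                    x[i] ^= t
            q <<= 1
        coords[h] = x
    return coords


def make_hilbert_phantom(
    outer_dims_mm: tuple[float, float, float] = (50.0, 50.0, 50.0),
    recursion_level: int = 2,
    pipe_width_mm: float = 5.0,
    pitch_mm: float = DEFAULT_PITCH_MM,
    face_tile_mm: float = 5.0,
    name: str = "Hilbert",
) -> VoxelPhantom:
    """Plastic square-section pipe along the 3D Hilbert curve, in solution.

    The outer faces additionally carry an alternating plastic/air rectangle
    pattern (a three-dimensional chessboard-like shell), tile size
    ``face_tile_mm``.
    """
    if recursion_level < 1:
        raise ValueError("recursion level must be >= 1")
    if pipe_width_mm < 2 * pitch_mm:
        raise PhantomResolutionError("pipe thinner than two ground-truth voxels")
    shape = _grid_shape(outer_dims_mm, pitch_mm)
    labels, w = _container(shape, pitch_mm)
    side = 2 ** recursion_level
    interior_mm = min(outer_dims_mm) - 2 * WALL_MM
    cell_mm = interior_mm / side
    if pipe_width_mm >= cell_mm:
        raise PhantomGeometryError(
            f"pipe width {pipe_width_mm} mm exceeds curve cell size {cell_mm:.2f} mm")
    path = hilbert_curve_3d(recursion_level)
    centers = (path + 0.5) * cell_mm + WALL_MM  # mm
    half = pipe_width_mm / 2.0

    def fill_segment(p, q):
        lo = np.minimum(p, q) - half
        hi = np.maximum(p, q) + half
        sl = tuple(
            slice(max(0, int(np.floor(l / pitch_mm))),
                  min(s, int(np.ceil(h / pitch_mm))))
            for l, h, s in zip(lo, hi, shape)
        )
        labels[sl] = LABEL_PLASTIC

    for a, b_ in zip(centers[:-1], centers[1:]):
        fill_segment(a, b_)
    fill_segment(centers[0], centers[0])
    # chessboard face pattern: carve air tiles out of the plastic wall shell
    tile = max(1, int(round(face_tile_mm / pitch_mm)))
    idx = [np.arange(s) // tile for s in shape]
    parity = (
        idx[0][:, None, None] + idx[1][None, :, None] + idx[2][None, None, :]
    ) % 2 == 1
    shell = np.zeros(shape, dtype=bool)
    shell[:w, :, :] = shell[-w:, :, :] = True
    shell[:, :w, :] = shell[:, -w:, :] = True
    shell[:, :, :w] = shell[:, :, -w:] = True
    labels[shell & parity & (labels == LABEL_PLASTIC)] = LABEL_AIR
    return VoxelPhantom(
        name=name,
        labels=labels,
        pitch_mm=pitch_mm,
        meta={
            "recursion_level": recursion_level,
            "cell_mm": cell_mm,
            "pipe_width_mm": pipe_width_mm,
        },
    )


# --------------------------------------------------------------------------
# Biological phantoms
# --------------------------------------------------------------------------

BIO_DEFAULTS = {
    # per-kind structural parameters; purely generative conventions chosen to
    # resemble MR appearance of the produce (shells, seeds, locules)
    "kiwi": {"core_frac": 0.22, "seed_density": 4e-4, "striation_count": 24},
    "tomato": {"locules": 4, "seed_cluster_frac": 0.5},
    "onion": {"shell_period_mm": 3.0},
}


def make_bio_phantom(
    kind: str,
    dims_mm: tuple[float, float, float],
    rng_seed: int,
    pitch_mm: float = 2 * DEFAULT_PITCH_MM,
    name: str | None = None,
) -> VoxelPhantom:
    """Procedural fruit/vegetable look-alike with >= 3 tissue classes.

    kiwi: bright flesh + pale core + radial striations + dark seeds in an
    annulus; tomato: pericarp + locule wedges with seed clusters; onion:
    concentric shells. A smooth random modulation field (~N(1, 0.1), 6 mm
    correlation length) provides continuous within-class texture.
    """
    if kind not in BIO_DEFAULTS:
        raise ValueError(f"unknown biological phantom kind {kind!r}")
    if max(dims_mm) > 50.0 + 1e-9:
        raise PhantomGeometryError("biological phantoms must fit in 5x5x5 cm^3")
    rng = np.random.default_rng(rng_seed)
    shape = _grid_shape(dims_mm, pitch_mm)
    labels = np.zeros(shape, dtype=np.int16)
    ax = [(np.arange(s) + 0.5) * pitch_mm - d / 2.0 for s, d in zip(shape, dims_mm)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    semi = np.array(dims_mm) / 2.0 * 0.92
    r2 = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2
    body = r2 <= 1.0
    r = np.sqrt(r2)
    theta = np.arctan2(Z, X)

    params = BIO_DEFAULTS[kind]
    if kind == "kiwi":
        labels[body] = 3  # flesh
        core = r <= params["core_frac"]
        labels[core & body] = 4
        stri = np.cos(theta * params["striation_count"]) > 0.82
        labels[body & stri & (r > params["core_frac"]) & (r < 0.85)] = 5
        annulus = body & (r > 0.35) & (r < 0.6)
        seeds = rng.random(shape) < params["seed_density"]
        seed_mask = annulus & seeds
        from scipy.ndimage import binary_dilation
        seed_mask = binary_dilation(seed_mask, iterations=2)
        labels[seed_mask & body] = 6
    elif kind == "tomato":
        labels[body] = 3  # pericarp
        wedge = (np.floor((theta + np.pi) / (2 * np.pi) * params["locules"])
                 % 2).astype(bool)
        inner = body & (r < 0.75)
        labels[inner & wedge] = 4  # locular gel
        clusters = inner & wedge & (r > 0.3) & (
            rng.random(shape) < 5e-4)
        from scipy.ndimage import binary_dilation
        labels[binary_dilation(clusters, iterations=3) & inner] = 5  # seeds
    else:  # onion
        period = params["shell_period_mm"]
        rad_mm = r * float(np.mean(semi))
        shell_idx = np.floor(rad_mm / period).astype(int)
        labels[body] = 3 + (shell_idx[body] % 2)
        labels[body & (r < 0.12)] = 5  # bud core

    # smooth multiplicative modulation field
    from scipy.ndimage import gaussian_filter
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=6.0 / pitch_mm)
    smooth /= max(smooth.std(), 1e-12)
    modulation = 1.0 + 0.10 * smooth
    return VoxelPhantom(
        name=name or f"{kind}_{rng_seed}",
        labels=labels,
        pitch_mm=pitch_mm,
        rng_seed=rng_seed,
        modulation=modulation,
        meta={"kind": kind},
    )


# --------------------------------------------------------------------------
# Rotation
# --------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def rotate_phantom(phantom: VoxelPhantom, axis: str, angle_deg: float) -> VoxelPhantom:
    """Rotate the label grid about a principal axis.

    Multiples of 90 degrees are exact index permutations; other angles use
    nearest-neighbor label resampling (labels are categorical).
    """
    ax = _AXIS_INDEX[axis]
    plane = tuple(i for i in range(3) if i != ax)
    k, rem = divmod(angle_deg % 360.0, 90.0)
    arrays = [phantom.labels] + (
        [phantom.modulation] if phantom.modulation is not None else [])
    if abs(rem) < 1e-9:
        rotated = [np.rot90(a, k=int(k), axes=plane) for a in arrays]
    else:
        from scipy.ndimage import rotate as nd_rotate
        rotated = [
            nd_rotate(a, angle_deg, axes=plane, reshape=True, order=0,
                      mode="constant", cval=LABEL_AIR if i == 0 else 1.0)
            for i, a in enumerate(arrays)
        ]
    out = VoxelPhantom(
        name=f"{phantom.name}_rot{axis}{angle_deg:g}",
        labels=rotated[0],
        pitch_mm=phantom.pitch_mm,
        payload=phantom.payload,
        rng_seed=phantom.rng_seed,
        modulation=rotated[1] if len(rotated) > 1 else None,
        meta=dict(phantom.meta),
    )
    return out


# --------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# --------------------------------------------------------------------------

def save_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write the label grid as an integer NIfTI plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([phantom.pitch_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(phantom.labels.astype(np.int16), affine), str(path))
    sidecar = {
        "name": phantom.name,
        "payload": phantom.payload,
        "pitch_mm": phantom.pitch_mm,
        "rng_seed": phantom.rng_seed,
        "labels": {"0": "air", "1": "plastic", "2": "solution"},
        "meta": phantom.meta,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))
    if phantom.modulation is not None:
        nib.save(nib.Nifti1Image(phantom.modulation.astype(np.float32), affine),
                 str(path.with_name(path.name.replace(".nii", "_mod.nii"))))


def load_phantom(path: str | Path) -> VoxelPhantom:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    mod_path = path.with_name(path.name.replace(".nii", "_mod.nii"))
    modulation = None
    if mod_path.exists():
        modulation = np.asarray(nib.load(str(mod_path)).dataobj, dtype=float)
    return VoxelPhantom(
        name=sidecar["name"],
        labels=np.asarray(img.dataobj, dtype=np.int16),
        pitch_mm=float(sidecar["pitch_mm"]),
        payload=sidecar.get("payload"),
        rng_seed=sidecar.get("rng_seed"),
        modulation=modulation,
        meta=sidecar.get("meta", {}),
    )
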