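"""Virtual MR scanner: contrast presets, PSF blur, partial volume, bias, Rician noise.

Sequence physics (TR/TE/NSA) is deliberately not simulated; what the texture
analysis sees is contrast, resolution and noise, so a material-to-intensity
preset per (label, weighting, field) stands in for the pulse sequence. The
acquisition chain per repetition:

1. Gaussian point-spread blur with FWHM equal to the acquired voxel size,
2. sub-voxel repositioning shift (the table moves between repetitions),
3. box-average downsampling onto the acquired grid (partial-volume model),
4. multiplicative smooth bias field (larger amplitude at 3 T),
5. Rician noise: magnitude of (signal + g1, g2), g ~ N(0, sigma) with
   sigma = fill-solution mean / SNR; the SNR preset scales linearly with the
   voxel volume (2 mm isotropic => 8x the 1 mm SNR).

Background air is Rayleigh-distributed under this model (mean/std = 1.91),
which the noise-recovery diagnostics exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift

from .phantom_forge import LABEL_AIR, LABEL_PLASTIC, LABEL_SOLUTION, VoxelPhantom

__all__ = [
    "AcquisitionSetup",
    "MRVolume",
    "ContrastModel",
    "enumerate_setups",
    "parse_setup_label",
    "assign_contrast",
    "acquire",
    "repeat_scan",
    "estimate_background_sigma",
    "save_volume",
    "load_volume",
]

_RAYLEIGH_MEAN_STD = float(np.sqrt(np.pi / 2) / np.sqrt(2 - np.pi / 2))  # ~1.9131


@dataclass(frozen=True)
class AcquisitionSetup:
    """One row of the acquisition matrix: field, weighting, coil, voxel, binning."""

    field_T: float
    weighting: str  # "T1" | "T2"
    channels: int
    voxel_mm: float
    discretization: str  # "FBS" | "FBN"

    def __post_init__(self):
        if self.field_T == 1.5 and self.channels != 6:
            raise ValueError("1.5 T acquisitions use the 6-channel coil")
        if self.field_T == 3.0 and self.channels not in (8, 32):
            raise ValueError("3 T acquisitions use 8- or 32-channel coils")

    @property
    def label(self) -> str:
        f = "1.5T" if self.field_T == 1.5 else "3T"
        v = f"{int(self.voxel_mm)}mm"
        return f"{f}_{self.weighting}_{self.channels}ch_{v}_{self.discretization}"

    @property
    def protocol_label(self) -> str:
        """Imaging-only identity (discretization ignored)."""
        f = "1.5T" if self.field_T == 1.5 else "3T"
        return f"{f}_{self.weighting}_{self.channels}ch_{int(self.voxel_mm)}mm"


def parse_setup_label(label: str) -> AcquisitionSetup:
    f, wgt, ch, vox, disc = label.split("_")
    return AcquisitionSetup(
        field_T=1.5 if f == "1.5T" else 3.0,
        weighting=wgt,
        channels=int(ch.removesuffix("ch")),
        voxel_mm=float(vox.removesuffix("mm")),
        discretization=disc,
    )


def enumerate_setups() -> list[AcquisitionSetup]:
    """The full 24-row acquisition matrix, in canonical table order.

    Order: T1 before T2; within a weighting: 1.5T/6ch, 3T/8ch, 3T/32ch; within
    a coil: 1 mm before 2 mm; within a voxel size: FBS before FBN.
    """
    setups = []
    for wgt in ("T1", "T2"):
        for field_T, channels in ((1.5, 6), (3.0, 8), (3.0, 32)):
            for voxel in (1.0, 2.0):
                for disc in ("FBS", "FBN"):
                    setups.append(AcquisitionSetup(field_T, wgt, channels,
                                                   voxel, disc))
    return setups


@dataclass
class MRVolume:
    """A simulated (or loaded) magnitude MR volume with voxel geometry."""

    intensities: np.ndarray  # (x, y, z), float, >= 0
    voxel_mm: float
    setup: AcquisitionSetup | None = None
    repetition_index: int = 1
    noise_seed: int | None = None
    provenance: str = ""
    meta: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Contrast and noise presets
# --------------------------------------------------------------------------

# mean signal per material label for each weighting; plastic and air are
# signal-poor, the NiCl2 solution bright; tissue classes span intermediate
# values. T2 presets give the printed phantoms lower contrast-to-noise, which
# is what degrades the T2 QR readability.
_DEFAULT_MEANS = {
    "T1": {LABEL_AIR: 0.0, LABEL_PLASTIC: 50.0, LABEL_SOLUTION: 1000.0,
           3: 650.0, 4: 850.0, 5: 400.0, 6: 150.0},
    "T2": {LABEL_AIR: 0.0, LABEL_PLASTIC: 250.0, LABEL_SOLUTION: 900.0,
           3: 700.0, 4: 500.0, 5: 850.0, 6: 200.0},
}

# SNR in the fill solution at 1 mm isotropic, per (field, channels)
_DEFAULT_SNR = {(1.5, 6): 18.0, (3.0, 8): 25.0, (3.0, 32): 35.0}

# peak-to-peak relative amplitude of the multiplicative bias field
_DEFAULT_BIAS = {1.5: 0.05, 3.0: 0.075}


@dataclass
class ContrastModel:
    """Material intensity means, SNR presets and bias amplitudes."""

    means: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MEANS.items()})
    snr_1mm: dict = field(default_factory=lambda: dict(_DEFAULT_SNR))
    bias_amplitude: dict = field(default_factory=lambda: dict(_DEFAULT_BIAS))
    shift_frac: float = 0.3  # repositioning shift, fraction of acquired voxel

    def mean_for(self, label: int, weighting: str) -> float:
        table = self.means[weighting]
        if label not in table:
            raise KeyError(f"no contrast entry for label {label} at {weighting}")
        return table[label]

    def snr(self, setup: AcquisitionSetup) -> float:
        base = self.snr_1mm[(setup.field_T, setup.channels)]
        return base * setup.voxel_mm ** 3  # SNR scales with voxel volume

    def sigma(self, setup: AcquisitionSetup) -> float:
        return self.means[setup.weighting][LABEL_SOLUTION] / self.snr(setup)


def assign_contrast(
    phantom: VoxelPhantom,
    model: ContrastModel | None = None,
    weighting: str = "T1",
    field_T: float = 1.5,
) -> np.ndarray:
    """Map the label grid to a continuous ground-truth intensity volume."""
    model = model or ContrastModel()
    labels = phantom.labels
    out = np.zeros(labels.shape, dtype=np.float64)
    for lab in phantom.label_set():
        out[labels == lab] = model.mean_for(int(lab), weighting)
    if phantom.modulation is not None:
        out = out * phantom.modulation
    return out


def _bias_field(shape, amplitude, rng):
    """Smooth multiplicative field 1 + a * f, f a low-order random surface."""
    coords = [np.linspace(-1, 1, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c = rng.standard_normal(7)
    f = (c[0] * X + c[1] * Y + c[2] * Z + c[3] * X * Y + c[4] * Y * Z
         + c[5] * X * Z + c[6] * (X ** 2 - Z ** 2))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + amplitude * f


def acquire(
    truth: np.ndarray,
    truth_pitch_mm: float,
    setup: AcquisitionSetup,
    noise_seed: int,
    model: ContrastModel | None = None,
    pad_mm: float = 10.0,
    provenance: str = "",
    repetition_index: int = 1,
) -> MRVolume:
    """Simulate one magnitude acquisition of a continuous ground-truth volume.

    ``pad_mm`` of air is added around the object so the field of view, like a
    real scan, contains signal-free background. Set ``model.shift_frac = 0``
    and SNR presets to ``inf`` for the noiseless limit.
    """
    model = model or ContrastModel()
    factor = setup.voxel_mm / truth_pitch_mm
    if abs(factor - round(factor)) > 1e-9 or factor < 2:
        raise ValueError(
            f"ground pitch {truth_pitch_mm} mm incompatible with "
            f"{setup.voxel_mm} mm voxels")
    factor = int(round(factor))
    rng = np.random.default_rng(noise_seed)

    pad_vox = int(round(pad_mm / truth_pitch_mm / factor)) * factor
    vol = np.pad(truth.astype(np.float64), pad_vox, mode="constant")
    # 1. PSF blur, FWHM = acquired voxel size
    sigma_mm = setup.voxel_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vol = gaussian_filter(vol, sigma=sigma_mm / truth_pitch_mm, mode="nearest")
    # 2. sub-voxel repositioning shift (in acquired-voxel units)
    if model.shift_frac > 0:
        shift_vox = rng.uniform(-model.shift_frac, model.shift_frac, size=3)
        vol = nd_shift(vol, shift_vox * factor, order=1, mode="nearest")
    # 3. box-average downsample
    trim = [s - s % factor for s in vol.shape]
    vol = vol[: trim[0], : trim[1], : trim[2]]
    new_shape = tuple(s // factor for s in trim)
    vol = vol.reshape(new_shape[0], factor, new_shape[1], factor,
                      new_shape[2], factor).mean(axis=(1, 3, 5))
    # 4. multiplicative bias field
    amp = model.bias_amplitude.get(setup.field_T, 0.0)
    if amp > 0:
        vol = vol * _bias_field(vol.shape, amp, rng)
    # 5. Rician noise
    sigma = model.sigma(setup)
    if np.isfinite(sigma) and sigma > 0:
        g1 = rng.normal(0.0, sigma, vol.shape)
        g2 = rng.normal(0.0, sigma, vol.shape)
        vol = np.hypot(vol + g1, g2)
    return MRVolume(
        intensities=vol,
        voxel_mm=setup.voxel_mm,
        setup=setup,
        repetition_index=repetition_index,
        noise_seed=noise_seed,
        provenance=provenance,
        meta={"pad_mm": pad_vox * truth_pitch_mm, "sigma": float(sigma)
              if np.isfinite(sigma) else None},
    )


def repeat_scan(
    phantom: VoxelPhantom,
    setup: AcquisitionSetup,
    n_rep: int = 3,
    base_seed: int = 0,
    model: ContrastModel | None = None,
    pad_mm: float = 10.0,
) -> list[MRVolume]:
    """``n_rep`` acquisitions differing only in noise and repositioning."""
    if n_rep < 2:
        raise ValueError("repeatability needs at least 2 repetitions")
    model = model or ContrastModel()
    truth = assign_contrast(phantom, model, setup.weighting, setup.field_T)
    seeds = np.random.SeedSequence(base_seed).spawn(n_rep)
    out = []
    for i, ss in enumerate(seeds):
        seed = int(ss.generate_state(1)[0] % (2 ** 31))
        out.append(acquire(truth, phantom.pitch_mm, setup, seed, model,
                           pad_mm=pad_mm, provenance=phantom.name,
                           repetition_index=i + 1))
    return out


def estimate_background_sigma(volumes: list[MRVolume], border_mm: float = 4.0) -> float:
    """Estimate the Gaussian noise level from signal-free background.

    Uses the Rayleigh relation E[|n|] = sigma * sqrt(pi/2) on voxels in the
    outermost ``border_mm`` shell of the field of view (air padding), pooled
    over all volumes.
    """
    vals = []
    for v in volumes:
        b = max(1, int(round(border_mm / v.voxel_mm)))
        arr = v.intensities
        shell = np.ones(arr.shape, dtype=bool)
        shell[b:-b, b:-b, b:-b] = False
        vals.append(arr[shell])
    pooled = np.concatenate(vals)
    return float(pooled.mean() / np.sqrt(np.pi / 2.0))


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def save_volume(vol: MRVolume, path: str | Path) -> None:
    import nibabel as nib

    path = Path(path)
    affine = np.diag([vol.voxel_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), affine)
    if vol.setup is not None:
        img.header["descrip"] = vol.setup.label.encode()[:79]
    nib.save(img, str(path))
    sidecar = {
        "setup": vol.setup.label if vol.setup else None,
        "voxel_mm": vol.voxel_mm,
        "repetition_index": vol.repetition_index,
        "noise_seed": vol.noise_seed,
        "provenance": vol.provenance,
        "meta": vol.meta,
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2))


def load_volume(path: str | Path) -> MRVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return MRVolume(
        intensities=np.asarray(img.dataobj, dtype=np.float64),
        voxel_mm=float(sidecar["voxel_mm"]),
        setup=parse_setup_label(sidecar["setup"]) if sidecar.get("setup") else None,
        repetition_index=sidecar.get("repetition_index", 1),
        noise_seed=sidecar.get("noise_seed"),
        provenance=sidecar.get("provenance", ""),
        meta=sidecar.get("meta", {}),
    )
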