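"""QR read-out from simulated scans: the texture-fidelity end point.

A successful machine read of the embedded QR code means the acquisition
preserved the high-frequency texture; the fraction of decodable coronal
slices (the reading ratio) and a per-decoder middle-slice success grid
quantify that. "Readers" are software decoder backends with different
binarization strategies (global Otsu vs. local adaptive), emulating the
reader-algorithm diversity of handheld devices.

Coronal slices are fixed-y planes of the (x, y, z) volume grid; each slice is
min-max windowed to 8-bit, optionally square-padded and Lanczos-resampled to
1024 x 1024 before decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import qrcodec
from .virtual_mr import MRVolume

__all__ = [
    "DECODERS",
    "SliceImage",
    "ReadoutReport",
    "export_coronal_slices",
    "interpolate_slice",
    "decode_slice",
    "reading_ratio",
    "middle_slice_grid",
]

#: registered decoder backends (id -> binarization strategy)
DECODERS: dict[str, str] = {
    "reader-otsu": "otsu",
    "reader-adaptive": "adaptive",
}

INTERP_SIZE = 1024


@dataclass
class SliceImage:
    pixels: np.ndarray  # uint8, (rows, cols)
    source: str
    slice_index: int
    variant: str = "original"  # "original" | "interpolated"


@dataclass
class ReadoutReport:
    """Per-slice outcomes plus Table-7-style middle-slice success counts."""

    outcomes: dict = field(default_factory=dict)  # (setup, decoder) -> successes
    n_rep: int = 3

    def as_grid(self):
        import pandas as pd

        rows = sorted({k[0] for k in self.outcomes})
        cols = sorted({k[1] for k in self.outcomes})
        return pd.DataFrame(
            [[f"{self.outcomes[(r, c)]}/{self.n_rep}" for c in cols] for r in rows],
            index=rows, columns=cols)


def window_to_uint8(plane: np.ndarray) -> np.ndarray:
    """Min-max window a 2D array to 8-bit; constant planes map to mid-gray."""
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        return np.full(plane.shape, 128, dtype=np.uint8)
    return np.round((plane - lo) / (hi - lo) * 255.0).astype(np.uint8)


def export_coronal_slices(volume: MRVolume) -> list[SliceImage]:
    """Every coronal (fixed-y) plane as an 8-bit image.

    The image row axis is -z (superior at the top) and the column axis is +x,
    matching how a scanner console would display the plane.
    """
    arr = volume.intensities
    out = []
    for y in range(arr.shape[1]):
        plane = arr[:, y, :]  # (x, z)
        img = window_to_uint8(plane.T[::-1, :])  # rows: -z, cols: +x
        out.append(SliceImage(img, volume.provenance or "volume", y))
    return out


def interpolate_slice(img: SliceImage) -> SliceImage:
    """Square-pad then Lanczos-resample to 1024 x 1024."""
    px = img.pixels
    side = max(px.shape)
    if px.shape != (side, side):
        canvas = np.zeros((side, side), dtype=np.uint8)
        r0 = (side - px.shape[0]) // 2
        c0 = (side - px.shape[1]) // 2
        canvas[r0:r0 + px.shape[0], c0:c0 + px.shape[1]] = px
        px = canvas
    big = Image.fromarray(px).resize((INTERP_SIZE, INTERP_SIZE), Image.LANCZOS)
    return SliceImage(np.asarray(big, dtype=np.uint8), img.source,
                      img.slice_index, variant="interpolated")


def decode_slice(img: SliceImage, decoder_id: str, payload: str) -> bool:
    """True iff the backend decodes the slice to exactly ``payload``."""
    if decoder_id not in DECODERS:
        raise KeyError(f"decoder {decoder_id!r} not registered")
    try:
        return qrcodec.decode_image(img.pixels, DECODERS[decoder_id]) == payload
    except qrcodec.QRDecodeError:
        return False


def reading_ratio(
    volume: MRVolume, payload: str, decoder_id: str, variant: str = "interpolated"
) -> float:
    """Percentage of coronal slices whose QR code decodes to the payload."""
    slices = export_coronal_slices(volume)
    if variant == "interpolated":
        slices = [interpolate_slice(s) for s in slices]
    hits = sum(decode_slice(s, decoder_id, payload) for s in slices)
    return 100.0 * hits / len(slices)


def middle_slice_grid(
    volumes_by_setup: dict[str, list[MRVolume]],
    payload: str,
    decoders=tuple(DECODERS),
    variant: str = "interpolated",
) -> ReadoutReport:
    """Successes out of n repetitions on the middle coronal slice.

    ``volumes_by_setup`` maps a setup label to its repeated volumes. The
    middle slice is index floor(N/2) (0-based). Layout follows the
    setup-by-reader success tables of phone read-out studies.
    """
    outcomes = {}
    n_rep = max(len(v) for v in volumes_by_setup.values())
    for setup_label, vols in volumes_by_setup.items():
        per_decoder = {d: 0 for d in decoders}
        for vol in vols:
            slices = export_coronal_slices(vol)
            mid = slices[len(slices) // 2]
            if variant == "interpolated":
                mid = interpolate_slice(mid)
            for d in decoders:
                per_decoder[d] += decode_slice(mid, d, payload)
        for d in decoders:
            outcomes[(setup_label, d)] = per_decoder[d]
    return ReadoutReport(outcomes=outcomes, n_rep=n_rep)
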