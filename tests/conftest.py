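import numpy as np
import pytest

from texphan import phantom_forge, virtual_mr
from texphan.voiprep import DiscreteVOI, DiscretizationSpec

PAYLOAD = "UNIDEB MRI Texture Analysis Phantom"


def make_discrete(arr) -> DiscreteVOI:
    """Wrap an integer array (level 0 = outside) as a DiscreteVOI."""
    arr = np.asarray(arr, dtype=np.int64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return DiscreteVOI(levels=arr, mask=arr > 0, n_levels=int(arr.max()),
                       spec=DiscretizationSpec("FBS"))


@pytest.fixture(scope="session")
def payload():
    return PAYLOAD


@pytest.fixture(scope="session")
def large_qr_coarse():
    """Large QR phantom at 0.5 mm pitch (test-economy grid)."""
    return phantom_forge.large_qr_phantom(pitch_mm=0.5)


@pytest.fixture(scope="session")
def small_qr_coarse():
    return phantom_forge.small_qr_phantom(pitch_mm=0.5)


@pytest.fixture(scope="session")
def t1_1mm_setup():
    return virtual_mr.parse_setup_label("1.5T_T1_6ch_1mm_FBS")


@pytest.fixture(scope="session")
def large_qr_scans(t1_1mm_setup):
    """Three repeated 1.5T/T1/1mm acquisitions of the large QR phantom.

    Full 0.25 mm ground-truth pitch: the QR read-out is sensitive to
    partial-volume fidelity, so the readability fixtures do not use the
    coarser test-economy grid.
    """
    phantom = phantom_forge.large_qr_phantom()
    return virtual_mr.repeat_scan(phantom, t1_1mm_setup, 3, base_seed=42)
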