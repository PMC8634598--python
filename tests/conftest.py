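import numpy as np
import pytest

from nmjquant import Calibration, ChannelImage, RegionMask


@pytest.fixture
def cal8() -> Calibration:
    return Calibration(pixel_size_um=1.0, bit_depth=8)


@pytest.fixture
def cal_hi() -> Calibration:
    """Fine calibration matching the synthetic fixture geometry."""
    return Calibration(pixel_size_um=0.1, bit_depth=8)


def img8(array, pixel_size_um: float = 1.0) -> ChannelImage:
    return ChannelImage(
        np.asarray(array, dtype=np.uint8), Calibration(pixel_size_um, 8)
    )


def mask_of(array) -> RegionMask:
    return RegionMask(np.asarray(array, dtype=bool))
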