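import numpy as np
import pytest

from vibmatch.records import (
    Channel,
    FrequencyPair,
    ModeClass,
    Peak,
    SpectrumRecord,
    TheoryLevel,
)
from vibmatch.synthetic import make_pair_database

REF_LEVEL = TheoryLevel("M06-2X-D3", "6-311++G(d,p)")


@pytest.fixture(scope="session")
def ref_level():
    return REF_LEVEL


@pytest.fixture(scope="session")
def synth_database():
    """Full-size synthetic pair database at the reference theory level."""
    return make_pair_database(levels=[REF_LEVEL], seed=12345)


@pytest.fixture
def simple_record():
    return SpectrumRecord(
        species="toy",
        conformer="A",
        peaks=(
            Peak(400.0, 2.0, fwhm=6.0, snr=10.0),
            Peak(1600.0, 4.0, fwhm=5.0, snr=8.0),
            Peak(3600.0, 1.0, fwhm=7.0, snr=12.0),
        ),
    )


@pytest.fixture
def computed_record():
    return SpectrumRecord(
        species="toy",
        conformer="calc",
        source="computed",
        theory=REF_LEVEL,
        peaks=(
            Peak(500.0, 1.0, channel=Channel.COMPUTED),
            Peak(1500.0, 0.5, channel=Channel.COMPUTED),
            Peak(3200.0, 0.8, channel=Channel.COMPUTED),
            Peak(3700.0, 0.3, channel=Channel.COMPUTED),
        ),
        metadata={"mode_classes": ("low", "mid", "CH_ring", "OH")},
    )


def make_pairs(nu_omega, mode_class=ModeClass.MID, intensities=None):
    """Helper: FrequencyPair list from (nu, omega) tuples."""
    if intensities is None:
        intensities = [1.0] * len(nu_omega)
    return [
        FrequencyPair(nu, om, intensity_exp=inten, mode_class=mode_class)
        for (nu, om), inten in zip(nu_omega, intensities)
    ]
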