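import numpy as np
import pytest
from hypothesis import settings

from mrkit import HarmonizedInstrument, InstrumentSet
from mrkit.datasets import load_pth_ad, load_vitd_ad

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pth_set() -> InstrumentSet:
    """The 5 serum-PTH instruments harmonized against Alzheimer's disease."""
    return load_pth_ad()


@pytest.fixture(scope="session")
def vitd_set() -> InstrumentSet:
    """The 7 serum-25OHD instruments (proxy applied, SD units converted)."""
    return load_vitd_ad()


def random_instrument_set(seed: int, n: int, sd_scale: float = 0.33) -> InstrumentSet:
    """A reproducible random instrument set in Table-scale magnitudes."""
    rng = np.random.default_rng(seed)
    return InstrumentSet(
        "random",
        sd_scale,
        tuple(
            HarmonizedInstrument(
                rsid=f"rs{j}",
                beta_exp=float(rng.uniform(0.01, 0.1)),
                se_exp=float(rng.uniform(0.002, 0.01)),
                beta_out=float(rng.normal(0, 0.05)),
                se_out=float(rng.uniform(0.01, 0.03)),
            )
            for j in range(n)
        ),
    )
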