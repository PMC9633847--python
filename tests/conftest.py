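import numpy as np
import pytest

from eosmap import ScanConfig
from eosmap.synthetic import SynthImageSpec, generate_wsi


@pytest.fixture(scope="session")
def small_cfg() -> ScanConfig:
    """Desk-scale scan geometry: 64-px HPF of 2x2 32-px sub-patches."""
    return ScanConfig(
        hpf_side_px=64,
        hpf_side_um=16.4,
        stride_px=16,
        subpatch_side_px=32,
        eos_min_area_px=20,
        bz_min_area_px=20,
    )


@pytest.fixture(scope="session")
def small_slide_factory():
    """Factory for small synthetic slides with radius-4 eosinophil disks."""

    def make(seed: int, *, width: int = 100, height: int = 100, n_eos: int = 4,
             tissue_fraction: float = 0.9, bz_band_fraction: float = 0.3):
        spec = SynthImageSpec(
            width_px=width,
            height_px=height,
            tissue_fraction=tissue_fraction,
            n_eos=n_eos,
            eos_radius_px=4,
            bz_band_fraction=bz_band_fraction,
            seed=seed,
        )
        return generate_wsi(spec)

    return make


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
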