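import math
from dataclasses import replace

import numpy as np
import pytest

from pettex import (
    DiscretizationConfig,
    PhantomSpec,
    SegmentationConfig,
    calibrate_adaptive_thresholds,
    generate_phantom,
)


def sphere_spec(volume_ml: float, sbr: float = 20.0, **kwargs) -> PhantomSpec:
    """Homogeneous sphere phantom spec of a given true volume."""
    r = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1 / 3)
    defaults = dict(tumor_radii_mm=(r, r, r), suv_peak=float(sbr),
                    target_sbr=float(sbr), heterogeneity_amp=0.0, noise_sd=0.0)
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def calibrated_config() -> SegmentationConfig:
    """Segmentation config with the adaptive law calibrated once per session."""
    coeffs = calibrate_adaptive_thresholds(
        [6.0, 12.0, 20.0, 32.0], [8.0, 15.0, 25.0, 40.0], blur_fwhm_mm=6.0
    )
    return replace(SegmentationConfig(), adaptive_coeffs=coeffs)


@pytest.fixture(scope="session")
def textured_phantom():
    """One heterogeneous ~20 ml phantom with its center seed point."""
    spec = sphere_spec(20.0, sbr=20.0, heterogeneity_amp=0.4, noise_sd=0.0, seed=7)
    vol = generate_phantom(spec)
    seed_point = tuple(int(round(c)) for c in spec.center)
    return vol, seed_point, spec


@pytest.fixture
def disc64() -> DiscretizationConfig:
    return DiscretizationConfig()


def random_dvoi(rng: np.random.Generator, shape=(3, 3, 3), n_levels: int = 6,
                mask_p: float = 0.8):
    """Random small discretized VOI (levels + mask) for oracle comparisons."""
    from pettex.texture import DiscretizedVOI

    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask.flat[rng.integers(0, mask.size)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedVOI(levels=levels, mask=mask, n_levels=n_levels,
                          spacing=(1.0, 1.0, 1.0))
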