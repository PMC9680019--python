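import numpy as np
import pytest

from thermocal.pls import CVConfig
from thermocal.preprocess import crop_range
from thermocal.spectra_core import SpectralAxis, SpectralDataset, SpectrumMeta
from thermocal.synthetic_data import (
    default_uv_config,
    generate_calibration_set,
    generate_validation_set,
    table1_design,
)
from thermocal.workflows import default_uv_variants, run_calibration_comparison

UV_RANGE = (218.0, 285.0)


def random_dataset(seed: int, n_spectra: int = 4, n_points: int = 10) -> SpectralDataset:
    """Small random but valid dataset for round-trip/property checks."""
    rng = np.random.default_rng(seed)
    axis = SpectralAxis(
        kind="wavelength_nm",
        values=np.sort(200 + 100 * rng.random(n_points)),
    )
    meta = [
        SpectrumMeta(
            sample_id=f"s{i % 3}",
            concentration=None if i == 0 else float(10 * rng.random()),
            temperature=float(rng.uniform(-10, 80)),
            time=float(i * 7.5),
            replicate=i + 1,
            role="calibration",
        )
        for i in range(n_spectra)
    ]
    X = rng.normal(size=(n_spectra, n_points)) * 10.0 ** float(rng.integers(-3, 3))
    return SpectralDataset(axis=axis, intensities=X, meta=meta)


@pytest.fixture(scope="session")
def lin_config():
    """Linearized, noise-free UV instrument (exactly rank-2 data)."""
    return default_uv_config(mode="linearized", noise_sd=0.0, n_replicates=1)


@pytest.fixture(scope="session")
def lin_cal(lin_config):
    return generate_calibration_set(table1_design(), lin_config, seed=0)


@pytest.fixture(scope="session")
def lin_lss_subset(lin_cal):
    """Three lower concentrations at all ten temperatures, UV range."""
    idx = [i for i, m in enumerate(lin_cal.meta) if m.concentration in (4.0, 8.0, 12.0)]
    return crop_range(lin_cal.subset(idx), *UV_RANGE)


@pytest.fixture(scope="session")
def realistic_report():
    """The default four-variant comparison at the standard seed."""
    cfg = default_uv_config()
    cal = generate_calibration_set(table1_design(), cfg, seed=0)
    val = generate_validation_set(cfg, seed=1)
    return run_calibration_comparison(cal, val, default_uv_variants(), CVConfig(seed=0))
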