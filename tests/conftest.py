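"""Shared fixtures.

The calibration and the two headline batched simulations are expensive
(minutes), so they are session-scoped and shared by every test that needs
the calibrated model.
"""

from dataclasses import replace

import numpy as np
import pytest

import surgesim as ss


@pytest.fixture(scope="session")
def raw_hospitals():
    return ss.load_hospitals()


@pytest.fixture(scope="session")
def imputed_hospitals(raw_hospitals):
    return ss.impute_missing(ss.place_hospitals(raw_hospitals))


@pytest.fixture(scope="session")
def facility_model():
    return ss.build_facility_model()


@pytest.fixture(scope="session")
def base_config():
    """Packaged default configuration (master seed 0)."""
    return ss.load_config()


@pytest.fixture(scope="session")
def calibration(base_config):
    """Two-anchor calibration run once per session."""
    return ss.calibrate(config=base_config)


@pytest.fixture(scope="session")
def calibrated_config(base_config, calibration):
    return replace(base_config, weights=calibration.weights)


@pytest.fixture(scope="session")
def batch_t0(calibrated_config):
    """50 runs x 20,000 agents at zero transfer."""
    return ss.run_batch(calibrated_config.at_dose(0.0))


@pytest.fixture(scope="session")
def batch_t280(calibrated_config):
    """50 runs x 20,000 agents at a 280,000 GNF transfer."""
    return ss.run_batch(calibrated_config.at_dose(280_000.0))


def toy_facilities(prices, xy=None, quality=None):
    """FacilityModel from a (J, 4) price array; NaN marks not-offered."""
    prices = np.asarray(prices, dtype=float)
    J = prices.shape[0]
    if xy is None:
        xy = np.column_stack([np.linspace(5, 55, J), np.full(J, 30.0)])
    if quality is None:
        quality = np.linspace(0.2, 1.0, J)
    return ss.FacilityModel(
        hospital_ids=tuple(f"T{i}" for i in range(J)),
        xy=np.asarray(xy, dtype=float),
        quality=np.asarray(quality, dtype=float),
        prices=prices,
        offered=~np.isnan(prices),
    )
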