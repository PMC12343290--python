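"""Shared fixtures: a fast small-grid scenario and the full-size study setup.

Expensive end-to-end runs (retention, feed/waste, thickness scan) are
session-scoped so multiple checks can read one simulation.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np
import pytest

import thermotrap as tt
from thermotrap.build import build

# the exponential-fitting scheme is uniformly stable; the Peclet report is
# informational and would otherwise flood the test logs
pytestmark = pytest.mark.filterwarnings("ignore:cell Peclet number")


@pytest.fixture(autouse=True)
def _quiet_peclet():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell Peclet number")
        yield


@pytest.fixture(scope="session")
def small_cfg():
    """Coarse-grid closed-trap scenario with a fixed (numeric) Soret coefficient."""
    cfg = tt.default_scenario("closed_accumulation")
    cfg["geometry"]["n_x"] = 16
    cfg["geometry"]["n_z"] = 60
    cfg["species"] = [
        {
            "name": "sfGFP",
            "role": "protein",
            "stokes_radius_nm": 2.4,
            "S_T_per_K": 0.02,
            "c0_uM": 1.0,
        }
    ]
    cfg["duration_h"] = 24.0
    return cfg


@pytest.fixture(scope="session")
def small_components(small_cfg):
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell Peclet number")
        return build(small_cfg)


@pytest.fixture(scope="session")
def default_cfg_calibrated():
    """Full-size study scenario with the 25-fold-calibrated reporter."""
    from thermotrap.scenarios import _resolve_calibrated

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell Peclet number")
        return _resolve_calibrated(tt.default_scenario("closed_accumulation"))


@pytest.fixture(scope="session")
def closed_accumulation_report(default_cfg_calibrated):
    from thermotrap.scenarios import run_closed_accumulation

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell Peclet number")
        return run_closed_accumulation(copy.deepcopy(default_cfg_calibrated))


@pytest.fixture(scope="session")
def retention_report():
    from thermotrap.scenarios import run_retention

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell Peclet number")
        return run_retention()


@pytest.fixture(scope="session")
def feed_waste_report():
    from thermotrap.scenarios import run_feed_waste

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="cell Peclet number")
        return run_feed_waste()


def exponential_state(geometry, k: float, species: str = "sfGFP"):
    """Analytic unit-mean exponential profile c(z~) = k e^{-k z~} / (1 - e^{-k}).

    Cell values are the exact cell averages of the continuous profile, so
    volume-weighted statistics can be compared against analytic integrals.
    """
    edges = np.linspace(0.0, 1.0, geometry.n_z + 1)
    cell_avg = (np.exp(-k * edges[:-1]) - np.exp(-k * edges[1:])) / (
        (1.0 - np.exp(-k)) * (edges[1] - edges[0])
    )
    grid = np.repeat(cell_avg[:, None], geometry.n_x, axis=1)
    return tt.TransportState(geometry, 0.0, {species: grid})
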