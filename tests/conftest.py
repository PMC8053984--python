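"""Shared fixtures: the default SDR model and small reusable panels."""

from __future__ import annotations

import pytest

import vitis_sdr as v


@pytest.fixture(scope="session")
def model():
    """Default SDR model: 145.5 kb span, 1,066 sex-linked sites."""
    return v.build_sdr_model()


@pytest.fixture(scope="session")
def small_model():
    """Reduced-site model for fast per-operation tests."""
    return v.build_sdr_model(
        {
            "n_sites_a": 30,
            "n_sites_c": 60,
            "n_sites_d": 40,
            "n_b_diagnostic": 12,
            "site_seed": 7,
        }
    )


@pytest.fixture(scope="session")
def wild_panel(model):
    """Error-free dioecious panel (females f/f, males M/f)."""
    return v.simulate_panel(model, {"f/f": 15, "M/f": 14}, seed=11)


@pytest.fixture(scope="session")
def mixed_panel(model):
    """Panel covering the six observed genotype classes, with noise."""
    return v.simulate_panel(
        model,
        {"f/f": 4, "M/f": 4, "H1/f": 3, "H2/f": 3, "H1/H1": 2, "H1/H2": 2},
        error_rate=0.005,
        missing_rate=0.02,
        seed=13,
    )
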