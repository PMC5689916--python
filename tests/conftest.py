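"""Shared fixtures: one medium-statistics MC run reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from seedchar.geometry import SeedModel
from seedchar.materials import default_table
from seedchar.tg43 import (
    TG43Dataset,
    anisotropy_function,
    dose_rate_constant,
    fit_radial_poly,
    radial_dose_function,
)
from seedchar.transport import air_kerma_strength, dose_rate_table

FULL_RADII = tuple(np.concatenate([[0.5, 0.7], np.arange(1.0, 10.01, 0.5)]))
FULL_ANGLES = tuple(np.arange(0.0, 180.01, 10.0))


@pytest.fixture(scope="session")
def xs():
    return default_table()


@pytest.fixture(scope="session")
def gms():
    return SeedModel()


@pytest.fixture(scope="session")
def water_tally(gms):
    """Water-phantom dose table for the default seed, 2e6 histories."""
    return dose_rate_table(
        gms, "water", FULL_RADII, FULL_ANGLES, histories=2_000_000,
        rng_seed=20170914,
    )


@pytest.fixture(scope="session")
def sk_run(gms):
    """Air-kerma strength in vacuum, 2e6 histories: (S_k/history, rel err)."""
    return air_kerma_strength(gms, histories=2_000_000, rng_seed=20170915)


@pytest.fixture(scope="session")
def mc_dataset(water_tally, sk_run, gms):
    """TG-43 dataset extracted from the session MC run."""
    sk, _ = sk_run
    g_table = radial_dose_function(water_tally, gms.marker_length)
    g_coeffs, _ = fit_radial_poly(g_table)
    return TG43Dataset(
        lambda_=dose_rate_constant(water_tally.value(1.0, 90.0), sk),
        active_length_cm=gms.marker_length,
        g_table=g_table,
        f_table=anisotropy_function(water_tally, gms.marker_length),
        g_coeffs=g_coeffs,
        provenance={"arm": "session fixture"},
    )
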