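"""Shared fixtures: chromophore library, probe, and synthetic cohorts.

The tiny cohort keeps unit tests fast; the desk cohort (all 19
specimens at reduced location counts) backs the end-to-end checks and
is generated once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from nervespec.chromophores import load_default_library
from nervespec.cohort import CohortConfig, generate_cohort
from nervespec.fitmodel import FitConfig, fit_dataset
from nervespec.optics import ProbeGeometry, TissueOpticalParams


@pytest.fixture(scope="session")
def lib():
    return load_default_library()


@pytest.fixture(scope="session")
def geom():
    return ProbeGeometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def midrange_params():
    return TissueOpticalParams(
        blood_fraction=0.012, sto2=0.55, beta_carotene=0.4,
        fat_fraction=0.3, water_fraction=0.4, collagen_fraction=0.15,
        s800=11.0, mie_slope=0.9, f_mie=0.7,
        vessel_diameter_mm=0.1, amplitude=1.0, offset=0.0,
    )


TINY_COUNTS = {
    "cervical": {"fascicular_nerve": 12, "muscle": 6,
                 "sliding_fat": 4, "subcutaneous_fat": 4},
    "forearm": {"fascicular_nerve": 6, "muscle": 4,
                "sliding_fat": 2, "subcutaneous_fat": 2},
}


def tiny_config(seed: int = 42, **kw) -> CohortConfig:
    defaults = dict(n_specimens=4, n_forearm_specimens=2,
                    counts={a: dict(c) for a, c in TINY_COUNTS.items()},
                    replicates_per_location=3, rng_seed=seed)
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_config())


@pytest.fixture(scope="session")
def desk_cohort():
    """Desk-profile cohort: 19 specimens, ~15 % of the study's
    per-class location counts, fixed seed."""
    return generate_cohort(CohortConfig.desk_profile(rng_seed=0))


@pytest.fixture(scope="session")
def desk_fit_table(desk_cohort):
    dataset, _ = desk_cohort
    return fit_dataset(dataset, config=FitConfig())
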