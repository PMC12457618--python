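"""Shared fixtures: grids, presets, and the reference synthetic cohorts.

The heaviest fixture (`cohort_fits`) fits the 10 + 10 reference cohort once
per session; several acceptance and recovery tests share it.
"""

from __future__ import annotations

import numpy as np
import pytest

from stomadry.dielectrics import FrequencyGrid
from stomadry.fitting import fit_drying_curve
from stomadry.model import LightSchedule, simulate_drying
from stomadry.synthetic import OST1_2, WILDTYPE, generate_drying_series

#: (preset, horizon_days, noise seeds) defining the reference cohorts: ten
#: wildtype plants over 12 days and ten mutants over 10 days at the default
#: 1 wt% measurement noise.
COHORT_SPEC = ((WILDTYPE, 12.0, tuple(range(1, 11))),
               (OST1_2, 10.0, tuple(range(11, 21))))


@pytest.fixture(scope="session")
def band_grid() -> FrequencyGrid:
    """Dense grid covering the 0.1-0.3 THz extraction band."""
    return FrequencyGrid(np.linspace(0.1, 0.3, 41))


@pytest.fixture(scope="session")
def schedule() -> LightSchedule:
    return LightSchedule()


@pytest.fixture(scope="session")
def wildtype_trajectory():
    """Noise-free wildtype forward run over 12 days with wt% mapping."""
    return simulate_drying(WILDTYPE.params, horizon_h=12 * 24.0,
                           m_dry=WILDTYPE.m_dry)


@pytest.fixture(scope="session")
def mutant_trajectory():
    return simulate_drying(OST1_2.params, horizon_h=10 * 24.0,
                           m_dry=OST1_2.m_dry)


@pytest.fixture(scope="session")
def cohort_fits():
    """Fits of the reference cohorts: {genotype: [(series, FitResult), ...]}."""
    out = {}
    for preset, horizon, seeds in COHORT_SPEC:
        pairs = []
        for seed in seeds:
            series = generate_drying_series(preset, seed=seed,
                                            horizon_days=horizon)
            pairs.append((series, fit_drying_curve(series)))
        out[preset.name] = pairs
    return out
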