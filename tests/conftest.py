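"""Shared fixtures: synthetic tables and the mid-risk analysis cohort.

The "analysis cohort" restricts baseline eGFR to 40-85 and age to 40-65:
the screening-relevant CKD G2-G3a region where crossing probabilities are
informative (away from the 0/1 tails), used by the stochastic
bisection-vs-Monte-Carlo and calibration checks.
"""

import numpy as np
import pytest

from ckdrisk.parameters import BandEntry, ParameterTable
from ckdrisk.synthetic_data import CohortSpec, TableSpec, generate_parameter_table


def make_flat_table(mu: float, sd: float) -> ParameterTable:
    """Single-band table: the same (mu, sd) at every age/eGFR/sex."""
    entries = {
        sex: [BandEntry(age_lo=0, age_hi=120, egfr_lo=0, egfr_hi=200, mu_base=mu, sd_base=sd)]
        for sex in ("male", "female")
    }
    return ParameterTable(entries)


@pytest.fixture(scope="session")
def default_table():
    return generate_parameter_table(TableSpec())


@pytest.fixture(scope="session")
def seeded_table():
    return generate_parameter_table(TableSpec(seed=42))


ANALYSIS_COHORT = CohortSpec(
    n=20,
    egfr_mean=60.0,
    egfr_sd=12.0,
    egfr_bounds=(40.0, 85.0),
    age_range=(40.0, 65.0),
    seed=123,
)


@pytest.fixture(scope="session")
def analysis_cohort_spec():
    return ANALYSIS_COHORT
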