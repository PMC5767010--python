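"""Shared fixtures: small synthetic cohorts and analysis matrices.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from bmaselect import (
    build_analysis_matrix,
    complete_case_filter,
    default_config,
    generate_cohort,
    null_config,
    tiny_config,
)
from bmaselect.cohort import default_predictor_specs


@pytest.fixture(scope="session")
def specs23():
    return default_predictor_specs()


@pytest.fixture(scope="session")
def specs10(specs23):
    return specs23[:10]


@pytest.fixture(scope="session")
def specs4(specs23):
    # includes two truly active markers (change in serum Cr at position 8 is
    # inside the first ten; here we take a small mixed slice)
    names = {"ntprobnp_plasma", "hfabp_plasma", "creatinine_serum_change", "il6_plasma"}
    return [s for s in specs23 if s.name in names]


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(default_config(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    cohort, _ = default_cohort
    filtered, _ = complete_case_filter(cohort)
    return build_analysis_matrix(filtered)


@pytest.fixture(scope="session")
def signal_matrix4(default_cohort, specs4):
    """Complete-case matrix on 4 candidates, two of them truly predictive."""
    cohort, _ = default_cohort
    filtered, _ = complete_case_filter(cohort, [s.name for s in specs4])
    return build_analysis_matrix(filtered, specs4)


@pytest.fixture(scope="session")
def null_matrix10(specs10):
    """Global-null cohort, first ten candidates, no missingness."""
    cohort, _ = generate_cohort(null_config(n=900, seed=21))
    return build_analysis_matrix(cohort, specs10)


@pytest.fixture(scope="session")
def tiny_matrix(specs4):
    """60-subject two-center cohort on 4 candidates (fast exact paths)."""
    cohort, _ = generate_cohort(tiny_config(seed=5))
    return build_analysis_matrix(cohort, specs4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
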