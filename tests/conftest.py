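"""Shared fixtures: published reference tables and small synthetic cohorts.

The 3x3 agreement matrices and the mRNA-cluster association counts are the
printed reference tables from the development cohort of the refined HER2
score; they serve as frozen oracles for the agreement and association
statistics.
"""

import numpy as np
import pytest

from her2refine.concordance import ConfusionMatrix3
from her2refine.synthetic import GeneratorConfig, generate_cohort

#: Interobserver cross-tabulation of the refined score (two observers).
INTEROBSERVER_COUNTS = [[128, 9, 0], [8, 122, 10], [0, 9, 77]]
#: Intra-observer cross-tabulation (same observer, 3-month washout).
INTRAOBSERVER_COUNTS = [[124, 11, 0], [12, 119, 13], [0, 10, 74]]

#: mRNA cluster (rows: low/high) x refined score counts (0, 1+, 2+).
MRNA_CLUSTER_COUNTS = {
    "0": [64, 51],
    "1+": [35, 84],
    "2+": [10, 64],
}


@pytest.fixture(scope="session")
def interobserver_matrix() -> ConfusionMatrix3:
    return ConfusionMatrix3.from_array(INTEROBSERVER_COUNTS)


@pytest.fixture(scope="session")
def intraobserver_matrix() -> ConfusionMatrix3:
    return ConfusionMatrix3.from_array(INTRAOBSERVER_COUNTS)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort (363 cases, fixed seed)."""
    return generate_cohort(GeneratorConfig(seed=20240901 % 1000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
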