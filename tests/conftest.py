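"""Shared fixtures: a small synthetic cohort reused across module tests.

The small cohort trades the study-scale conditions (47 sites, 50-100
replicates, 96-mm volumes) for speed: 8 patients, 5-8 replicates and
56-mm volumes.  Class-effect structure is the package default.
"""

import numpy as np
import pytest

import ramrad as rr

SMALL_COHORT_KWARGS = dict(
    n_patients=8,
    n_sites_total=None,
    sites_per_patient_range=(2, 4),
    n_replicates_range=(5, 8),
    volume_extent_mm=56.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return rr.SyntheticConfig(**SMALL_COHORT_KWARGS)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return rr.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """(FeatureTable, histology) extracted once from the small cohort."""
    return rr.extract_features(small_cohort)


@pytest.fixture(scope="session")
def table2_histology():
    """The published cohort's histology distribution as a table:
    23 benign, 3 GG1 (all HG<20%), 10 GG2 (3 of them HG<20%), 8 GG3, 3 GG4."""
    import pandas as pd

    rows = []
    spec_counts = [(0, 23, None), (1, 3, 10.0), (2, 3, 15.0), (2, 7, 40.0), (3, 8, 60.0), (4, 3, 95.0)]
    k = 0
    for gg, n, hg in spec_counts:
        for _ in range(n):
            rows.append(
                {
                    "patient_id": f"P{k % 18:02d}",
                    "isup_gg": gg,
                    "hg_percent": np.nan if hg is None else hg,
                }
            )
            k += 1
    return pd.DataFrame(rows, index=[f"S{i:02d}" for i in range(len(rows))])
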