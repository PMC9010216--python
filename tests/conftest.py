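import numpy as np
import pandas as pd
import pytest

from fcmod.roi_model import EdgeMask, ROIConfiguration, ROISet, load_roi_table
from fcmod.synthetic_data import CohortSpec, simulate_cohort


def make_mask(edges, n_rois, name="S-SP"):
    """EdgeMask over explicit unordered pairs, for unit fixtures."""
    cfg = ROIConfiguration(name, tuple(range(n_rois)), tuple(range(n_rois)))
    return EdgeMask(edges=tuple(sorted((min(i, j), max(i, j)) for i, j in edges)),
                    config=cfg)


def all_pairs_mask(n_rois):
    return make_mask([(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)],
                     n_rois)


def stat_matrix(n, entries):
    """Symmetric statistic matrix with NaN elsewhere; entries {(i,j): t}."""
    m = np.full((n, n), np.nan)
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return m


@pytest.fixture(scope="session")
def atlas():
    return load_roi_table()


@pytest.fixture(scope="session")
def study_cohort():
    """Default 34 pain / 14 no-pain cohort at the emulated study's moments."""
    return simulate_cohort(CohortSpec(seed=20240601))


@pytest.fixture
def toy_roi_table(tmp_path):
    path = tmp_path / "rois.tsv"
    pd.DataFrame({
        "name": ["A", "B", "C"],
        "hemisphere": ["left", "right", "midline"],
        "is_sleep": [1, 0, 0],
        "is_pain": [0, 1, 0],
    }).to_csv(path, sep="\t", index=False)
    return path
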