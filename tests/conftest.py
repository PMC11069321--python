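import numpy as np
import pandas as pd
import pytest

from tauconnect import AtlasSpec, SubjectTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_atlas():
    """6 ROIs over 3 networks with simple integer centroids."""
    return AtlasSpec(
        roi_id=np.arange(1, 7),
        roi_name=tuple(f"r{i}" for i in range(1, 7)),
        network=("DMN", "DMN", "DAN", "DAN", "Vis", "Vis"),
        centroid=np.array(
            [[0, 0, 0], [3, 4, 0], [10, 0, 0], [10, 3, 4], [-5, -5, 0], [-5, -5, 7]],
            dtype=float,
        ),
    )


def make_subject_table(tau, fdg, groups, seed=0):
    """Build a SubjectTable from SUVR arrays and group labels."""
    rng = np.random.default_rng(seed)
    n = len(groups)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": list(groups),
            "age": rng.normal(60, 8, n).round(1),
            "sex": rng.choice(["M", "F"], n),
            "education": rng.normal(10, 3, n).round(1),
        }
    )
    return SubjectTable(subjects=subjects, tau=np.asarray(tau, float), fdg=np.asarray(fdg, float))


@pytest.fixture
def small_cohort():
    """Small synthetic cohort shared by slower integration tests."""
    from tauconnect import CohortConfig, simulate_cohort

    return simulate_cohort(CohortConfig(P=20, T=120, n_nc=10, n_ad=20, seed=7))
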