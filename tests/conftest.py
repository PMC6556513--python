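import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import msresponse as mr

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 15 patients, 6 region pairs."""
    return mr.CohortConfig(
        n_pre_only=4, n_post_only=6, n_both=5, n_region_pairs=6, seed=101
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return mr.generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale cohort at the study's printed composition
    (16 pre-only / 60 post-only / 27 both, 72 region pairs)."""
    return mr.generate_cohort(mr.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def default_trajectories(default_cohort):
    deconf = mr.residualize_features(mr.normalize_by_tiv(default_cohort))
    return mr.build_trajectory_dataset(deconf)


def make_toy_cohort_frame(n_patients=6, scans_per_patient=4, seed=0):
    """A minimal hand-built cohort table with one region pair and the
    global aggregates, for unit tests that need full control."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"T{i:02d}"
        times = np.sort(rng.uniform(-3, 4, size=scans_per_patient))
        for t in times:
            vol_l = 5000 + rng.normal(0, 30)
            vol_r = 5100 + rng.normal(0, 30)
            rows.append(
                {
                    "patient_id": pid,
                    "scan_time_years": float(t),
                    "age": 40 + t,
                    "gender": "F" if i % 2 else "M",
                    "vol_roi01_L": vol_l,
                    "vol_roi01_R": vol_r,
                    "disc_roi01_L": 0.3 + rng.normal(0, 0.01),
                    "disc_roi01_R": 0.35 + rng.normal(0, 0.01),
                    "total_brain_vol": vol_l + vol_r,
                    "total_lesion_vol": 3000 + rng.normal(0, 100),
                    "lesion_count": int(rng.integers(5, 20)),
                    "tiv": 1.4e6,
                }
            )
    return pd.DataFrame(rows)
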