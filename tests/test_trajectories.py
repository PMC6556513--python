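"""Slope fitting, sign trajectories and hemispheric collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import msresponse as mr
from msresponse.trajectories import RegionPairing, fit_slope


def ols_slope_oracle(times, values):
    """Normal-equations least-squares slope, solved explicitly."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1]


@pytest.mark.parametrize(
    "times, values, expected",
    [
        ((0, 1, 2), (5, 5, 5), 0.0),
        ((0, 1), (0, 2), 2.0),
        ((0, 1, 2), (1, 2, 4), 1.5),
    ],
)
def test_fit_slope_matches_normal_equations(times, values, expected):
    est = fit_slope(times, values)
    assert est.slope == pytest.approx(expected)
    assert est.slope == pytest.approx(ols_slope_oracle(times, values))
    assert est.n_scans == len(times)


def test_fit_slope_random_series_matches_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(2, 8)
        t = rng.normal(size=n)
        if np.ptp(t) < 1e-6:
            continue
        y = rng.normal(size=n)
        assert fit_slope(t, y).slope == pytest.approx(ols_slope_oracle(t, y))


def test_fit_slope_errors():
    with pytest.raises(ValueError, match="insufficient scans"):
        fit_slope([1.0], [2.0])
    with pytest.raises(ValueError, match="degenerate times"):
        fit_slope([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("slope, expected", [(0.07, 1), (-3.2, -1), (0.0, 0)])
def test_slope_sign_trajectory(slope, expected):
    assert mr.slope_to_trajectory(slope) == expected


def test_trajectory_rejects_nonfinite():
    with pytest.raises(ValueError):
        mr.slope_to_trajectory(float("nan"))


@pytest.mark.parametrize(
    "left, right, expected", [(-1, -1, -2), (1, -1, 0), (1, 1, 2), (0, -1, -1)]
)
def test_collapse_hemispheres(left, right, expected):
    assert mr.collapse_hemispheres(left, right) == expected


def test_collapse_rejects_out_of_range():
    with pytest.raises(ValueError):
        mr.collapse_hemispheres(2, 0)


@given(st.integers(-1, 1), st.integers(-1, 1))
def test_collapse_symmetric_and_bounded(a, b):
    v = mr.collapse_hemispheres(a, b)
    assert v == mr.collapse_hemispheres(b, a) == a + b
    assert -2 <= v <= 2


@given(
    st.lists(st.floats(-5, 5), min_size=3, max_size=6, unique=True),
    st.floats(0.1, 100.0),
    st.floats(-50.0, 50.0),
)
def test_trajectory_invariant_to_increasing_affine_transform(times, scale, offset):
    """The sign of an OLS slope is unchanged by y -> a*y + b with a > 0."""
    rng = np.random.default_rng(12)
    y = rng.normal(size=len(times))
    s1 = mr.slope_to_trajectory(fit_slope(times, y).slope)
    s2 = mr.slope_to_trajectory(fit_slope(times, scale * y + offset).slope)
    assert s1 == s2


def _frame(times):
    return pd.DataFrame({"scan_time_years": times, "f": np.arange(len(times))})


def test_split_periods_sign_partition():
    pre, post = mr.split_periods(_frame([-2, -1, 0.5, 1.5]))
    assert list(pre["scan_time_years"]) == [-2, -1]
    assert list(post["scan_time_years"]) == [0.5, 1.5]


def test_split_periods_single_pre_scan():
    pre, post = mr.split_periods(_frame([-1.0]))
    assert len(pre) == 1 and len(post) == 0


def test_split_periods_scan_at_zero_excluded_with_warning():
    with pytest.warns(UserWarning, match="t=0"):
        pre, post = mr.split_periods(_frame([0.0]))
    assert len(pre) == 0 and len(post) == 0


def test_build_dataset_vector_counts(small_cohort, small_config):
    traj = mr.build_trajectory_dataset(small_cohort)
    assert len(traj) == small_config.n_trajectory_periods
    cls0 = (traj["period_class"] == 0).mean()
    assert cls0 == pytest.approx(small_config.class0_fraction)
    # both-period patients contribute exactly one vector per class
    counts = traj.groupby("patient_id")["period_class"].agg(["count", "nunique"])
    both = counts[counts["count"] == 2]
    assert (both["nunique"] == 2).all()
    assert len(both) == small_config.n_both


def test_build_dataset_skips_single_scan_period():
    rng = np.random.default_rng(3)
    rows = []
    for t in (-1.0, 0.5, 1.0, 2.5):  # 1 pre scan, 3 post scans
        rows.append(
            {
                "patient_id": "P1",
                "scan_time_years": t,
                "vol_roi01_L": rng.normal(),
                "vol_roi01_R": rng.normal(),
                "total_brain_vol": rng.normal(),
                "total_lesion_vol": rng.normal(),
                "lesion_count": 3,
            }
        )
    traj = mr.build_trajectory_dataset(pd.DataFrame(rows))
    assert len(traj) == 1
    assert traj.iloc[0]["period_class"] == 1


def test_build_dataset_unknown_pairing_features(small_cohort):
    pairing = RegionPairing(
        pairs={"vol_bogus": ("vol_bogus_L", "vol_bogus_R")}, singletons=()
    )
    with pytest.raises(ValueError, match="unknown features"):
        mr.build_trajectory_dataset(small_cohort, pairing)


def test_noiseless_recovery_of_generating_slopes():
    """With zero noise and no confounding, fitted slopes equal the
    generating slopes and trajectories equal their signs."""
    cfg = mr.CohortConfig(
        n_pre_only=2, n_post_only=2, n_both=2, n_region_pairs=4,
        affected_fraction=1.0, noise_sd=0.0, disc_noise_sd=0.0,
        global_slope_sd=0.0, disc_global_slope_sd=0.0,
        confounder_effects={}, seed=5,
    )
    cohort = mr.generate_cohort(cfg)
    truth = cohort.ground_truth.slopes.set_index(["patient_id", "period", "feature"])
    for pid, sub in cohort.scans.groupby("patient_id"):
        pre, post = mr.split_periods(sub)
        for period, scans in (("pre", pre), ("post", post)):
            if len(scans) < 2:
                continue
            for feat in ("vol_roi01_L", "disc_roi03_R"):
                est = fit_slope(scans["scan_time_years"], scans[feat])
                true = truth.loc[(pid, period, feat), "slope"]
                assert est.slope == pytest.approx(true, abs=1e-8)
                assert mr.slope_to_trajectory(est.slope) == np.sign(true)


def test_pairing_rejects_duplicates():
    with pytest.raises(ValueError, match="more than one pair"):
        RegionPairing(
            pairs={
                "a": ("vol_a_L", "vol_a_R"),
                "b": ("vol_a_L", "vol_b_R"),
            },
            singletons=(),
        )
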