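"""Classifier contracts, subject-level bootstrap CV, selection, ensembling
and the permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

import msresponse as mr
from msresponse.models import (
    ClassifierSpec,
    _subsample_majority,
    bootstrap_cv,
    ensemble_results,
    make_classifier,
    subject_level_split,
)


def make_vectors(n_patients=40, n_features=4, informative=1, flip=0.15, seed=0,
                 both_fraction=0.3):
    """Trajectory-like integer vectors with a controllable signal.

    Informative features equal -2 for class 0 / +2 for class 1, with sign
    flips at rate ``flip``; the rest are uniform noise in {-2..2}.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        classes = (0, 1) if rng.random() < both_fraction else (int(rng.random() < 0.6),)
        for cls in classes:
            row = {"patient_id": pid, "period_class": cls}
            for j in range(n_features):
                if j < informative:
                    v = 2 * (1 if cls == 1 else -1)
                    if rng.random() < flip:
                        v = -v
                    row[f"f{j}"] = v
                else:
                    row[f"f{j}"] = int(rng.integers(-2, 3))
            rows.append(row)
    return pd.DataFrame(rows)


def test_classifier_hyperparameters():
    svm = make_classifier(ClassifierSpec(kind="svm"), n_features=3)
    params = svm._est.get_params()
    assert params["C"] == 10 and params["kernel"] == "rbf"
    assert params["gamma"] == pytest.approx(1 / 3)
    assert params["class_weight"] == "balanced"

    ert = make_classifier(ClassifierSpec(kind="ert"), n_features=9)
    params = ert._est.get_params()
    assert params["n_estimators"] == 100 and params["criterion"] == "gini"
    assert params["max_features"] == "sqrt"  # 3 candidate features at 9 inputs
    assert params["class_weight"] == "balanced"

    with pytest.raises(ValueError, match="unknown classifier"):
        ClassifierSpec(kind="boosting")
    with pytest.raises(ValueError, match="n_features"):
        make_classifier(ClassifierSpec(kind="svm"), n_features=0)


@pytest.mark.parametrize("kind", ["svm", "ert"])
def test_separable_toy_training_auc(kind):
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
    y = np.array([0] * 20 + [1] * 20)
    model = make_classifier(ClassifierSpec(kind=kind), 2, random_state=0).fit(X, y)
    scores = model.score_samples(X)
    assert np.all((scores >= 0) & (scores <= 1))
    assert mr.roc_auc(scores, y) == 1.0


def test_subject_level_split_basics():
    pats = [f"P{i}" for i in range(10)]
    plan = subject_level_split(pats, seed=3)
    assert len(plan.test_ids) == 2 and len(plan.train_ids) == 8
    assert not set(plan.train_ids) & set(plan.test_ids)
    again = subject_level_split(pats, seed=3)
    assert plan == again
    with pytest.raises(ValueError, match=">=5"):
        subject_level_split(["a", "b"], seed=0)


def test_subject_level_split_retries_for_class_coverage():
    # only one patient carries class 0: it must end up in training
    labels = {f"P{i}": {1} for i in range(10)}
    labels["P0"] = {0}
    for s in range(20):
        plan = subject_level_split(list(labels), labels, seed=s)
        assert "P0" in plan.train_ids


def test_bootstrap_cv_deterministic():
    vec = make_vectors(seed=4)
    kw = dict(spec=ClassifierSpec(kind="svm"), n_iter=2, seed=9)
    a = bootstrap_cv(vec, **kw)
    b = bootstrap_cv(vec, **kw)
    pd.testing.assert_frame_equal(a.per_iteration, b.per_iteration)
    assert a.oof == b.oof
    assert a.aggregate == b.aggregate


def test_bootstrap_cv_ledger_respects_subject_constraint():
    """Both vectors of a both-period patient are held out at exactly the
    same iterations: the out-of-fold ledger never splits a patient."""
    vec = make_vectors(seed=6, both_fraction=0.5)
    res = bootstrap_cv(vec, spec=ClassifierSpec(kind="svm"), n_iter=20, seed=1)
    pos_by_patient = vec.groupby("patient_id").indices
    for pid, positions in pos_by_patient.items():
        if len(positions) < 2:
            continue
        iter_sets = [set(it for it, _ in res.oof[int(p)]) for p in positions]
        assert all(s == iter_sets[0] for s in iter_sets)
    # every vector's scores exist and lie in [0, 1]
    for entries in res.oof.values():
        assert all(0.0 <= s <= 1.0 for _, s in entries)


def test_bootstrap_cv_detects_signal_and_null():
    signal = make_vectors(n_patients=60, informative=2, flip=0.1, seed=8)
    res = bootstrap_cv(signal, spec=ClassifierSpec(kind="svm"), n_iter=40, seed=2)
    assert res.mean_auc() > 0.8

    # shuffling labels destroys the signal: the mean AUC drops to the chance
    # band (out-of-fold CV on a fixed null dataset is mildly pessimistic, so
    # the band is centred on but not pinned to 0.5)
    rng = np.random.default_rng(3)
    shuffled = signal.copy()
    shuffled["period_class"] = rng.permutation(shuffled["period_class"].to_numpy())
    null = bootstrap_cv(shuffled, spec=ClassifierSpec(kind="svm"), n_iter=40, seed=2)
    assert 0.40 <= null.mean_auc() <= 0.60
    assert null.mean_auc() < res.mean_auc() - 0.2


def test_bootstrap_cv_requires_two_per_class():
    vec = make_vectors(seed=4)
    vec = vec[vec["period_class"] == 1]
    with pytest.raises(ValueError, match="per class"):
        bootstrap_cv(vec, spec=ClassifierSpec(kind="svm"), n_iter=2, seed=0)


def test_subsample_majority_balances_training():
    y = np.array([0] * 4 + [1] * 10)
    idx = np.arange(len(y))
    out = _subsample_majority(idx, y, np.random.default_rng(0))
    assert np.bincount(y[out])[0] == np.bincount(y[out])[1] == 4


def test_bootstrap_cv_balanced_subsampling_runs():
    vec = make_vectors(seed=12)
    res = bootstrap_cv(
        vec, spec=ClassifierSpec(kind="svm"), n_iter=5, seed=3, balance="subsample"
    )
    assert res.n_iterations == 5
    with pytest.raises(ValueError, match="balance"):
        bootstrap_cv(vec, spec=ClassifierSpec(kind="svm"), n_iter=2, balance="up")


def test_greedy_selects_informative_feature_first():
    """With one informative and five noise features, the informative one
    opens the selection in nearly every seeded replicate."""
    hits = 0
    for rep in range(25):
        vec = make_vectors(
            n_patients=40, n_features=6, informative=1, flip=0.1, seed=100 + rep
        )
        trace = mr.greedy_forward_selection(
            vec,
            [f"f{j}" for j in range(6)],
            spec=ClassifierSpec(kind="svm"),
            n_iter=10,
            seed=rep,
            max_features=1,
        )
        hits += trace.ordered_features[0] == "f0"
    assert hits >= 23


def test_greedy_matches_exhaustive_subset_search():
    """On a small 3-feature problem the greedy choice coincides with the
    best subset found by exhaustive search over all feature subsets."""
    vec = make_vectors(n_patients=30, n_features=3, informative=2, flip=0.2, seed=42)
    spec = ClassifierSpec(kind="svm")
    feats = ["f0", "f1", "f2"]

    def mean_auc(subset):
        return bootstrap_cv(
            vec, spec=spec, features=list(subset), n_iter=25, seed=7
        ).mean_auc()

    best_subset, best_auc = None, -1.0
    for r in range(1, 4):
        for subset in itertools.combinations(feats, r):
            auc = mean_auc(subset)
            if auc > best_auc:
                best_subset, best_auc = set(subset), auc

    trace = mr.greedy_forward_selection(vec, feats, spec=spec, n_iter=25, seed=7)
    assert set(trace.chosen_features) == best_subset
    assert trace.steps["auc_mean"].iloc[trace.chosen_size - 1] == pytest.approx(best_auc)


def test_greedy_single_candidate():
    vec = make_vectors(seed=9)
    trace = mr.greedy_forward_selection(
        vec, ["f0"], spec=ClassifierSpec(kind="svm"), n_iter=5, seed=1
    )
    assert trace.ordered_features == ["f0"]
    assert trace.chosen_features == ["f0"]


def test_ensemble_predict():
    out = mr.ensemble_predict([0.6], [0.8], 0.857, 0.817)
    assert out[0] == pytest.approx(0.6976, abs=1e-4)
    # equal AUCs reduce to the arithmetic mean
    np.testing.assert_allclose(
        mr.ensemble_predict([0.2, 0.9], [0.6, 0.1], 0.8, 0.8), [0.4, 0.5]
    )
    same = mr.ensemble_predict([0.3, 0.7], [0.3, 0.7], 0.9, 0.6)
    np.testing.assert_allclose(same, [0.3, 0.7])
    with pytest.raises(ValueError, match="AUC"):
        mr.ensemble_predict([0.5], [0.5], 0.0, 0.8)
    with pytest.raises(ValueError, match="length"):
        mr.ensemble_predict([0.5], [0.5, 0.6], 0.8, 0.8)


def test_ensemble_results_requires_matching_splits():
    vec = make_vectors(n_patients=30, n_features=4, informative=2, seed=15)
    spec = ClassifierSpec(kind="svm")
    a = bootstrap_cv(vec, spec=spec, features=["f0", "f1"], n_iter=10, seed=5)
    b = bootstrap_cv(vec, spec=spec, features=["f2", "f3"], n_iter=10, seed=5)
    ens = ensemble_results(a, b)
    assert ens.n_iterations == 10
    assert set(ens.features) == {"f0", "f1", "f2", "f3"}
    assert 0.0 <= ens.mean_auc() <= 1.0

    c = bootstrap_cv(vec, spec=spec, features=["f2", "f3"], n_iter=10, seed=6)
    with pytest.raises(ValueError, match="splits"):
        ensemble_results(a, c)


def test_permute_null_preserves_multisets(small_cohort):
    null = mr.permute_null(small_cohort, seed=3)
    scans, orig = null.scans, small_cohort.scans
    # covariates and times untouched
    for col in ("scan_time_years", "age", "manufacturer"):
        pd.testing.assert_series_equal(scans[col], orig[col])
    changed = 0
    for pid in small_cohort.patient_ids:
        mask = orig["patient_id"] == pid
        for col in ("vol_roi01_L", "disc_roi02_R", "lesion_count"):
            a = sorted(orig.loc[mask, col])
            b = sorted(scans.loc[mask, col])
            assert a == pytest.approx(b)
            changed += not np.array_equal(orig.loc[mask, col], scans.loc[mask, col])
    assert changed > 0  # some series actually reordered
    again = mr.permute_null(small_cohort, seed=3)
    pd.testing.assert_frame_equal(null.scans, again.scans)


def test_permute_null_single_scan_patient_unchanged():
    scans = pd.DataFrame(
        {
            "patient_id": ["A"],
            "scan_time_years": [1.0],
            "vol_r_L": [5.0],
            "vol_r_R": [6.0],
            "total_brain_vol": [11.0],
            "total_lesion_vol": [1.0],
            "lesion_count": [2],
            "tiv": [1e6],
        }
    )
    from msresponse.synthetic import CohortTable
    from msresponse.trajectories import RegionPairing

    cohort = CohortTable(scans, RegionPairing.from_feature_columns(scans.columns))
    null = mr.permute_null(cohort, seed=0)
    pd.testing.assert_frame_equal(null.scans, scans)
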