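"""Classifiers of treatment period under subject-constrained bootstrap CV.

Two classifier families detect whether a trajectory vector belongs to the
pre- or post-treatment period: a Gaussian-RBF support vector machine
(C = 10, gamma = 1/n_features, balanced class weights) and extremely
randomised trees (100 trees, Gini splits, sqrt(n_features) features per
split, balanced class weights).  Hyperparameters are fixed; there is no
search.

Evaluation is Monte-Carlo cross-validation with 500 iterations by default:
at each iteration 80% of *patients* are randomly assigned to training and
20% to testing, so the two trajectory vectors of a patient observed in both
periods always land on the same side -- information can never leak between a
patient's periods.  Per-iteration metrics on the fully held-out test vectors
are aggregated as mean +/- 1.96 SE, and every held-out score is recorded in
an out-of-fold ledger keyed by vector, from which consensus predictions and
ensembles are built.

Feature selection is greedy and forward-stepwise on the mean out-of-fold
AUC; the volume-only and disconnection-only models are combined into an
ensemble by averaging their scores weighted by the models' mean AUCs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.svm import SVC

from . import evaluation
from .synthetic import CohortTable

__all__ = [
    "ClassifierSpec",
    "SplitPlan",
    "BootstrapCVResult",
    "SelectionTrace",
    "make_classifier",
    "subject_level_split",
    "bootstrap_cv",
    "greedy_forward_selection",
    "ensemble_predict",
    "ensemble_results",
    "permute_null",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc", "accuracy", "sensitivity", "specificity", "balanced_f", "mcc")


@dataclasses.dataclass(frozen=True)
class ClassifierSpec:
    """Fixed classifier hyperparameters.

    ``kind`` is ``"svm"`` (kernel-margin: Gaussian RBF, C = 10,
    gamma = 1/n_features, balanced class weighting) or ``"ert"``
    (randomized-tree-ensemble: 100 trees, Gini impurity,
    sqrt(n_features) candidate features per split, balanced weighting).
    """

    kind: str = "ert"
    C: float = 10.0
    n_trees: int = 100

    def __post_init__(self):
        if self.kind not in ("svm", "ert"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


class _FittedModel:
    """Uniform fit/score contract over the two classifier families.

    ``score`` returns a continuous response in [0, 1]: the fraction of trees
    voting class 1 for the tree ensemble, and a logistic transform of the
    decision value for the SVM.  Class decisions threshold the score at 0.5.
    """

    def __init__(self, spec: ClassifierSpec, n_features: int, random_state: int | None):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.spec = spec
        if spec.kind == "svm":
            self._est = SVC(
                kernel="rbf",
                C=spec.C,
                gamma=1.0 / n_features,
                class_weight="balanced",
                random_state=random_state,
            )
        else:
            self._est = ExtraTreesClassifier(
                n_estimators=spec.n_trees,
                criterion="gini",
                max_features="sqrt",
                class_weight="balanced",
                random_state=random_state,
            )

    def fit(self, X, y) -> "_FittedModel":
        self._est.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def score_samples(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.spec.kind == "svm":
            d = self._est.decision_function(X)
            return 1.0 / (1.0 + np.exp(-d))
        votes = np.stack([tree.predict(X) for tree in self._est.estimators_])
        return votes.mean(axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.score_samples(X) >= 0.5).astype(int)


def make_classifier(
    spec: ClassifierSpec, n_features: int, random_state: int | None = None
) -> _FittedModel:
    """Instantiate a trainable model for ``n_features`` input dimensions."""
    return _FittedModel(spec, n_features, random_state)


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """One iteration's random subject-level 80/20 partition."""

    iteration: int
    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test patient sets overlap")


def subject_level_split(
    patient_ids: Sequence,
    labels_by_patient: Mapping | None = None,
    test_frac: float = 0.2,
    seed: int | None = None,
    iteration: int = 0,
    max_retries: int = 50,
) -> SplitPlan:
    """Randomly partition patients into 80% train / 20% test.

    All of a patient's trajectory vectors follow the patient, so both vectors
    of a both-period patient land on the same side.  If ``labels_by_patient``
    is given (patient -> set of classes), the split is redrawn (bounded
    retries) until the training side contains both classes.
    """
    unique = list(dict.fromkeys(patient_ids))
    if len(unique) < 5:
        raise ValueError("need >=5 patients for a subject-level split")
    n_test = max(1, int(round(test_frac * len(unique))))
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        perm = rng.permutation(len(unique))
        test = tuple(unique[i] for i in perm[:n_test])
        train = tuple(unique[i] for i in perm[n_test:])
        if labels_by_patient is not None:
            train_classes = set().union(*(labels_by_patient[p] for p in train))
            if len(train_classes) < 2:
                continue
        return SplitPlan(iteration=iteration, train_ids=train, test_ids=test, seed=seed or 0)
    raise ValueError("could not draw a training set containing both classes")


@dataclasses.dataclass
class BootstrapCVResult:
    """Out-of-fold performance distributions over bootstrap iterations.

    ``per_iteration`` holds one row per iteration with each metric (NaN when
    undefined, e.g. AUC on a single-class test set); ``aggregate`` maps
    metric -> (mean, ci_low, ci_high); ``oof`` is the out-of-fold ledger:
    sample position -> list of (iteration, score).
    """

    spec: ClassifierSpec
    features: tuple[str, ...]
    n_iterations: int
    per_iteration: pd.DataFrame
    aggregate: dict[str, tuple[float, float, float]]
    oof: dict[int, list[tuple[int, float]]]
    labels: np.ndarray
    index: np.ndarray

    def mean_auc(self) -> float:
        return self.aggregate["auc"][0]

    def iteration_scores(self, iteration: int) -> tuple[np.ndarray, np.ndarray]:
        """(sample positions, scores) held out at one iteration."""
        pos, sc = [], []
        for i, entries in self.oof.items():
            for it, s in entries:
                if it == iteration:
                    pos.append(i)
                    sc.append(s)
        return np.asarray(pos, dtype=int), np.asarray(sc, dtype=float)

    def consensus_scores(self) -> np.ndarray:
        """Mean out-of-fold score per sample (NaN if never held out)."""
        out = np.full(len(self.labels), np.nan)
        for i, entries in self.oof.items():
            if entries:
                out[i] = float(np.mean([s for _, s in entries]))
        return out


def _prepare_xy(vectors, features, y=None, groups=None):
    if isinstance(vectors, pd.DataFrame) and y is None:
        if "period_class" not in vectors.columns:
            raise ValueError("trajectory table lacks a period_class column")
        y = vectors["period_class"].to_numpy(dtype=int)
        groups = vectors["patient_id"].to_numpy()
        X = vectors[list(features)].to_numpy(dtype=float)
        index = vectors.index.to_numpy()
    else:
        X = np.asarray(vectors[list(features)] if features else vectors, dtype=float)
        y = np.asarray(y, dtype=int)
        groups = np.asarray(groups)
        index = np.arange(len(y))
    return X, y, groups, index


def bootstrap_cv(
    vectors,
    y=None,
    groups=None,
    spec: ClassifierSpec | None = None,
    features: Sequence[str] | None = None,
    n_iter: int = 500,
    seed: int | None = None,
    balance: str = "off",
    test_frac: float = 0.2,
) -> BootstrapCVResult:
    """Subject-constrained Monte-Carlo cross-validation.

    ``vectors`` may be a trajectory table (with ``patient_id`` and
    ``period_class`` columns, predictors named by ``features``) or a plain
    feature matrix with explicit ``y`` and ``groups``.  ``balance`` is
    ``"off"`` or ``"subsample"`` (the majority class in each training set is
    randomly subsampled to the minority size).  Deterministic given ``seed``.
    """
    spec = spec or ClassifierSpec()
    if balance not in ("off", "subsample"):
        raise ValueError("balance must be 'off' or 'subsample'")
    if features is None and isinstance(vectors, pd.DataFrame):
        features = [c for c in vectors.columns if c not in ("patient_id", "period_class")]
    X, y, groups, index = _prepare_xy(vectors, features or [], y, groups)
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need >=2 vectors per class")

    labels_by_patient: dict = {}
    for g, lab in zip(groups, y):
        labels_by_patient.setdefault(g, set()).add(int(lab))
    patients = list(dict.fromkeys(groups))

    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=n_iter)

    records = []
    oof: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(y))}

    for it in range(n_iter):
        it_seed = int(iter_seeds[it])
        plan = subject_level_split(
            patients, labels_by_patient, test_frac=test_frac, seed=it_seed, iteration=it
        )
        train_set, test_set = set(plan.train_ids), set(plan.test_ids)
        assert not train_set & test_set
        train_mask = np.fromiter((g in train_set for g in groups), bool, len(groups))
        test_mask = ~train_mask

        tr_idx = np.flatnonzero(train_mask)
        if balance == "subsample":
            tr_idx = _subsample_majority(tr_idx, y, np.random.default_rng(it_seed + 1))

        model = make_classifier(spec, X.shape[1], random_state=it_seed)
        model.fit(X[tr_idx], y[tr_idx])
        te_idx = np.flatnonzero(test_mask)
        scores = model.score_samples(X[te_idx])
        te_y = y[te_idx]

        for pos, s in zip(te_idx, scores):
            oof[int(pos)].append((it, float(s)))

        pred = (scores >= 0.5).astype(int)
        bundle = evaluation.confusion_metrics(pred, te_y)
        if len(np.unique(te_y)) == 2:
            auc = evaluation.roc_auc(scores, te_y)
        else:
            auc = np.nan
            logger.debug("iteration %d: single-class test set, AUC undefined", it)
        records.append(
            {
                "iteration": it,
                "auc": auc,
                "accuracy": bundle.accuracy,
                "sensitivity": bundle.sensitivity,
                "specificity": bundle.specificity,
                "balanced_f": bundle.balanced_f,
                "mcc": bundle.mcc,
            }
        )

    per_iteration = pd.DataFrame.from_records(records)
    aggregate = {m: _aggregate_metric(per_iteration[m]) for m in METRIC_NAMES}
    return BootstrapCVResult(
        spec=spec,
        features=tuple(features or ()),
        n_iterations=n_iter,
        per_iteration=per_iteration,
        aggregate=aggregate,
        oof=oof,
        labels=y,
        index=index,
    )


def _aggregate_metric(values) -> tuple[float, float, float]:
    """Aggregate one metric across iterations; (nan, nan, nan) when fewer
    than two iterations produced a defined value."""
    vals = np.asarray(values, dtype=float)
    if np.sum(~np.isnan(vals)) < 2:
        logger.warning("metric defined in <2 iterations; aggregate is missing")
        return (math.nan, math.nan, math.nan)
    return evaluation.aggregate_bootstrap(vals)


def _subsample_majority(tr_idx: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Randomly drop majority-class training vectors down to minority size."""
    tr_y = y[tr_idx]
    counts = np.bincount(tr_y, minlength=2)
    if counts[0] == counts[1]:
        return tr_idx
    majority = int(np.argmax(counts))
    maj_pos = tr_idx[tr_y == majority]
    keep = rng.choice(maj_pos, size=int(counts.min()), replace=False)
    out = np.concatenate([tr_idx[tr_y != majority], keep])
    return np.sort(out)


@dataclasses.dataclass
class SelectionTrace:
    """Greedy forward-stepwise selection record.

    ``steps`` has one row per addition: step, feature, auc_mean, ci_low,
    ci_high.  ``chosen_features`` is the prefix maximising the cumulative
    mean AUC (ties resolved toward the smaller set).
    """

    steps: pd.DataFrame

    @property
    def ordered_features(self) -> list[str]:
        return list(self.steps["feature"])

    @property
    def chosen_size(self) -> int:
        aucs = self.steps["auc_mean"].to_numpy()
        return int(np.argmax(aucs)) + 1  # argmax takes the first (smallest) maximum

    @property
    def chosen_features(self) -> list[str]:
        return self.ordered_features[: self.chosen_size]


def greedy_forward_selection(
    vectors,
    candidates: Sequence[str],
    spec: ClassifierSpec | None = None,
    n_iter: int = 100,
    seed: int | None = None,
    max_features: int | None = None,
    balance: str = "off",
) -> SelectionTrace:
    """Greedy forward-stepwise feature selection on mean out-of-fold AUC.

    Starts from the single best feature and at each step adds the candidate
    that maximises the mean bootstrapped out-of-fold AUC of the augmented
    set.  Every evaluation reuses the same ``seed``, hence the identical
    split sequence: candidate comparisons are paired.  Selection is intended
    to be carried out once and its result reused.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    limit = len(candidates) if max_features is None else min(max_features, len(candidates))

    selected: list[str] = []
    rows = []
    while len(selected) < limit:
        best = None
        for cand in candidates:
            if cand in selected:
                continue
            res = bootstrap_cv(
                vectors,
                spec=spec,
                features=selected + [cand],
                n_iter=n_iter,
                seed=seed,
                balance=balance,
            )
            mean, lo, hi = res.aggregate["auc"]
            if best is None or mean > best[1][0]:
                best = (cand, (mean, lo, hi))
        cand, (mean, lo, hi) = best
        selected.append(cand)
        rows.append(
            {
                "step": len(selected),
                "feature": cand,
                "auc_mean": mean,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
        logger.info("selection step %d: %s (mean AUC %.3f)", len(selected), cand, mean)
    return SelectionTrace(steps=pd.DataFrame(rows))


def ensemble_predict(
    scores_v: Sequence[float],
    scores_d: Sequence[float],
    auc_v: float,
    auc_d: float,
) -> np.ndarray:
    """AUC-weighted average of the volume and disconnectome model scores:
    (auc_v * s_v + auc_d * s_d) / (auc_v + auc_d)."""
    sv = np.asarray(scores_v, dtype=float)
    sd = np.asarray(scores_d, dtype=float)
    if sv.shape != sd.shape:
        raise ValueError("score lists must have equal length")
    for a in (auc_v, auc_d):
        if not (0.0 < a <= 1.0):
            raise ValueError("ensemble weights require AUCs in (0, 1]")
    return (auc_v * sv + auc_d * sd) / (auc_v + auc_d)


def ensemble_results(
    result_v: BootstrapCVResult, result_d: BootstrapCVResult
) -> BootstrapCVResult:
    """Combine two bootstrap results (run with the same seed, hence identical
    splits) into the AUC-weighted ensemble, re-deriving all per-iteration
    metrics from the combined out-of-fold scores."""
    if result_v.n_iterations != result_d.n_iterations:
        raise ValueError("component results differ in n_iterations")
    if not np.array_equal(result_v.labels, result_d.labels):
        raise ValueError("component results refer to different vectors")
    auc_v, auc_d = result_v.mean_auc(), result_d.mean_auc()
    y = result_v.labels

    records = []
    oof: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(y))}
    for it in range(result_v.n_iterations):
        pos_v, sc_v = result_v.iteration_scores(it)
        pos_d, sc_d = result_d.iteration_scores(it)
        if not np.array_equal(pos_v, pos_d):
            raise ValueError(
                "component results used different splits; run both with the same seed"
            )
        scores = ensemble_predict(sc_v, sc_d, auc_v, auc_d)
        for pos, s in zip(pos_v, scores):
            oof[int(pos)].append((it, float(s)))
        te_y = y[pos_v]
        pred = (scores >= 0.5).astype(int)
        bundle = evaluation.confusion_metrics(pred, te_y)
        auc = evaluation.roc_auc(scores, te_y) if len(np.unique(te_y)) == 2 else np.nan
        records.append(
            {
                "iteration": it,
                "auc": auc,
                "accuracy": bundle.accuracy,
                "sensitivity": bundle.sensitivity,
                "specificity": bundle.specificity,
                "balanced_f": bundle.balanced_f,
                "mcc": bundle.mcc,
            }
        )
    per_iteration = pd.DataFrame.from_records(records)
    aggregate = {m: _aggregate_metric(per_iteration[m]) for m in METRIC_NAMES}
    return BootstrapCVResult(
        spec=result_v.spec,
        features=tuple(result_v.features) + tuple(result_d.features),
        n_iterations=result_v.n_iterations,
        per_iteration=per_iteration,
        aggregate=aggregate,
        oof=oof,
        labels=y,
        index=result_v.index,
    )


def permute_null(cohort: CohortTable, seed: int | None = None) -> CohortTable:
    """Null cohort: each patient's per-feature time series randomly permuted.

    For every patient and every imaging feature independently, the feature's
    values are shuffled across that patient's scan times (times and
    covariates unchanged), destroying any real temporal trend while
    preserving the per-patient value multiset and the scan timing structure.
    """
    rng = np.random.default_rng(seed)
    scans = cohort.scans.copy()
    feature_cols = cohort.feature_columns()
    for _, idx in scans.groupby("patient_id", sort=False).indices.items():
        if len(idx) < 2:
            continue
        for col in feature_cols:
            vals = scans[col].to_numpy()[idx]
            scans.loc[scans.index[idx], col] = vals[rng.permutation(len(idx))]
    return CohortTable(scans, cohort.pairing, ground_truth=None)
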