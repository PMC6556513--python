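"""Confounder removal and adversarial verification.

Routine clinical imaging is acquired on heterogeneous scanners with varying
field strength and voxel geometry, from patients of varying age, disability
and disease duration.  Before any longitudinal modelling, volumes are
normalised by total intracranial volume and every imaging-derived feature is
residualised on the covariate design with a Bayesian ridge regression
(conjugate Gaussian model, penalty set by evidence maximisation), keeping
features on their original scale by adding back the grand mean.

Removal is then verified *adversarially*: for each confounder we dichotomise
its values (below sample mean vs. not for continuous covariates, modal
category vs. rest for manufacturer, 1.5 T vs. 3.0 T, slice thickness < 6 mm
vs. not) and ask a multivariate classifier, under the same subject-level
bootstrap cross-validation used for response modelling, to predict the
binarised confounder from the per-scan feature vector.  Successful removal
means no confounder can be predicted better than chance.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge, Ridge

from .synthetic import COVARIATE_COLUMNS, CohortTable

__all__ = [
    "ConfounderSpec",
    "DEFAULT_CONFOUNDERS",
    "normalize_by_tiv",
    "residualize_features",
    "binarize_confounder",
    "verify_deconfounding",
]


@dataclasses.dataclass(frozen=True)
class ConfounderSpec:
    """One covariate and how it is dichotomised for verification.

    ``binarization_rule`` is one of ``below_mean`` (continuous), ``modal``
    (categorical: most common category vs. rest), ``binary`` (two-level
    categorical such as gender or 1.5 T vs. 3.0 T field strength) or
    ``below_6mm`` (slice thickness).
    """

    name: str
    kind: str  # "continuous" | "categorical"
    binarization_rule: str
    #: verify against the value at the start of treatment (t = 0), removing
    #: the within-patient drift of covariates that advance with scan time --
    #: otherwise the verification target would leak pre/post information,
    #: which the imaging features legitimately carry
    at_treatment_start: bool = False


DEFAULT_CONFOUNDERS: tuple[ConfounderSpec, ...] = (
    ConfounderSpec("age", "continuous", "below_mean", at_treatment_start=True),
    ConfounderSpec("gender", "categorical", "binary"),
    ConfounderSpec("manufacturer", "categorical", "modal"),
    ConfounderSpec("field_strength", "categorical", "binary"),
    ConfounderSpec("disease_duration", "continuous", "below_mean"),
    ConfounderSpec("edss", "continuous", "below_mean"),
    ConfounderSpec("t1_slice_thickness", "continuous", "below_6mm"),
    ConfounderSpec("t1_voxel_resolution", "continuous", "below_mean"),
    ConfounderSpec("flair_slice_thickness", "continuous", "below_6mm"),
    ConfounderSpec("flair_voxel_resolution", "continuous", "below_mean"),
)


def normalize_by_tiv(cohort: CohortTable) -> CohortTable:
    """Divide every volume feature by that scan's total intracranial volume.

    Applies to regional volumes, total brain volume and total lesion volume;
    disconnection values and the lesion count are left untouched.
    """
    scans = cohort.scans
    if "tiv" not in scans.columns or scans["tiv"].isna().any():
        raise ValueError("tiv missing")
    tiv = scans["tiv"].to_numpy(dtype=float)
    if np.any(tiv <= 0):
        raise ValueError("tiv must be strictly positive on every scan")

    out = scans.copy()
    vol_cols = [c for c in scans.columns if c.startswith("vol_")]
    for col in vol_cols + ["total_brain_vol", "total_lesion_vol"]:
        if col in out.columns:
            out[col] = out[col].to_numpy(dtype=float) / tiv
    return CohortTable(out, cohort.pairing, cohort.ground_truth)


def _design_matrix(scans: pd.DataFrame, confounders: Sequence[ConfounderSpec]) -> np.ndarray:
    """Covariate design: standardized continuous columns, one-hot categorical
    with the reference level dropped.  The intercept is handled by the
    regression itself."""
    cols: list[np.ndarray] = []
    for spec in confounders:
        v = scans[spec.name]
        if v.isna().any():
            raise ValueError(f"missing values in covariate {spec.name!r}")
        if spec.kind == "categorical" or v.dtype == object:
            levels = sorted(pd.unique(v))
            for level in levels[1:]:  # drop reference level
                cols.append((v == level).to_numpy(dtype=float))
        else:
            x = v.to_numpy(dtype=float)
            sd = x.std()
            cols.append((x - x.mean()) / sd if sd > 0 else np.zeros_like(x))
    if not cols:
        return np.empty((len(scans), 0))
    return np.column_stack(cols)


def residualize_features(
    cohort: CohortTable,
    confounders: Sequence[ConfounderSpec] = DEFAULT_CONFOUNDERS,
    regularization: float | str = "auto",
) -> CohortTable:
    """Regress the covariate design out of every imaging feature.

    Each feature is replaced by its regression residual plus the feature's
    grand mean, so deconfounded features stay on their original scale.  The
    fit uses *all* scans in the table, including scans of patients whose
    periods are too short to contribute trajectories downstream.

    Parameters
    ----------
    regularization
        ``"auto"`` (default) fits a Bayesian ridge with its penalty set by
        evidence maximisation; a float fits an ordinary ridge with that
        penalty (useful near 0 to obtain the exact OLS residual).
    """
    scans = cohort.scans
    X = _design_matrix(scans, confounders)
    out = scans.copy()
    feature_cols = cohort.feature_columns()
    feature_cols = [c for c in feature_cols if c != "tiv"]

    if X.shape[1] == 0:
        return CohortTable(out, cohort.pairing, cohort.ground_truth)
    if len(scans) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} scans to fit the covariate design"
        )

    for col in feature_cols:
        y = scans[col].to_numpy(dtype=float)
        if regularization == "auto":
            model = BayesianRidge()
        else:
            model = Ridge(alpha=float(regularization))
        model.fit(X, y)
        resid = y - model.predict(X)
        out[col] = resid + y.mean()
    return CohortTable(out, cohort.pairing, cohort.ground_truth)


def binarize_confounder(values: Sequence, spec: ConfounderSpec) -> np.ndarray:
    """Dichotomise confounder values for adversarial verification.

    Rules: ``below_mean`` -> 1 where the value is below the sample mean;
    ``modal`` -> 1 for the most common category; ``binary`` -> 1 for the
    lexically smaller level (e.g. 1.5 T, or 'F'); ``below_6mm`` -> 1 where
    the slice thickness is < 6 mm.
    """
    v = pd.Series(list(values))
    if len(v) == 0:
        raise ValueError("empty confounder values")
    rule = spec.binarization_rule
    if rule == "below_mean":
        x = v.astype(float)
        return (x < x.mean()).to_numpy(dtype=int)
    if rule == "modal":
        if spec.kind != "categorical":
            raise ValueError("modal rule requires a categorical confounder")
        mode = v.mode().iloc[0]
        return (v == mode).to_numpy(dtype=int)
    if rule == "binary":
        levels = sorted(pd.unique(v))
        if len(levels) > 2:
            raise ValueError(f"{spec.name}: binary rule with >2 levels {levels}")
        return (v == levels[0]).to_numpy(dtype=int)
    if rule == "below_6mm":
        x = v.astype(float)
        return (x < 6.0).to_numpy(dtype=int)
    raise ValueError(f"unknown binarization rule {rule!r}")


def verify_deconfounding(
    cohort: CohortTable,
    confounders: Sequence[ConfounderSpec] = DEFAULT_CONFOUNDERS,
    classifier_spec=None,
    n_iter: int = 100,
    seed: int | None = None,
) -> dict[str, dict[str, float]]:
    """Mean AUC (with 95% CI) for predicting each binarised confounder from
    the per-scan imaging feature vector.

    Uses the same subject-level bootstrap cross-validation as the response
    models; after successful residualisation every AUC should sit at chance.
    Returns ``{confounder: {"auc_mean", "ci_low", "ci_high"}}``.
    """
    from .models import ClassifierSpec, bootstrap_cv  # deferred: avoids cycle

    spec = classifier_spec or ClassifierSpec(kind="svm")
    feature_cols = [c for c in cohort.feature_columns() if c != "tiv"]
    # z-score the feature columns: the per-scan features span several orders
    # of magnitude (normalised volumes vs. lesion counts) and an RBF kernel
    # on raw scales would only ever see the largest-scale features
    X = cohort.scans[feature_cols].astype(float)
    sd = X.std(ddof=0).replace(0.0, 1.0)
    X = (X - X.mean()) / sd
    groups = cohort.scans["patient_id"].to_numpy()

    report: dict[str, dict[str, float]] = {}
    for i, conf in enumerate(confounders):
        values = cohort.scans[conf.name]
        if conf.at_treatment_start:
            values = values - cohort.scans["scan_time_years"]
        y = binarize_confounder(values, conf)
        counts = np.bincount(y, minlength=2)
        if counts.min() < 2:
            raise ValueError(
                f"binarized confounder {conf.name!r} has a class with <2 members"
            )
        sub_seed = None if seed is None else seed + 7919 * i
        res = bootstrap_cv(X, y, groups, spec, n_iter=n_iter, seed=sub_seed)
        mean, lo, hi = res.aggregate["auc"]
        report[conf.name] = {"auc_mean": mean, "ci_low": lo, "ci_high": hi}
    return report
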