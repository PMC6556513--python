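"""End-to-end experiment driver.

Runs the full analysis on a synthetic cohort -- generate, deconfound, verify,
extract trajectories, (optionally) select features, fit and evaluate every
predictor set with both classifier families, repeat on a permutation-null
cohort, and simulate RCTs -- and writes the table/figure-analogue CSV/JSON
bundle plus a manifest from which the run can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .deconfound import DEFAULT_CONFOUNDERS, normalize_by_tiv, residualize_features, verify_deconfounding
from .models import (
    ClassifierSpec,
    BootstrapCVResult,
    bootstrap_cv,
    ensemble_results,
    greedy_forward_selection,
    permute_null,
)
from .rct import RCTConfig, consensus_predictions, simulate_rcts
from .synthetic import CohortConfig, CohortTable, generate_cohort, write_cohort
from .trajectories import LOW_DIMENSIONAL_FEATURES, build_trajectory_dataset, write_trajectories

__all__ = ["ExperimentConfig", "run_experiment", "predictor_sets", "results_table"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ExperimentConfig:
    """Settings for one full experiment run."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    classifiers: tuple[str, ...] = ("svm", "ert")
    n_iter: int = 100
    seed: int = 0
    balance: str = "off"
    select: bool = False
    selection_n_iter: int = 20
    selection_max_features: int = 12
    verify: bool = True
    verify_n_iter: int = 50
    run_null: bool = True
    rct: RCTConfig = dataclasses.field(default_factory=RCTConfig)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["confounder_effects"] = {
            k: list(v) for k, v in self.cohort.confounder_effects.items()
        }
        d["version"] = __version__
        blob = json.dumps(d, sort_keys=True, default=list)
        d["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
        return d


def predictor_sets(traj: pd.DataFrame) -> dict[str, list[str]]:
    """Named predictor sets mirroring the analysis' model rows."""
    vol = [c for c in traj.columns if c.startswith("vol_")]
    disc = [c for c in traj.columns if c.startswith("disc_")]
    return {
        "brain_volume": ["total_brain_vol"],
        "lesion_count": ["lesion_count"],
        "total_lesion_volume": ["total_lesion_vol"],
        "best_low_dimensional": list(LOW_DIMENSIONAL_FEATURES),
        "regional_volume": vol,
        "regional_disconnection": disc,
    }


def _fit_all(
    traj: pd.DataFrame,
    sets: dict[str, list[str]],
    classifiers: tuple[str, ...],
    n_iter: int,
    seed: int,
    balance: str,
) -> dict[str, dict[str, BootstrapCVResult]]:
    """Fit every predictor set with every classifier; add the AUC-weighted
    ensemble of the two regional models per classifier."""
    results: dict[str, dict[str, BootstrapCVResult]] = {}
    for kind in classifiers:
        spec = ClassifierSpec(kind=kind)
        kres = {}
        for name, feats in sets.items():
            kres[name] = bootstrap_cv(
                traj, spec=spec, features=feats, n_iter=n_iter, seed=seed, balance=balance
            )
            logger.info("%s/%s: mean AUC %.3f", kind, name, kres[name].mean_auc())
        kres["ensemble_high_dimensional"] = ensemble_results(
            kres["regional_volume"], kres["regional_disconnection"]
        )
        results[kind] = kres
    return results


def results_table(results: dict[str, dict[str, BootstrapCVResult]], metric: str = "auc") -> pd.DataFrame:
    """One row per predictor set, one column triple per classifier."""
    rows = []
    some = next(iter(results.values()))
    for name in some:
        row: dict[str, object] = {"predictor_set": name}
        for kind, kres in results.items():
            mean, lo, hi = kres[name].aggregate[metric]
            row[f"{kind}_mean"] = mean
            row[f"{kind}_ci_low"] = lo
            row[f"{kind}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def _write_model_json(results, out_dir: Path, stem: str, n_iter: int) -> None:
    payload = {}
    for kind, kres in results.items():
        payload[kind] = {}
        for name, res in kres.items():
            payload[kind][name] = {
                "features": list(res.features),
                "classifier": kind,
                "n_iter": n_iter,
                "metrics": {
                    m: {"mean": v[0], "ci_low": v[1], "ci_high": v[2]}
                    for m, v in res.aggregate.items()
                },
            }
    (out_dir / f"{stem}.json").write_text(json.dumps(payload, indent=2))


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the in-memory report bundle.

    Writes to ``out_dir``: the cohort, deconfounded cohort and trajectory
    CSVs, the confounder-verification JSON, AUC / balanced-F / MCC model
    tables, the permutation-null table, selection traces (when enabled), the
    RCT curves for the best high- and low-dimensional models, and
    ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    logger.info("stage simulate: %d patients", cohort_cfg.n_patients)
    cohort = generate_cohort(cohort_cfg)
    write_cohort(cohort, out / "cohort.csv")

    logger.info("stage deconfound")
    normalized = normalize_by_tiv(cohort)
    deconf = residualize_features(normalized)
    write_cohort(deconf, out / "cohort_deconfounded.csv")

    verification = None
    if config.verify:
        logger.info("stage verify")
        verification = {
            "before": verify_deconfounding(
                normalized, DEFAULT_CONFOUNDERS, n_iter=config.verify_n_iter,
                seed=config.seed + 101,
            ),
            "after": verify_deconfounding(
                deconf, DEFAULT_CONFOUNDERS, n_iter=config.verify_n_iter,
                seed=config.seed + 101,
            ),
        }
        (out / "verification.json").write_text(json.dumps(verification, indent=2))

    logger.info("stage features")
    traj = build_trajectory_dataset(deconf)
    write_trajectories(traj, out / "trajectories.csv")

    sets = predictor_sets(traj)
    if config.select:
        logger.info("stage select")
        spec = ClassifierSpec(kind="svm")
        for name in ("regional_volume", "regional_disconnection"):
            trace = greedy_forward_selection(
                traj,
                sets[name],
                spec=spec,
                n_iter=config.selection_n_iter,
                seed=config.seed + 211,
                max_features=config.selection_max_features,
            )
            trace.steps.to_csv(out / f"selection_{name}.csv", index=False)
            sets[name] = trace.chosen_features

    logger.info("stage fit")
    results = _fit_all(
        traj, sets, config.classifiers, config.n_iter, config.seed + 307, config.balance
    )
    for metric, stem in (("auc", "table_auc"), ("balanced_f", "table_balanced_f"), ("mcc", "table_mcc")):
        results_table(results, metric).to_csv(out / f"{stem}.csv", index=False)
    _write_model_json(results, out, "models", config.n_iter)

    null_results = None
    if config.run_null:
        logger.info("stage null")
        null_cohort = permute_null(cohort, seed=config.seed + 401)
        null_traj = build_trajectory_dataset(residualize_features(normalize_by_tiv(null_cohort)))
        null_results = _fit_all(
            null_traj, predictor_sets(null_traj), config.classifiers,
            config.n_iter, config.seed + 307, config.balance,
        )
        results_table(null_results).to_csv(out / "table_null_auc.csv", index=False)
        _write_model_json(null_results, out, "models_null", config.n_iter)

    logger.info("stage rct")
    best_kind = max(
        config.classifiers,
        key=lambda k: results[k]["ensemble_high_dimensional"].mean_auc(),
    )
    rct_curves = {}
    for label, set_name in (
        ("high", "ensemble_high_dimensional"),
        ("low", "best_low_dimensional"),
    ):
        res = results[best_kind][set_name]
        frame = pd.DataFrame(
            {
                "patient_id": traj["patient_id"],
                "label": res.labels,
                "prediction": consensus_predictions(res),
            }
        )
        rct_cfg = dataclasses.replace(config.rct, seed=config.seed + 503)
        curve = simulate_rcts(frame, rct_cfg)
        curve.to_csv(out / f"rct_{label}.csv", index=False)
        rct_curves[label] = curve

    manifest = config.manifest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))

    return {
        "cohort": cohort,
        "trajectories": traj,
        "verification": verification,
        "results": results,
        "null_results": null_results,
        "rct": rct_curves,
        "best_classifier": best_kind,
        "manifest": manifest,
    }
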