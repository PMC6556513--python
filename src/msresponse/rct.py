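"""Simulated randomised controlled trials of varying enrolment.

A trial of size N is simulated by sampling N distinct patients, pooling all
their trajectory vectors into a 2x2 table of classifier-predicted class
against true period class, and testing the association with Fisher's exact
test.  Repeating this (500 times by default) for a grid of N yields, per N,
the mean sample odds ratio with a 95% CI and the *achieved power*: the
fraction of repetitions rejecting independence at the significance level
alpha (0.01 by default), with a Wilson binomial CI.

An informative classifier produces odds ratios and power that grow with N;
an uninformative one rejects at about the rate alpha regardless of N.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .evaluation import Z95
from .models import BootstrapCVResult

__all__ = [
    "RCTConfig",
    "ContingencyTable",
    "consensus_predictions",
    "fisher_exact",
    "odds_ratio",
    "simulate_rcts",
]


@dataclasses.dataclass
class RCTConfig:
    """Trial-simulation settings.

    ``N_grid`` lists enrolment sizes; ``None`` spans 19 up to the cohort size
    in five steps.  ``alpha`` is the two-sided significance level of the
    Fisher test.
    """

    n_rep: int = 500
    alpha: float = 0.01
    N_grid: Sequence[int] | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_rep < 1:
            raise ValueError("n_rep must be positive")

    def grid_for(self, n_patients: int) -> list[int]:
        if self.N_grid is not None:
            grid = [int(n) for n in self.N_grid]
            if any(n < 2 or n > n_patients for n in grid):
                raise ValueError(f"N values must lie in [2, {n_patients}]")
            return grid
        lo = min(19, n_patients)
        return sorted(set(np.linspace(lo, n_patients, 5).round().astype(int)))


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of predicted class (rows) by true class (columns):
    a = pred1/true1, b = pred1/true0, c = pred0/true1, d = pred0/true0."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative counts")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @classmethod
    def from_predictions(cls, predicted, labels) -> "ContingencyTable":
        predicted = np.asarray(predicted)
        labels = np.asarray(labels)
        return cls(
            a=int(np.sum((predicted == 1) & (labels == 1))),
            b=int(np.sum((predicted == 1) & (labels == 0))),
            c=int(np.sum((predicted == 0) & (labels == 1))),
            d=int(np.sum((predicted == 0) & (labels == 0))),
        )

    def degenerate(self) -> bool:
        """True when a margin is zero (Fisher's test is then uninformative)."""
        t = self.as_array()
        return bool(np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0))


def consensus_predictions(result: BootstrapCVResult, threshold: float = 0.5) -> np.ndarray:
    """Per-vector predicted class from the mean out-of-fold score.

    Ties at the threshold resolve to class 1.  Raises if any vector was
    never held out (increase ``n_iter``).
    """
    scores = result.consensus_scores()
    if np.isnan(scores).any():
        missing = int(np.isnan(scores).sum())
        raise ValueError(
            f"{missing} vector(s) have no out-of-fold score; increase n_iter"
        )
    return (scores >= threshold).astype(int)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of all
    tables with the observed margins at most as probable as the observed."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio (a*d)/(b*c), with the Haldane-Anscombe correction
    (add 0.5 to every cell) whenever any cell is zero."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def simulate_rcts(
    vectors: pd.DataFrame,
    config: RCTConfig,
) -> pd.DataFrame:
    """Run the trial simulation over the enrolment grid.

    ``vectors`` needs columns ``patient_id``, ``label`` (true period class)
    and ``prediction`` (classifier output class); all available periods of a
    sampled patient enter that repetition's table.  Returns one row per N:
    ``N, or_mean, or_ci_low, or_ci_high, power, power_ci_low, power_ci_high``.
    """
    for col in ("patient_id", "label", "prediction"):
        if col not in vectors.columns:
            raise ValueError(f"vectors table missing column {col!r}")
    patients = list(dict.fromkeys(vectors["patient_id"]))
    n_patients = len(patients)
    grid = config.grid_for(n_patients)
    rng = np.random.default_rng(config.seed)

    by_patient = {
        p: (sub["prediction"].to_numpy(), sub["label"].to_numpy())
        for p, sub in vectors.groupby("patient_id", sort=False)
    }

    rows = []
    for N in grid:
        ors = np.empty(config.n_rep)
        rejected = 0
        for r in range(config.n_rep):
            chosen = rng.choice(n_patients, size=N, replace=False)
            preds = np.concatenate([by_patient[patients[i]][0] for i in chosen])
            labs = np.concatenate([by_patient[patients[i]][1] for i in chosen])
            table = ContingencyTable.from_predictions(preds, labs)
            ors[r] = odds_ratio(table)
            p = 1.0 if table.degenerate() else fisher_exact(table)
            if p < config.alpha:
                rejected += 1
        or_mean = float(ors.mean())
        se = float(ors.std(ddof=1) / np.sqrt(config.n_rep)) if config.n_rep > 1 else 0.0
        power = rejected / config.n_rep
        lo, hi = proportion_confint(rejected, config.n_rep, alpha=0.05, method="wilson")
        rows.append(
            {
                "N": N,
                "or_mean": or_mean,
                "or_ci_low": or_mean - Z95 * se,
                "or_ci_high": or_mean + Z95 * se,
                "power": power,
                "power_ci_low": float(lo),
                "power_ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
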