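"""Longitudinal slope-sign trajectory features.

The unit of analysis for response detection is the *patient-period*: the set
of a patient's scans acquired before (period class 0) or after (class 1) the
start of treatment at t = 0.  For every imaging feature we fit an ordinary
least-squares line to the feature values against scan time within a period
and keep only the *sign* of the slope -- the trajectory: +1 rising,
-1 falling, 0 for an exactly zero slope (relevant for ordinal or bounded
variables).  Trajectories of homologous left/right region pairs are collapsed
by summation, giving integers in {-2..+2}; unpaired global aggregates keep
their single sign in {-1, 0, +1}.

Discarding slope magnitudes trades sensitivity for robustness to the very
heterogeneous scan timing of routine clinical imaging: a slope estimated from
two scans a month apart carries far less information than one spanning years,
and keeping magnitudes would let that unreliability leak into the models.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionPairing",
    "SlopeEstimate",
    "split_periods",
    "fit_slope",
    "slope_to_trajectory",
    "collapse_hemispheres",
    "build_trajectory_dataset",
    "write_trajectories",
    "read_trajectories",
    "LOW_DIMENSIONAL_FEATURES",
]

#: Trajectories of these global aggregates form the conventional
#: low-dimensional predictor set (the "best low dimensional" model uses all
#: three; each is also evaluated alone).
LOW_DIMENSIONAL_FEATURES = ("total_brain_vol", "total_lesion_vol", "lesion_count")

#: Global aggregate columns that are trajectory-eligible singletons.  The
#: total intracranial volume is a normalising denominator, never a predictor.
_SINGLETON_FEATURES = ("total_brain_vol", "total_lesion_vol", "lesion_count")

_PAIR_RE = re.compile(r"^(vol|disc)_(.+)_(L|R)$")


@dataclasses.dataclass(frozen=True)
class RegionPairing:
    """Mapping from collapsed feature names to hemispheric column pairs.

    ``pairs`` maps e.g. ``"vol_roi01" -> ("vol_roi01_L", "vol_roi01_R")``;
    ``singletons`` lists global aggregates with no homologue.
    """

    pairs: Mapping[str, tuple[str, str]]
    singletons: tuple[str, ...]

    def __post_init__(self):
        seen: set[str] = set()
        for name, (left, right) in self.pairs.items():
            for col in (left, right):
                if col in seen:
                    raise ValueError(f"feature {col!r} appears in more than one pair")
                seen.add(col)
        overlap = seen.intersection(self.singletons)
        if overlap:
            raise ValueError(f"features in both pairs and singletons: {sorted(overlap)}")

    @property
    def collapsed_names(self) -> list[str]:
        return list(self.pairs) + list(self.singletons)

    def regional_columns(self) -> list[str]:
        return [c for pair in self.pairs.values() for c in pair]

    @classmethod
    def from_feature_columns(cls, columns: Iterable[str]) -> "RegionPairing":
        """Infer the pairing from ``vol_<region>_<L|R>`` / ``disc_<region>_<L|R>``
        column names; known global aggregates become singletons."""
        halves: dict[str, dict[str, str]] = {}
        singles: list[str] = []
        for col in columns:
            m = _PAIR_RE.match(col)
            if m:
                key = f"{m.group(1)}_{m.group(2)}"
                halves.setdefault(key, {})[m.group(3)] = col
            elif col in _SINGLETON_FEATURES:
                singles.append(col)
        pairs = {}
        for key, sides in sorted(halves.items()):
            if set(sides) != {"L", "R"}:
                raise ValueError(f"region {key!r} lacks a hemispheric homologue")
            pairs[key] = (sides["L"], sides["R"])
        return cls(pairs=pairs, singletons=tuple(singles))


@dataclasses.dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of one feature over one patient-period."""

    feature: str
    period: str  # "pre" | "post"
    slope: float
    n_scans: int


def split_periods(scans: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition one patient's scans into pre- (t < 0) and post-treatment
    (t > 0) sets.

    A scan at exactly t = 0 falls at the start of treatment and belongs to
    neither change regime; it is excluded with a warning.
    """
    t = scans["scan_time_years"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite scan times")
    if np.any(t == 0.0):
        warnings.warn(
            "scan at exactly t=0 excluded from both periods", UserWarning, stacklevel=2
        )
    return scans[t < 0], scans[t > 0]


def fit_slope(
    times: Iterable[float],
    values: Iterable[float],
    feature: str = "",
    period: str = "",
) -> SlopeEstimate:
    """Ordinary least-squares slope of ``values`` on ``times``.

    Raises ``ValueError`` for fewer than two points ("insufficient scans") or
    zero time variance ("degenerate times").
    """
    t = np.asarray(list(times), dtype=float)
    y = np.asarray(list(values), dtype=float)
    if t.size < 2:
        raise ValueError("insufficient scans: need >=2 points for a slope")
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        raise ValueError("degenerate times: zero time variance")
    slope = float(tc @ (y - y.mean())) / denom
    return SlopeEstimate(feature=feature, period=period, slope=slope, n_scans=t.size)


def slope_to_trajectory(slope: float) -> int:
    """Sign of a slope: +1 rising, -1 falling, 0 for an exactly zero slope."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return int(np.sign(slope))


def collapse_hemispheres(left_traj: int, right_traj: int) -> int:
    """Sum of the two hemispheric trajectories of a homologous region pair."""
    for v in (left_traj, right_traj):
        if v not in (-1, 0, 1):
            raise ValueError(f"trajectory {v!r} outside {{-1, 0, +1}}")
    return int(left_traj + right_traj)


def _period_slopes(sub: pd.DataFrame, feature_cols: list[str]) -> np.ndarray:
    """Vectorised OLS slopes of every feature column over one period."""
    t = sub["scan_time_years"].to_numpy(dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        raise ValueError("degenerate times: zero time variance")
    x = sub[feature_cols].to_numpy(dtype=float)
    return tc @ (x - x.mean(axis=0)) / denom


def build_trajectory_dataset(cohort, pairing: RegionPairing | None = None) -> pd.DataFrame:
    """Convert a (deconfounded) cohort table into per-patient-period
    trajectory vectors.

    One row per patient-period with >=2 scans; periods with fewer scans are
    skipped.  Columns: ``patient_id``, ``period_class`` (0 pre / 1 post) and
    one integer column per collapsed feature.
    """
    from .synthetic import CohortTable  # local import to avoid a cycle

    if isinstance(cohort, CohortTable):
        scans = cohort.scans
        pairing = pairing or cohort.pairing
    else:
        scans = cohort
        if pairing is None:
            pairing = RegionPairing.from_feature_columns(scans.columns)

    needed = set(pairing.regional_columns()) | set(pairing.singletons)
    missing = needed.difference(scans.columns)
    if missing:
        raise ValueError(f"pairing references unknown features: {sorted(missing)}")

    feature_cols = pairing.regional_columns() + list(pairing.singletons)
    col_idx = {c: i for i, c in enumerate(feature_cols)}

    rows = []
    for pid, sub in scans.groupby("patient_id", sort=False):
        pre, post = split_periods(sub)
        for period_class, period_scans in ((0, pre), (1, post)):
            if len(period_scans) < 2:
                continue
            slopes = _period_slopes(period_scans, feature_cols)
            signs = np.sign(slopes).astype(int)
            row: dict[str, object] = {"patient_id": pid, "period_class": period_class}
            for name, (left, right) in pairing.pairs.items():
                row[name] = collapse_hemispheres(
                    int(signs[col_idx[left]]), int(signs[col_idx[right]])
                )
            for name in pairing.singletons:
                row[name] = int(signs[col_idx[name]])
            rows.append(row)

    out = pd.DataFrame(rows, columns=["patient_id", "period_class"] + pairing.collapsed_names)
    return out


def write_trajectories(trajectories: pd.DataFrame, path) -> None:
    """Write the wide trajectory table (integer values) as CSV."""
    trajectories.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "period_class"):
        if col not in df.columns:
            raise ValueError(f"trajectory table missing required column {col!r}")
    return df
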