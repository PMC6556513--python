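"""Synthetic longitudinal imaging cohorts.

The study design this package analyses -- per-scan tables of regional brain
volumes and regional disconnection estimates from routinely imaged,
natalizumab-treated multiple-sclerosis patients -- cannot be shipped with
real data, so this module generates cohorts with the same statistical
structure:

* a cohort of patients with >=2 scans only before treatment (default 16),
  only after treatment (default 60), or in both periods (default 27);
* 72 homologous left/right region pairs, i.e. 144 regional volumes and 144
  regional disconnection estimates per scan (a 288-variable fingerprint),
  plus total brain volume, total lesion volume, lesion count and total
  intracranial volume;
* in a randomly chosen *affected* subset of region pairs, volumes decline
  before treatment and stabilise/recover after it, while disconnection rises
  before and flattens/falls after (mirrored signs);
* a per-patient-period *global* slope component shared by every region
  (brain-wide physiological variability, e.g. hydration).  It dominates the
  sign of aggregate measures such as total brain volume, keeping the
  low-dimensional aggregates weakly informative while the regional pattern
  remains strongly informative -- the qualitative ordering the analysis is
  designed to detect;
* linear covariate (confounder) effects on the imaging features, with
  scanner-type covariates resampled per scan and age advancing with time;
* a lesion burden that accrues as a monotone step process before treatment
  (Poisson new-lesion arrivals) and plateaus after, observed with counting
  noise;
* i.i.d. Gaussian per-scan measurement noise on every regional feature.

Ground truth (the affected pair set and every generating slope) is retained
on the returned :class:`CohortTable` for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .trajectories import RegionPairing

__all__ = [
    "CohortConfig",
    "CohortTable",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "save_config",
    "load_config",
    "strong_effect_config",
    "COVARIATE_COLUMNS",
    "GLOBAL_FEATURES",
]

COVARIATE_COLUMNS = (
    "age",
    "gender",
    "manufacturer",
    "field_strength",
    "disease_duration",
    "edss",
    "t1_slice_thickness",
    "t1_voxel_resolution",
    "flair_slice_thickness",
    "flair_voxel_resolution",
)

GLOBAL_FEATURES = ("total_brain_vol", "total_lesion_vol", "lesion_count", "tiv")

#: Default linear confounder effects: covariate -> (volume offset in mm^3,
#: disconnection offset) per unit of the internally centred design value.
#: Scanner manufacturer, field strength and voxel resolution carry the large
#: effects, mimicking inter-scanner measurement offsets.
DEFAULT_CONFOUNDER_EFFECTS: dict[str, tuple[float, float]] = {
    "age": (-10.0, 0.0005),
    "gender": (120.0, 0.0),
    "manufacturer": (250.0, 0.02),
    "field_strength": (300.0, 0.03),
    "disease_duration": (0.0, 0.0),
    "edss": (0.0, 0.0),
    "t1_slice_thickness": (-40.0, 0.0),
    "t1_voxel_resolution": (150.0, 0.004),
    "flair_slice_thickness": (0.0, -0.004),
    "flair_voxel_resolution": (0.0, 0.01),
}


@dataclasses.dataclass
class CohortConfig:
    """Generator settings.

    Slope units are feature units per year: mm^3/year for volumes,
    disconnection-probability/year for disconnection.  ``noise_sd`` and
    ``disc_noise_sd`` are per-scan measurement noise in the same units as the
    respective features.  Defaults put the per-region standardised slope
    change (post minus pre) at about one volume noise-sd per year, a strong
    but noisy distributed signal, while ``global_slope_sd`` keeps the
    aggregate signal weak.
    """

    n_pre_only: int = 16
    n_post_only: int = 60
    n_both: int = 27
    scans_per_period: tuple[int, int] = (2, 5)
    time_window_years: tuple[float, float] = (3.0, 4.0)
    n_region_pairs: int = 72
    affected_fraction: float = 0.3
    pre_slope_mean: float = -40.0
    pre_slope_sd: float = 10.0
    post_slope_mean: float = 10.0
    post_slope_sd: float = 5.0
    disc_pre_slope_mean: float = 0.02
    disc_pre_slope_sd: float = 0.005
    disc_post_slope_mean: float = -0.005
    disc_post_slope_sd: float = 0.003
    noise_sd: float = 50.0
    disc_noise_sd: float = 0.025
    global_slope_sd: float = 15.0
    disc_global_slope_sd: float = 0.0075
    lesion_rate_pre: float = 1.0
    lesion_rate_post: float = 0.05
    lesion_count_noise_sd: float = 1.5
    lesion_vol_per_lesion: float = 200.0
    lesion_vol_noise_sd: float = 150.0
    confounder_effects: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("n_pre_only", "n_post_only", "n_both"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_pre_only + self.n_post_only + self.n_both < 1:
            raise ValueError("empty cohort")
        lo, hi = self.scans_per_period
        if lo < 2 or hi < lo:
            raise ValueError(
                "scans_per_period must satisfy 2 <= min <= max: a slope needs "
                ">=2 scans in every period a patient group is assigned"
            )
        if min(self.time_window_years) <= 0:
            raise ValueError("time windows must be strictly positive")
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must lie in [0, 1]")
        for name in (
            "pre_slope_sd", "post_slope_sd", "disc_pre_slope_sd",
            "disc_post_slope_sd", "n_region_pairs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("noise_sd", "disc_noise_sd", "global_slope_sd", "disc_global_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.n_pre_only + self.n_post_only + self.n_both

    @property
    def n_trajectory_periods(self) -> int:
        """Number of trajectory-eligible patient-periods."""
        return self.n_pre_only + self.n_post_only + 2 * self.n_both

    @property
    def class0_fraction(self) -> float:
        """Expected fraction of pre-treatment (class 0) trajectory vectors."""
        return (self.n_pre_only + self.n_both) / self.n_trajectory_periods


def strong_effect_config(**overrides) -> CohortConfig:
    """A small, strong-effect cohort for feature-recovery experiments.

    Fewer region pairs and a larger standardised slope change (~1.8 noise-sd
    per year) with a weak global component, so that individual affected pairs
    are clearly but not perfectly informative; the cohort is large enough
    (75 patients, 105 trajectory vectors) that single-feature AUC rankings
    are stable.
    """
    defaults = dict(
        n_pre_only=20,
        n_post_only=25,
        n_both=30,
        n_region_pairs=12,
        affected_fraction=1 / 3,
        pre_slope_mean=-60.0,
        post_slope_mean=30.0,
        disc_pre_slope_mean=0.03,
        disc_post_slope_mean=-0.015,
        global_slope_sd=5.0,
        disc_global_slope_sd=0.002,
        confounder_effects={},
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters retained for parameter-recovery tests.

    ``slopes`` has one row per (patient, period, feature) with the total
    deterministic slope used in generation (treatment/affected component plus
    the patient-period global component); fitting a line to noiseless,
    unconfounded data recovers it exactly.
    """

    affected_pairs: tuple[str, ...]
    slopes: pd.DataFrame  # columns: patient_id, period, feature, slope

    def affected_columns(self, kind: str = "vol") -> list[str]:
        """Collapsed affected feature names, e.g. ``vol_roi03``."""
        return [f"{kind}_{p}" for p in self.affected_pairs]


@dataclasses.dataclass
class CohortTable:
    """A generated or loaded cohort: one row per scan."""

    scans: pd.DataFrame
    pairing: RegionPairing
    ground_truth: GroundTruth | None = None

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.scans["patient_id"]))

    def feature_columns(self) -> list[str]:
        return self.pairing.regional_columns() + [
            c for c in GLOBAL_FEATURES if c in self.scans.columns
        ]

    def copy(self) -> "CohortTable":
        return CohortTable(self.scans.copy(), self.pairing, self.ground_truth)


# --------------------------------------------------------------------------
# generation

def _sample_times(rng, n: int, lo: float, hi: float) -> np.ndarray:
    """Strictly increasing scan times, uniformly drawn in [lo, hi]."""
    while True:
        t = np.sort(rng.uniform(lo, hi, size=n))
        if np.all(np.diff(t) > 1e-6):
            return t


_CENTER = {
    "age": 38.0,
    "gender": 0.0,  # indicator for male
    "manufacturer": 0.0,  # Siemens 0, Philips +1, GE -1
    "field_strength": 1.5,
    "disease_duration": 6.3,
    "edss": 4.8,
    "t1_slice_thickness": 4.0,
    "t1_voxel_resolution": 1.0,
    "flair_slice_thickness": 4.0,
    "flair_voxel_resolution": 1.0,
}

_MANUFACTURER_CODE = {"Siemens": 0.0, "Philips": 1.0, "GE": -1.0}


def _design_value(name: str, value) -> float:
    if name == "gender":
        return 1.0 if value == "M" else 0.0
    if name == "manufacturer":
        return _MANUFACTURER_CODE[value]
    return float(value) - _CENTER[name]


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a cohort table; bit-reproducible for a fixed seed.

    Each regional feature at time t is
    ``baseline + slope_period * t + confounder terms + noise`` with the
    period slope composed of the affected-region treatment slope (zero for
    unaffected regions) and the patient-period global component.  Times are
    drawn in [-pre_span, -0.1] and [0.1, post_span]; no scan falls at t = 0.
    """
    rng = np.random.default_rng(config.seed)
    npairs = config.n_region_pairs
    pair_names = [f"roi{i + 1:02d}" for i in range(npairs)]
    regions = [(p, h) for p in pair_names for h in ("L", "R")]

    n_affected = int(round(config.affected_fraction * npairs))
    affected_pairs = tuple(
        sorted(rng.choice(pair_names, size=n_affected, replace=False))
    )
    affected = {p: (p in affected_pairs) for p in pair_names}

    vol_base = np.clip(rng.normal(7000.0, 1200.0, size=2 * npairs), 500.0, None)
    # baselines away from the [0, 1] bounds: clipping would make the linear
    # confounder effects nonlinear in the observed values and hence not
    # removable by the downstream linear residualisation
    disc_base = rng.uniform(0.2, 0.5, size=2 * npairs)
    # region-specific susceptibility to scanner/covariate offsets
    vol_conf_scale = rng.uniform(0.5, 1.5, size=2 * npairs)
    disc_conf_scale = rng.uniform(0.5, 1.5, size=2 * npairs)

    effects = dict(config.confounder_effects)

    groups = (
        ["pre_only"] * config.n_pre_only
        + ["post_only"] * config.n_post_only
        + ["both"] * config.n_both
    )

    pre_span, post_span = config.time_window_years
    lo_n, hi_n = config.scans_per_period

    vol_cols = [f"vol_{p}_{h}" for p, h in regions]
    disc_cols = [f"disc_{p}_{h}" for p, h in regions]

    rows: list[dict] = []
    slope_rows: list[dict] = []

    for i, group in enumerate(groups):
        pid = f"P{i + 1:03d}"
        age0 = float(np.clip(rng.normal(38.0, 10.0), 20.0, 70.0))
        gender = "M" if rng.random() < 44 / 124 else "F"
        duration = float(np.clip(rng.normal(6.3, 2.2), 0.5, None))
        edss = float(np.clip(np.round(rng.normal(4.8, 1.7) * 2) / 2, 0.0, 10.0))
        tiv0 = float(rng.normal(1.45e6, 7.0e4))
        lesion_count0 = int(rng.poisson(15))

        periods: list[str] = []
        if group in ("pre_only", "both"):
            periods.append("pre")
        if group in ("post_only", "both"):
            periods.append("post")

        # per-region treatment slopes for this patient
        treat = {}
        for period in ("pre", "post"):
            if period == "pre":
                mu_v, sd_v = config.pre_slope_mean, config.pre_slope_sd
                mu_d, sd_d = config.disc_pre_slope_mean, config.disc_pre_slope_sd
            else:
                mu_v, sd_v = config.post_slope_mean, config.post_slope_sd
                mu_d, sd_d = config.disc_post_slope_mean, config.disc_post_slope_sd
            v = np.zeros(2 * npairs)
            d = np.zeros(2 * npairs)
            for j, (p, _h) in enumerate(regions):
                if affected[p]:
                    v[j] = rng.normal(mu_v, sd_v)
                    d[j] = rng.normal(mu_d, sd_d)
            treat[period] = (v, d)

        global_slope = {p: rng.normal(0.0, config.global_slope_sd) for p in periods}
        disc_global = {p: rng.normal(0.0, config.disc_global_slope_sd) for p in periods}

        for period in periods:
            n_scans = int(rng.integers(lo_n, hi_n + 1))
            if period == "pre":
                times = _sample_times(rng, n_scans, -pre_span, -0.1)
            else:
                times = _sample_times(rng, n_scans, 0.1, post_span)

            v_slope = treat[period][0] + global_slope[period]
            d_slope = treat[period][1] + disc_global[period]
            for j, (p, h) in enumerate(regions):
                slope_rows.append(
                    {"patient_id": pid, "period": period,
                     "feature": f"vol_{p}_{h}", "slope": v_slope[j]}
                )
                slope_rows.append(
                    {"patient_id": pid, "period": period,
                     "feature": f"disc_{p}_{h}", "slope": d_slope[j]}
                )

            # lesion accrual between consecutive scans (monotone step process)
            rate = config.lesion_rate_pre if period == "pre" else config.lesion_rate_post
            # pre-period lesion history starts at the earliest scan; post
            # continues from the patient's baseline burden
            lesion_true = lesion_count0
            prev_t = times[0]

            for k, t in enumerate(times):
                if k > 0:
                    lesion_true += int(rng.poisson(rate * (t - prev_t)))
                    prev_t = t

                manufacturer = str(
                    rng.choice(["Siemens", "Philips", "GE"], p=[0.5, 0.3, 0.2])
                )
                field = float(rng.choice([1.5, 3.0], p=[0.4, 0.6]))
                t1_thick = float(rng.choice([1.0, 3.0, 6.0], p=[0.2, 0.3, 0.5]))
                fl_thick = float(rng.choice([1.0, 3.0, 6.0], p=[0.2, 0.3, 0.5]))
                t1_res = float(rng.choice([0.9, 1.0, 1.2]))
                fl_res = float(rng.choice([0.9, 1.0, 1.2]))

                cov = {
                    "age": age0 + t,
                    "gender": gender,
                    "manufacturer": manufacturer,
                    "field_strength": field,
                    "disease_duration": duration,
                    "edss": edss,
                    "t1_slice_thickness": t1_thick,
                    "t1_voxel_resolution": t1_res,
                    "flair_slice_thickness": fl_thick,
                    "flair_voxel_resolution": fl_res,
                }

                vol_off = 0.0
                disc_off = 0.0
                for name, (cv, cd) in effects.items():
                    x = _design_value(name, cov[name])
                    vol_off += cv * x
                    disc_off += cd * x

                vols = (
                    vol_base
                    + v_slope * t
                    + vol_off * vol_conf_scale
                    + rng.normal(0.0, config.noise_sd, size=2 * npairs)
                )
                vols = np.clip(vols, 0.0, None)
                discs = (
                    disc_base
                    + d_slope * t
                    + disc_off * disc_conf_scale
                    + rng.normal(0.0, config.disc_noise_sd, size=2 * npairs)
                )
                discs = np.clip(discs, 0.0, 1.0)

                lesion_obs = max(
                    0, int(round(lesion_true + rng.normal(0.0, config.lesion_count_noise_sd)))
                )
                lesion_vol = max(
                    0.0,
                    lesion_true * config.lesion_vol_per_lesion
                    + rng.normal(0.0, config.lesion_vol_noise_sd),
                )
                total_brain = float(vols.sum())
                tiv = max(tiv0 + rng.normal(0.0, 1000.0), total_brain * 1.05)

                row = {"patient_id": pid, "scan_time_years": float(t)}
                row.update(cov)
                row.update(dict(zip(vol_cols, vols)))
                row.update(dict(zip(disc_cols, discs)))
                row.update(
                    total_brain_vol=total_brain,
                    total_lesion_vol=lesion_vol,
                    lesion_count=lesion_obs,
                    tiv=float(tiv),
                )
                rows.append(row)

    columns = (
        ["patient_id", "scan_time_years"]
        + list(COVARIATE_COLUMNS)
        + vol_cols
        + disc_cols
        + list(GLOBAL_FEATURES)
    )
    scans = pd.DataFrame(rows, columns=columns)
    pairing = RegionPairing.from_feature_columns(scans.columns)
    truth = GroundTruth(
        affected_pairs=affected_pairs,
        slopes=pd.DataFrame(slope_rows, columns=["patient_id", "period", "feature", "slope"]),
    )
    return CohortTable(scans=scans, pairing=pairing, ground_truth=truth)


# --------------------------------------------------------------------------
# I/O

REQUIRED_COLUMNS = ("patient_id", "scan_time_years")


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the long-format cohort CSV (UTF-8, header, '.' decimals)."""
    if len(cohort.scans) == 0:
        raise ValueError("empty cohort")
    cohort.scans.to_csv(path, index=False)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort`.

    Ground truth is not serialised; the returned table carries ``None``.
    """
    scans = pd.read_csv(path)
    if len(scans) == 0:
        raise ValueError("empty cohort")
    for col in REQUIRED_COLUMNS:
        if col not in scans.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    dup = scans.duplicated(subset=["patient_id", "scan_time_years"])
    if dup.any():
        raise ValueError("duplicate (patient_id, scan_time) keys in cohort table")
    pairing = RegionPairing.from_feature_columns(scans.columns)
    return CohortTable(scans=scans, pairing=pairing, ground_truth=None)


def save_config(config: CohortConfig, path) -> None:
    """Write a flat YAML document mirroring the config fields."""
    d = dataclasses.asdict(config)
    d["scans_per_period"] = list(config.scans_per_period)
    d["time_window_years"] = list(config.time_window_years)
    d["confounder_effects"] = {k: list(v) for k, v in config.confounder_effects.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    d["scans_per_period"] = tuple(d["scans_per_period"])
    d["time_window_years"] = tuple(d["time_window_years"])
    d["confounder_effects"] = {
        k: tuple(v) for k, v in (d.get("confounder_effects") or {}).items()
    }
    return CohortConfig(**d)
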