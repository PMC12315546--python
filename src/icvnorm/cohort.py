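"""Synthetic scan-level cohort generator.

Emulates the tabular output of an automated brain-MRI segmentation tool
(one row per 3D scan: subject/visit/scan identifiers, age, self-reported
race, sex, an automatic QC score in [0, 1], and one volume column per ROI
including total intracranial volume).  The generator's defaults are
calibrated to the printed demographics of a 5977-subject hospital cohort:
per-group subject counts and age moments, and per-group ICV means and
standard deviations in litres for the six race x sex cells
(Asian/Black/White x Female/Male).

Generative model (per subject):

* ICV ~ Normal(group mean, group SD), truncated at zero (never binding at
  the default parameters).
* Age ~ Normal(group mean, group SD) truncated to [18, 90]; each extra
  visit adds a small positive gap.
* For each ROI, the subject's deviation from the age trajectory is a
  single Laplace draw shared across that subject's visits; the trajectory
  is ICV x f(age) with f a B-spline in litres-per-litre-of-ICV.  ROIs in
  ``log_normal_rois`` (ventricles by default) instead apply the Laplace
  residual on the log scale, giving the right-skewed volume distributions
  those structures show.
* Each scan adds small Gaussian measurement jitter and draws a QC score;
  a configurable fraction of subjects is planted whose scans all fail the
  QC threshold, to exercise subject exclusion downstream.

All volumes in the emitted table are in millilitres; ``CohortSpec`` ICV
parameters are in litres, mirroring how such tables are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .splines import DEFAULT_AGE_DOMAIN, DEFAULT_CONTROL_AGES, build_basis

RACES: tuple[str, ...] = ("Asian", "Black", "White")
SEXES: tuple[str, ...] = ("Female", "Male")

#: name of the ICV column in scan/subject tables (segmentation-tool style)
ICV_COLUMN = "total intracranial"

ML_PER_L = 1000.0


def ml_to_l(volumes_ml):
    """Millilitres to litres."""
    return np.asarray(volumes_ml, dtype=float) / ML_PER_L


def l_to_ml(volumes_l):
    """Litres to millilitres."""
    return np.asarray(volumes_l, dtype=float) * ML_PER_L


class GroupLabel(NamedTuple):
    """One of the six closed race x sex cells."""

    race: str
    sex: str

    def validate(self) -> "GroupLabel":
        if self.race not in RACES or self.sex not in SEXES:
            raise ValueError(f"unknown group {self!r}; races={RACES}, sexes={SEXES}")
        return self


ALL_GROUPS: tuple[GroupLabel, ...] = tuple(
    GroupLabel(r, s) for r in RACES for s in SEXES
)

# printed cohort statistics used as generator defaults --------------------

#: per-group subject counts (sum to 5977)
DEFAULT_GROUP_SIZES: dict[GroupLabel, int] = {
    GroupLabel("Asian", "Female"): 1058,
    GroupLabel("Asian", "Male"): 733,
    GroupLabel("Black", "Female"): 1213,
    GroupLabel("Black", "Male"): 833,
    GroupLabel("White", "Female"): 1179,
    GroupLabel("White", "Male"): 961,
}

#: per-group ICV mean and SD in litres
DEFAULT_ICV_MEAN_L: dict[GroupLabel, float] = {
    GroupLabel("Asian", "Female"): 1.4078,
    GroupLabel("Asian", "Male"): 1.5753,
    GroupLabel("Black", "Female"): 1.3641,
    GroupLabel("Black", "Male"): 1.5296,
    GroupLabel("White", "Female"): 1.4319,
    GroupLabel("White", "Male"): 1.6144,
}
DEFAULT_ICV_SD_L: dict[GroupLabel, float] = {
    GroupLabel("Asian", "Female"): 0.10769,
    GroupLabel("Asian", "Male"): 0.12189,
    GroupLabel("Black", "Female"): 0.10857,
    GroupLabel("Black", "Male"): 0.12255,
    GroupLabel("White", "Female"): 0.11411,
    GroupLabel("White", "Male"): 0.1277,
}

#: per-group age mean and SD in years
DEFAULT_AGE_MEAN: dict[GroupLabel, float] = {
    GroupLabel("Asian", "Female"): 48.9,
    GroupLabel("Asian", "Male"): 52.3,
    GroupLabel("Black", "Female"): 52.0,
    GroupLabel("Black", "Male"): 53.1,
    GroupLabel("White", "Female"): 55.1,
    GroupLabel("White", "Male"): 55.4,
}
DEFAULT_AGE_SD: dict[GroupLabel, float] = {
    GroupLabel("Asian", "Female"): 18.6,
    GroupLabel("Asian", "Male"): 18.6,
    GroupLabel("Black", "Female"): 18.5,
    GroupLabel("Black", "Male"): 18.1,
    GroupLabel("White", "Female"): 19.0,
    GroupLabel("White", "Male"): 17.7,
}


@dataclass(frozen=True)
class RoiModel:
    """Generative trajectory for one ROI.

    ``control_points`` are spline coefficients in litres of ROI volume per
    litre of ICV at the four anchor ages; ``scale_frac`` is the Laplace
    residual scale as a fraction of the age-specific median volume (for
    log-scale ROIs it is the Laplace scale of the log-volume directly,
    dimensionless).
    """

    control_points: tuple[float, ...]
    scale_frac: float


# plausible adult trajectory shapes (litres per litre of ICV at the anchor
# ages); only the ICV statistics above are calibrated to printed values —
# no per-ROI group medians are published for this cohort
DEFAULT_ROI_MODELS: dict[str, RoiModel] = {
    "whole brain": RoiModel((0.80, 0.77, 0.73, 0.66), 0.040),
    "cerebral cortex": RoiModel((0.315, 0.300, 0.285, 0.260), 0.050),
    "white matter": RoiModel((0.300, 0.310, 0.300, 0.270), 0.050),
    "hippocampus": RoiModel((0.0056, 0.0054, 0.0050, 0.0042), 0.060),
    "amygdala": RoiModel((0.0024, 0.0024, 0.0023, 0.0021), 0.060),
    "thalamus": RoiModel((0.0105, 0.0100, 0.0094, 0.0085), 0.050),
    "brainstem": RoiModel((0.0190, 0.0190, 0.0188, 0.0185), 0.050),
    "ventricles": RoiModel((0.008, 0.012, 0.020, 0.034), 0.40),
}

#: fraction of subjects planted with all-failing scans (23 of 6000
#: candidates had no scan passing QC in the emulated cohort)
DEFAULT_ALL_FAIL_FRACTION = 23.0 / 6000.0


@dataclass(frozen=True)
class CohortSpec:
    """Complete generative description of a synthetic cohort."""

    group_sizes: dict[GroupLabel, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    icv_mean_l: dict[GroupLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_ICV_MEAN_L)
    )
    icv_sd_l: dict[GroupLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_ICV_SD_L)
    )
    age_mean: dict[GroupLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_MEAN)
    )
    age_sd: dict[GroupLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_SD)
    )
    age_bounds: tuple[float, float] = DEFAULT_AGE_DOMAIN
    roi_models: dict[str, RoiModel] = field(
        default_factory=lambda: dict(DEFAULT_ROI_MODELS)
    )
    log_normal_rois: frozenset[str] = frozenset({"ventricles"})
    scans_per_visit_range: tuple[int, int] = (1, 4)
    visits_per_subject_range: tuple[int, int] = (1, 3)
    qc_beta: tuple[float, float] = (2.0, 2.0)
    qc_threshold: float = 0.75
    all_fail_fraction: float = DEFAULT_ALL_FAIL_FRACTION
    scan_jitter_frac: float = 0.05
    control_ages: tuple[float, ...] = DEFAULT_CONTROL_AGES
    spline_degree: int = 3
    misspecified: bool = False  # piecewise-linear truth instead of spline
    seed: int = 0

    def validate(self) -> "CohortSpec":
        for g in self.group_sizes:
            GroupLabel(*g).validate()
            if self.group_sizes[g] < 0:
                raise ValueError(f"negative group size for {g}")
        for g in self.group_sizes:
            for name, d in (
                ("icv_mean_l", self.icv_mean_l),
                ("icv_sd_l", self.icv_sd_l),
                ("age_mean", self.age_mean),
                ("age_sd", self.age_sd),
            ):
                if g not in d:
                    raise ValueError(f"{name} missing entry for group {g}")
        if any(sd <= 0 for sd in self.icv_sd_l.values()):
            raise ValueError("ICV SDs must be positive")
        if any(sd <= 0 for sd in self.age_sd.values()):
            raise ValueError("age SDs must be positive")
        lo, hi = self.age_bounds
        if not (18.0 <= lo < hi <= 90.0):
            raise ValueError("age bounds must lie within [18, 90]")
        unknown = set(self.log_normal_rois) - set(self.roi_models)
        if unknown:
            raise ValueError(f"log_normal_rois not in roi_models: {sorted(unknown)}")
        for rng_name, rng_val in (
            ("scans_per_visit_range", self.scans_per_visit_range),
            ("visits_per_subject_range", self.visits_per_subject_range),
        ):
            if rng_val[0] < 1 or rng_val[1] < rng_val[0]:
                raise ValueError(f"invalid {rng_name}: {rng_val}")
        if not 0.0 <= self.all_fail_fraction < 1.0:
            raise ValueError("all_fail_fraction must be in [0, 1)")
        if not 0.0 < self.qc_threshold < 1.0:
            raise ValueError("qc_threshold must be in (0, 1)")
        return self

    def with_(self, **kwargs) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def trajectory_basis(self):
        return build_basis(self.control_ages, self.spline_degree, self.age_bounds)


def _trajectory_fraction(spec: CohortSpec, roi: str, ages) -> np.ndarray:
    """Litres-of-ROI per litre-of-ICV at the given ages."""
    model = spec.roi_models[roi]
    a = np.atleast_1d(np.asarray(ages, dtype=float))
    if spec.misspecified:
        # piecewise-linear through the control points, clamped outside
        return np.interp(a, spec.control_ages, model.control_points)
    basis = spec.trajectory_basis()
    return basis.evaluate(np.asarray(model.control_points, dtype=float), a)


def true_trajectory(spec: CohortSpec, roi: str, group: GroupLabel, age):
    """Exact generative (location, scale) for one ROI/group at ``age``.

    For additive ROIs both are in millilitres (location is the median of
    the subject-level volume; the scale is the Laplace residual scale).
    For log-scale ROIs they describe the log-millilitre distribution:
    location ``ln(median mL)``, scale dimensionless.  Pure function; the
    ground-truth accessor for parameter-recovery tests.
    """
    group = GroupLabel(*group).validate()
    if roi not in spec.roi_models:
        raise KeyError(f"unknown ROI {roi!r}")
    if group not in spec.group_sizes:
        raise KeyError(f"group {group} not in spec.group_sizes")
    med_ml = l_to_ml(spec.icv_mean_l[group] * _trajectory_fraction(spec, roi, age))
    frac = spec.roi_models[roi].scale_frac
    if roi in spec.log_normal_rois:
        return np.log(med_ml), np.full_like(med_ml, frac)
    return med_ml, frac * med_ml


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draws truncated to [lo, hi] by rejection (vectorized)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a scan-level table from the spec; deterministic given the seed.

    Returns one row per scan with columns ``subject_id, visit_id, scan_id,
    age, sex, race, qc`` followed by one column per ROI and the
    ``"total intracranial"`` ICV column, volumes in millilitres.
    """
    spec.validate()
    if sum(spec.group_sizes.values()) == 0:
        raise ValueError("empty cohort: all group sizes are zero")
    rng = np.random.default_rng(spec.seed)
    roi_names = list(spec.roi_models)
    lo, hi = spec.age_bounds
    qa, qb = spec.qc_beta
    rows: list[dict] = []
    for gi, group in enumerate(ALL_GROUPS):
        n_sub = spec.group_sizes.get(group, 0)
        if n_sub == 0:
            continue
        icv_ml = l_to_ml(
            _truncated_normal(
                rng, spec.icv_mean_l[group], spec.icv_sd_l[group],
                0.0, np.inf, n_sub,
            )
        )
        base_age = _truncated_normal(
            rng, spec.age_mean[group], spec.age_sd[group], lo, hi, n_sub
        )
        for si in range(n_sub):
            sid = f"S{gi}{si:05d}"
            n_visits = int(
                rng.integers(
                    spec.visits_per_subject_range[0],
                    spec.visits_per_subject_range[1] + 1,
                )
            )
            gaps = rng.uniform(0.3, 2.0, n_visits - 1) if n_visits > 1 else []
            visit_ages = np.clip(base_age[si] + np.concatenate([[0.0], np.cumsum(gaps)]), lo, hi)
            all_fail = rng.random() < spec.all_fail_fraction
            # one residual per ROI per subject (between-subject spread)
            z = {roi: rng.laplace(0.0, 1.0) for roi in roi_names}
            for vi in range(n_visits):
                vid = f"{sid}v{vi}"
                age = float(visit_ages[vi])
                frac = {
                    roi: float(_trajectory_fraction(spec, roi, age)[0])
                    for roi in roi_names
                }
                n_scans = int(
                    rng.integers(
                        spec.scans_per_visit_range[0],
                        spec.scans_per_visit_range[1] + 1,
                    )
                )
                for ki in range(n_scans):
                    vols: dict[str, float] = {ICV_COLUMN: float(icv_ml[si])}
                    for roi in roi_names:
                        m = spec.roi_models[roi]
                        med = icv_ml[si] * frac[roi]
                        zr = z[roi]
                        while True:
                            jit = rng.normal(0.0, spec.scan_jitter_frac)
                            if roi in spec.log_normal_rois:
                                vol = med * np.exp(m.scale_frac * (zr + jit))
                            else:
                                b = m.scale_frac * med
                                vol = med + b * (zr + jit)
                            if 0.0 < vol < icv_ml[si]:
                                break
                            # invariant 0 < volume < ICV: redraw the
                            # subject residual (vanishingly rare at defaults)
                            zr = rng.laplace(0.0, 1.0)
                        vols[roi] = float(vol)
                    if all_fail:
                        qc = spec.qc_threshold * rng.beta(qa, qb)
                    else:
                        qc = spec.qc_threshold + (1.0 - spec.qc_threshold) * rng.beta(qa, qb)
                    rows.append(
                        {
                            "subject_id": sid,
                            "visit_id": vid,
                            "scan_id": f"{vid}s{ki}",
                            "age": age,
                            "sex": group.sex,
                            "race": group.race,
                            "qc": float(qc),
                            **vols,
                        }
                    )
    columns = (
        ["subject_id", "visit_id", "scan_id", "age", "sex", "race", "qc"]
        + roi_names
        + [ICV_COLUMN]
    )
    return pd.DataFrame(rows, columns=columns)


def planted_all_fail_subjects(spec: CohortSpec, scans: pd.DataFrame) -> list[str]:
    """Subjects whose scans were all planted below the QC threshold."""
    by_subj = scans.groupby("subject_id")["qc"].max()
    return sorted(by_subj.index[by_subj <= spec.qc_threshold])


def write_cohort_csv(scans: pd.DataFrame, path) -> None:
    """Write the scan table as UTF-8 CSV with a header row."""
    scans.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a scan table written by :func:`write_cohort_csv` (or any
    segmentation-tool-style per-scan CSV with the same columns)."""
    df = pd.read_csv(path)
    required = {"subject_id", "visit_id", "scan_id", "age", "sex", "race", "qc", ICV_COLUMN}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scan CSV missing columns: {sorted(missing)}")
    return df
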