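"""ICV-correction schemes for subject-level ROI volumes.

The primary scheme is direct division: each volume is divided by the
subject's intracranial volume and multiplied by the cohort-mean ICV, which
removes proportional head-size effects while preserving the mean volume
and the original units.  Three comparison schemes from the normalization
literature are provided: residual (subtracting a robustly estimated linear
ICV dependence), covariate (a token routing ICV into the trajectory model
as a nuisance regressor), and matching (head-size-balanced subsets of two
groups).  Ventricular volumes are right-skewed, so they are modelled on
the log scale via :func:`log_transform`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ICV_COLUMN, GroupLabel
from .qc import volume_columns

#: token consumed by the pipeline/model: handle ICV as a nuisance
#: regressor inside the trajectory fit instead of pre-correcting volumes
COVARIATE_ICV = "icv-covariate"


def covariate_adjust_flag() -> str:
    """Return the covariate-adjustment configuration token."""
    return COVARIATE_ICV


@dataclass
class NormalizedCohort:
    """Subject records after an ICV-correction scheme.

    ``reference_mean_icv`` is the unweighted mean ICV of the input cohort,
    in the records' own unit (millilitres for generated cohorts).
    """

    records: pd.DataFrame
    method: str
    reference_mean_icv: float
    matched_ids: list[str] | None = None
    matching_report: pd.DataFrame | None = None
    residual_slopes: dict[str, float] = field(default_factory=dict)


def _check_icv(subjects: pd.DataFrame) -> pd.Series:
    icv = subjects[ICV_COLUMN]
    bad = subjects.loc[icv <= 0, "subject_id"]
    if len(bad):
        raise ValueError(f"nonpositive ICV for subjects: {list(bad)[:5]}")
    return icv


def divide_normalize(subjects: pd.DataFrame) -> NormalizedCohort:
    """Division correction: ``v' = (v / ICV) * mean(ICV)``.

    The mean is the unweighted grand mean over all subjects (a group-
    stratified mean would reintroduce group offsets by construction).  The
    ICV column itself maps to the constant mean, so a second application is
    the identity.
    """
    icv = _check_icv(subjects)
    mean_icv = float(icv.mean())
    out = subjects.copy()
    for col in volume_columns(subjects):
        out[col] = subjects[col] / icv * mean_icv
    return NormalizedCohort(records=out, method="division", reference_mean_icv=mean_icv)


def residual_normalize(
    subjects: pd.DataFrame, reference: pd.DataFrame | None = None
) -> NormalizedCohort:
    """Residual correction: ``v' = v - slope * (ICV - mean(ICV))``.

    The slope of each ROI on ICV is the least-absolute-deviation (median
    regression) estimate on the reference subset — robust, and coherent
    with the Laplace trajectory model.  Defaults to the whole cohort as
    reference.  The ICV column is left unchanged.
    """
    if reference is None:
        reference = subjects
    if len(reference) == 0:
        raise ValueError("reference subset is empty")
    icv_ref = np.asarray(reference[ICV_COLUMN], dtype=float)
    if np.ptp(icv_ref) == 0.0:
        raise ValueError("reference ICV is constant; slope is unidentifiable")
    icv = _check_icv(subjects)
    mean_icv = float(icv.mean())
    X = sm.add_constant(icv_ref)
    out = subjects.copy()
    slopes: dict[str, float] = {}
    for col in volume_columns(subjects):
        if col == ICV_COLUMN:
            continue
        qr = sm.QuantReg(np.asarray(reference[col], dtype=float), X)
        slope = float(qr.fit(q=0.5).params[1])
        slopes[col] = slope
        out[col] = subjects[col] - slope * (icv - mean_icv)
    return NormalizedCohort(
        records=out, method="residual", reference_mean_icv=mean_icv,
        residual_slopes=slopes,
    )


def match_groups(
    subjects: pd.DataFrame,
    group_a: GroupLabel,
    group_b: GroupLabel,
    caliper: float,
) -> NormalizedCohort:
    """Greedy 1:1 nearest-neighbour ICV matching without replacement.

    ``caliper`` is the maximum allowed ICV distance for a pair, in the
    table's volume unit.  Volumes are never altered — the result is the
    matched subset of rows, with a pair list and the post-matching
    standardized mean ICV difference in ``matching_report``.  An empty
    matched set triggers a warning, not an error.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    group_a, group_b = GroupLabel(*group_a).validate(), GroupLabel(*group_b).validate()
    icv = _check_icv(subjects)
    mean_icv = float(icv.mean())

    def _rows(g: GroupLabel) -> pd.DataFrame:
        sel = (subjects["race"] == g.race) & (subjects["sex"] == g.sex)
        return subjects[sel]

    a_rows, b_rows = _rows(group_a), _rows(group_b)
    if len(a_rows) == 0 or len(b_rows) == 0:
        raise ValueError("both groups must be nonempty")

    a_rows = a_rows.sort_values("subject_id")  # deterministic processing order
    b_icv = np.asarray(b_rows[ICV_COLUMN], dtype=float)
    b_ids = list(b_rows["subject_id"])
    available = np.ones(len(b_rows), dtype=bool)
    pairs: list[tuple[str, str, float]] = []
    for _, row in a_rows.iterrows():
        if not available.any():
            break
        dist = np.abs(b_icv - row[ICV_COLUMN])
        dist[~available] = np.inf
        j = int(np.argmin(dist))  # ties: first (lowest) index of sorted b
        if dist[j] <= caliper:
            available[j] = False
            pairs.append((row["subject_id"], b_ids[j], float(dist[j])))

    if not pairs:
        warnings.warn(
            f"no ICV matches within caliper {caliper} between {group_a} and {group_b}",
            UserWarning,
            stacklevel=2,
        )
        report = pd.DataFrame(columns=["a_id", "b_id", "icv_distance"])
        smd = np.nan
    else:
        report = pd.DataFrame(pairs, columns=["a_id", "b_id", "icv_distance"])
        icv_a = subjects.set_index("subject_id").loc[report["a_id"], ICV_COLUMN].to_numpy()
        icv_b = subjects.set_index("subject_id").loc[report["b_id"], ICV_COLUMN].to_numpy()
        pooled_sd = np.sqrt((icv_a.var(ddof=1) + icv_b.var(ddof=1)) / 2.0) if len(pairs) > 1 else np.nan
        smd = float((icv_a.mean() - icv_b.mean()) / pooled_sd) if pooled_sd else np.nan
    report.attrs["standardized_mean_difference"] = smd

    matched_ids = [p[0] for p in pairs] + [p[1] for p in pairs]
    matched = subjects[subjects["subject_id"].isin(matched_ids)]
    return NormalizedCohort(
        records=matched, method="matching", reference_mean_icv=mean_icv,
        matched_ids=matched_ids, matching_report=report,
    )


def log_transform(subjects: pd.DataFrame, rois) -> pd.DataFrame:
    """Replace the listed ROI volumes by their natural logarithm.

    The applied set is recorded in ``df.attrs["log_rois"]`` so reports can
    invert the transform; an empty set is the identity.  Nonpositive
    volumes are an error.
    """
    rois = sorted(set(rois))
    unknown = [r for r in rois if r not in subjects.columns]
    if unknown:
        raise KeyError(f"unknown ROI columns: {unknown}")
    out = subjects.copy()
    for roi in rois:
        if (out[roi] <= 0).any():
            raise ValueError(f"nonpositive volumes in {roi!r}; cannot log-transform")
        out[roi] = np.log(out[roi])
    out.attrs["log_rois"] = tuple(rois)
    return out


def invert_log_transform(subjects: pd.DataFrame) -> pd.DataFrame:
    """Undo :func:`log_transform` using the recorded ROI set."""
    rois = subjects.attrs.get("log_rois", ())
    out = subjects.copy()
    for roi in rois:
        out[roi] = np.exp(out[roi])
    out.attrs["log_rois"] = ()
    return out
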