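"""Scan-to-subject reduction: QC filtering, top-k selection, averaging.

The analysis uses one record per subject.  Scans with an automatic QC
score strictly greater than 0.75 are kept; if a session (visit) has more
than three passing scans, the three with the highest scores are used.  ROI
volumes are averaged over the retained scans of a visit, and then volumes
and ages are averaged over visits with equal weight, so a subject's
estimate does not depend on how many times they were scanned.  Subjects
with no passing scan in any visit are excluded (and logged), not emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ICV_COLUMN

DEFAULT_QC_THRESHOLD = 0.75
DEFAULT_TOP_K = 3

_META_COLUMNS = ("subject_id", "visit_id", "scan_id", "age", "sex", "race", "qc")


def volume_columns(scans: pd.DataFrame) -> list[str]:
    """ROI volume columns of a scan/subject table (ICV included, last)."""
    cols = [c for c in scans.columns if c not in _META_COLUMNS
            and c not in ("n_scans_used", "n_visits_used")]
    if ICV_COLUMN in cols:  # keep ICV last for readability
        cols = [c for c in cols if c != ICV_COLUMN] + [ICV_COLUMN]
    return cols


def filter_scans(scans: pd.DataFrame, qc_threshold: float = DEFAULT_QC_THRESHOLD) -> pd.DataFrame:
    """Scans with QC score strictly greater than the threshold.

    Order-stable; an empty result is legal.
    """
    if not 0.0 <= qc_threshold <= 1.0:
        raise ValueError("qc_threshold must be in [0, 1]")
    return scans[scans["qc"] > qc_threshold]


def select_top_scans(scans_of_one_visit: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """The ``k`` scans of one visit with the highest QC scores.

    If the visit has at most ``k`` scans, all are returned.  Ties at the
    k-th rank break by ``scan_id`` lexicographic order for determinism.
    All rows must share one subject and one visit.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(scans_of_one_visit) == 0:
        return scans_of_one_visit
    if (
        scans_of_one_visit["subject_id"].nunique() > 1
        or scans_of_one_visit["visit_id"].nunique() > 1
    ):
        raise ValueError("select_top_scans expects scans of a single visit")
    ranked = scans_of_one_visit.sort_values(
        ["qc", "scan_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k)


def aggregate_subjects(
    scans: pd.DataFrame,
    *,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
    pooled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce a scan table to one row per subject.

    Returns ``(subjects, exclusions)``.  ``subjects`` has columns
    ``subject_id, sex, race, age, n_scans_used, n_visits_used`` plus the
    volume columns (means).  ``exclusions`` lists subjects with no passing
    scans (columns ``subject_id, reason``).

    By default averaging is two-stage (scans within a visit, then visits
    with equal weight); ``pooled=True`` instead averages all retained scans
    directly, weighting visits by their scan counts.
    """
    # exact duplicate rows are the same physical scan listed twice
    scans = scans.drop_duplicates()
    vol_cols = volume_columns(scans)
    groups = scans.groupby("subject_id")[["sex", "race"]].nunique()
    bad = groups.index[(groups["sex"] > 1) | (groups["race"] > 1)]
    if len(bad):
        raise ValueError(f"conflicting group labels for subjects: {list(bad)[:5]}")

    passing = filter_scans(scans, qc_threshold)
    retained = (
        passing.groupby(["subject_id", "visit_id"], group_keys=False, sort=False)[passing.columns]
        .apply(select_top_scans, k=top_k)
    )

    records = []
    for sid, sub in retained.groupby("subject_id", sort=True):
        if pooled:
            vols = sub[vol_cols].mean()
            age = sub["age"].mean()
            n_visits = sub["visit_id"].nunique()
        else:
            per_visit = sub.groupby("visit_id")[vol_cols + ["age"]].mean()
            vols = per_visit[vol_cols].mean()
            age = per_visit["age"].mean()
            n_visits = len(per_visit)
        records.append(
            {
                "subject_id": sid,
                "sex": sub["sex"].iloc[0],
                "race": sub["race"].iloc[0],
                "age": float(age),
                "n_scans_used": int(len(sub)),
                "n_visits_used": int(n_visits),
                **{c: float(vols[c]) for c in vol_cols},
            }
        )
    subjects = pd.DataFrame(
        records,
        columns=["subject_id", "sex", "race", "age", "n_scans_used", "n_visits_used"]
        + vol_cols,
    )
    all_ids = pd.unique(scans["subject_id"])
    kept = set(subjects["subject_id"])
    excluded = sorted(sid for sid in all_ids if sid not in kept)
    exclusions = pd.DataFrame(
        {"subject_id": excluded, "reason": ["no_scans_passed_qc"] * len(excluded)},
        columns=["subject_id", "reason"],
    )
    return subjects, exclusions
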