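"""End-to-end orchestration: simulate/ingest -> aggregate -> normalize ->
fit -> effect sizes -> reports.

``run_pipeline`` drives the whole analysis from a :class:`PipelineConfig`
and writes a reproducible bundle: per-subject table, per-ROI-per-group fit
JSONs, effect-size tables, the group summary table with its ICV ratio
block, and a manifest recording the config hash, seed and every output
file.  ``group_summary_table`` / ``icv_ratio_block`` also work directly on
printed cohort statistics, so reported tables can be pushed through the
same arithmetic the pipeline uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    ICV_COLUMN,
    RACES,
    SEXES,
    CohortSpec,
    GroupLabel,
    RoiModel,
    generate_cohort,
    ml_to_l,
    read_cohort_csv,
    write_cohort_csv,
)
from .effects import max_effect_size, normalization_effect_ratio
from .model import FitWarning, fit as fit_model
from .normalization import (
    COVARIATE_ICV,
    divide_normalize,
    log_transform,
    residual_normalize,
)
from .qc import DEFAULT_QC_THRESHOLD, DEFAULT_TOP_K, aggregate_subjects
from .splines import DEFAULT_CONTROL_AGES, build_basis

logger = logging.getLogger("icvnorm")

NORMALIZATION_METHODS = ("none", "division", "residual", "covariate")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; defaults are the analysis' stated
    settings (QC > 0.75, top-3 scans, division correction, log ventricles,
    cubic splines anchored at ages 27/45/63/81)."""

    cohort: CohortSpec | None = None  # generate ...
    input_csv: str | None = None  # ... or ingest
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    top_k: int = DEFAULT_TOP_K
    normalization: str = "division"
    log_rois: tuple[str, ...] = ("ventricles",)
    log_before_division: bool = False  # sensitivity flag; default log-after
    control_ages: tuple[float, ...] = DEFAULT_CONTROL_AGES
    spline_degree: int = 3
    rois: tuple[str, ...] | None = None  # None = all volume columns but ICV
    age_grid_step: float = 1.0
    output_dir: str = "icvnorm_output"
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> "PipelineConfig":
        if (self.cohort is None) == (self.input_csv is None):
            raise ValueError("provide exactly one of cohort spec or input CSV")
        if self.normalization not in NORMALIZATION_METHODS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATION_METHODS}"
            )
        if not 0.0 <= self.qc_threshold <= 1.0:
            raise ValueError("qc_threshold must be in [0, 1]")
        return self

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = _spec_to_jsonable(self.cohort)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# -- cohort spec serialization -------------------------------------------

def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    for key in ("group_sizes", "icv_mean_l", "icv_sd_l", "age_mean", "age_sd"):
        d[key] = {f"{g[0]}/{g[1]}": v for g, v in d[key].items()}
    d["roi_models"] = {
        name: {"control_points": list(m["control_points"]), "scale_frac": m["scale_frac"]}
        for name, m in d["roi_models"].items()
    }
    d["log_normal_rois"] = sorted(spec.log_normal_rois)
    for key in ("age_bounds", "scans_per_visit_range", "visits_per_subject_range",
                "qc_beta", "control_ages"):
        d[key] = list(d[key])
    return d


def _spec_from_jsonable(d: dict) -> CohortSpec:
    kwargs = dict(d)
    for key in ("group_sizes", "icv_mean_l", "icv_sd_l", "age_mean", "age_sd"):
        if key in kwargs:
            kwargs[key] = {
                GroupLabel(*k.split("/")): v for k, v in kwargs[key].items()
            }
    if "roi_models" in kwargs:
        kwargs["roi_models"] = {
            name: RoiModel(tuple(m["control_points"]), m["scale_frac"])
            for name, m in kwargs["roi_models"].items()
        }
    if "log_normal_rois" in kwargs:
        kwargs["log_normal_rois"] = frozenset(kwargs["log_normal_rois"])
    for key in ("age_bounds", "scans_per_visit_range", "visits_per_subject_range",
                "qc_beta", "control_ages"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return CohortSpec(**kwargs).validate()


def cohort_spec_template() -> str:
    """YAML text of a default cohort spec (all calibrated defaults printed)."""
    return yaml.safe_dump(_spec_to_jsonable(CohortSpec()), sort_keys=False)


def load_cohort_spec(path) -> CohortSpec:
    """Read a cohort spec from a YAML (or JSON) config file."""
    with open(path, encoding="utf-8") as fh:
        return _spec_from_jsonable(yaml.safe_load(fh))


def save_cohort_spec(spec: CohortSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_spec_to_jsonable(spec), fh, sort_keys=False)


# -- summary tables -------------------------------------------------------

def group_summary_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Counts, age mean +/- SD and ICV mean +/- SD per race x sex cell.

    ICV is reported in litres.  Cells absent from the data are omitted.
    """
    rows = []
    for race in RACES:
        for sex in SEXES:
            cell = subjects[(subjects["race"] == race) & (subjects["sex"] == sex)]
            if len(cell) == 0:
                continue
            icv_l = ml_to_l(cell[ICV_COLUMN])
            rows.append(
                {
                    "race": race,
                    "sex": sex,
                    "n": len(cell),
                    "age_mean": float(cell["age"].mean()),
                    "age_sd": float(cell["age"].std(ddof=1)) if len(cell) > 1 else np.nan,
                    "icv_mean_l": float(np.mean(icv_l)),
                    "icv_sd_l": float(np.std(icv_l, ddof=1)) if len(cell) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["race", "sex", "n", "age_mean", "age_sd",
                                       "icv_mean_l", "icv_sd_l"])


_RACE_PAIRS = (("Asian", "Black"), ("Black", "White"), ("Asian", "White"))


def icv_ratio_block(summary: pd.DataFrame) -> dict[str, float]:
    """The in-text ICV ratio block from a group summary table.

    Expects columns ``race, sex, n, icv_mean_l`` (as produced by
    :func:`group_summary_table`, or built directly from printed cohort
    statistics).  Returns per-race male/female ratios, per-sex race
    ratios (Asian/Black, Black/White, Asian/White) and the count-weighted
    global male/female ratio.  Empty cells yield ``nan`` entries, never an
    error.
    """
    cells = {
        (r.race, r.sex): (float(r.icv_mean_l), int(r.n))
        for r in summary.itertuples()
    }

    def mean_of(race, sex):
        return cells.get((race, sex), (np.nan, 0))[0]

    ratios: dict[str, float] = {}
    for race in RACES:
        ratios[f"male_female_{race}"] = mean_of(race, "Male") / mean_of(race, "Female")
    for sex in SEXES:
        for r1, r2 in _RACE_PAIRS:
            ratios[f"{r1}_{r2}_{sex}".lower()] = mean_of(r1, sex) / mean_of(r2, sex)
    weighted = {}
    for sex in SEXES:
        pairs = [cells[(race, sex)] for race in RACES if (race, sex) in cells]
        tot = sum(n for _, n in pairs)
        weighted[sex] = (
            sum(m * n for m, n in pairs) / tot if tot else np.nan
        )
    ratios["male_female_global"] = weighted["Male"] / weighted["Female"]
    return ratios


def format_ratio_block(ratios: dict[str, float]) -> dict[str, float]:
    """Printing convention: 3 decimals per-group, 2 for the global ratio."""
    return {
        k: round(v, 2 if k == "male_female_global" else 3)
        for k, v in ratios.items()
    }


# -- pipeline -------------------------------------------------------------

@dataclass
class PipelineResult:
    subjects: pd.DataFrame
    exclusions: pd.DataFrame
    summary: pd.DataFrame
    ratios: dict[str, float]
    fits_raw: dict
    fits_corrected: dict
    effects_raw: pd.DataFrame
    effects_corrected: pd.DataFrame
    effects_summary: pd.DataFrame
    manifest: dict
    output_dir: Path


def _fit_groups(subjects, rois, log_rois, basis, covariate_mode, warnings_log):
    """One Laplace spline fit per (ROI, race x sex group)."""
    fits: dict[str, dict[GroupLabel, object]] = {roi: {} for roi in rois}
    for race in RACES:
        for sex in SEXES:
            cell = subjects[(subjects["race"] == race) & (subjects["sex"] == sex)]
            if len(cell) == 0:
                continue
            group = GroupLabel(race, sex)
            ages = cell["age"].to_numpy()
            icv = cell[ICV_COLUMN].to_numpy() if covariate_mode else None
            for roi in rois:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always", FitWarning)
                    f = fit_model(
                        ages,
                        cell[roi].to_numpy(),
                        basis,
                        covariate=icv,
                        roi=roi,
                        group=(race, sex),
                        log_transformed=roi in log_rois,
                    )
                for w in caught:
                    msg = f"{roi} {race}/{sex}: {w.message}"
                    warnings_log.append(msg)
                    logger.warning(msg)
                fits[roi][group] = f
    return fits


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle.

    Deterministic given the config (the only randomness is the cohort
    seed).  Partial failures (a non-converged fit) are recorded in the
    manifest's warning list, never dropped silently.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "fits").mkdir(exist_ok=True)
    outputs: list[str] = []
    warnings_log: list[str] = []

    # 1) obtain scans
    if config.cohort is not None:
        spec = config.cohort.with_(seed=config.seed)
        scans = generate_cohort(spec)
        write_cohort_csv(scans, out / "scans.csv")
        outputs.append("scans.csv")
    else:
        scans = read_cohort_csv(config.input_csv)

    # 2) aggregate to subjects
    subjects, exclusions = aggregate_subjects(
        scans, qc_threshold=config.qc_threshold, top_k=config.top_k
    )
    subjects.to_csv(out / "subjects.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    outputs += ["subjects.csv", "exclusions.csv"]

    # 3) summary table + ratio block (pre-normalization, raw ICV)
    summary = group_summary_table(subjects)
    ratios = icv_ratio_block(summary)
    summary.to_csv(out / "group_summary.csv", index=False)
    outputs.append("group_summary.csv")

    # 4) normalize
    rois = list(config.rois) if config.rois else [
        c for c in subjects.columns
        if c not in ("subject_id", "sex", "race", "age", "n_scans_used",
                     "n_visits_used", ICV_COLUMN)
    ]
    log_rois = tuple(r for r in config.log_rois if r in rois)
    covariate_mode = config.normalization == "covariate"
    raw = log_transform(subjects, log_rois)
    if config.normalization == "division":
        if config.log_before_division:
            corrected = divide_normalize(subjects).records
            corrected = log_transform(corrected, log_rois)
        else:
            corrected = log_transform(divide_normalize(subjects).records, log_rois)
    elif config.normalization == "residual":
        corrected = log_transform(residual_normalize(subjects).records, log_rois)
    else:  # none or covariate: volumes unchanged
        corrected = raw

    # 5) fit trajectories (raw always; corrected when a method is active)
    basis = build_basis(config.control_ages, config.spline_degree)
    fits_raw = _fit_groups(raw, rois, log_rois, basis, False, warnings_log)
    fits_corrected = _fit_groups(
        corrected, rois, log_rois, basis, covariate_mode, warnings_log
    )
    for fits, tag in ((fits_raw, "raw"), (fits_corrected, "corrected")):
        for roi in rois:
            for group, f in fits[roi].items():
                name = f"fits/{roi.replace(' ', '_')}__{group.race}_{group.sex}__{tag}.json"
                f.to_json(out / name)
                outputs.append(name)

    # 6) effect sizes
    step = config.age_grid_step
    lo, hi = basis.domain
    grid = np.arange(np.ceil(lo), np.floor(hi) + step / 2, step)
    eff_raw_frames, eff_corr_frames, summary_rows = [], [], []
    for roi in rois:
        if len(fits_raw[roi]) < 2:
            continue
        s_raw = max_effect_size(fits_raw[roi], grid)
        s_corr = max_effect_size(fits_corrected[roi], grid)
        eff_raw_frames.append(s_raw.to_frame())
        eff_corr_frames.append(s_corr.to_frame())
        ratio_df = normalization_effect_ratio(fits_raw[roi], fits_corrected[roi], grid)
        for c_raw, row in zip(s_raw.curves, ratio_df.itertuples()):
            summary_rows.append(
                {
                    "roi": roi,
                    "pair": row.pair,
                    "d_max_raw": row.d_max_raw,
                    "age_at_max_raw": c_raw.age_at_max,
                    "d_max_corrected": row.d_max_corrected,
                    "ratio_raw_over_corrected": row.ratio,
                    "infinite_ratio": row.infinite,
                }
            )
    effects_raw = pd.concat(eff_raw_frames, ignore_index=True) if eff_raw_frames else pd.DataFrame()
    effects_corrected = pd.concat(eff_corr_frames, ignore_index=True) if eff_corr_frames else pd.DataFrame()
    effects_summary = pd.DataFrame(summary_rows)
    effects_raw.to_csv(out / "effects_raw.csv", index=False)
    effects_corrected.to_csv(out / "effects_corrected.csv", index=False)
    effects_summary.to_csv(out / "effects_summary.csv", index=False)
    outputs += ["effects_raw.csv", "effects_corrected.csv", "effects_summary.csv"]

    if config.make_plots:
        outputs += _plot_trajectories(out, fits_raw, fits_corrected, rois, grid)

    # 7) manifest
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "normalization": config.normalization,
        "n_subjects": int(len(subjects)),
        "n_excluded": int(len(exclusions)),
        "ratio_block": format_ratio_block(ratios),
        "warnings": warnings_log,
        "outputs": sorted(outputs + ["manifest.json"]),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        subjects=subjects,
        exclusions=exclusions,
        summary=summary,
        ratios=ratios,
        fits_raw=fits_raw,
        fits_corrected=fits_corrected,
        effects_raw=effects_raw,
        effects_corrected=effects_corrected,
        effects_summary=effects_summary,
        manifest=manifest,
        output_dir=out,
    )


def _plot_trajectories(out, fits_raw, fits_corrected, rois, grid):
    """Optional per-ROI band plots (before/after correction)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for roi in rois:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, fits, title in (
            (axes[0], fits_raw[roi], "before ICV correction"),
            (axes[1], fits_corrected[roi], "after ICV correction"),
        ):
            for group, f in fits.items():
                mu, b, lob, upb = f.predict(grid)
                (line,) = ax.plot(grid, mu, label=f"{group.race} {group.sex}")
                ax.fill_between(grid, lob, upb, alpha=0.12, color=line.get_color())
            ax.set_title(f"{roi} — {title}")
            ax.set_xlabel("age (years)")
        axes[0].set_ylabel("volume (mL)")
        axes[0].legend(fontsize=7)
        name = f"trajectories_{roi.replace(' ', '_')}.png"
        fig.tight_layout()
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        written.append(name)
    return written
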