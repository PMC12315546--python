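"""Effect sizes between group trajectories, before and after correction.

d(a) = 2|mu1 - mu2| / (b1 + b2) compares two groups' medians in units of
their pooled Laplace scale.  On a cohort whose volumes are proportional to
head size, ICV division collapses the sex differences: the maximum effect
size drops by well over a factor of 2.
"""

import warnings

import numpy as np

from icvnorm import (
    CohortSpec,
    aggregate_subjects,
    divide_normalize,
    generate_cohort,
    normalization_effect_ratio,
)
from icvnorm.cohort import DEFAULT_GROUP_SIZES, RoiModel
from icvnorm.model import FitWarning
from icvnorm.pipeline import _fit_groups
from icvnorm.splines import build_basis

spec = CohortSpec(
    group_sizes={g: 1000 for g in DEFAULT_GROUP_SIZES},
    roi_models={"roi": RoiModel((0.05,) * 4, 0.05)},
    log_normal_rois=frozenset(),
    visits_per_subject_range=(1, 1),
    scans_per_visit_range=(1, 1),
    all_fail_fraction=0.0,
    seed=5,
)
subjects, _ = aggregate_subjects(generate_cohort(spec))
corrected = divide_normalize(subjects).records

basis = build_basis()
with warnings.catch_warnings():
    warnings.simplefilter("ignore", FitWarning)
    fits_raw = _fit_groups(subjects, ["roi"], (), basis, False, [])
    fits_corr = _fit_groups(corrected, ["roi"], (), basis, False, [])

table = normalization_effect_ratio(fits_raw["roi"], fits_corr["roi"])
print(table[["pair", "d_max_raw", "d_max_corrected", "ratio"]]
      .to_string(index=False, float_format=lambda x: f"{x:6.2f}"))
print("-> sex pairs start near d~2 (head-size driven) and shrink by factors "
      "well above 2 after division correction")
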