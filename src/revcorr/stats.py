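"""Accuracy quantification and group-level inference.

Reconstruction accuracy is Pearson's r between the estimate x_hat and the
binned target spectrum s.  Group inference follows the standard recipe
for correlations: Fisher z-transform the per-subject r values, run a
one-sample t-test against zero on the z scale, and report mean/sd on the
r scale.  A two-factor additive ANOVA (subject + target) tests for a
target effect when each subject contributes one r per target.  No
multiple-testing correction is applied across the group tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "AccuracyResult",
    "GroupTestResult",
    "pearson_r",
    "fisher_z",
    "one_sample_t",
    "two_way_anova",
]


@dataclass
class AccuracyResult:
    """Per-subject, per-target reconstruction accuracy."""

    r: float
    subject_id: str | None = None
    target_label: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.r) or abs(self.r) > 1:
            raise ValueError(f"r must lie in [-1, 1], got {self.r}")


@dataclass
class GroupTestResult:
    """One-sample t-test summary (test on Fisher-z, report on r scale)."""

    mean_r: float
    sd_r: float
    t_stat: float
    df: int
    p_value: float
    n: int

    def format(self) -> str:
        return (
            f"{self.mean_r:.2f} ± {self.sd_r:.2f} (mean ± s.d.), "
            f"t({self.df}) = {self.t_stat:.3f}, p = {self.p_value:.3g}"
        )


def pearson_r(a, b_vec) -> float:
    """Product-moment correlation between two vectors."""
    a = np.asarray(a, dtype=float)
    b_vec = np.asarray(b_vec, dtype=float)
    if a.shape != b_vec.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b_vec.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if a.std() == 0 or b_vec.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sst.pearsonr(a, b_vec).statistic)


def fisher_z(r) -> float | np.ndarray:
    """Variance-stabilizing Fisher transform, z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def one_sample_t(values, transform: str = "fisher") -> GroupTestResult:
    """Two-sided one-sample t-test of correlations against zero.

    With ``transform="fisher"`` (default) the test statistic is computed
    on Fisher-z values while mean/sd are reported on the r scale;
    ``transform="none"`` tests the raw values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a t-test")
    if values.std() == 0:
        raise ValueError("t-test undefined for constant values")
    if transform == "fisher":
        tested = fisher_z(values)
    elif transform == "none":
        tested = values
    else:
        raise ValueError(f"unknown transform {transform!r}")
    res = sst.ttest_1samp(tested, popmean=0.0)
    n = values.size
    return GroupTestResult(
        mean_r=float(values.mean()),
        sd_r=float(values.std(ddof=1)),
        t_stat=float(res.statistic),
        df=n - 1,
        p_value=float(res.pvalue),
        n=n,
    )


def two_way_anova(r_table: pd.DataFrame) -> pd.DataFrame:
    """Additive two-way ANOVA on Fisher-z accuracies.

    ``r_table`` has columns ``subject``, ``target``, and ``z`` (one
    Fisher-z value per subject x target cell).  With a single replicate
    per cell no interaction is estimable, so the additive model
    ``z ~ subject + target`` is fit; returns the type-II ANOVA table with
    per-factor F statistics and p-values.
    """
    required = {"subject", "target", "z"}
    if not required.issubset(r_table.columns):
        raise ValueError(f"r_table must have columns {sorted(required)}")
    counts = r_table.groupby(["subject", "target"]).size().unstack(fill_value=0)
    if (counts.values == 0).any():
        raise ValueError("incomplete layout: every subject x target cell needs data")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 levels per factor")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("z ~ C(subject) + C(target)", data=r_table).fit()
    return sm.stats.anova_lm(model, typ=2)
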