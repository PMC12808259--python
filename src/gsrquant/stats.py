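"""Inter-rater agreement and group-comparison statistics.

Visibility of residues on a photograph is scored by human raters on an
ordinal 0-5 scale.  Agreement between a fixed set of raters is measured
by the intraclass correlation coefficient for a two-way mixed model,
single measures, consistency definition — ICC(3,1) in the Shrout-Fleiss
taxonomy:

    ICC(3,1) = (MS_rows - MS_err) / (MS_rows + (k - 1) * MS_err)

where MS_rows is the between-subject mean square and MS_err the residual
(subject x rater interaction) mean square of the two-way ANOVA without
replication, and k the number of raters.  Group differences are tested
with independent-samples t-tests at alpha = 0.05.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RATING_LABELS", "encode_rating", "RatingMatrix", "ICCResult",
           "icc_two_way_mixed_single", "classify_icc", "TTestResult",
           "independent_t_test", "ALPHA"]

ALPHA = 0.05

#: Ordinal visibility scale: 0 = no residue visible ... 5 = substantial.
RATING_LABELS: dict[str, int] = {
    "none_visible": 0,
    "minimal": 1,
    "slight": 2,
    "moderate": 3,
    "considerable": 4,
    "substantial": 5,
}


def encode_rating(label: str) -> int:
    """Map a visibility label to its 0-5 ordinal score."""
    try:
        return RATING_LABELS[label]
    except KeyError:
        raise ValueError(
            f"unknown rating label {label!r}; expected one of {sorted(RATING_LABELS)}"
        ) from None


@dataclass(frozen=True)
class RatingMatrix:
    """Subjects x raters grid of integer visibility scores in 0-5."""

    values: np.ndarray
    subject_ids: tuple = ()
    rater_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("rating matrix needs >= 2 subjects and >= 2 raters")
        if np.any(pd.isna(v)):
            raise ValueError("rating matrix has missing cells")
        v = v.astype(float)
        if np.any((v < 0) | (v > 5)) or np.any(v != np.round(v)):
            raise ValueError("ratings must be integers in 0..5")
        object.__setattr__(self, "values", v)
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids",
                               tuple(range(1, v.shape[0] + 1)))
        if not self.rater_ids:
            object.__setattr__(self, "rater_ids",
                               tuple(f"rater{i}" for i in range(1, v.shape[1] + 1)))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingMatrix":
        """Read a CSV with rows = subjects and columns = raters."""
        df = pd.read_csv(path)
        return cls(df.to_numpy(), subject_ids=tuple(df.index),
                   rater_ids=tuple(df.columns))


@dataclass(frozen=True)
class ICCResult:
    """ICC(3,1) value with its ANOVA mean squares and agreement category."""

    icc: float
    model: str
    category: str
    ms_rows: float
    ms_error: float


def classify_icc(icc: float) -> str:
    """Agreement category of an ICC value.

    Bands: excellent >= 0.75, good [0.60, 0.75), fair [0.40, 0.60),
    poor < 0.40.
    """
    if icc > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {icc}")
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


def icc_two_way_mixed_single(m: RatingMatrix, agreement: bool = False) -> ICCResult:
    """Two-way mixed, single-measures intraclass correlation.

    The default is the consistency definition ICC(3,1): raters are fixed,
    systematic rater offsets do not count against agreement.  With
    ``agreement=True`` the absolute-agreement coefficient ICC(2,1) is
    returned instead (rater variance penalized), as a sensitivity check.

    Raises
    ------
    ValueError
        If the matrix is constant (total variance zero): the ICC is then
        undefined because there is no subject variance to apportion.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_total = ((x - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("ICC undefined: all ratings identical (zero total variance)")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if agreement:
        icc = (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n)
        model = "two-way random, single measures, absolute agreement (ICC(2,1))"
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        model = "two-way mixed, single measures, consistency (ICC(3,1))"
    # the coefficient is <= 1 by construction; trim float round-off
    icc = min(float(icc), 1.0)
    return ICCResult(icc=float(icc), model=model, category=classify_icc(float(icc)),
                     ms_rows=float(ms_rows), ms_error=float(ms_err))


@dataclass(frozen=True)
class TTestResult:
    """Independent-samples t-test outcome at alpha = 0.05."""

    t: float
    df: float
    p: float
    significant: bool
    variant: str


def independent_t_test(a, b, variant: str = "student") -> TTestResult:
    """Two-sided independent-samples t-test.

    ``variant="student"`` pools the variances (df = n_a + n_b - 2);
    ``variant="welch"`` uses the Welch-Satterthwaite approximation.  Two
    identical samples give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    equal_var = variant == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return TTestResult(t=t, df=df, p=p, significant=p < ALPHA, variant=variant)
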