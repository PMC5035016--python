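"""Agreement statistics for paired RFFT assessments.

Implements the three agreement measures used to validate automated
scoring against human raters, plus the human-rater reconciliation rule:

* ICC(A,1): two-way mixed-model, absolute-agreement, single-measures
  intraclass correlation (McGraw & Wong 1996), with F-based confidence
  interval and p-value.
* Lin's concordance correlation coefficient (Lin 1989) with a Fisher-z
  confidence interval.  CCC measures agreement with the identity line,
  so it penalizes scale and location shifts that Pearson r ignores.
* Bland-Altman 95% limits of agreement: mean difference +/- 1.96 times
  the sample SD of the differences.

The reconciliation procedure mirrors double-rating practice: a third
rater re-scores a protocol when the first two raters differ by more than
two points in any part or more than four points in total, and the final
score is the average of the two most concordant raters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. zero variance)."""


class ReconciliationIncompleteError(ValueError):
    """A third rating is required but was not provided."""


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float
    df1: float
    df2: float


def icc_absolute_single(scores: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way, absolute agreement, single measures.

    ``scores`` is an (n subjects x k raters) table with no missing cells.
    The estimate is
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``
    from the two-way ANOVA mean squares for rows (subjects), columns
    (raters) and error; CI and p-value follow McGraw & Wong (1996).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("scores must be a 2-D subjects x raters table")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise UndefinedStatisticError("zero total variance")
    est = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0:
        # perfect within-subject agreement: degenerate, CI collapses
        return ICCResult(est, est, est, 0.0, n - 1, (n - 1) * (k - 1))
    f_obs = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = float(stats.f.sf(f_obs, df1, df2))
    a = k * est / (n * (1.0 - est)) if est < 1 else np.inf
    b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1 else np.inf
    if np.isfinite(a):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    return ICCResult(float(est), float(lower), float(upper), p, df1, df2)


@dataclass(frozen=True)
class CCCResult:
    estimate: float
    ci_lower: float
    ci_upper: float


def lin_ccc(x, y, confidence: float = 0.95) -> CCCResult:
    """Lin's concordance correlation coefficient.

    ``CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with biased
    (1/n) moment estimators; the confidence interval uses Lin's (1989)
    asymptotic variance of the Fisher z transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    sx2 = x.var()          # 1/n moments
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    shift = x.mean() - y.mean()
    denom = sx2 + sy2 + shift ** 2
    if denom == 0:
        raise UndefinedStatisticError("zero variance in both inputs")
    ccc = 2.0 * sxy / denom
    if sx2 == 0 or sy2 == 0:
        return CCCResult(float(ccc), float(ccc), float(ccc))
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 or r == 0:
        return CCCResult(float(ccc), float(ccc), float(ccc))
    u = shift / (sx2 * sy2) ** 0.25
    z = np.arctanh(ccc)
    se_z2 = (
        (1 - r ** 2) * ccc ** 2 / ((1 - ccc ** 2) * r ** 2)
        + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * (1 - ccc ** 2) ** 2)
        - ccc ** 4 * u ** 4 / (2 * r ** 2 * (1 - ccc ** 2) ** 2)
    ) / (n - 2)
    se_z = np.sqrt(max(se_z2, 0.0))
    zcrit = stats.norm.ppf(1 - (1 - confidence) / 2)
    return CCCResult(float(ccc), float(np.tanh(z - zcrit * se_z)),
                     float(np.tanh(z + zcrit * se_z)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Limits of agreement for differences ``d = x - y``.

    The sign convention (first minus second argument) is recorded so
    reports can state which assessment runs high.
    """

    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n: int
    convention: str = "x - y"


def bland_altman(x, y) -> BlandAltmanResult:
    """95% limits of agreement: mean difference +/- 1.96 sample SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise UndefinedStatisticError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, len(x))


def limits_of_agreement(mean_difference: float, sd_difference: float,
                        ) -> tuple[float, float]:
    """Closed-form 95% limits from a printed mean difference and SD."""
    return (mean_difference - 1.96 * sd_difference,
            mean_difference + 1.96 * sd_difference)


@dataclass(frozen=True)
class RaterScores:
    """Per-part scores of one rater for one measure (e.g. unique designs)."""

    parts: tuple[float, float, float, float, float]

    @property
    def total(self) -> float:
        return float(sum(self.parts))


@dataclass(frozen=True)
class ReconciliationResult:
    final_parts: tuple[float, ...]
    final_total: float
    third_rater_required: bool
    raters_used: tuple[int, int]
    part_differences: tuple[float, ...]
    total_difference: float


def needs_third_rater(rater1: RaterScores, rater2: RaterScores) -> bool:
    """True iff raters 1 and 2 differ by more than two points in any part
    or by more than four points in total."""
    part_diff = max(abs(a - b) for a, b in zip(rater1.parts, rater2.parts))
    return part_diff > 2 or abs(rater1.total - rater2.total) > 4


def reconcile_raters(
    rater1: RaterScores,
    rater2: RaterScores,
    rater3: RaterScores | None = None,
) -> ReconciliationResult:
    """Resolve a double (or triple) rating into a final score.

    If the first two raters disagree beyond the threshold a third rating
    is required; the final score averages the two most concordant raters
    (smallest absolute difference in total score, ties resolved in the
    order (1,2), (1,3), (2,3)).
    """
    required = needs_third_rater(rater1, rater2)
    raters = {1: rater1, 2: rater2}
    if rater3 is not None:
        raters[3] = rater3
    if required and rater3 is None:
        raise ReconciliationIncompleteError(
            "raters 1 and 2 disagree beyond threshold; third rating required")
    best_pair = min(
        combinations(sorted(raters), 2),
        key=lambda pair: (abs(raters[pair[0]].total - raters[pair[1]].total),
                          pair),
    )
    a, b = (raters[best_pair[0]], raters[best_pair[1]])
    final_parts = tuple((pa + pb) / 2.0 for pa, pb in zip(a.parts, b.parts))
    return ReconciliationResult(
        final_parts=final_parts,
        final_total=float(sum(final_parts)),
        third_rater_required=required,
        raters_used=best_pair,
        part_differences=tuple(abs(pa - pb)
                               for pa, pb in zip(rater1.parts, rater2.parts)),
        total_difference=abs(rater1.total - rater2.total),
    )


@dataclass(frozen=True)
class AgreementResult:
    """Bundle of the three agreement analyses for one paired measure."""

    icc: ICCResult
    ccc: CCCResult
    bland_altman: BlandAltmanResult
    n: int


def agreement_report(x, y) -> AgreementResult:
    """All three agreement statistics for paired scores ``x`` (e.g.
    computerized) and ``y`` (e.g. human); differences are ``x - y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return AgreementResult(
        icc=icc_absolute_single(np.column_stack([x, y])),
        ccc=lin_ccc(x, y),
        bland_altman=bland_altman(x, y),
        n=len(x),
    )
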