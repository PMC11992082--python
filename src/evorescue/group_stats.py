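"""Treatment-comparison tests for rescue and growth metrics.

Three nonparametric/robust comparisons: the two-sided Mann–Whitney U test
(exact for small tie-free samples, tie-corrected normal approximation with
continuity correction otherwise), Levene's test of equality of variances
(median-centered Brown–Forsythe variant by default), and the Pearson
chi-squared test of association on a 2×2 survival table (reported both
with and without Yates continuity correction, since the appropriate
variant for small expected counts is a judgement call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .plate_io import DataError

__all__ = [
    "TreatmentComparison",
    "mann_whitney_u",
    "levene_test",
    "chi2_association",
]

EXACT_LIMIT = 12  # combined sample size up to which the exact MWU null is used


@dataclass
class TreatmentComparison:
    test_name: str  # mann_whitney | levene | chi2
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method_detail: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_row(self) -> dict:
        row = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": "/".join(str(n) for n in self.n_per_group),
            "method_detail": self.method_detail,
        }
        row.update(self.extra)
        return row


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_limit: int = EXACT_LIMIT,
) -> TreatmentComparison:
    """Two-sided Mann–Whitney U test.

    The statistic is U for the first sample, #{(i,j): x_i > y_j} plus half
    the ties.  ``mode='auto'`` uses the exact null distribution when the
    combined sample size is at most ``exact_limit`` and there are no ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.  The route taken is recorded in ``method_detail``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("mann_whitney_u requires two nonempty samples")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if mode == "auto":
        use_exact = (len(combined) <= exact_limit) and not has_ties
    elif mode == "exact":
        if has_ties:
            raise DataError("exact Mann-Whitney p undefined in the presence of ties")
        use_exact = True
    elif mode == "approx":
        use_exact = False
    else:
        raise DataError(f"unknown mode {mode!r}")
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    detail = "exact" if use_exact else "normal_approx_tie_corrected_cc"
    return TreatmentComparison(
        "mann_whitney",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        (len(x), len(y)),
        detail,
    )


def levene_test(
    x: Sequence[float],
    y: Sequence[float],
    center: str = "median",
) -> TreatmentComparison:
    """Levene's equality-of-variances test (Brown–Forsythe by default).

    One-way ANOVA F on absolute deviations from each group's center
    (median for robustness on skewed OD-derived metrics; mean by flag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DataError("levene_test requires n >= 2 per group")
    if center not in {"median", "mean"}:
        raise DataError(f"unknown center {center!r}")
    loc = np.median if center == "median" else np.mean
    if np.all(np.abs(x - loc(x)) == 0) and np.all(np.abs(y - loc(y)) == 0):
        raise DataError("zero within-group deviation in all groups")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.levene(x, y, center=center)
    return TreatmentComparison(
        "levene",
        float(stat),
        float(min(p, 1.0)),
        (len(x), len(y)),
        f"center={center}",
    )


def chi2_association(table: Sequence[Sequence[int]]) -> TreatmentComparison:
    """Pearson chi-squared test of association on a 2×2 count table.

    df = 1.  The headline statistic/p are uncorrected; the Yates
    continuity-corrected variant is reported alongside in ``extra``.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DataError("chi2_association expects a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise DataError("counts must be nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DataError("chi2_association requires all margins > 0")
    plain = stats.chi2_contingency(arr, correction=False)
    yates = stats.chi2_contingency(arr, correction=True)
    return TreatmentComparison(
        "chi2",
        float(plain.statistic),
        float(plain.pvalue),
        tuple(int(n) for n in arr.sum(axis=1)),
        "pearson_df1_uncorrected",
        extra={
            "statistic_yates": float(yates.statistic),
            "p_value_yates": float(yates.pvalue),
        },
    )
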