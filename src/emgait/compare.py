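"""Group-level statistical battery on per-animal gait metrics.

Conventions: all tests two-tailed; normality screened with the
D'Agostino-Pearson omnibus test; between-group location differences use the
pooled-variance unpaired Student's t-test, except r-values (bounded on
[0, 1]) which use the Mann-Whitney test; post-drug values expressed as
ratios to pre-drug are tested against unity with a one-sample t-test;
per-animal coefficients of variation are compared with the unpaired t-test.
The unit of analysis is always the per-animal summary, never pooled steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, UsageError


@dataclass
class GroupDataset:
    """Per-animal values of one parameter in two groups."""

    parameter: str
    group_a: np.ndarray
    group_b: np.ndarray
    labels: tuple[str, str] = ("TTx2EB", "TTnoEB")

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=float)
        self.group_b = np.asarray(self.group_b, dtype=float)
        if self.group_a.size < 2 or self.group_b.size < 2:
            raise InsufficientDataError("each group needs n >= 2 per-animal values")
        if not (np.all(np.isfinite(self.group_a)) and np.all(np.isfinite(self.group_b))):
            raise UsageError("group values must be finite")


@dataclass
class RatioDataset:
    """Per-animal post-drug / pre-drug ratios of one parameter."""

    parameter: str
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if not np.all(np.isfinite(self.ratios)):
            raise UsageError("ratios must be finite")


@dataclass
class TestResult:
    """Outcome of one hypothesis test (two-tailed)."""

    test_name: str
    statistic: float
    p_value: float
    effect_direction: int  # sign of (a - b) or (mean ratio - 1)
    n_a: int
    n_b: int
    flags: list[str] = field(default_factory=list)

    @property
    def untestable(self) -> bool:
        return "untestable" in self.flags


def normality_screen(values: "list[float] | np.ndarray") -> TestResult:
    """D'Agostino-Pearson K² omnibus normality test.

    The omnibus test is unreliable below n = 8; smaller samples return an
    "untestable" marker (NaN statistic/p) instead of a p-value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        return TestResult(
            "dagostino_pearson", float("nan"), float("nan"), 0, int(x.size), 0,
            flags=["untestable"],
        )
    k2, p = stats.normaltest(x)
    return TestResult("dagostino_pearson", float(k2), float(p), 0, int(x.size), 0)


def _degenerate(data: GroupDataset) -> bool:
    both = np.concatenate([data.group_a, data.group_b])
    return np.all(both == both[0])


def compare_groups(data: GroupDataset, test: str = "student_t") -> TestResult:
    """Two-tailed between-group test on per-animal values.

    ``student_t`` is the classic pooled-variance unpaired t-test;
    ``mann_whitney`` uses the exact null distribution when min(n) <= 8 and
    there are no ties, otherwise the normal approximation with tie
    correction.  Identical groups short-circuit to p = 1.
    """
    a, b = data.group_a, data.group_b
    direction = int(np.sign(a.mean() - b.mean()))
    if _degenerate(data):
        return TestResult(test, 0.0, 1.0, 0, a.size, b.size, flags=["degenerate"])
    if test == "student_t":
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return TestResult("student_t", float(t), float(p), direction, a.size, b.size)
    if test == "mann_whitney":
        has_ties = np.unique(np.concatenate([a, b])).size != a.size + b.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return TestResult(
            "mann_whitney", float(res.statistic), float(res.pvalue),
            direction, a.size, b.size, flags=[method],
        )
    raise UsageError(f"unknown test {test!r}")


def ratio_vs_unity(data: RatioDataset) -> TestResult:
    """One-sample two-tailed t-test of post/pre ratios against 1.

    Zero-variance ratios: all exactly 1 gives p = 1; all equal but != 1 is
    reported as p = 0 with a ``zero-variance`` flag.
    """
    r = data.ratios
    if r.size < 2:
        raise InsufficientDataError("ratio_vs_unity requires n >= 2 ratios")
    direction = int(np.sign(r.mean() - 1.0))
    if np.all(r == r[0]):
        if r[0] == 1.0:
            return TestResult("one_sample_t", 0.0, 1.0, 0, r.size, 0, flags=["degenerate"])
        return TestResult(
            "one_sample_t", float("inf") * direction, 0.0, direction, r.size, 0,
            flags=["zero-variance"],
        )
    t, p = stats.ttest_1samp(r, popmean=1.0)
    return TestResult("one_sample_t", float(t), float(p), direction, int(r.size), 0)


def compare_cv(data: GroupDataset) -> TestResult:
    """Unpaired two-tailed Student's t-test on per-animal CVs."""
    return compare_groups(data, test="student_t")
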