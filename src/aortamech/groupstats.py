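"""Adaptive two-sample comparisons with mean +/- SEM summaries.

Group values (one per animal) are compared pairwise with a test chosen by a
decision tree common in experimental physiology:

1. normality of each group (Kolmogorov-Smirnov; Lilliefors-corrected
   critical values by default since the normal parameters are estimated
   from the sample);
2. if both groups are normal, an F-test compares variances: equal variances
   select the unpaired Student t-test, unequal the Welch t-test;
3. if either group departs from normality, the Mann-Whitney U test is used.

All tests are two-sided; significance is declared at p <= alpha (default
0.05).  No multiplicity correction is applied by default; an optional Holm
adjustment is available for users who want family-wise control.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import InsufficientDataError

__all__ = [
    "GroupSample",
    "NormalityResult",
    "VarianceResult",
    "ComparisonResult",
    "summarize",
    "check_normality",
    "compare_variances",
    "select_and_test",
    "compare_all_groups",
]

TEST_UNPAIRED_T = "unpaired_t"
TEST_WELCH_T = "welch_t"
TEST_MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class GroupSample:
    """Measurements of one variable in one experimental group (one per animal)."""

    values: tuple
    group: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or len(arr) < 3:
            raise InsufficientDataError(
                f"group {self.group!r} needs >= 3 finite values, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InsufficientDataError(f"group {self.group!r} contains non-finite values")
        object.__setattr__(self, "values", tuple(float(v) for v in arr))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def summarize(sample: GroupSample | np.ndarray) -> tuple[float, float]:
    """Mean and SEM (sample SD with n-1 denominator over sqrt(n))."""
    arr = sample.array if isinstance(sample, GroupSample) else np.asarray(sample, float)
    if arr.size < 2:
        raise InsufficientDataError("SEM needs at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


@dataclass(frozen=True)
class NormalityResult:
    is_normal: bool
    p_value: float
    statistic: float
    flags: frozenset = frozenset()


def check_normality(
    sample: GroupSample, alpha: float = 0.05, variant: str = "lilliefors"
) -> NormalityResult:
    """Kolmogorov-Smirnov-type normality check with estimated parameters.

    ``variant='lilliefors'`` (default) uses critical values corrected for
    mean and SD being estimated from the sample; ``'plain'`` runs the naive
    KS test against N(mean, SD), which is anticonservative.
    """
    arr = sample.array
    if arr.size < 4:
        raise InsufficientDataError("normality check needs n >= 4")
    if arr.std(ddof=1) == 0:
        return NormalityResult(False, 0.0, np.inf, frozenset({"degenerate"}))
    if variant == "lilliefors":
        stat, p = _lilliefors(arr, dist="norm", pvalmethod="table")
    elif variant == "plain":
        stat, p = stats.kstest(arr, "norm", args=(arr.mean(), arr.std(ddof=1)))
    else:
        raise ValueError(f"unknown ks variant {variant!r}")
    return NormalityResult(bool(p > alpha), float(p), float(stat))


@dataclass(frozen=True)
class VarianceResult:
    equal_variance: bool
    p_value: float
    f_statistic: float
    flags: frozenset = frozenset()


def compare_variances(
    a: GroupSample, b: GroupSample, alpha: float = 0.05
) -> VarianceResult:
    """Two-sided F-test of variance equality.

    F is the larger over the smaller sample variance with degrees of
    freedom ordered to match; the two-sided p doubles the upper tail
    (capped at 1).
    """
    va, vb = a.array.var(ddof=1), b.array.var(ddof=1)
    if va == 0 or vb == 0:
        return VarianceResult(False, 0.0, np.inf, frozenset({"degenerate"}))
    if va >= vb:
        f, dfn, dfd = va / vb, a.n - 1, b.n - 1
    else:
        f, dfn, dfd = vb / va, b.n - 1, a.n - 1
    p = min(2.0 * stats.f.sf(f, dfn, dfd), 1.0)
    return VarianceResult(bool(p > alpha), float(p), float(f))


@dataclass
class ComparisonResult:
    """Outcome of one pairwise comparison through the decision tree."""

    group_a: str
    group_b: str
    test_used: str
    p_value: float
    significant: bool
    alpha: float
    normality_p: tuple[float, float]
    variance_p: float | None
    summary_a: tuple[float, float]  # (mean, SEM)
    summary_b: tuple[float, float]
    variable: str = ""
    p_adjusted: float | None = None
    flags: set = field(default_factory=set)

    def summary(self) -> str:
        lines = [
            f"Comparison {self.group_a} vs {self.group_b}"
            + (f"  [{self.variable}]" if self.variable else ""),
            f"  {self.group_a}: {self.summary_a[0]:.4g} +/- {self.summary_a[1]:.4g} (SEM)",
            f"  {self.group_b}: {self.summary_b[0]:.4g} +/- {self.summary_b[1]:.4g} (SEM)",
            f"  test: {self.test_used}   p = {self.p_value:.4g}"
            + ("  *" if self.significant else ""),
            f"  normality p = ({self.normality_p[0]:.3g}, {self.normality_p[1]:.3g})"
            + (
                f"   variance p = {self.variance_p:.3g}"
                if self.variance_p is not None
                else ""
            ),
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "test_used": self.test_used,
            "p_value": self.p_value,
            "significant": self.significant,
            "mean_a": self.summary_a[0],
            "sem_a": self.summary_a[1],
            "mean_b": self.summary_b[0],
            "sem_b": self.summary_b[1],
        }


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value: exact for small untied samples,
    normal approximation with tie correction otherwise."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def select_and_test(
    a: GroupSample,
    b: GroupSample,
    alpha: float = 0.05,
    ks_variant: str = "lilliefors",
    variable: str = "",
) -> ComparisonResult:
    """Run the full decision tree on one pair of groups."""
    norm_a = check_normality(a, alpha, ks_variant)
    norm_b = check_normality(b, alpha, ks_variant)
    flags = set(norm_a.flags) | set(norm_b.flags)
    xa, xb = a.array, b.array

    if norm_a.is_normal and norm_b.is_normal:
        var_res = compare_variances(a, b, alpha)
        flags |= set(var_res.flags)
        variance_p = var_res.p_value
        if var_res.equal_variance:
            test_used = TEST_UNPAIRED_T
            p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
        else:
            test_used = TEST_WELCH_T
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    else:
        test_used = TEST_MANN_WHITNEY
        variance_p = None
        p = _mann_whitney(xa, xb)

    return ComparisonResult(
        group_a=a.group,
        group_b=b.group,
        test_used=test_used,
        p_value=p,
        significant=bool(p <= alpha),
        alpha=alpha,
        normality_p=(norm_a.p_value, norm_b.p_value),
        variance_p=variance_p,
        summary_a=summarize(a),
        summary_b=summarize(b),
        variable=variable,
        flags=flags,
    )


def compare_all_groups(
    samples: list[GroupSample],
    alpha: float = 0.05,
    adjust: str | None = None,
    ks_variant: str = "lilliefors",
    variable: str = "",
) -> list[ComparisonResult]:
    """All unordered pairwise comparisons.

    ``adjust=None`` (default) applies no multiplicity correction;
    ``adjust='holm'`` recomputes the significance flags from Holm-adjusted
    p-values (stored in ``p_adjusted``).
    """
    if len(samples) < 2:
        raise InsufficientDataError("need at least 2 groups")
    results = [
        select_and_test(a, b, alpha, ks_variant, variable)
        for a, b in itertools.combinations(samples, 2)
    ]
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="holm"
        )
        for r, rej, pa in zip(results, reject, p_adj):
            r.p_adjusted = float(pa)
            r.significant = bool(rej)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results
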