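"""Group descriptive comparisons: Welch t-tests with default Bayes factors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..bayes.evidence import jzs_two_sample_bf


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    t: float
    p: float
    bf10: float
    n_a: int
    n_b: int


def _mean_ci(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(x))
    if x.size < 2:
        return m, (m, m)
    half = stats.t.ppf(0.975, x.size - 1) * np.std(x, ddof=1) / np.sqrt(x.size)
    return m, (m - half, m + half)


def group_compare(values_a, values_b) -> GroupComparison:
    """Welch two-sample t-test plus the JZS default Bayes factor.

    The Bayes factor uses the pooled-variance t statistic (the convention of
    the default Bayesian t-test); the reported frequentist t is Welch's.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    mean_a, ci_a = _mean_ci(a)
    mean_b, ci_b = _mean_ci(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    t_welch, p = stats.ttest_ind(a, b, equal_var=False)
    t_pooled, _ = stats.ttest_ind(a, b, equal_var=True)
    bf10 = jzs_two_sample_bf(float(t_pooled), a.size, b.size)
    return GroupComparison(
        mean_a=mean_a, mean_b=mean_b, ci95_a=ci_a, ci95_b=ci_b,
        t=float(t_welch), p=float(p), bf10=bf10, n_a=a.size, n_b=b.size,
    )
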