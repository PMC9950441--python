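"""Posterior evidence summaries: directional evidence ratios, Savage-Dickey
null-support Bayes factors, and default JZS two-sample Bayes factors."""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats


def evidence_ratio(draws, direction: int | float = +1) -> float:
    """Ratio of posterior draws in the hypothesized direction over draws
    against it.  If no draw opposes the hypothesis, the ratio is capped at the
    total draw count (logged by callers as a capped value)."""
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("no posterior draws")
    sign = 1.0 if direction >= 0 else -1.0
    n_for = int(np.sum(sign * d > 0))
    n_against = int(np.sum(sign * d < 0))
    if n_against == 0:
        return float(d.size)
    return n_for / n_against


def savage_dickey_bf01(
    draws,
    prior_mean: float,
    prior_sd: float,
    min_local_draws: int = 10,
) -> tuple[float, bool]:
    """BF01 = posterior density at 0 (Gaussian KDE, Silverman bandwidth) over
    the prior density at 0.

    Returns (bf01, widened): if too few draws fall near zero for a stable
    density estimate, the bandwidth is doubled and the result flagged.
    """
    d = np.asarray(draws, dtype=float)
    if d.size < 10:
        raise ValueError("too few draws for a density estimate")
    if prior_sd <= 0:
        raise ValueError("prior sd must be positive")
    prior_at_zero = stats.norm.pdf(0.0, loc=prior_mean, scale=prior_sd)

    kde = stats.gaussian_kde(d, bw_method="silverman")
    bw = float(kde.factor * d.std(ddof=1))
    widened = False
    if np.sum(np.abs(d) < bw) < min_local_draws:
        kde = stats.gaussian_kde(d, bw_method=2.0 * kde.factor)
        widened = True
    posterior_at_zero = float(kde(0.0)[0])
    return posterior_at_zero / prior_at_zero, widened


def jzs_two_sample_bf(t: float, n1: int, n2: int, r: float = np.sqrt(2) / 2) -> float:
    """Default (JZS) Bayes factor BF10 for a two-sample t statistic.

    Under H1 the standardized effect size has a Cauchy(0, r) prior, i.e.
    delta | g ~ N(0, g) with g ~ InverseGamma(1/2, r^2/2).  Marginalizing the
    normal slab analytically leaves a one-dimensional integral over g whose
    integrand is evaluated in log space (stable for large |t| and df):

        BF10 = int (1+Ng)^(-1/2)
                   [ (1 + t^2/(nu(1+Ng))) / (1 + t^2/nu) ]^(-(nu+1)/2)
                   p(g) dg,      N = n1 n2 / (n1 + n2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    log_denom = np.log1p(t * t / nu)

    def log_integrand(g: float) -> float:
        one_ng = 1.0 + n_eff * g
        ll = (-0.5 * np.log(one_ng)
              - 0.5 * (nu + 1) * (np.log1p(t * t / (nu * one_ng)) - log_denom))
        # InverseGamma(1/2, r^2/2) density
        lp = (0.5 * np.log(r * r / 2.0) - np.log(np.sqrt(np.pi))
              - 1.5 * np.log(g) - r * r / (2.0 * g))
        return ll + lp

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        return np.exp(log_integrand(g)) / (1.0 - u) ** 2

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=400,
                            points=[r * r / (1 + r * r)])
    return float(val)


EVIDENCE_BANDS = (
    (3.0, np.inf, "moderate+ evidence for H1"),
    (1.0, 3.0, "anecdotal for H1"),
    (1 / 3, 1.0, "anecdotal for H0"),
    (0.0, 1 / 3, "moderate+ evidence for H0"),
)


def evidence_band(bf10: float) -> str:
    """Interpretive label: BF > 3 (resp. < 1/3) counts as moderate evidence."""
    for lo, hi, label in EVIDENCE_BANDS:
        if lo <= bf10 < hi or (np.isinf(hi) and bf10 >= lo):
            return label
    return "anecdotal"
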