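"""Meta-d' estimation by maximum likelihood (response-collapsed variant).

The type-1 criterion is fixed from the type-1 fit (meta criterion scaled as
mc = c * meta_d / d, the standard convention); confidence-rating criteria are
free parameters above mc, shared across responses by symmetry.  The type-2
likelihood is a multinomial over confidence bins conditional on correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .sdt import SDTCounts, compute_dprime

_EPS = 1e-10


def _rating_probs(meta_d: float, taus: np.ndarray, mc: float) -> tuple[np.ndarray, np.ndarray]:
    """P(confidence bin | correct) and P(bin | incorrect) for given criteria.

    ``taus`` are the k-1 type-2 criteria strictly above mc; bins partition
    [mc, inf) into k intervals.
    """
    edges = np.concatenate([[mc], taus, [np.inf]])
    upper_c = norm.cdf(edges[1:] - meta_d / 2.0)
    lower_c = norm.cdf(edges[:-1] - meta_d / 2.0)
    denom_c = max(1.0 - norm.cdf(mc - meta_d / 2.0), _EPS)
    p_correct = (upper_c - lower_c) / denom_c

    upper_i = norm.cdf(edges[1:] + meta_d / 2.0)
    lower_i = norm.cdf(edges[:-1] + meta_d / 2.0)
    denom_i = max(1.0 - norm.cdf(mc + meta_d / 2.0), _EPS)
    p_incorrect = (upper_i - lower_i) / denom_i
    return np.maximum(p_correct, _EPS), np.maximum(p_incorrect, _EPS)


def type2_loglik(meta_d: float, taus: np.ndarray, n_correct: np.ndarray,
                 n_incorrect: np.ndarray, mc: float) -> float:
    p_c, p_i = _rating_probs(meta_d, taus, mc)
    return float(np.sum(n_correct * np.log(p_c)) + np.sum(n_incorrect * np.log(p_i)))


def _meta_criterion(c: float, d: float, meta_d: float) -> float:
    if abs(d) < 1e-6:
        return c
    return c * meta_d / d


def profile_loglik(meta_d: float, counts: SDTCounts,
                   d: float | None = None, c: float | None = None) -> float:
    """Type-2 log-likelihood at ``meta_d`` with criteria profiled out."""
    if d is None or c is None:
        d, c = compute_dprime(counts)
    n_c = counts.correct_by_bin()
    n_i = counts.incorrect_by_bin()
    k = counts.n_bins
    mc = _meta_criterion(c, d, meta_d)

    def neg(eta: np.ndarray) -> float:
        taus = mc + np.cumsum(np.exp(eta))
        return -type2_loglik(meta_d, taus, n_c, n_i, mc)

    eta0 = np.log(np.full(k - 1, 0.5))
    res = optimize.minimize(neg, eta0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 1000})
    return -float(res.fun)


@dataclass
class MetaDFit:
    d: float
    criterion: float
    meta_d: float
    m_ratio: float
    taus: np.ndarray
    loglik: float
    converged: bool


def fit_meta_d_mle(counts: SDTCounts) -> MetaDFit:
    """Joint MLE of meta-d' and the type-2 criteria."""
    n_c = counts.correct_by_bin()
    n_i = counts.incorrect_by_bin()
    if np.count_nonzero(n_c + n_i) < 2:
        raise ValueError("need nonzero counts in at least 2 confidence bins")
    if n_c.sum() == 0 or n_i.sum() == 0:
        raise ValueError("need both correct and incorrect trials for meta-d'")
    d, c = compute_dprime(counts)
    k = counts.n_bins

    def neg(params: np.ndarray) -> float:
        meta_d = params[0]
        mc = _meta_criterion(c, d, meta_d)
        taus = mc + np.cumsum(np.exp(params[1:]))
        return -type2_loglik(meta_d, taus, n_c, n_i, mc)

    best = None
    for md0 in (d, 0.2, 1.0):
        x0 = np.concatenate([[md0], np.log(np.full(k - 1, 0.5))])
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-10,
                                         "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    meta_d = float(best.x[0])
    mc = _meta_criterion(c, d, meta_d)
    taus = mc + np.cumsum(np.exp(best.x[1:]))
    return MetaDFit(
        d=d, criterion=c, meta_d=meta_d,
        m_ratio=meta_d / d if abs(d) > 1e-9 else np.nan,
        taus=taus, loglik=-float(best.fun), converged=bool(best.success),
    )


def meta_d_se(counts: SDTCounts, fit: MetaDFit, h: float = 1e-3) -> float:
    """Standard error of meta-d' from the finite-difference observed information
    of the profile likelihood."""
    d, c = fit.d, fit.criterion
    f0 = profile_loglik(fit.meta_d, counts, d, c)
    fp = profile_loglik(fit.meta_d + h, counts, d, c)
    fm = profile_loglik(fit.meta_d - h, counts, d, c)
    info = -(fp - 2 * f0 + fm) / h**2
    if info <= 0:
        return float("inf")
    return float(1.0 / np.sqrt(info))
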