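"""Hierarchical Bayesian group model for metacognitive efficiency.

Participant-level log M-ratios (MLE point estimates with delta-method standard
errors) feed a normal-normal hierarchy per group:

    log m_hat_i ~ N(theta_i, s_i^2)
    theta_i     ~ N(mu_group(i), tau^2)
    mu_g        ~ N(0, 1),  tau ~ half-Cauchy(1)

The group-difference Bayes factor is Savage-Dickey on delta = mu_a - mu_b
(prior sd sqrt(2)).  This is a measurement-error simplification of a full
hierarchical rating model; the shrinkage and group-level contrasts behave the
same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..bayes.evidence import savage_dickey_bf01
from .metad import fit_meta_d_mle, meta_d_se
from .sdt import SDTCounts

_MIN_MRATIO = 0.05
_WIDE_SE = 1.0


@dataclass
class HierarchicalMratioFit:
    participant_table: pd.DataFrame
    group_mean: dict[str, float]          # posterior mean of exp(mu_g)
    group_hdi: dict[str, tuple[float, float]]
    bf01_difference: float
    bf10_difference: float
    mu_draws: dict[str, np.ndarray]
    theta_means: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def _participant_estimates(counts_by_pid: dict[str, SDTCounts]) -> tuple[pd.DataFrame, list[str]]:
    rows, notes = [], []
    for pid, counts in counts_by_pid.items():
        fit = fit_meta_d_mle(counts)
        m = fit.m_ratio
        if not np.isfinite(m) or m < _MIN_MRATIO:
            notes.append(f"{pid}: M-ratio {m:.3f} floored at {_MIN_MRATIO} (wide SE)")
            log_m, se = np.log(_MIN_MRATIO), _WIDE_SE
        else:
            se_md = meta_d_se(counts, fit)
            se = se_md / abs(fit.meta_d) if np.isfinite(se_md) else _WIDE_SE
            se = float(np.clip(se, 0.05, _WIDE_SE))
            log_m = float(np.log(m))
        rows.append({"participant": pid, "d": fit.d, "meta_d": fit.meta_d,
                     "m_ratio": m, "log_m": log_m, "se_log_m": se})
    return pd.DataFrame(rows), notes


def fit_hierarchical_mratio(
    counts_by_pid: dict[str, SDTCounts],
    groups: dict[str, str],
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed: int | None = None,
    tau_scale: float = 1.0,
) -> HierarchicalMratioFit:
    """Fit the two-group hierarchy and the group-difference Bayes factor."""
    table, notes = _participant_estimates(counts_by_pid)
    table["group"] = table["participant"].map(groups)
    labels = sorted(table["group"].unique())
    for g in labels:
        if (table["group"] == g).sum() < 2:
            notes.append(f"group {g!r} has < 2 participants; posterior is prior-dominated")
            warnings.warn(notes[-1])

    rng_master = np.random.default_rng(seed)
    kept = n_iter - n_warmup
    mu_store = {g: np.empty((n_chains, kept)) for g in labels}
    theta_sum = np.zeros(len(table))

    ell = table["log_m"].to_numpy()
    s2 = table["se_log_m"].to_numpy() ** 2
    gidx = {g: np.flatnonzero((table["group"] == g).to_numpy()) for g in labels}

    for ch in range(n_chains):
        rng = np.random.default_rng(int(rng_master.integers(0, 2**31 - 1)))
        mu = {g: 0.0 for g in labels}
        tau2 = 0.25
        a_tau = 1.0
        theta = ell.copy()
        for it in range(n_iter):
            # theta_i | rest: precision-weighted average of data and group mean
            mu_vec = np.array([mu[g] for g in table["group"]])
            prec = 1.0 / s2 + 1.0 / tau2
            mean = (ell / s2 + mu_vec / tau2) / prec
            theta = mean + rng.standard_normal(len(ell)) / np.sqrt(prec)
            # mu_g | rest with N(0,1) prior
            for g in labels:
                idx = gidx[g]
                prec_g = idx.size / tau2 + 1.0
                mean_g = theta[idx].sum() / tau2 / prec_g
                mu[g] = mean_g + rng.standard_normal() / np.sqrt(prec_g)
            # tau^2 | rest: Huang-Wand half-Cauchy(tau_scale)
            resid = theta - np.array([mu[g] for g in table["group"]])
            rate = 1.0 / a_tau + 0.5 * float(resid @ resid)
            tau2 = rate / rng.gamma(0.5 * (len(ell) + 1))
            a_tau = (1.0 / tau_scale**2 + 1.0 / tau2) / rng.gamma(1.0)
            if it >= n_warmup:
                for g in labels:
                    mu_store[g][ch, it - n_warmup] = mu[g]
                theta_sum += theta
    theta_mean = theta_sum / (n_chains * kept)

    mu_draws = {g: mu_store[g].reshape(-1) for g in labels}
    group_mean, group_hdi = {}, {}
    for g in labels:
        m_draws = np.exp(mu_draws[g])
        group_mean[g] = float(m_draws.mean())
        d = np.sort(m_draws)
        k = int(np.floor(0.95 * d.size))
        i = int(np.argmin(d[k:] - d[: d.size - k]))
        group_hdi[g] = (float(d[i]), float(d[i + k]))

    if len(labels) == 2:
        delta = mu_draws[labels[0]] - mu_draws[labels[1]]
        bf01, _ = savage_dickey_bf01(delta, 0.0, float(np.sqrt(2.0)))
    else:
        bf01 = float("nan")

    return HierarchicalMratioFit(
        participant_table=table,
        group_mean=group_mean,
        group_hdi=group_hdi,
        bf01_difference=bf01,
        bf10_difference=1.0 / bf01 if bf01 > 0 else float("inf"),
        mu_draws=mu_draws,
        theta_means={pid: float(t) for pid, t in zip(table["participant"], theta_mean)},
        warnings=notes,
    )
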