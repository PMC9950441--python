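"""Cluster-level Bayesian mixed models (step 3 of the EEG analysis).

Model 4: amplitude ~ correctness * group with (correctness | participant/electrode)
Model 5: amplitude ~ z_confidence * group * z_movementRT with
         (z_confidence * z_movementRT | participant/electrode)

Amplitudes are the per-trial, per-electrode averages over the cluster's
time window.  Random-effect columns use independent variances (see gibbs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..epochs import EpochArray
from ..massuni.cluster import ClusterResult
from .gibbs import (
    DEFAULT_PRIORS,
    HYPOTHESIZED_DIRECTION,
    PosteriorSummary,
    PriorSpec,
    gibbs_lmm,
)

MODEL4_TERMS = ["Intercept", "correctness", "group", "correctness:group"]
MODEL5_TERMS = [
    "Intercept", "z_confidence", "group", "z_movementRT",
    "z_confidence:group", "z_confidence:z_movementRT", "group:z_movementRT",
    "z_confidence:group:z_movementRT",
]
MODEL4_RANDOM = ["Intercept", "correctness"]
MODEL5_RANDOM = ["Intercept", "z_confidence", "z_movementRT",
                 "z_confidence:z_movementRT"]


def cluster_amplitude_table(epochs: EpochArray, cluster: ClusterResult) -> pd.DataFrame:
    """Per-trial, per-electrode amplitudes averaged over the cluster window."""
    tmask = epochs.time_mask(cluster.t_start, cluster.t_end)
    rows = []
    meta = epochs.metadata.reset_index(drop=True)
    for ch in cluster.electrodes:
        ci = epochs.channel_index(ch)
        amp = epochs.data[:, ci, :][:, tmask].mean(axis=1)
        df = meta.copy()
        df["electrode"] = ch
        df["amplitude"] = amp
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _column(data: pd.DataFrame, name: str) -> np.ndarray:
    if name == "Intercept":
        return np.ones(len(data))
    if name == "correctness":
        return data["correct"].to_numpy(dtype=float)
    if name == "group":
        return (data["group"].astype(str) == "ssd").astype(float).to_numpy()
    if name in ("z_confidence", "z_movementRT"):
        col = "z_confidence" if name == "z_confidence" else "z_onset"
        return data[col].to_numpy(dtype=float)
    if ":" in name:
        parts = name.split(":")
        out = np.ones(len(data))
        for part in parts:
            out = out * _column(data, part)
        return out
    raise KeyError(name)


def fit_cluster_model(
    data: pd.DataFrame,
    model: int,
    priors: PriorSpec = DEFAULT_PRIORS,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed: int | None = None,
) -> PosteriorSummary:
    """Fit model 4 or 5 on a cluster amplitude table.

    ``data`` needs columns amplitude, participant, group, correct and (for
    model 5) z_confidence / z_onset; an electrode column enables the nested
    random structure.
    """
    if model == 4:
        terms, random_cols = MODEL4_TERMS, MODEL4_RANDOM
    elif model == 5:
        terms, random_cols = MODEL5_TERMS, MODEL5_RANDOM
    else:
        raise ValueError("model must be 4 or 5")

    X = np.column_stack([_column(data, t) for t in terms])
    U = np.column_stack([_column(data, t) for t in random_cols])
    y = data["amplitude"].to_numpy(dtype=float)

    part = pd.factorize(data["participant"].astype(str))[0]
    random_factors = [(part, U, random_cols)]
    if "electrode" in data.columns and data["electrode"].nunique() > 1:
        pe = pd.factorize(data["participant"].astype(str) + "/" +
                          data["electrode"].astype(str))[0]
        random_factors.append((pe, U, [f"{c}|pe" for c in random_cols]))

    return gibbs_lmm(
        y=y, X=X, term_names=terms, random_factors=random_factors,
        priors=priors, n_chains=n_chains, n_iter=n_iter, n_warmup=n_warmup,
        seed=seed,
    )


def summarize_terms(summary: PosteriorSummary, priors: PriorSpec = DEFAULT_PRIORS) -> pd.DataFrame:
    """Side-by-side evidence table: posterior mean, CI, ER and BF01 per term."""
    from .evidence import evidence_ratio, savage_dickey_bf01

    rows = []
    for term in summary.term_names:
        d = summary.draws[term]
        direction = HYPOTHESIZED_DIRECTION.get(term, +1)
        er = evidence_ratio(d, direction)
        m0, s0 = priors.mean_sd(term)
        bf01, widened = savage_dickey_bf01(d, m0, s0)
        lo, hi = summary.ci95[term]
        rows.append({
            "term": term, "mean": summary.mean[term], "ci_lo": lo, "ci_hi": hi,
            "evidence_ratio": er, "bf01": bf01, "bf01_widened_bw": widened,
            "rhat": summary.rhat[term],
        })
    return pd.DataFrame(rows)
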