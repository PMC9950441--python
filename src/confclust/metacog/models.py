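"""Behavioral regression: confidence (0-1) on standardized movement onset,
correctness and group, with participant random intercepts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..bayes.evidence import evidence_ratio
from ..bayes.gibbs import PosteriorSummary, PriorSpec, gibbs_lmm

CONFIDENCE_RT_TERMS = [
    "Intercept", "z_movementRT", "correctness", "group",
    "z_movementRT:correctness", "z_movementRT:group", "correctness:group",
    "z_movementRT:correctness:group",
]

#: Hypothesized directions: confidence falls with later onsets, steeper for
#: correct trials, and the coupling is weaker (positive interaction) in ssd.
CONFIDENCE_RT_DIRECTIONS = {
    "z_movementRT": -1,
    "z_movementRT:correctness": -1,
    "z_movementRT:group": +1,
    "z_movementRT:correctness:group": +1,
}

_PRIORS = PriorSpec(means={}, sds={"Intercept": 10.0})


def _design(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z_rt = trials.groupby("participant")["onset"].transform(
        lambda s: (s - s.mean()) / max(s.std(ddof=0), 1e-12)
    ).to_numpy()
    corr = trials["correct"].to_numpy(dtype=float)
    grp = (trials["group"].astype(str) == "ssd").astype(float).to_numpy()
    cols = {
        "Intercept": np.ones(len(trials)),
        "z_movementRT": z_rt,
        "correctness": corr,
        "group": grp,
        "z_movementRT:correctness": z_rt * corr,
        "z_movementRT:group": z_rt * grp,
        "correctness:group": corr * grp,
        "z_movementRT:correctness:group": z_rt * corr * grp,
    }
    X = np.column_stack([cols[t] for t in CONFIDENCE_RT_TERMS])
    y = trials["confidence"].to_numpy(dtype=float) / 100.0  # 0-1 scale
    part = pd.factorize(trials["participant"].astype(str))[0]
    return X, y, part


def confidence_rt_model(
    trials: pd.DataFrame,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int = 1000,
    seed: int | None = None,
) -> tuple[PosteriorSummary, pd.DataFrame]:
    """Bayesian regression of confidence on z_movementRT x correctness x group.

    Returns the posterior summary and an evidence table (posterior mean,
    95% CI, directional evidence ratio per term).
    """
    X, y, part = _design(trials)
    summary = gibbs_lmm(
        y=y, X=X, term_names=CONFIDENCE_RT_TERMS,
        random_factors=[(part, np.ones((len(y), 1)), ["Intercept"])],
        priors=_PRIORS, n_chains=n_chains, n_iter=n_iter, n_warmup=n_warmup,
        seed=seed, resid_sd_scale=1.0,
    )
    rows = []
    for term in CONFIDENCE_RT_TERMS:
        d = summary.draws[term]
        lo, hi = summary.ci95[term]
        rows.append({
            "term": term, "estimate": summary.mean[term],
            "ci_lo": lo, "ci_hi": hi,
            "evidence_ratio": evidence_ratio(
                d, CONFIDENCE_RT_DIRECTIONS.get(term, +1)),
            "rhat": summary.rhat[term],
        })
    return summary, pd.DataFrame(rows)
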