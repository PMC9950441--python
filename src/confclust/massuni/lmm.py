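"""General-purpose mixed-model fit for a single response (statsmodels backend).

The mass-univariate scans use the vectorized REML engine in ``fastlmm``;
this wrapper serves one-off fits, exposes variance components, and provides
the convergence-failure fallback (simplified random structure, flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .design import ModelSpec, build_design, participant_codes


@dataclass
class LmmFit:
    term_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    sigma2: float
    variance_components: dict[str, float]
    converged: bool
    singular: bool
    flags: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.beta[self.term_names.index(term)])


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, response: str = "amplitude") -> LmmFit:
    """REML linear mixed model; on convergence failure, refit with a simplified
    random structure and flag the result.

    ``data`` must carry the response plus participant / group / covariate
    columns (and electrode for nested structures).
    """
    if data["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    X, names = build_design(data, spec.formula)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient fixed-effects design for formula {spec.formula!r}"
        )
    y = data[response].to_numpy(dtype=float)
    groups = participant_codes(data)

    exog_vc = None
    if spec.random == "participant/electrode":
        if "electrode" not in data.columns:
            raise ValueError("nested structure needs an 'electrode' column")
        pe = (data["participant"].astype(str) + "/" + data["electrode"].astype(str))
        dummies = pd.get_dummies(pe, dtype=float)
        exog_vc = {"electrode": {"pe": dummies.to_numpy()}}

    flags: list[str] = []

    def _fit(vc):
        if vc is None:
            model = sm.MixedLM(y, X, groups=groups)
        else:
            from statsmodels.regression.mixed_linear_model import VCSpec

            names_vc = [["pe"]]
            colnames = [[list(dummies.columns)]]
            mats = [[vc["electrode"]["pe"]]]
            model = sm.MixedLM(y, X, groups=groups,
                               exog_vc=VCSpec(names_vc, colnames, mats))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            return model.fit(reml=True, method=["lbfgs", "powell"])

    try:
        res = _fit(exog_vc)
        converged = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError):
        res = None
        converged = False

    if (res is None or not converged) and exog_vc is not None:
        flags.append("nested structure failed to converge; refit with (1|participant)")
        res = _fit(None)
        converged = bool(res.converged)
    if res is None:
        raise RuntimeError("mixed model failed to converge in any configuration")

    fe = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    pv = np.asarray(res.pvalues, dtype=float)[: len(fe)]
    vcomp = {"participant": float(np.asarray(res.cov_re).ravel()[0])}
    if exog_vc is not None and res.vcomp.size:
        vcomp["participant:electrode"] = float(res.vcomp[0])
    singular = any(v <= 1e-10 for v in vcomp.values())
    if singular:
        flags.append("singular random-effect variance (kept, flagged)")
    if not converged:
        flags.append("optimizer did not report convergence")
    return LmmFit(
        term_names=names, beta=fe, se=se, pval=pv,
        sigma2=float(res.scale), variance_components=vcomp,
        converged=converged, singular=singular, flags=flags,
    )
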