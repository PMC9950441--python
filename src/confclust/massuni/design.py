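"""Fixed-effect design construction for the mass-univariate models.

Covariates prefixed ``z_`` are standardized within participant.  group is
dummy-coded with control as the reference level (ssd = 1); correctness is
0/1 (incorrect/correct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODEL_FORMULAS: dict[str, list[str]] = {
    "correctness*group": [
        "Intercept", "correctness", "group", "correctness:group",
    ],
    "z_confidence*group": [
        "Intercept", "z_confidence", "group", "z_confidence:group",
    ],
    "z_movementRT*group": [
        "Intercept", "z_movementRT", "group", "z_movementRT:group",
    ],
    "z_confidence*group + z_movementRT": [
        "Intercept", "z_confidence", "group", "z_confidence:group", "z_movementRT",
    ],
    "z_movementRT*group + z_confidence": [
        "Intercept", "z_movementRT", "group", "z_movementRT:group", "z_confidence",
    ],
}

#: Step-1 scan formula per term of interest (group-moderated main effects).
SCAN_FORMULA_BY_TERM = {
    "correctness": "correctness*group",
    "z_confidence": "z_confidence*group",
    "z_movementRT": "z_movementRT*group",
}

#: Step-2 cluster formula per term (nested random effects, added covariates).
CLUSTER_FORMULA_BY_TERM = {
    "correctness": "correctness*group",
    "z_confidence": "z_confidence*group + z_movementRT",
    "z_movementRT": "z_movementRT*group + z_confidence",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect formula plus random-intercept structure."""

    formula: str
    random: str = "participant"  # or "participant/electrode"

    def __post_init__(self) -> None:
        if self.formula not in MODEL_FORMULAS:
            raise ValueError(f"unknown formula {self.formula!r}")
        if self.random not in ("participant", "participant/electrode"):
            raise ValueError(f"unknown random structure {self.random!r}")

    @property
    def term_names(self) -> list[str]:
        return MODEL_FORMULAS[self.formula]


def _zscore_by(df: pd.DataFrame, col: str, by: str = "participant") -> np.ndarray:
    z = df.groupby(by)[col].transform(lambda s: (s - s.mean()) / max(s.std(ddof=0), 1e-12))
    return z.to_numpy(dtype=float)


def covariate_frame(meta: pd.DataFrame) -> pd.DataFrame:
    """Derive the model covariates from trial metadata."""
    out = pd.DataFrame(index=meta.index)
    out["correctness"] = meta["correct"].to_numpy(dtype=float)
    out["group"] = (meta["group"].astype(str) == "ssd").astype(float).to_numpy()
    if "z_confidence" in meta.columns:
        out["z_confidence"] = meta["z_confidence"].to_numpy(dtype=float)
    elif "confidence" in meta.columns:
        out["z_confidence"] = _zscore_by(meta, "confidence")
    if "z_onset" in meta.columns:
        out["z_movementRT"] = meta["z_onset"].to_numpy(dtype=float)
    elif "onset" in meta.columns:
        out["z_movementRT"] = _zscore_by(meta, "onset")
    return out


def build_design(meta: pd.DataFrame, formula: str) -> tuple[np.ndarray, list[str]]:
    """Design matrix (n x p) and column names for one of the model formulas."""
    terms = MODEL_FORMULAS[formula]
    cov = covariate_frame(meta)
    cols = []
    for term in terms:
        if term == "Intercept":
            cols.append(np.ones(len(meta)))
        elif ":" in term:
            a, b = term.split(":")
            cols.append(cov[a].to_numpy() * cov[b].to_numpy())
        else:
            cols.append(cov[term].to_numpy())
    return np.column_stack(cols), list(terms)


def participant_codes(meta: pd.DataFrame) -> np.ndarray:
    return pd.factorize(meta["participant"].astype(str))[0]
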