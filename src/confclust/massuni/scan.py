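"""Step 1: per-(sample, electrode) mixed-model scans with joint FDR correction.

The FDR family for a given term spans all electrodes x samples in the scan
window (the most conservative reading of per-sample, per-electrode testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..epochs import EpochArray
from .design import SCAN_FORMULA_BY_TERM, build_design, participant_codes
from .fastlmm import reml_scan
from .fdr import benjamini_hochberg

SCAN_WINDOW = (0.0, 0.5)  # closed interval, seconds post movement onset


@dataclass
class ScanGrid:
    """Per-(electrode, sample) coefficients, p-values and BH q-values."""

    term: str
    electrodes: list[str]
    times: np.ndarray
    coef: np.ndarray       # (E, T)
    pval: np.ndarray       # (E, T)
    qval: np.ndarray       # (E, T)
    reject: np.ndarray     # (E, T) bool
    alpha: float
    family_size: int
    selected: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for e, ch in enumerate(self.electrodes):
            for t_i, t in enumerate(self.times):
                rows.append({
                    "term": self.term, "electrode": ch, "time": t,
                    "coef": self.coef[e, t_i], "p": self.pval[e, t_i],
                    "q": self.qval[e, t_i], "significant": bool(self.reject[e, t_i]),
                })
        return pd.DataFrame(rows)


def scan_responsive_electrodes(
    epochs: EpochArray,
    term: str,
    roi: list[str],
    window: tuple[float, float] = SCAN_WINDOW,
    alpha: float = 0.05,
    formula: str | None = None,
    scan_channels: list[str] | None = None,
) -> ScanGrid:
    """Identify ROI electrodes with at least one FDR-significant sample.

    The model per cell is the step-1 regression for ``term`` with a random
    intercept per participant.  The scan (and the BH family) covers all
    ``scan_channels`` (default: every channel in the epochs) x samples;
    the *selection* is then intersected with the region of interest.
    """
    if not roi:
        raise ValueError("empty region of interest")
    missing = [ch for ch in roi if ch not in epochs.channels]
    if missing:
        raise ValueError(f"ROI channels not present in epochs: {missing}")
    if formula is None:
        formula = SCAN_FORMULA_BY_TERM[term]
    if scan_channels is None:
        scan_channels = list(epochs.channels)

    tmask = epochs.time_mask(*window)
    times = epochs.times[tmask]
    e_idx = [epochs.channel_index(ch) for ch in scan_channels]
    # (trials, E, T) -> columns are electrode-major
    Y = epochs.data[np.ix_(np.arange(epochs.n_trials), e_idx, np.flatnonzero(tmask))]
    n_tr, E, T = Y.shape
    Y = Y.reshape(n_tr, E * T)

    X, names = build_design(epochs.metadata, formula)
    codes = participant_codes(epochs.metadata)
    fit = reml_scan(X, Y, [codes], names)
    ti = fit.term_index(term)
    coef = fit.beta[ti].reshape(E, T)
    pval = fit.pval[ti].reshape(E, T)
    reject, qval = benjamini_hochberg(pval, alpha)
    roi_set = set(roi)
    selected = [ch for e, ch in enumerate(scan_channels)
                if ch in roi_set and reject[e].any()]
    return ScanGrid(
        term=term, electrodes=list(scan_channels), times=times, coef=coef,
        pval=pval, qval=qval.reshape(E, T), reject=reject, alpha=alpha,
        family_size=int(pval.size), selected=selected,
    )
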