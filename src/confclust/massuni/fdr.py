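"""Benjamini-Hochberg step-up false discovery rate control."""

from __future__ import annotations

import numpy as np


def benjamini_hochberg(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH procedure.

    Returns (reject, qvalues) with the input shape preserved.  q-values are the
    usual monotone adjusted p-values (q >= p elementwise, capped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(p.shape, dtype=bool), p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order]

    q = ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)

    qvalues = np.empty(m)
    qvalues[order] = q

    crit = ranked <= alpha * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if crit.any():
        k = int(np.max(np.flatnonzero(crit)))
        reject[order[: k + 1]] = True
    return reject.reshape(p.shape), qvalues.reshape(p.shape)
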