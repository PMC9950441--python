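"""Vectorized REML for random-intercept linear mixed models.

The mass-univariate scans fit the same fixed-effect design and grouping
structure to thousands of response vectors (one per electrode x time sample).
This module profiles the REML criterion over the variance ratios
psi_f = sigma_f^2 / sigma_e^2 (one per random-intercept factor) on a log grid
with local refinement, sharing every design-dependent quantity across response
columns.  Only sufficient statistics (X'X, Z'X, Z'Z, Z'Y, ...) touch the data.

p-values use Wald t statistics with n - p residual degrees of freedom; this is
the documented normal/t approximation fallback (no Satterthwaite correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular


@dataclass
class LmmScan:
    """Per-column mixed-model results for a shared design."""

    term_names: list[str]
    beta: np.ndarray      # (p, K)
    se: np.ndarray        # (p, K)
    tstat: np.ndarray     # (p, K)
    pval: np.ndarray      # (p, K)
    sigma2: np.ndarray    # (K,) residual variance
    ratios: np.ndarray    # (n_factors, K) variance ratios sigma_f^2/sigma_e^2
    df: float

    def term_index(self, name: str) -> int:
        return self.term_names.index(name)


class _Sufficient:
    """Shared sufficient statistics for a design + grouping structure."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, factors: list[np.ndarray]):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError(
                "rank-deficient fixed-effects design; drop collinear terms"
            )
        self.n, self.p = n, p
        self.K = Y.shape[1]
        levels = [int(f.max()) + 1 for f in factors]
        self.block_sizes = levels
        self.slices = []
        off = 0
        for L in levels:
            self.slices.append(slice(off, off + L))
            off += L
        q = off
        self.q = q

        ZtZ = np.zeros((q, q))
        ZtX = np.zeros((q, p))
        ZtY = np.zeros((q, self.K))
        for fi, codes in enumerate(factors):
            sl = self.slices[fi]
            counts = np.bincount(codes, minlength=levels[fi]).astype(float)
            ZtZ[sl, sl] = np.diag(counts)
            np.add.at(ZtX[sl], codes, X)
            np.add.at(ZtY[sl], codes, Y)
            for fj in range(fi + 1, len(factors)):
                sl2 = self.slices[fj]
                cross = np.zeros((levels[fi], levels[fj]))
                np.add.at(cross, (codes, factors[fj]), 1.0)
                ZtZ[sl, sl2] = cross
                ZtZ[sl2, sl] = cross.T
        self.ZtZ, self.ZtX, self.ZtY = ZtZ, ZtX, ZtY
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.YtY = np.einsum("ij,ij->j", Y, Y)

    def evaluate(self, psi: np.ndarray, columns: slice | np.ndarray = slice(None)):
        """Profiled REML criterion (per column) and GLS pieces at ratio vector psi."""
        d = np.concatenate([np.full(L, max(float(ps), 0.0))
                            for L, ps in zip(self.block_sizes, psi)])
        s = np.sqrt(d)
        M = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        L = np.linalg.cholesky(M)
        logdet_M = 2.0 * np.sum(np.log(np.diag(L)))

        A = s[:, None] * self.ZtX
        B = s[:, None] * self.ZtY[:, columns]
        LA = solve_triangular(L, A, lower=True)
        LB = solve_triangular(L, B, lower=True)

        XtVinvX = self.XtX - LA.T @ LA
        XtVinvY = self.XtY[:, columns] - LA.T @ LB
        ytViny = self.YtY[columns] - np.einsum("ij,ij->j", LB, LB)

        cf = cho_factor(XtVinvX)
        logdet_XVX = 2.0 * np.sum(np.log(np.diag(cf[0])))
        beta = cho_solve(cf, XtVinvY)
        yPy = np.maximum(ytViny - np.einsum("ij,ij->j", XtVinvY, beta), 1e-300)
        dfres = self.n - self.p
        crit = logdet_M + logdet_XVX + dfres * np.log(yPy)
        return crit, beta, yPy, cf


def _grid(n_points: int) -> np.ndarray:
    return np.concatenate([[0.0], np.logspace(-3.0, 2.0, n_points)])


def reml_scan(
    X: np.ndarray,
    Y: np.ndarray,
    factors: list[np.ndarray],
    term_names: list[str],
    n_grid: int = 13,
    n_refine: int = 5,
) -> LmmScan:
    """REML random-intercept fit for every column of Y.

    ``factors`` are integer-coded grouping vectors (e.g. participant, or
    participant plus electrode-within-participant), each contributing an
    independent random intercept.
    """
    suff = _Sufficient(X, Y, factors)
    n_f = len(factors)
    axes = [_grid(n_grid) for _ in range(n_f)]
    grids = np.stack([g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1)

    best_crit = np.full(suff.K, np.inf)
    best_psi = np.zeros((suff.K, n_f))
    for psi in grids:
        crit, *_ = suff.evaluate(psi)
        better = crit < best_crit
        best_crit = np.where(better, crit, best_crit)
        best_psi[better] = psi

    # local refinement with a shrinking multiplicative step so the selected
    # ratio converges toward the REML optimum (zero ratios probe small values)
    factors = [1.6, 1.3, 1.15, 1.07, 1.03, 1.015][: max(n_refine, 1)]
    for factor in factors:
        unique, inverse = np.unique(best_psi, axis=0, return_inverse=True)
        for u_i, psi0 in enumerate(unique):
            cols = np.flatnonzero(inverse == u_i)
            for fi in range(n_f):
                base = psi0[fi]
                candidates = ([base / factor, base * factor]
                              if base > 0 else [1e-4, 5e-4])
                for cand in candidates:
                    psi_t = psi0.copy()
                    psi_t[fi] = cand
                    crit, *_ = suff.evaluate(psi_t, cols)
                    better = crit < best_crit[cols]
                    if better.any():
                        idx = cols[better]
                        best_crit[idx] = crit[better]
                        best_psi[idx] = psi_t

    # final extraction at the selected ratios
    p = suff.p
    beta = np.empty((p, suff.K))
    se = np.empty((p, suff.K))
    sigma2 = np.empty(suff.K)
    unique, inverse = np.unique(best_psi, axis=0, return_inverse=True)
    dfres = suff.n - p
    for u_i, psi in enumerate(unique):
        cols = np.flatnonzero(inverse == u_i)
        _, b, yPy, cf = suff.evaluate(psi, cols)
        s2 = yPy / dfres
        cov_unit = cho_solve(cf, np.eye(p))
        beta[:, cols] = b
        sigma2[cols] = s2
        se[:, cols] = np.sqrt(np.outer(np.diag(cov_unit), s2))

    tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dfres)
    return LmmScan(
        term_names=list(term_names), beta=beta, se=se, tstat=tstat, pval=pval,
        sigma2=sigma2, ratios=best_psi.T, df=float(dfres),
    )
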