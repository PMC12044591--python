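"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Bilinear decomposition D ~= C S^T with non-negativity constraints on both the
concentration profiles C (rows: observations) and the component spectra S
(rows: wavenumber points).  Each half-step solves a batch of non-negative
least-squares problems with scipy's NNLS.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import nnls

__all__ = ["mcr_als", "McrConvergenceWarning"]


class McrConvergenceWarning(UserWarning):
    """MCR-ALS did not reach the residual tolerance within the budget."""


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_i - b_i|| s.t. x_i >= 0 for every column b_i of B."""
    out = np.zeros((B.shape[1], A.shape[1]))
    for i in range(B.shape[1]):
        out[i], _ = nnls(A, B[:, i])
    return out


def mcr_als(
    D: np.ndarray,
    S_init: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    fix_spectra: bool = False,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Factor ``D`` (m x g) as C @ S with C (m x k), S (k x g) >= 0.

    ``S_init`` (k x g) seeds the component spectra (typically library means).
    With ``fix_spectra`` the spectra are held at ``S_init`` (equality
    constraint for known components) and only C is solved — this keeps the
    decomposition identifiable when the data matrix is (near) rank-deficient,
    e.g. a segment of constant composition.  Returns ``(C, S, converged)``;
    convergence is a relative change of the residual Frobenius norm below
    ``tol``.
    """
    D = np.asarray(D, dtype=float)
    S = np.maximum(np.asarray(S_init, dtype=float), 0.0)
    if fix_spectra:
        return _nnls_rows(S.T, D.T), S, True
    norms = np.linalg.norm(S, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    S = S / norms
    prev_residual = np.inf
    converged = False
    C = np.zeros((D.shape[0], S.shape[0]))
    for _ in range(max_iter):
        C = _nnls_rows(S.T, D.T)  # rows of D against spectra
        S_new = _nnls_rows(C, D)  # columns of D against concentrations
        S_new = S_new.T
        norms = np.linalg.norm(S_new, axis=1, keepdims=True)
        degenerate = norms[:, 0] < 1e-12
        if degenerate.any():
            # component vanished: keep its previous (normalised) spectrum
            S_new[degenerate] = S[degenerate]
            norms[degenerate] = 1.0
        S = S_new / norms
        residual = float(np.linalg.norm(D - C @ S))
        if prev_residual - residual <= tol * max(prev_residual, 1e-30):
            converged = True
            break
        prev_residual = residual
    if not converged:
        warnings.warn(
            f"MCR-ALS did not converge within {max_iter} iterations",
            McrConvergenceWarning,
        )
    C = _nnls_rows(S.T, D.T)  # final concentrations for the final spectra
    return C, S, converged
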