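"""Kernel SHAP: Shapley-value attribution by weighted coalition regression.

For the small feature counts this pipeline produces (six after screening),
all 2^M coalitions are enumerated, so the kernel-weighted least squares
recovers the exact Shapley values of the conditional-expectation game
``v(S) = E_background[f(x_S, X_{S̄})]`` and the efficiency property
``Σ φ_j = f(x) − E f`` holds by construction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import comb

__all__ = ["kernel_shap"]

_MAX_EXACT = 16


def _coalition_matrix(m: int) -> tuple[np.ndarray, np.ndarray]:
    """All non-trivial coalitions and their Shapley kernel weights."""
    masks, weights = [], []
    for size in range(1, m):
        w = (m - 1) / (comb(m, size) * size * (m - size))
        for subset in combinations(range(m), size):
            row = np.zeros(m, dtype=bool)
            row[list(subset)] = True
            masks.append(row)
            weights.append(w)
    return np.array(masks), np.array(weights)


def kernel_shap(
    f,
    background: np.ndarray,
    X_explain: np.ndarray,
    batch_size: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Exact kernel SHAP values.

    Parameters
    ----------
    f : callable mapping an (n, M) array to (n,) model outputs
    background : (B, M) reference sample defining E[f]
    X_explain : (N, M) points to attribute

    Returns ``(phi, base)`` where ``phi`` is (N, M) and
    ``base = mean f(background)``.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    n_bg, m = background.shape
    if X_explain.shape[1] != m:
        raise ValueError("feature dimension mismatch between background and explain set")
    if m > _MAX_EXACT:
        raise ValueError(f"exact enumeration supports at most {_MAX_EXACT} features (got {m})")

    base = float(np.mean(f(background)))
    fx = np.asarray(f(X_explain), dtype=float)

    if m == 1:
        return (fx - base)[:, None], base

    masks, weights = _coalition_matrix(m)
    n_coal = masks.shape[0]
    n_exp = X_explain.shape[0]

    # v[i, s] = mean over background of f(x_i on masks[s], background elsewhere)
    v = np.empty((n_exp, n_coal))
    rows_per_eval = n_bg
    chunk = max(1, batch_size // rows_per_eval)
    for s0 in range(0, n_coal, chunk):
        sl = slice(s0, min(s0 + chunk, n_coal))
        msk = masks[sl]  # (c, m)
        for i in range(n_exp):
            # (c, B, m): background with explained values substituted on S
            synth = np.broadcast_to(background, (msk.shape[0], n_bg, m)).copy()
            synth[:, :, :] = np.where(msk[:, None, :], X_explain[i][None, None, :], synth)
            out = f(synth.reshape(-1, m)).reshape(msk.shape[0], n_bg)
            v[i, sl] = out.mean(axis=1)

    # weighted least squares with the efficiency constraint folded in:
    # phi_M is eliminated via sum(phi) = fx - base
    z = masks.astype(float)
    zt = z[:, :-1] - z[:, -1:]
    w = weights
    a = zt.T @ (w[:, None] * zt)
    phi = np.empty((n_exp, m))
    a_inv = np.linalg.pinv(a)
    for i in range(n_exp):
        yv = (v[i] - base) - z[:, -1] * (fx[i] - base)
        b = zt.T @ (w * yv)
        head = a_inv @ b
        phi[i, :-1] = head
        phi[i, -1] = (fx[i] - base) - head.sum()
    return phi, base
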