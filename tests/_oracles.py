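"""Independent reference implementations used only to validate the package.

Each oracle is deliberately naive (loops, enumeration, coordinate
methods) and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def cd_lasso(A: np.ndarray, b: np.ndarray, gamma: float,
             max_iter: int = 20000, tol: float = 1e-12) -> np.ndarray:
    """Coordinate-descent minimizer of theta'A theta - 2 b'theta + gamma||theta||_1.

    Exact single-coordinate updates: holding the others fixed, the optimum
    of coordinate i is soft(b_i - sum_{j!=i} A_ij theta_j, gamma/2) / A_ii.
    """
    dim = b.size
    theta = np.zeros(dim)
    for _ in range(max_iter):
        delta = 0.0
        for i in range(dim):
            r = b[i] - A[i] @ theta + A[i, i] * theta[i]
            if A[i, i] <= 0:
                continue
            new = np.sign(r) * max(abs(r) - gamma / 2.0, 0.0) / A[i, i]
            delta = max(delta, abs(new - theta[i]))
            theta[i] = new
        if delta < tol:
            break
    return theta


def direct_weighted_objective(windows, lam: float, theta: np.ndarray) -> float:
    """Direct evaluation of sum_j lam^(k-j) ||y_j - X_j theta||^2."""
    k = len(windows)
    total = 0.0
    for j, (X, y) in enumerate(windows, start=1):
        r = y - X @ theta
        total += lam ** (k - j) * float(r @ r)
    return total


def brute_force_decoding_response(s1, s2, h, w1, w2, mu):
    """Double-loop evaluation of e_t = w1_t (s1*h)_t + w2_t (s2*h)_t + mu."""
    T = len(s1)
    e = np.zeros(T)
    for t in range(T):
        acc1 = acc2 = 0.0
        for tau in range(len(h)):
            if t - tau >= 0:
                acc1 += h[tau] * s1[t - tau]
                acc2 += h[tau] * s2[t - tau]
        e[t] = w1[t] * acc1 + w2[t] * acc2 + mu
    return e


def brute_force_encoding_response(s1, s2, h_att, h_unatt, schedule):
    """Loop evaluation of E_t with attention-modulated kernels."""
    T = len(s1)
    e = np.zeros(T)
    for t in range(T):
        for tau in range(len(h_att)):
            if t - tau < 0:
                continue
            if schedule[t] == 1:
                e[t] += h_att[tau] * s1[t - tau] + h_unatt[tau] * s2[t - tau]
            else:
                e[t] += h_unatt[tau] * s1[t - tau] + h_att[tau] * s2[t - tau]
    return e


def grid_map_z(r: np.ndarray, eta: np.ndarray, z0: float, c0: float,
               lo: float = -8.0, hi: float = 8.0, step: float = 0.01) -> np.ndarray:
    """Exact grid-restricted joint MAP of the logistic chain.

    The posterior factorizes over consecutive pairs, so the joint maximum
    over the dense grid is found exactly by dynamic programming (Viterbi):
    no approximation beyond the grid resolution itself.
    """
    grid = np.arange(lo, hi + step / 2, step)
    K = r.size
    n = grid.size
    unary = r[:, None] * grid[None, :] - np.logaddexp(0.0, grid)[None, :]
    # pairwise transition cost from state i (previous) to state j (current)
    diff = grid[None, :] - c0 * grid[:, None]  # [i, j]
    score = -(grid - c0 * z0) ** 2 / (2 * eta[0]) + unary[0]
    back = np.zeros((K, n), dtype=int)
    for k in range(1, K):
        cand = score[:, None] - diff ** 2 / (2 * eta[k])  # [i, j]
        back[k] = np.argmax(cand, axis=0)
        score = cand[back[k], np.arange(n)] + unary[k]
    z = np.empty(K)
    j = int(np.argmax(score))
    z[-1] = grid[j]
    for k in range(K - 1, 0, -1):
        j = back[k, j]
        z[k - 1] = grid[j]
    return z


def pearson(y, yhat):
    """Textbook Pearson correlation coefficient."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ym, yhm = y.mean(), yhat.mean()
    num = np.sum((y - ym) * (yhat - yhm))
    den = np.sqrt(np.sum((y - ym) ** 2) * np.sum((yhat - yhm) ** 2))
    return num / den
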