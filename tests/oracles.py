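"""Independent reference computations used only by the test suite.

Each oracle takes a route algorithmically disjoint from the library code it
checks: scalar grid search for the elementwise shrinkage, the Moreau dual
(projection onto the spectral-norm ball by projected gradient ascent) for
singular value thresholding, an SLSQP quadratic program for the
sum-to-one sparse codes, the classical inexact ALM with an exact
linear-solve Z-step for the plain low-rank representation program, and
direct textbook formulas for the statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def prox_l1_grid(a: float, tau: float, width: float = 6.0,
                 n: int = 200_001) -> float:
    """Minimize tau|z| + 0.5 (z - a)^2 over a fine grid around a."""
    zs = np.linspace(a - width, a + width, n)
    obj = tau * np.abs(zs) + 0.5 * (zs - a) ** 2
    return float(zs[np.argmin(obj)])


def svt_dual(A: np.ndarray, tau: float, iters: int = 500) -> np.ndarray:
    """Nuclear-norm prox via its Moreau dual.

    The dual of min_Z tau||Z||_* + 0.5||Z - A||^2 is the projection of A
    onto the spectral-norm ball of radius tau (singular values clipped,
    not shrunk); projected gradient ascent converges to it and the primal
    solution is A minus the projection.
    """
    W = np.zeros_like(A)
    for _ in range(iters):
        W = W + 0.5 * (A - W)
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        W = (U * np.minimum(s, tau)) @ Vt
    return A - W


def sparse_code_slsqp(X: np.ndarray, i: int, beta: float,
                      sum_to_one: bool = True) -> tuple[float, np.ndarray]:
    """min_s ||x_i - X_(-i) s||^2 + beta ||s||_1 (s.t. 1^T s = 1) by SLSQP
    on the split s = p - q, p, q >= 0.  Returns (objective, s)."""
    D, N = X.shape
    cols = [j for j in range(N) if j != i]
    A, y = X[:, cols], X[:, i]
    n = len(cols)

    def f(w):
        p, q = w[:n], w[n:]
        r = y - A @ (p - q)
        return float(r @ r + beta * (p.sum() + q.sum()))

    cons = ([{"type": "eq",
              "fun": lambda w: w[:n].sum() - w[n:].sum() - 1.0}]
            if sum_to_one else [])
    w0 = np.concatenate([np.full(n, 0.5), np.full(n, 0.3)])
    res = minimize(f, w0, bounds=[(0, None)] * (2 * n), constraints=cons,
                   method="SLSQP", options={"maxiter": 3000, "ftol": 1e-14})
    return float(res.fun), res.x[:n] - res.x[n:]


def lrr_ialm(X: np.ndarray, gamma: float, tol: float = 1e-9,
             max_iter: int = 5000) -> tuple[np.ndarray, np.ndarray, float]:
    """Classical inexact ALM for min ||Z||_* + gamma ||E||_1, X = XZ + E.

    Uses the exact linear-solve Z-step (a different splitting and update
    path than the linearized solver under test).  Returns (Z, E, objective)
    with E = X - XZ at the iterate.
    """
    D, N = X.shape
    Z = np.zeros((N, N))
    E = np.zeros((D, N))
    Y1 = np.zeros((D, N))
    Y2 = np.zeros((N, N))
    mu, mu_max, rho = 1e-6, 1e10, 1.1
    XtX = X.T @ X
    I = np.eye(N)
    normX = np.linalg.norm(X)
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(Z + Y2 / mu, full_matrices=False)
        J = (U * np.maximum(s - 1.0 / mu, 0.0)) @ Vt
        Z = np.linalg.solve(I + XtX,
                            XtX - X.T @ E + J + (X.T @ Y1 - Y2) / mu)
        Arg = X - X @ Z + Y1 / mu
        E = np.sign(Arg) * np.maximum(np.abs(Arg) - gamma / mu, 0.0)
        R1 = X - X @ Z - E
        R2 = Z - J
        Y1 += mu * R1
        Y2 += mu * R2
        mu = min(mu_max, rho * mu)
        if max(np.linalg.norm(R1), np.linalg.norm(R2)) / normX < tol:
            break
    obj = (np.linalg.svd(Z, compute_uv=False).sum()
           + gamma * np.abs(X - X @ Z).sum())
    return Z, X - X @ Z, float(obj)


def degrees_loops(H: np.ndarray, w: np.ndarray):
    """Brute-force vertex and hyperedge degrees."""
    n, ne = H.shape
    d_v = np.zeros(n)
    delta_e = np.zeros(ne)
    for i in range(n):
        for j in range(ne):
            d_v[i] += w[j] * H[i, j]
            delta_e[j] += H[i, j]
    return d_v, delta_e


def metrics_loops(y_true_pm, y_pred_pm, scores):
    """Brute-force confusion counting and pairwise AUC."""
    tp = fp = tn = fn = 0
    for yt, yp in zip(y_true_pm, y_pred_pm):
        if yt == 1 and yp == 1:
            tp += 1
        elif yt == 1:
            fn += 1
        elif yp == 1:
            fp += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    wins = ties = pairs = 0
    for si, yi in zip(scores, y_true_pm):
        for sj, yj in zip(scores, y_true_pm):
            if yi == 1 and yj == -1:
                pairs += 1
                if si > sj:
                    wins += 1
                elif si == sj:
                    ties += 1
    auc = (wins + 0.5 * ties) / pairs if pairs else float("nan")
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    return {"ACC": (tp + tn) / n, "SEN": sen, "SPE": spe,
            "BAC": (sen + spe) / 2,
            "PPV": tp / (tp + fp) if tp + fp else float("nan"),
            "NPV": tn / (tn + fn) if tn + fn else float("nan"),
            "AUC": auc}


def friedman_alt(rank_table: np.ndarray) -> float:
    """Friedman chi-square via the algebraically different textbook form
    12/(N k (k+1)) * sum_j R_j^2 - 3 N (k+1) with R_j the rank sums."""
    R = np.asarray(rank_table, dtype=float)
    k, N = R.shape
    Rj = R.sum(axis=1)
    return float(12.0 / (N * k * (k + 1)) * np.sum(Rj ** 2) - 3.0 * N * (k + 1))


def nemenyi_cd_alt(k: int, N: int, alpha: float) -> float:
    """CD from the studentized-range quantile at infinite df."""
    from scipy.stats import studentized_range
    q = studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * N)))
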