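"""Sparse-representation hypergraphs and the normalized hyper-Laplacian.

Each sample in a group becomes a vertex; hyperedge j is built from sample
j's sparse code over the remaining samples (an l1-regularized regression of
x_j on the other columns), so an edge can join any number of vertices and
encodes higher-order, globally informed sample relations — unlike a
Euclidean k-NN graph, the code is noise-robust and reflects global
structure.  The normalized hyper-Laplacian

    L = I - D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}

is symmetric PSD with null vector d_v^{1/2}; its quadratic form
tr(Z L Z^T) penalizes representation differences inside hyperedges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso

__all__ = [
    "SparseCodeMatrix",
    "Hypergraph",
    "HyperLaplacian",
    "solve_sparse_codes",
    "build_incidence",
    "vertex_and_edge_degrees",
    "hyper_laplacian",
    "build_group_hypergraph",
]


@dataclass
class SparseCodeMatrix:
    """N x N sparse representation coefficients with zero diagonal.

    Row i holds sample i's code over the other samples; ``sr_beta`` is the
    l1 weight of the coding problem (distinct from the representation
    learner's hypergraph weight).
    """

    S: np.ndarray
    sr_beta: float
    sum_to_one: bool
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class Hypergraph:
    """Incidence matrix H (N x N_e, nonnegative), edge weights and degrees."""

    H: np.ndarray
    w: np.ndarray
    d_v: np.ndarray
    delta_e: np.ndarray
    theta: float


@dataclass
class HyperLaplacian:
    L: np.ndarray


def _prox_columns_sum_to_one(V: np.ndarray, t: float,
                             bisect_iters: int = 40) -> np.ndarray:
    """Columnwise prox of t*||.||_1 on {1^T c = 1, c_ii = 0}, vectorized.

    For each column the minimizer of t||c||_1 + 0.5||c - v||^2 subject to
    the sum-to-one constraint is soft(v - nu, t) with a per-column shift nu
    making the off-diagonal entries sum to one; the sum is nonincreasing in
    nu, so vectorized bisection over all columns finds every shift at once,
    followed by an exact affine correction on the active set.
    """
    N = V.shape[0]
    offdiag = ~np.eye(N, dtype=bool)
    lo = V.min(axis=0) - t - 1.0
    hi = V.max(axis=0) + t + 1.0
    for _ in range(bisect_iters):
        nu = 0.5 * (lo + hi)
        S = np.sign(V - nu) * np.maximum(np.abs(V - nu) - t, 0.0)
        tot = np.where(offdiag, S, 0.0).sum(axis=0)
        grow = tot > 1.0
        lo = np.where(grow, nu, lo)
        hi = np.where(grow, hi, nu)
    nu = 0.5 * (lo + hi)
    S = np.sign(V - nu) * np.maximum(np.abs(V - nu) - t, 0.0)
    np.fill_diagonal(S, 0.0)
    free = offdiag & (np.abs(V - nu) > t)
    nfree = np.maximum(free.sum(axis=0), 1)
    S += free * ((1.0 - S.sum(axis=0)) / nfree)
    return S


def _fista_codes_sum_to_one(X: np.ndarray, beta: float,
                            max_iter: int = 500,
                            tol: float = 1e-9) -> np.ndarray:
    """All-columns FISTA for min_C sum_i ||x_i - X c_i||^2 + beta||c_i||_1
    s.t. 1^T c_i = 1, c_ii = 0.  Returns C with codes as columns."""
    N = X.shape[1]
    G = X.T @ X
    Lip = 2.0 * np.linalg.norm(X, 2) ** 2 + 1e-12
    C = (np.ones((N, N)) - np.eye(N)) / max(N - 1, 1)
    Cy = C.copy()
    tk = 1.0
    f_prev = np.inf
    for _ in range(max_iter):
        grad = 2.0 * (G @ Cy - G)
        C_new = _prox_columns_sum_to_one(Cy - grad / Lip, beta / Lip)
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        Cy = C_new + ((tk - 1.0) / tk_new) * (C_new - C)
        C = C_new
        tk = tk_new
        R = X - X @ C
        f = float((R * R).sum() + beta * np.abs(C).sum())
        if abs(f_prev - f) <= tol * max(1.0, abs(f)):
            break
        f_prev = f
    return C


def solve_sparse_codes(X: np.ndarray, sr_beta: float = 0.1,
                       sum_to_one: bool = True,
                       max_iter: int = 500,
                       tol: float = 1e-9) -> SparseCodeMatrix:
    """Code each column of X over the remaining columns with an l1 penalty.

    Column i's code minimizes ``||x_i - X s_i||^2 + sr_beta * ||s_i||_1``
    with the self-coefficient fixed at zero, subject to ``1^T s_i = 1``
    when ``sum_to_one`` is on.  The constrained problem is solved by FISTA
    with an exact affine-constrained shrinkage prox, so the sum-to-one
    constraint holds to machine precision; the unconstrained problem is a
    plain lasso solved by coordinate descent.

    Parameters
    ----------
    X : ndarray, shape (D, N)
        Samples as columns; N >= 2, all entries finite.
    sr_beta : float
        Sparsity weight (> 0).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a D x N matrix with N >= 2")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in X")
    D, N = X.shape
    if sum_to_one:
        if N == 2:
            S = np.array([[0.0, 1.0], [1.0, 0.0]])  # constraint pins both
        else:
            S = _fista_codes_sum_to_one(X, sr_beta, max_iter=max_iter,
                                        tol=tol).T
    else:
        S = np.zeros((N, N))
        idx = np.arange(N)
        for i in range(N):
            cols = idx[idx != i]
            # sklearn lasso: (1/(2n))||y-Aw||^2 + alpha||w||_1 -> alpha=beta/(2D)
            reg = Lasso(alpha=max(sr_beta, 1e-12) / (2.0 * D),
                        fit_intercept=False, max_iter=50_000, tol=1e-10)
            reg.fit(X[:, cols], X[:, i])
            S[i, cols] = reg.coef_
    residuals = np.linalg.norm(X - X @ S.T, axis=0)
    return SparseCodeMatrix(S=S, sr_beta=sr_beta, sum_to_one=sum_to_one,
                            residuals=residuals)


def build_incidence(codes: SparseCodeMatrix | np.ndarray, theta: float = 1e-4,
                    max_edge_size: int | None = None,
                    weight_scheme: str = "uniform") -> Hypergraph:
    """Threshold sparse codes into a hyperedge incidence matrix.

    Hyperedge j is centered on sample j: it contains vertex i with incidence
    ``|s_{ji}|`` whenever ``|s_{ji}| > theta``, plus the centroid itself with
    incidence 1 (so no edge is ever empty).  ``max_edge_size`` keeps only
    the that-many largest off-centroid entries.  Edge weights are uniform by
    default; ``weight_scheme="incidence_sum"`` uses the column sums of H.
    """
    S = codes.S if isinstance(codes, SparseCodeMatrix) else np.asarray(codes, float)
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    N = S.shape[0]
    A = np.abs(S.T)          # A[i, j] = |s_{ji}|: vertex i's weight in edge j
    H = np.where(A > theta, A, 0.0)
    np.fill_diagonal(H, 0.0)
    if max_edge_size is not None:
        for j in range(N):
            col = H[:, j]
            nz = np.flatnonzero(col)
            if nz.size > max_edge_size:
                keep = nz[np.argsort(col[nz])[-max_edge_size:]]
                mask = np.zeros(N, bool)
                mask[keep] = True
                col[~mask] = 0.0
    np.fill_diagonal(H, 1.0)  # centroid self-membership
    if weight_scheme == "uniform":
        w = np.ones(N)
    elif weight_scheme == "incidence_sum":
        w = H.sum(axis=0)
    else:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    d_v, delta_e = vertex_and_edge_degrees_raw(H, w)
    return Hypergraph(H=H, w=w, d_v=d_v, delta_e=delta_e, theta=theta)


def vertex_and_edge_degrees_raw(H: np.ndarray, w: np.ndarray):
    """d_v(i) = sum_j w_j H(i,j);  delta_e(j) = sum_i H(i,j)."""
    return H @ w, H.sum(axis=0)


def vertex_and_edge_degrees(hg: Hypergraph):
    return vertex_and_edge_degrees_raw(hg.H, hg.w)


def hyper_laplacian(hg: Hypergraph) -> HyperLaplacian:
    """Normalized hyper-Laplacian ``I - Dv^{-1/2} H W De^{-1} H^T Dv^{-1/2}``.

    Requires every vertex degree positive — guaranteed by centroid
    self-membership; a zero degree signals a construction bug.
    """
    d_v, delta_e = vertex_and_edge_degrees(hg)
    if np.any(d_v <= 0):
        raise ValueError("zero vertex degree: hypergraph construction bug")
    if np.any(delta_e <= 0):
        raise ValueError("empty hyperedge: hypergraph construction bug")
    inv_sqrt_dv = 1.0 / np.sqrt(d_v)
    Hn = hg.H * inv_sqrt_dv[:, None]          # Dv^{-1/2} H
    M = (Hn * (hg.w / delta_e)) @ Hn.T        # Dv^-1/2 H W De^-1 H^T Dv^-1/2
    L = np.eye(len(d_v)) - M
    L = 0.5 * (L + L.T)                       # kill round-off asymmetry
    return HyperLaplacian(L=L)


def export_hypergraph(hg: Hypergraph, matrix_path=None, edge_list_path=None,
                      laplacian: HyperLaplacian | None = None,
                      laplacian_path=None) -> None:
    """Write the incidence matrix and/or an (edge, vertex, incidence,
    weight) edge list and/or the Laplacian as dense text files."""
    if matrix_path is not None:
        np.savetxt(matrix_path, hg.H)
    if edge_list_path is not None:
        rows = ["edge_id\tvertex_id\tincidence\tweight"]
        for j in range(hg.H.shape[1]):
            for i in np.flatnonzero(hg.H[:, j]):
                rows.append(f"{j}\t{i}\t{hg.H[i, j]:.10g}\t{hg.w[j]:.10g}")
        with open(edge_list_path, "w") as fh:
            fh.write("\n".join(rows) + "\n")
    if laplacian is not None and laplacian_path is not None:
        np.savetxt(laplacian_path, laplacian.L)


def build_group_hypergraph(X: np.ndarray, *, sr_beta: float = 0.1,
                           theta: float = 1e-4,
                           sum_to_one: bool = True,
                           max_edge_size: int | None = None,
                           weight_scheme: str = "uniform"
                           ) -> tuple[Hypergraph, HyperLaplacian]:
    """Sparse codes -> incidence -> Laplacian for one group's D x N matrix.

    Degenerate sizes: a single sample gets the 1x1 zero Laplacian (a lone
    vertex in its own edge).
    """
    N = X.shape[1]
    if N < 2:
        H = np.ones((N, N))
        hg = Hypergraph(H=H, w=np.ones(N), d_v=np.ones(N),
                        delta_e=np.ones(N), theta=theta)
        return hg, HyperLaplacian(L=np.zeros((N, N)))
    codes = solve_sparse_codes(X, sr_beta=sr_beta, sum_to_one=sum_to_one)
    hg = build_incidence(codes, theta=theta, max_edge_size=max_edge_size,
                         weight_scheme=weight_scheme)
    return hg, hyper_laplacian(hg)
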