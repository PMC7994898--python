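"""Hypergraph-regularized low-rank representation by linearized ADM.

Per modality-complete group with data matrix X (features x subjects) and
hyper-Laplacian L, the program solved is

    min_{Z,E}  ||Z||_* + lam ||Z||_1 + beta tr(Z L Z^T) + gamma ||E||_1
    s.t.       X = X Z + E,   Z >= 0.

Splitting Z = J (J carries the l1 term and the nonnegativity) gives an
augmented Lagrangian with multipliers G (for the reconstruction constraint)
and Q (for Z = J) and penalty mu.  The Z-step linearizes the smooth part of
the Lagrangian around the current iterate and applies singular value
thresholding; E and J steps are elementwise shrinkages; mu grows
geometrically whenever the iterates stagnate (linearized ADM with adaptive
penalty).  With beta = 0, lam = 0 and nonnegativity off the program reduces
to classical low-rank representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypergraph import Hypergraph, HyperLaplacian, build_group_hypergraph
from .datamodel import ModalityGroup

__all__ = ["HLRRParams", "HLRRSolution", "soft_threshold", "svt",
           "hlrr_solve", "hlrr_solve_groups"]


@dataclass
class HLRRParams:
    """Solver hyperparameters and stopping controls.

    lam, beta, gamma weight the l1 term on Z, the hyper-Laplacian trace and
    the error sparsity; mu0/mu_max/rho0 drive the adaptive penalty; eps1 is
    the relative feasibility tolerance and eps2 the iterate-change
    tolerance.  Defaults follow the reference initialization
    (lam=0.05, beta=2.0, gamma=5.0, rho0=3, mu0=1e-6, mu_max=1e6,
    eps1=eps2=1e-6).
    """

    lam: float = 0.05
    beta: float = 2.0
    gamma: float = 5.0
    mu0: float = 1e-6
    mu_max: float = 1e6
    rho0: float = 3.0
    eps1: float = 1e-6
    eps2: float = 1e-6
    max_iter: int = 500
    nonnegative: bool = True
    # "ladmap": rho=rho0 if mu*max(sqrt(eta)||dZ||, ||dJ||, ||dE||)/||X|| <= eps2,
    #           else rho=rho_idle (mild unconditional growth keeps mu moving)
    # "literal": rho=rho0 under max(eta||dZ||, mu||dJ||, mu||dE||) <= eps2, else 1
    penalty_rule: str = "ladmap"
    rho_idle: float = 1.1

    def __post_init__(self) -> None:
        if min(self.lam, self.beta, self.gamma) < 0:
            raise ValueError("lam, beta, gamma must be nonnegative")
        if not (0 < self.mu0 <= self.mu_max):
            raise ValueError("need 0 < mu0 <= mu_max")
        if self.eps1 <= 0 or self.eps2 <= 0 or self.max_iter < 1:
            raise ValueError("bad stopping controls")


@dataclass
class HLRRSolution:
    """Learned representation and diagnostics for one group.

    J is the exactly nonnegative sparse copy of Z handed to the classifier;
    Z is kept for diagnostics.  ``trace`` records per-iteration objective,
    relative feasibility residual, ||Z - J||_F and mu.
    """

    Z: np.ndarray
    J: np.ndarray
    E: np.ndarray
    G: np.ndarray
    Q: np.ndarray
    converged: bool
    iterations: int
    trace: dict[str, list[float]] = field(default_factory=dict)


def soft_threshold(A: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage sign(a) * max(|a| - tau, 0), the prox of tau|.|_1."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    A = np.asarray(A, dtype=float)
    return np.sign(A) * np.maximum(np.abs(A) - tau, 0.0)


def svt(A: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding, the prox of tau||.||_*.

    Soft-shrinks the singular values of A; the result is unique regardless
    of SVD sign or ordering conventions.
    """
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    A = np.asarray(A, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("non-finite entries in A")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _objective(X, Z, E, L, p: HLRRParams) -> float:
    nuc = np.linalg.svd(Z, compute_uv=False).sum()
    obj = nuc + p.gamma * np.abs(E).sum()
    if p.lam:
        obj += p.lam * np.abs(Z).sum()
    if p.beta and L is not None:
        obj += p.beta * float(np.einsum("ij,jk,ik->", Z, L, Z))
    return float(obj)


def hlrr_solve(X: np.ndarray, L: HyperLaplacian | np.ndarray | None,
               params: HLRRParams | None = None) -> HLRRSolution:
    """Solve the hypergraph-regularized LRR program for one group.

    Parameters
    ----------
    X : ndarray, shape (D, N)
        Group data, samples as columns.
    L : ndarray (N x N), HyperLaplacian, or None
        PSD hyper-Laplacian; None means no hypergraph term (as does beta=0).
    params : HLRRParams

    Returns
    -------
    HLRRSolution with the full per-iteration trace.  Hitting ``max_iter``
    returns ``converged=False`` rather than raising; a non-finite iterate
    raises with the offending iteration index.
    """
    p = params or HLRRParams()
    X = np.asarray(X, dtype=float)
    D, N = X.shape
    Lm = L.L if isinstance(L, HyperLaplacian) else L
    if Lm is not None:
        Lm = np.asarray(Lm, dtype=float)
        if Lm.shape != (N, N):
            raise ValueError(f"L must be {N}x{N}, got {Lm.shape}")
    use_graph = p.beta > 0 and Lm is not None

    normX = np.linalg.norm(X)
    if normX == 0:
        Zz = np.zeros((N, N))
        return HLRRSolution(Z=Zz, J=Zz.copy(), E=np.zeros((D, N)),
                            G=np.zeros((D, N)), Q=np.zeros((N, N)),
                            converged=True, iterations=1,
                            trace={"objective": [0.0], "residual_rel": [0.0],
                                   "dZ": [0.0], "dJ": [0.0], "dE": [0.0],
                                   "mu": [p.mu0]})

    smax2 = np.linalg.norm(X, 2) ** 2              # sigma_max(X)^2
    lmax = (float(np.linalg.eigvalsh(Lm)[-1]) if use_graph else 0.0)

    Z = np.zeros((N, N))
    J = np.zeros((N, N))
    E = np.zeros((D, N))
    G = np.zeros((D, N))
    Q = np.zeros((N, N))
    mu = p.mu0
    XtX = X.T @ X
    XtG = X.T @ G

    trace: dict[str, list[float]] = {k: [] for k in
                                     ("objective", "residual_rel", "dZ",
                                      "dJ", "dE", "mu")}
    converged = False
    it = 0
    for it in range(1, p.max_iter + 1):
        eta = smax2 + 1.0 + (2.0 * p.beta * lmax / mu if use_graph else 0.0)

        # Z-step: linearize the smooth part, then SVT
        R = X - X @ Z - E                          # reconstruction residual
        grad = -XtG + Q + mu * (XtX @ Z - X.T @ (X - E) + (Z - J))
        if use_graph:
            grad = grad + 2.0 * p.beta * (Z @ Lm)
        Z_new = svt(Z - grad / (eta * mu), 1.0 / (eta * mu))

        # E-step
        E_new = soft_threshold(X - X @ Z_new + G / mu, p.gamma / mu)

        # J-step: prox of lam|.|_1 (+ nonnegativity)
        T = Z_new + Q / mu
        if p.nonnegative:
            J_new = np.maximum(T - p.lam / mu, 0.0)
        else:
            J_new = soft_threshold(T, p.lam / mu)

        dZ = float(np.linalg.norm(Z_new - Z))
        dJ = float(np.linalg.norm(J_new - J))
        dE = float(np.linalg.norm(E_new - E))
        Z, J, E = Z_new, J_new, E_new

        R = X - X @ Z - E
        G = G + mu * R
        Q = Q + mu * (Z - J)
        XtG = X.T @ G

        res_rel = float(np.linalg.norm(R) / normX)
        if not (np.isfinite(res_rel) and np.isfinite(dZ)):
            raise FloatingPointError(f"solver diverged at iteration {it}")

        trace["objective"].append(_objective(X, Z, E, Lm if use_graph else None, p))
        trace["residual_rel"].append(res_rel)
        trace["dZ"].append(dZ)
        trace["dJ"].append(dJ)
        trace["dE"].append(dE)
        trace["mu"].append(mu)

        # stopping: iterate change and feasibility (both relative to ||X||_F)
        change = max(dZ, dJ, dE) / normX
        if change <= p.eps2 and res_rel <= p.eps1:
            converged = True
            break

        if p.penalty_rule == "ladmap":
            stagnant = mu * max(np.sqrt(eta) * dZ, dJ, dE) / normX <= p.eps2
            rho = p.rho0 if stagnant else p.rho_idle
        elif p.penalty_rule == "literal":
            stagnant = max(eta * dZ, mu * dJ, mu * dE) <= p.eps2
            rho = p.rho0 if stagnant else 1.0
        else:
            raise ValueError(f"unknown penalty rule {p.penalty_rule!r}")
        mu = min(p.mu_max, rho * mu)

    return HLRRSolution(Z=Z, J=J, E=E, G=G, Q=Q, converged=converged,
                        iterations=it, trace=trace)


def hlrr_solve_groups(groups: list[ModalityGroup],
                      params: HLRRParams | None = None,
                      graph_cfg: dict | None = None
                      ) -> list[tuple[Hypergraph, HLRRSolution]]:
    """Build each group's hypergraph and solve its program independently.

    The groups are modality-complete, so the per-group indicator weights are
    all ones and the joint objective decouples into independent per-group
    problems; singleton groups get the zero Laplacian.
    """
    p = params or HLRRParams()
    cfg = graph_cfg or {}
    out = []
    for g in groups:
        hg, lap = build_group_hypergraph(g.X, **cfg)
        out.append((hg, hlrr_solve(g.X, lap, p)))
    return out


def trace_to_rows(sol: HLRRSolution) -> list[dict]:
    """Trace as row dicts (iteration, objective, residual_rel, dZ, dJ, dE, mu)."""
    keys = ("objective", "residual_rel", "dZ", "dJ", "dE", "mu")
    return [{"iteration": i + 1, **{k: sol.trace[k][i] for k in keys}}
            for i in range(sol.iterations)]
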