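"""L1-penalized Gibbs-likelihood solver.

The objective (to minimize) is

    f(β) = log Σ_background exp(x_i·β) − f̄·β + Σ_j λ_j |β_j|

where f̄ is the presence feature mean — the negative penalized
maximum-entropy log-likelihood per presence.

Algorithm: proximal Newton (glmnet-style).  Each outer iteration freezes
the Gibbs weights w = softmax(Xβ), builds the exact Hessian
H = XᵀWX − μμᵀ (a d×d matrix; d is small), solves the L1-penalized
quadratic subproblem by cyclic coordinate descent (numba-compiled when
available), and takes a backtracked step on the true objective.
Convergence is declared when no KKT condition is violated beyond a small
fraction of the penalty scale.  Coefficients are boxed to ±30: a feature
whose support misses the background sample has an unbounded unpenalized
optimum, and a coordinate pinned at the box satisfies the projected KKT
conditions.  The solver is deterministic.
"""

from __future__ import annotations

import numpy as np

#: Coefficient box (see module docstring).
COEF_BOUND = 30.0

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


def _lse(v: np.ndarray) -> float:
    """Bare log-sum-exp (scipy's wrapper overhead matters in hot loops)."""
    m = float(v.max())
    return m + float(np.log(np.exp(v - m).sum()))


class SolverDiagnostics:
    """Outcome of a solve: convergence flag and iteration / KKT info."""

    def __init__(self, converged: bool, n_iter: int, last_step: float, kkt: float):
        self.converged = converged
        self.n_iter = n_iter
        self.last_step = last_step
        self.kkt = kkt


@njit(cache=True)
def _qp_l1_cd(hess, grad0, lam, beta, delta, max_passes, tol):  # pragma: no cover
    """Coordinate descent on the L1 quadratic subproblem.

    Minimizes  grad0·δ + ½ δᵀHδ + Σ λ_j|β_j + δ_j|  over δ, keeping
    β + δ inside the coefficient box.  ``q = Hδ`` is maintained
    incrementally, so a pass costs O(d²) on the cached Hessian.
    """
    d = hess.shape[0]
    q = hess @ delta
    for _p in range(max_passes):
        biggest = 0.0
        for j in range(d):
            hjj = hess[j, j]
            if hjj < 1e-12:
                hjj = 1e-12
            gj = grad0[j] + q[j]
            bj = beta[j] + delta[j]
            u = bj - gj / hjj
            t = lam[j] / hjj
            if u > t:
                new = u - t
            elif u < -t:
                new = u + t
            else:
                new = 0.0
            if new > COEF_BOUND:
                new = COEF_BOUND
            elif new < -COEF_BOUND:
                new = -COEF_BOUND
            step = new - bj
            if step != 0.0:
                delta[j] += step
                for i in range(d):
                    q[i] += hess[i, j] * step
                a = abs(step)
                if a > biggest:
                    biggest = a
        if biggest < tol:
            break
    return delta


def _kkt_from_grad(g: np.ndarray, lam: np.ndarray, beta: np.ndarray) -> float:
    """Largest projected KKT violation at the current iterate."""
    viol = np.where(
        beta > 0, np.abs(g + lam),
        np.where(beta < 0, np.abs(g - lam), np.maximum(np.abs(g) - lam, 0.0)),
    )
    # at the box only inward moves are feasible: a violation exists iff the
    # objective decreases toward the interior
    viol = np.where(beta >= COEF_BOUND - 1e-9, np.maximum(g + lam, 0.0), viol)
    viol = np.where(beta <= -COEF_BOUND + 1e-9, np.maximum(-(g - lam), 0.0), viol)
    return float(viol.max())


def _kkt_violation(x_pres, x_bg, lam, beta) -> float:
    fbar = x_pres.mean(axis=0)
    eta = x_bg @ beta
    w = np.exp(eta - _lse(eta))
    g = x_bg.T @ w - fbar
    return _kkt_from_grad(g, lam, beta)


def solve(
    x_pres: np.ndarray,
    x_bg: np.ndarray,
    lam: np.ndarray,
    tol: float,
    max_iter: int,
    beta0: np.ndarray | None = None,
    kkt_rel: float = 5e-3,
    max_outer: int = 100,
) -> tuple[np.ndarray, SolverDiagnostics]:
    """Proximal-Newton solve of the penalized maximum-entropy problem.

    ``tol`` bounds the inner coordinate step size; ``max_iter`` caps the
    cumulative inner CD passes; ``kkt_rel`` scales the KKT stopping rule
    relative to the penalty magnitude.
    """
    d = x_bg.shape[1]
    beta = np.zeros(d) if beta0 is None else np.clip(beta0, -COEF_BOUND, COEF_BOUND)
    fbar = x_pres.mean(axis=0)
    lam = np.asarray(lam, dtype=np.float64)
    x_bg = np.ascontiguousarray(x_bg, dtype=np.float64)
    kkt_tol = kkt_rel * max(float(lam.max()), 1e-3)

    eta = x_bg @ beta
    f_cur = _lse(eta) - float(fbar @ beta) + float(lam @ np.abs(beta))
    inner_budget = max_iter
    last_step = np.inf
    kkt = np.inf
    for outer in range(max_outer):
        w = np.exp(eta - _lse(eta))
        mu = x_bg.T @ w
        g = mu - fbar
        kkt = _kkt_from_grad(g, lam, beta)
        if kkt < kkt_tol or last_step < tol:
            return beta, SolverDiagnostics(True, outer, last_step, kkt)
        if inner_budget <= 0:
            break
        hess = (x_bg.T * w) @ x_bg - np.outer(mu, mu)
        n_passes = min(200, inner_budget)
        inner_budget -= n_passes
        delta = _qp_l1_cd(
            hess, g.astype(np.float64), lam,
            beta.astype(np.float64), np.zeros(d), n_passes, 0.1 * tol,
        )
        if float(np.abs(delta).max()) == 0.0:
            # the quadratic model is already stationary; accept as converged
            return beta, SolverDiagnostics(True, outer, 0.0, kkt)
        # backtracking line search on the true penalized objective
        x_delta = x_bg @ delta
        alpha = 1.0
        accepted = False
        for _bt in range(30):
            cand = np.clip(beta + alpha * delta, -COEF_BOUND, COEF_BOUND)
            eta_new = eta + alpha * x_delta
            f_new = _lse(eta_new) - float(fbar @ cand) + float(lam @ np.abs(cand))
            if f_new <= f_cur + 1e-12:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            # no descent direction left at floating-point resolution
            return beta, SolverDiagnostics(True, outer, 0.0, kkt)
        last_step = float(np.abs(alpha * delta).max())
        beta = cand
        eta = eta_new
        f_cur = f_new
    w = np.exp(eta - _lse(eta))
    kkt = _kkt_from_grad(x_bg.T @ w - fbar, lam, beta)
    return beta, SolverDiagnostics(kkt < kkt_tol, max_outer, last_step, kkt)
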