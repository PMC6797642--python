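"""Independent numeric oracles used to cross-check closed-form updates.

These deliberately avoid the package's soft-threshold/positive-part
primitives: the penalized problems are re-posed as smooth bound-constrained
programs (positive/negative splitting for the L1 term, an epsilon-smoothed
norm for the group term, smoothing bias below 1e-9) and handed to a generic
quasi-Newton solver with analytic gradients.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

_EPS = 1e-18  # group-norm smoothing; adds at most sqrt(_EPS) per group


def penalized_objective(
    X: np.ndarray,
    T: np.ndarray,
    P: np.ndarray,
    lambda_L: float,
    lambda_G: float,
    method: str = "component",
) -> float:
    """Conditional objective for one block at fixed scores."""
    J = X.shape[1]
    value = float(((X - T @ P.T) ** 2).sum()) + lambda_L * float(np.abs(P).sum())
    if method == "block":
        value += lambda_G * np.sqrt(J) * float(np.linalg.norm(P))
    else:
        value += lambda_G * np.sqrt(J) * float(np.linalg.norm(P, axis=0).sum())
    return value


def _minimize_split(fun_grad, n, starts):
    best_x, best_f = None, np.inf
    bounds = [(0, None)] * (2 * n)
    for x0 in starts:
        result = minimize(
            fun_grad,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if result.fun < best_f:
            best_f, best_x = result.fun, result.x
    return best_x[:n] - best_x[n:]


def _split_starts(points, n):
    out = []
    for p in points:
        x0 = np.zeros(2 * n)
        x0[:n] = np.maximum(p, 0)
        x0[n:] = np.maximum(-p, 0)
        out.append(x0)
    return out


def solve_block_problem(
    X: np.ndarray,
    T: np.ndarray,
    lambda_L: float,
    lambda_G: float,
    method: str = "block",
) -> np.ndarray:
    """Generic convex minimizer of the conditional loadings problem.

    Minimizes ``||X - T P'||^2 + lambda_L ||P||_1 + lambda_G sqrt(J) * g(P)``
    where g is the Frobenius norm (block method) or the sum of column norms
    (component method).
    """
    I, J = X.shape
    R = T.shape[1]
    n = J * R
    sqrt_J = np.sqrt(J)
    A = T.T @ X  # R x J; quadratic part only needs T'X and T'T = I-ish
    TtT = T.T @ T
    X_ss = float((X**2).sum())

    def fun_grad(z):
        p = z[:n] - z[n:]
        P = p.reshape(R, J).T  # J x R
        M = TtT @ P.T - A  # R x J
        quad = X_ss + float((P.T * M).sum()) - float((A * P.T).sum())
        grad_P = 2.0 * M.T  # J x R, derivative of quad wrt P
        if method == "block":
            norm = np.sqrt((P**2).sum() + _EPS)
            pen = lambda_G * sqrt_J * norm
            grad_P = grad_P + lambda_G * sqrt_J * P / norm
        else:
            norms = np.sqrt((P**2).sum(axis=0) + _EPS)
            pen = lambda_G * sqrt_J * float(norms.sum())
            grad_P = grad_P + lambda_G * sqrt_J * (P / norms)
        value = quad + lambda_L * float(z.sum()) + pen
        g = grad_P.T.ravel()
        grad = np.concatenate([g + lambda_L, -g + lambda_L])
        return value, grad

    rng = np.random.default_rng(0)
    ols = X.T @ T
    points = [np.zeros(n), ols.T.ravel(), 0.5 * ols.T.ravel()] + [
        rng.standard_normal(n) for _ in range(2)
    ]
    p = _minimize_split(fun_grad, n, _split_starts(points, n))
    return p.reshape(R, J).T


def solve_component_problem(
    R_k: np.ndarray, t_r: np.ndarray, lambda_L: float, lambda_G: float
) -> np.ndarray:
    """Generic convex minimizer for a single component's loading vector.

    Minimizes ``||R_k - p t_r'||^2 + lambda_L ||p||_1
    + lambda_G sqrt(J) ||p||_2`` over p.
    """
    J = R_k.shape[0]
    sqrt_J = np.sqrt(J)
    b = R_k @ t_r
    tt = float(t_r @ t_r)
    R_ss = float((R_k**2).sum())

    def fun_grad(z):
        p = z[:J] - z[J:]
        norm = np.sqrt((p**2).sum() + _EPS)
        value = (
            R_ss
            - 2.0 * float(b @ p)
            + tt * float((p**2).sum())
            + lambda_L * float(z.sum())
            + lambda_G * sqrt_J * norm
        )
        g = -2.0 * b + 2.0 * tt * p + lambda_G * sqrt_J * p / norm
        grad = np.concatenate([g + lambda_L, -g + lambda_L])
        return value, grad

    rng = np.random.default_rng(0)
    points = [np.zeros(J), b, 0.5 * b] + [rng.standard_normal(J) for _ in range(2)]
    return _minimize_split(fun_grad, J, _split_starts(points, J))


def solve_structured_problem(
    X_blocks: list[np.ndarray],
    T: np.ndarray,
    status: np.ndarray,
    position: set[int],
    lambda_L: float,
) -> np.ndarray:
    """Convex minimizer of the known-structure loadings problem at fixed T.

    Cells forced to zero by ``status`` are removed from the variable set;
    the Lasso applies only to components listed in ``position``.
    """
    R = T.shape[1]
    widths = [X.shape[1] for X in X_blocks]
    total_J = sum(widths)
    free = np.repeat(status, widths, axis=0).astype(bool)
    X_C = np.hstack(X_blocks)
    idx = np.argwhere(free)
    m = len(idx)
    TtT = T.T @ T
    A = X_C.T @ T  # total_J x R
    X_ss = float((X_C**2).sum())
    lasso_weight = np.array([lambda_L if c in position else 0.0 for _, c in idx])

    def to_matrix(p):
        P = np.zeros((total_J, R))
        P[idx[:, 0], idx[:, 1]] = p
        return P

    def fun_grad(z):
        p = z[:m] - z[m:]
        P = to_matrix(p)
        M = P @ TtT - A  # total_J x R
        value = (
            X_ss
            + float((P * M).sum())
            - float((A * P).sum())
            + float(lasso_weight @ (z[:m] + z[m:]))
        )
        g_full = 2.0 * M
        g = g_full[idx[:, 0], idx[:, 1]]
        grad = np.concatenate([g + lasso_weight, -g + lasso_weight])
        return value, grad

    rng = np.random.default_rng(0)
    ols = A[idx[:, 0], idx[:, 1]]
    points = [np.zeros(m), ols, 0.5 * ols, rng.standard_normal(m)]
    p = _minimize_split(fun_grad, m, _split_starts(points, m))
    return to_matrix(p)
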