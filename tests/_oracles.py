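"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the BPDN oracle is a
generic nonlinear convex solver (SLSQP on the split-variable formulation),
and the metrics oracle counts outcomes from reconstructed label vectors
and uses sklearn's independent metric implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize


def bpdn_oracle(X: np.ndarray, y: np.ndarray, eps: float) -> np.ndarray:
    """Solve min ||a||_1 s.t. ||y - Xa||_2 <= eps with a generic convex solver.

    Split a = u - v with u, v >= 0 so the objective sum(u + v) is smooth,
    and hand the quadratic constraint to SLSQP with analytic gradients.
    """
    d, n = X.shape

    def fun(z):
        return z.sum()

    def jac(z):
        return np.ones(2 * n)

    def cons_f(z):
        r = y - X @ (z[:n] - z[n:])
        return eps**2 - r @ r

    def cons_j(z):
        r = y - X @ (z[:n] - z[n:])
        g = 2 * X.T @ r
        return np.concatenate([g, -g])

    a0, *_ = np.linalg.lstsq(X, y, rcond=None)
    z0 = np.concatenate([np.clip(a0, 0, None), np.clip(-a0, 0, None)])

    def feasible(z):
        return cons_f(z) >= -1e-10 * max(eps**2, 1.0)

    res = minimize(
        fun,
        z0,
        jac=jac,
        method="SLSQP",
        bounds=[(0, None)] * (2 * n),
        constraints=[{"type": "ineq", "fun": cons_f, "jac": cons_j}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if res.success and feasible(res.x):
        return res.x[:n] - res.x[n:]

    # fall back to the slower interior-point style solver
    res = minimize(
        fun,
        z0,
        jac=jac,
        method="trust-constr",
        bounds=[(0, None)] * (2 * n),
        constraints=[NonlinearConstraint(cons_f, 0, np.inf, jac=lambda z: cons_j(z)[None, :])],
        options={"maxiter": 3000, "gtol": 1e-12, "xtol": 1e-14},
    )
    if res.status not in (1, 2) or not feasible(res.x):
        raise RuntimeError(f"oracle did not converge: {res.message}")
    return res.x[:n] - res.x[n:]


def feasible_bpdn_instance(
    rng: np.random.Generator, d_max: int = 10, n_max: int = 8
) -> tuple[np.ndarray, np.ndarray, float]:
    """Random unit-column dictionary and query with a guaranteed-feasible eps.

    eps sits strictly above the least-squares residual floor of the
    instance, so the constraint set is non-empty even when d > n.
    """
    d = int(rng.integers(3, d_max + 1))
    n = int(rng.integers(2, n_max + 1))
    X = rng.normal(size=(d, n))
    X /= np.linalg.norm(X, axis=0)
    y = rng.normal(size=d)
    y /= np.linalg.norm(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    floor = float(np.linalg.norm(y - X @ coef))
    eps = floor + 0.05
    return X, y, eps
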