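"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle enumerates
polytope vertices by brute force instead of calling a solver; the feed-mass
oracle integrates the uptake flux numerically instead of using the closed form;
the regression oracle builds the normal equations directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad


def vertex_enumerate_lp(S, lb, ub, c, sense="max"):
    """Optimum of c·v over {v: S v = 0, lb <= v <= ub} by vertex enumeration.

    Every vertex of the polytope has at least n - rank(S) coordinates at a
    bound; enumerate all such coordinate subsets and bound choices, solve the
    remaining square-ish system, keep feasible points. All bounds must be
    finite (the polytope is then bounded and the LP optimum sits at a vertex).
    Returns None if no feasible vertex exists.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(lb)
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
    rank = np.linalg.matrix_rank(S) if S.size else 0
    best = None
    for free in itertools.combinations(range(n), rank):
        fixed = [j for j in range(n) if j not in free]
        A = S[:, list(free)] if rank else None
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.empty(n)
            v[fixed] = choice
            if rank:
                b = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
                x, *_ = np.linalg.lstsq(A, b, rcond=None)
                if not np.allclose(A @ x, b, atol=1e-9):
                    continue
                v[list(free)] = x
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            if S.size and np.max(np.abs(S @ v)) > 1e-8:
                continue
            val = float(c @ v)
            if best is None:
                best = val
            elif sense == "max":
                best = max(best, val)
            else:
                best = min(best, val)
    return best


def integrate_feed_mass(flux, mw, X0, mu, dt):
    """Numerically integrate flux·MW·X0·e^{mu t} over [0, dt]."""
    val, _ = quad(lambda t: flux * mw * X0 * np.exp(mu * t), 0.0, dt, limit=200)
    return val


def ols_poly(x, y, degree):
    """Polynomial OLS via the normal equations: coefficients and standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    V = np.vander(x, degree + 1, increasing=True)
    XtX_inv = np.linalg.inv(V.T @ V)
    beta = XtX_inv @ V.T @ y
    resid = y - V @ beta
    dof = len(x) - (degree + 1)
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * XtX_inv))
    return beta, se


def random_small_network(rng, max_reactions=6):
    """Random stoichiometry and finite bounds for the LP-oracle comparison."""
    m = rng.integers(1, 4)
    n = rng.integers(2, max_reactions + 1)
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    # keep every metabolite connected so Sv=0 is a real constraint
    for i in range(m):
        if not S[i].any():
            S[i, rng.integers(n)] = 1.0
    lb = np.where(rng.random(n) < 0.5, -rng.uniform(0.0, 5.0, n), 0.0)
    ub = rng.uniform(0.0, 5.0, n)
    obj = int(rng.integers(n))
    return S, lb, ub, obj
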