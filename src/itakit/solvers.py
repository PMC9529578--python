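"""Coordinate-descent path solver for penalized logistic regression.

The workhorse behind :mod:`itakit.penalized`: an IRLS (iteratively reweighted
least squares) outer loop with cyclic coordinate descent on the penalized
weighted least-squares subproblem, in the style of glmnet.  For L1 the
coordinate update is a soft-threshold; for L2 it is a closed-form shrink.  The
intercept is never penalized.  Along a descending λ path the solution is
warm-started from the previous λ, and for L1 the descent cycles only over the
current active set, with full sweeps to admit violators — this is what makes
whole cross-validation paths at n ≈ 2·10⁴, p ≈ 400 run in seconds.

Convergence is measured on the objective, not the iterates: the inner loop
stops when a sweep's total objective gain falls below tol·n, and the Newton
outer loop stops when an entire re-weighted step gains less than tol·n.  Full
(non-drop-first) one-hot designs carry near-flat directions — a constant
shift across one variable's dummy block traded against the intercept — along
which coordinate iterates can drift almost freely at negligible objective
change; an iterate-based criterion crawls there, an objective-based one does
not.

Inputs are assumed standardized by the caller; columns with zero weighted
curvature are skipped.
"""

from __future__ import annotations

import numpy as np

try:  # numba compiles the hot loops; the pure-Python fallback is identical
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is preinstalled in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

_W_MIN = 1e-6  # lower clamp on the IRLS weights p(1-p)
_ETA_CLIP = 30.0


@njit(cache=True)
def _sweep(X, w, r, beta, active, aj, lam, l1, full_pass):
    """One cyclic coordinate-descent pass; returns the objective gain."""
    n, p = X.shape
    gain = 0.0
    for j in range(p):
        if not full_pass and active[j] == 0:
            continue
        a = aj[j]
        if a <= 0.0:
            continue
        g = 0.0
        for i in range(n):
            g += w[i] * X[i, j] * r[i]
        old = beta[j]
        g += a * old
        if l1:
            if g > lam:
                nb = (g - lam) / a
            elif g < -lam:
                nb = (g + lam) / a
            else:
                nb = 0.0
        else:
            nb = g / (a + 2.0 * lam)
        d = nb - old
        if d != 0.0:
            beta[j] = nb
            for i in range(n):
                r[i] -= d * X[i, j]
            u = g / a
            gain += 0.5 * a * ((old - u) * (old - u) - (nb - u) * (nb - u))
            if l1:
                gain += lam * (abs(old) - abs(nb))
            else:
                gain += lam * (old * old - nb * nb)
        active[j] = 1 if beta[j] != 0.0 else 0
    return gain


@njit(cache=True)
def _cd_path(X, y, lams, l1, tol, max_outer, max_inner, beta, b):
    """Solve min −loglik + lam·penalty for every lam (descending), warm-started.

    Returns (coefs[len(lams), p], intercepts[len(lams)], converged[len(lams)]).
    ``beta`` is the warm-start state and is mutated in place.
    """
    n, p = X.shape
    n_lam = lams.shape[0]
    coefs = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)
    converged = np.zeros(n_lam, dtype=np.uint8)
    gain_tol = tol * n

    eta = X @ beta + b
    active = np.zeros(p, dtype=np.uint8)
    for j in range(p):
        if beta[j] != 0.0:
            active[j] = 1
    w = np.empty(n)
    r = np.empty(n)
    aj = np.empty(p)

    for li in range(n_lam):
        lam = lams[li]
        ok = False
        for _outer in range(max_outer):
            # IRLS weights, working residual and column curvatures at eta
            for i in range(n):
                e = eta[i]
                if e > _ETA_CLIP:
                    e = _ETA_CLIP
                elif e < -_ETA_CLIP:
                    e = -_ETA_CLIP
                pr = 1.0 / (1.0 + np.exp(-e))
                wi = pr * (1.0 - pr)
                if wi < _W_MIN:
                    wi = _W_MIN
                w[i] = wi
                r[i] = (y[i] - pr) / wi
            sw = 0.0
            for i in range(n):
                sw += w[i]
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                aj[j] = s

            outer_gain = 0.0
            full_pass = True  # first sweep visits every coordinate
            for _inner in range(max_inner):
                gain = 0.0
                # intercept (unpenalized)
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                db = num / sw
                if db != 0.0:
                    b += db
                    for i in range(n):
                        r[i] -= db
                    gain += 0.5 * sw * db * db
                gain += _sweep(X, w, r, beta, active, aj, lam, l1, full_pass)
                outer_gain += gain
                if gain < gain_tol:
                    if full_pass:
                        break
                    full_pass = True  # active set done: verify with full sweep
                else:
                    full_pass = False

            # refresh eta from the updated coefficients (column-major scans)
            for i in range(n):
                eta[i] = b
            for j in range(p):
                bj = beta[j]
                if bj != 0.0:
                    for i in range(n):
                        eta[i] += X[i, j] * bj
            # Newton converged when an entire re-weighted step gains ~nothing
            if outer_gain < gain_tol:
                ok = True
                break
        coefs[li] = beta
        intercepts[li] = b
        converged[li] = 1 if ok else 0
    return coefs, intercepts, converged


class WarmState:
    """Mutable warm-start state threaded through incremental path calls."""

    def __init__(self, p: int, y_mean: float):
        self.beta = np.zeros(p)
        ym = min(max(y_mean, 1e-12), 1 - 1e-12)
        self.b = float(np.log(ym / (1.0 - ym)))


def cd_penalized_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    penalty: str,
    tol: float = 1e-10,
    max_outer: int = 100,
    max_inner: int = 1000,
    state: WarmState | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coefficient path over a descending λ grid on pre-standardized X.

    ``tol`` is an objective-gain tolerance per observation (see module
    docstring).  Pass a :class:`WarmState` to continue a path across calls.
    """
    # column-major layout: the hot loops scan one column at a time
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.ascontiguousarray(np.asarray(y), dtype=np.float64)
    lams = np.ascontiguousarray(lams, dtype=np.float64)
    if np.any(np.diff(lams) > 0):
        raise ValueError("lams must be nonincreasing (warm-started path)")
    if state is None:
        state = WarmState(X.shape[1], float(y.mean()))
    coefs, intercepts, conv = _cd_path(
        X, y, lams, penalty == "l1", tol, max_outer, max_inner,
        state.beta, state.b,
    )
    state.b = float(intercepts[-1])
    return coefs, intercepts, conv.astype(bool)
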