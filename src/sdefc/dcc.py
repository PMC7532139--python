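"""Bivariate dynamic conditional correlation (DCC-GARCH) estimation.

Two-stage Gaussian quasi-maximum likelihood, fit independently per edge:

1. Each demeaned series gets a univariate GARCH(1,1) variance model
   ``h_t = omega + alpha * eps_{t-1}^2 + beta * h_{t-1}`` with variance
   targeting (``omega = s2 * (1 - alpha - beta)`` where ``s2`` is the sample
   variance), giving standardized residuals ``z_t = eps_t / sqrt(h_t)``.
2. The DCC(1,1) recursion on the standardized residual pair,
   ``Q_t = (1 - a - b) * Sbar + a * z_{t-1} z_{t-1}' + b * Q_{t-1}``,
   with correlation targeting (``Sbar`` = sample correlation of ``z``), gives
   the conditional correlation ``R_t = Q_t[0,1] / sqrt(Q_t[0,0] Q_t[1,1])``.

Both stages are optimized by bound-constrained L-BFGS-B from a small
multi-start grid; ties in log-likelihood are broken toward the smallest
persistence (alpha + beta, resp. a + b), which makes the fit deterministic.
Edges where estimation fails fall back to an exponentially weighted moving
correlation (lambda = 0.94) and are flagged.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .containers import EdgeCorrelationSeries

_PENALTY = 1e10
#: persistence bound for both stages
_MAX_PERSIST = 0.998


@njit(cache=True)
def _garch_nll(eps: np.ndarray, s2: float, alpha: float, beta: float) -> float:
    omega = s2 * (1.0 - alpha - beta)
    T = eps.shape[0]
    h = s2
    nll = 0.0
    for t in range(T):
        if t > 0:
            h = omega + alpha * eps[t - 1] * eps[t - 1] + beta * h
        if h <= 1e-12:
            return _PENALTY
        nll += np.log(h) + eps[t] * eps[t] / h
    return 0.5 * nll


@njit(cache=True)
def _garch_filter(eps: np.ndarray, s2: float, alpha: float, beta: float) -> np.ndarray:
    omega = s2 * (1.0 - alpha - beta)
    T = eps.shape[0]
    h = np.empty(T)
    h[0] = s2
    for t in range(1, T):
        h[t] = omega + alpha * eps[t - 1] * eps[t - 1] + beta * h[t - 1]
        if h[t] <= 1e-12:
            h[t] = 1e-12
    return h


@njit(cache=True)
def _dcc_nll(z1: np.ndarray, z2: np.ndarray, sbar: float, a: float, b: float) -> float:
    T = z1.shape[0]
    q11, q22, q12 = 1.0, 1.0, sbar
    nll = 0.0
    for t in range(T):
        if t > 0:
            q11 = (1.0 - a - b) * 1.0 + a * z1[t - 1] * z1[t - 1] + b * q11
            q22 = (1.0 - a - b) * 1.0 + a * z2[t - 1] * z2[t - 1] + b * q22
            q12 = (1.0 - a - b) * sbar + a * z1[t - 1] * z2[t - 1] + b * q12
        rho = q12 / np.sqrt(q11 * q22)
        if rho >= 0.9999:
            rho = 0.9999
        elif rho <= -0.9999:
            rho = -0.9999
        det = 1.0 - rho * rho
        nll += np.log(det) + (z1[t] * z1[t] + z2[t] * z2[t] - 2.0 * rho * z1[t] * z2[t]) / det
    return 0.5 * nll


@njit(cache=True)
def _dcc_filter(z1: np.ndarray, z2: np.ndarray, sbar: float, a: float, b: float) -> np.ndarray:
    T = z1.shape[0]
    r = np.empty(T)
    q11, q22, q12 = 1.0, 1.0, sbar
    for t in range(T):
        if t > 0:
            q11 = (1.0 - a - b) * 1.0 + a * z1[t - 1] * z1[t - 1] + b * q11
            q22 = (1.0 - a - b) * 1.0 + a * z2[t - 1] * z2[t - 1] + b * q22
            q12 = (1.0 - a - b) * sbar + a * z1[t - 1] * z2[t - 1] + b * q12
        rho = q12 / np.sqrt(q11 * q22)
        if rho >= 0.9999:
            rho = 0.9999
        elif rho <= -0.9999:
            rho = -0.9999
        r[t] = rho
    return r


def _multistart(fun, starts, bounds):
    """Best of several L-BFGS-B runs; ties (within 1e-6) broken toward the
    smallest parameter sum so the estimator is deterministic."""
    best = None
    for x0 in starts:
        res = minimize(fun, x0=np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        key = (round(float(res.fun), 6), float(np.sum(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
    return best[1] if best is not None else None


_GARCH_STARTS = [(0.02, 0.6), (0.02, 0.9), (0.1, 0.6), (0.1, 0.85)]
_DCC_STARTS = [(0.01, 0.8), (0.01, 0.95), (0.05, 0.8), (0.05, 0.9)]


def fit_garch(x: np.ndarray) -> dict:
    """Fit GARCH(1,1) with variance targeting to a demeaned series.

    Returns omega/alpha/beta, the conditional variance path ``h`` and the
    standardized residuals ``z``; ``converged`` is False when every start
    failed (the caller then falls back and flags the edge).
    """
    eps = np.ascontiguousarray(np.asarray(x, dtype=float))
    eps = eps - eps.mean()
    s2 = float(eps @ eps / len(eps))
    if s2 <= 0:
        raise ValueError("constant series: GARCH variance undefined")

    def nll(p):
        alpha, beta = p
        if alpha + beta >= _MAX_PERSIST:
            return _PENALTY
        return _garch_nll(eps, s2, alpha, beta)

    res = _multistart(nll, _GARCH_STARTS, bounds=[(0.0, 0.5), (0.0, 0.995)])
    if res is None or res.x[0] + res.x[1] >= _MAX_PERSIST:
        return {"converged": False, "eps": eps, "s2": s2}
    alpha, beta = (float(v) for v in res.x)
    h = _garch_filter(eps, s2, alpha, beta)
    return {
        "converged": True,
        "omega": s2 * (1.0 - alpha - beta),
        "alpha": alpha,
        "beta": beta,
        "h": h,
        "z": eps / np.sqrt(h),
        "eps": eps,
        "s2": s2,
    }


def fit_dcc(z1: np.ndarray, z2: np.ndarray, fix_ab: tuple[float, float] | None = None) -> dict:
    """Second-stage DCC(1,1) fit on a standardized residual pair.

    ``fix_ab`` imposes (a, b) instead of estimating them — the (0, 0) case
    reduces ``R_t`` to the constant sample correlation of the residuals, a
    useful closed-form check.
    """
    z1 = np.ascontiguousarray(z1, dtype=float)
    z2 = np.ascontiguousarray(z2, dtype=float)
    sbar = float(np.corrcoef(z1, z2)[0, 1])
    sbar = float(np.clip(sbar, -0.999, 0.999))

    if fix_ab is not None:
        a, b = fix_ab
        return {"converged": True, "a": float(a), "b": float(b), "sbar": sbar,
                "series": _dcc_filter(z1, z2, sbar, float(a), float(b))}

    def nll(p):
        a, b = p
        if a + b >= _MAX_PERSIST:
            return _PENALTY
        return _dcc_nll(z1, z2, sbar, a, b)

    res = _multistart(nll, _DCC_STARTS, bounds=[(0.0, 0.3), (0.0, 0.995)])
    if res is None or res.x[0] + res.x[1] >= _MAX_PERSIST:
        return {"converged": False, "sbar": sbar}
    a, b = (float(v) for v in res.x)
    return {"converged": True, "a": a, "b": b, "sbar": sbar,
            "series": _dcc_filter(z1, z2, sbar, a, b)}


def ewma_correlation(x: np.ndarray, y: np.ndarray, lam: float = 0.94) -> np.ndarray:
    """Exponentially weighted moving correlation — the non-convergence
    fallback (RiskMetrics smoothing, lambda = 0.94)."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    vx, vy, cxy = np.var(x), np.var(y), float(np.mean(x * y))
    out = np.empty(len(x))
    for t in range(len(x)):
        if t > 0:
            vx = lam * vx + (1 - lam) * x[t - 1] ** 2
            vy = lam * vy + (1 - lam) * y[t - 1] ** 2
            cxy = lam * cxy + (1 - lam) * x[t - 1] * y[t - 1]
        out[t] = np.clip(cxy / np.sqrt(max(vx * vy, 1e-24)), -0.9999, 0.9999)
    return out


def dcc_edge(
    x: np.ndarray,
    y: np.ndarray,
    edge: tuple[str, str] = ("x", "y"),
    fix_ab: tuple[float, float] | None = None,
) -> EdgeCorrelationSeries:
    """Conditional correlation series for one edge by two-stage QML.

    Raises on series shorter than 30 or constant; on optimizer failure the
    EWMA fallback is used and the result is flagged.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 30:
        raise ValueError("DCC estimation requires at least 30 timepoints")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"constant series for edge {edge}")

    g1, g2 = fit_garch(x), fit_garch(y)
    if g1["converged"] and g2["converged"]:
        d = fit_dcc(g1["z"], g2["z"], fix_ab=fix_ab)
        if d["converged"]:
            return EdgeCorrelationSeries(
                series=d["series"],
                edge=edge,
                params={
                    "a": d["a"], "b": d["b"], "sbar": d["sbar"],
                    "garch_x": (g1["omega"], g1["alpha"], g1["beta"]),
                    "garch_y": (g2["omega"], g2["alpha"], g2["beta"]),
                },
                flagged=False,
            )
    return EdgeCorrelationSeries(
        series=ewma_correlation(x, y),
        edge=edge,
        params={"fallback": "ewma", "lambda": 0.94},
        flagged=True,
    )


def dcc_all_edges(scan) -> dict[tuple[str, str], EdgeCorrelationSeries]:
    """Fit every upper-triangle edge of a scan independently.

    GARCH residuals are computed once per node and reused across its edges.
    """
    data = scan.data
    nodes = scan.node_ids
    n = len(nodes)
    fits = [fit_garch(data[:, i]) for i in range(n)]
    out: dict[tuple[str, str], EdgeCorrelationSeries] = {}
    for i in range(n):
        for j in range(i + 1, n):
            edge = (nodes[i], nodes[j])
            gi, gj = fits[i], fits[j]
            if gi["converged"] and gj["converged"]:
                d = fit_dcc(gi["z"], gj["z"])
                if d["converged"]:
                    out[edge] = EdgeCorrelationSeries(
                        series=d["series"], edge=edge,
                        params={"a": d["a"], "b": d["b"], "sbar": d["sbar"],
                                "garch_x": (gi["omega"], gi["alpha"], gi["beta"]),
                                "garch_y": (gj["omega"], gj["alpha"], gj["beta"])},
                        flagged=False,
                    )
                    continue
            out[edge] = EdgeCorrelationSeries(
                series=ewma_correlation(data[:, i], data[:, j]), edge=edge,
                params={"fallback": "ewma", "lambda": 0.94}, flagged=True,
            )
    return out
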