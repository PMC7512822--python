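"""Maximum-entropy coding of signal events.

A configuration of the cascade assigns each of the ``X`` signaling
molecules to one of the 2n species states, so the number of distinguishable
signal events is the multinomial coefficient

    Psi = X! / (prod_j X_mj! * prod_j X_mj*!)

whose logarithm, by Stirling's approximation, is the mixing entropy
``S = -X * sum_j (p_mj log p_mj + p_mj* log p_mj*)`` in terms of the
occurrence probabilities ``p_mj = X_mj / X``.  Maximizing S subject to
normalization (sum of all p equals 1) and a fixed total cascade duration
``tau_m = X * sum_j (p_mj tau_mj - p_mj* tau_-mj)`` yields the exponential
assignment

    -log p_mj = beta * tau_mj,      -log p_mj* = -beta * tau_-mj,

with a single Lagrange multiplier ``beta`` shared by every step — the
structural origin of the step-independent average entropy production rate
analyzed in :mod:`sigtherm.thermo`.  All logarithms are natural (entropy in
nats); the ``K`` constant for unit conversion lives in the thermo layer.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import gammaln, xlogy

from .core import CodingSolution, DurationProfile

__all__ = [
    "count_events_exact",
    "entropy_stirling",
    "total_duration",
    "solve_beta",
    "maxent_analytic",
    "maxent_numeric",
    "fit_beta",
]


def count_events_exact(counts_inactive, counts_active) -> float:
    """log of the exact multinomial signal-event count Psi.

    Counts must be non-negative integers; the result is computed with
    log-gamma, exact to floating precision for any feasible X.
    """
    ci = np.asarray(counts_inactive)
    ca = np.asarray(counts_active)
    counts = np.concatenate([ci, ca]).astype(float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts != np.round(counts)):
        raise ValueError("counts must be integers")
    x = counts.sum()
    return float(gammaln(x + 1.0) - gammaln(counts + 1.0).sum())


def entropy_stirling(p_forward, p_backward, X: float) -> float:
    """Stirling-approximate entropy S = -X * sum(p log p + p* log p*).

    The convention 0*log(0) = 0 applies, so degenerate distributions give
    exactly zero entropy.
    """
    p = np.asarray(p_forward, dtype=float)
    q = np.asarray(p_backward, dtype=float)
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    if X <= 0:
        raise ValueError("X must be positive")
    return float(-X * (xlogy(p, p).sum() + xlogy(q, q).sum()))


def total_duration(p_forward, p_backward, durations: DurationProfile, X: float) -> float:
    """Total cascade duration tau_m = X * sum(p tau - p* tau_-).

    Strictly positive whenever any probability is non-zero, because forward
    durations are positive and backward durations negative.
    """
    p = np.asarray(p_forward, dtype=float)
    q = np.asarray(p_backward, dtype=float)
    if len(p) != len(durations) or len(q) != len(durations):
        raise ValueError("probability and duration lengths must agree")
    if p.sum() + q.sum() <= 0:
        raise ValueError("at least one probability must be positive")
    return float(X * (p @ durations.forward - q @ durations.backward))


def _normalization_residual(beta: float, durations: DurationProfile) -> float:
    return float(
        np.exp(-beta * durations.forward).sum()
        + np.exp(beta * durations.backward).sum()
        - 1.0
    )


def solve_beta(durations: DurationProfile, tol: float = 1e-12) -> float:
    """Unique positive root of the normalization condition.

    Substituting the exponential maxent form into sum(p + p*) = 1 gives

        R(beta) = sum_j exp(-beta tau_mj) + sum_j exp(beta tau_-mj) - 1 = 0.

    R is strictly decreasing (every exponent has a negative coefficient),
    starts at 2n - 1 > 0 and tends to -1, so bracketed root-finding is
    unconditionally safe.  Requires 2n > 1.
    """
    n = len(durations)
    if n == 0:
        raise ValueError("empty duration profile")
    lo = 0.0
    hi = 1.0
    for _ in range(200):
        if _normalization_residual(hi, durations) < 0.0:
            break
        lo = hi
        hi *= 2.0
    else:  # pragma: no cover - unreachable for valid profiles
        raise RuntimeError("failed to bracket the normalization root")
    beta = brentq(
        _normalization_residual, lo, hi, args=(durations,), xtol=1e-300, rtol=8.9e-16
    )
    if abs(_normalization_residual(beta, durations)) > tol:
        raise RuntimeError("beta root did not reach requested residual tolerance")
    return float(beta)


def maxent_analytic(
    durations: DurationProfile, X: float = 1.0, tol: float = 1e-12
) -> CodingSolution:
    """Closed-form maximum-entropy solution p_mj = exp(-beta tau_mj).

    ``beta`` comes from :func:`solve_beta`; the normalization multiplier is
    alpha = -X.  The identity S = beta * tau_m holds exactly for the
    returned solution.
    """
    beta = solve_beta(durations, tol=tol)
    p = np.exp(-beta * durations.forward)
    q = np.exp(beta * durations.backward)
    S = entropy_stirling(p, q, X)
    tau_m = total_duration(p, q, durations, X)
    return CodingSolution(
        p_forward=p,
        p_backward=q,
        beta=beta,
        alpha=-X,
        entropy=S,
        total_duration=tau_m,
        event_count_log=S,
    )


def maxent_numeric(
    durations: DurationProfile,
    X: float = 1.0,
    target_tau: float | None = None,
    tol: float = 1e-12,
) -> CodingSolution:
    """Direct constrained maximization of the Stirling entropy.

    Maximizes S over the 2n occurrence probabilities subject to
    normalization and to a fixed total duration ``target_tau`` (defaulting
    to the total duration of the analytic optimum, so the two solvers can
    be compared at the shared optimum).  The optimization runs over
    log-probabilities to enforce positivity; the multipliers are recovered
    from the stationarity conditions of the converged point by linear least
    squares.
    """
    n = len(durations)
    if target_tau is None:
        target_tau = maxent_analytic(durations, X).total_duration
    tf, tb = durations.forward, durations.backward

    def neg_entropy(z: np.ndarray) -> float:
        p = np.exp(z)
        return float((p * z).sum())  # = sum p log p, per molecule

    def neg_entropy_grad(z: np.ndarray) -> np.ndarray:
        p = np.exp(z)
        return p * (z + 1.0)

    def norm_con(z: np.ndarray) -> float:
        return float(np.exp(z).sum() - 1.0)

    def norm_jac(z: np.ndarray) -> np.ndarray:
        return np.exp(z)

    w = np.concatenate([tf, -tb])  # per-molecule duration weights (positive)

    def tau_con(z: np.ndarray) -> float:
        return float(X * (np.exp(z) @ w) - target_tau)

    def tau_jac(z: np.ndarray) -> np.ndarray:
        return X * np.exp(z) * w

    z0 = np.full(2 * n, -np.log(2.0 * n))
    # start feasible in tau by rescaling durations weightings is unnecessary;
    # SLSQP restores feasibility from the uniform start
    res = minimize(
        neg_entropy,
        z0,
        jac=neg_entropy_grad,
        method="SLSQP",
        constraints=[
            {"type": "eq", "fun": norm_con, "jac": norm_jac},
            {"type": "eq", "fun": tau_con, "jac": tau_jac},
        ],
        options={"ftol": 1e-16, "maxiter": 2000},
    )
    if not res.success and abs(norm_con(res.x)) > 1e-9:
        raise RuntimeError(f"constrained optimizer failed: {res.message}")
    z = res.x
    p = np.exp(z[:n])
    q = np.exp(z[n:])
    # stationarity: log p_j = c - beta tau_j, log p_j* = c + beta tau_-j
    s = np.concatenate([-tf, tb])
    A = np.column_stack([np.ones(2 * n), s])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    c, beta = float(coef[0]), float(coef[1])
    alpha = -X * (1.0 + c)  # from -X(log p + 1) - alpha - X beta tau = 0
    S = entropy_stirling(p, q, X)
    tau_m = total_duration(p, q, durations, X)
    return CodingSolution(
        p_forward=p,
        p_backward=q,
        beta=beta,
        alpha=alpha,
        entropy=S,
        total_duration=tau_m,
        event_count_log=S,
    )


def fit_beta(p_forward, durations: DurationProfile) -> tuple[float, float]:
    """Recover the common rate from observed probabilities and durations.

    Least-squares slope through the origin of -log p_mj against tau_mj,
    together with the maximum relative residual.  A residual near zero
    certifies that the probabilities follow the exponential-in-duration law
    with a single step-independent rate.
    """
    p = np.asarray(p_forward, dtype=float)
    if len(p) < 1:
        raise ValueError("need at least one step")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    y = -np.log(p)
    tau = durations.forward
    if len(tau) != len(p):
        raise ValueError("probability and duration lengths must agree")
    beta_hat = float((tau @ y) / (tau @ tau))
    pred = beta_hat * tau
    residual = float(np.max(np.abs(y - pred) / np.maximum(np.abs(pred), 1e-300)))
    return beta_hat, residual
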