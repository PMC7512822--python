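"""Synthetic cascade generation.

Every stage of the package is testable without external data: fixtures are
reproducible from (parameters, seed) alone.  :func:`make_cascade` inverts
the coding layer — choose step durations, rescale them so the
maximum-entropy multiplier equals a requested ``beta_true``, then pick
kinetic rates whose quasi-steady occupancies approximate the
maximum-entropy probabilities.  :func:`make_non_maxent_profile` produces
normalized probability assignments that deliberately violate the
exponential-in-duration law, as negative controls for the conservation
test.
"""

from __future__ import annotations

import numpy as np

from .coding import maxent_analytic, solve_beta
from .core import CascadeSpec, DurationProfile, validate_spec

__all__ = ["make_cascade", "make_non_maxent_profile"]

#: total signaling concentration used by generated cascades
DEFAULT_TOTAL = 100.0


def make_cascade(
    n: int,
    beta_true: float = 0.7,
    duration_scale: float = 1.0,
    seed: int = 0,
    total: float = DEFAULT_TOTAL,
) -> tuple[CascadeSpec, DurationProfile]:
    """Generate a cascade spec and a duration profile with a known beta.

    Durations are drawn uniformly on [0.5, 1.5] * duration_scale (backward
    negated), then rescaled by the exact factor beta0 / beta_true so that
    :func:`solve_beta` returns ``beta_true`` (the normalization condition
    is invariant under tau -> c tau, beta -> beta / c).

    Kinetic rates follow a documented heuristic: deactivation rates are set
    from the backward-duration magnitudes (k_- Ph ~ 1 / |tau_-|) and
    activation rates from the quasi-steady balance so that the steady
    active:inactive ratio of each step approximates p* : p of the
    maximum-entropy solution with the upstream driver at its own
    quasi-steady level.  All molecules start inactive, distributed over
    steps in proportion to p + p*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if beta_true <= 0 or duration_scale <= 0:
        raise ValueError("beta_true and duration_scale must be positive")
    rng = np.random.default_rng(seed)
    fwd = rng.uniform(0.5, 1.5, n) * duration_scale
    bwd = -rng.uniform(0.5, 1.5, n) * duration_scale
    profile = DurationProfile(fwd, bwd)
    beta0 = solve_beta(profile)
    c = beta0 / beta_true
    profile = DurationProfile(fwd * c, bwd * c)

    sol = maxent_analytic(profile)
    p, q = sol.p_forward, sol.p_backward
    occupancy = (p + q) / (p + q).sum()
    initial_inactive = total * occupancy
    initial_active = np.zeros(n)

    atp = adp = pi = 1.0
    ph = np.ones(max(n - 1, 0))
    backward_rates = 1.0 / np.abs(profile.backward[1:]) if n > 1 else np.array([])
    forward_rates = np.empty(max(n - 1, 0))
    for t in range(1, n):
        rho = q[t] / (p[t] + q[t])  # target quasi-steady active fraction
        driver_ss = total * occupancy[0] if t == 1 else max(total * q[t - 1], 1e-6)
        forward_rates[t - 1] = (
            rho / (1.0 - rho) * backward_rates[t - 1] * ph[t - 1] / (atp * driver_ss)
        )
    spec = CascadeSpec(
        n_steps=n,
        forward_rates=forward_rates,
        backward_rates=backward_rates,
        phosphatase_levels=ph,
        atp=atp,
        adp=adp,
        pi=pi,
        initial_inactive=initial_inactive,
        initial_active=initial_active,
        volume=1.0,
        seed=seed,
    )
    return validate_spec(spec), profile


def make_non_maxent_profile(
    n: int, seed: int = 0, min_spread: float = 0.1, max_tries: int = 1000
) -> tuple[np.ndarray, np.ndarray, DurationProfile]:
    """Normalized probabilities that violate the common-rate law.

    Draws a random duration profile and a random (Dirichlet) probability
    assignment, rejection-sampling until the 2n per-step ratios
    -log p / tau differ by at least ``min_spread`` relative max-min spread.
    Useful as a negative control: the conservation test must fail on the
    output.
    """
    if n < 2:
        raise ValueError("need n >= 2 to violate conservation across steps")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        fwd = rng.uniform(0.5, 1.5, n)
        bwd = -rng.uniform(0.5, 1.5, n)
        probs = rng.dirichlet(np.ones(2 * n))
        p, q = probs[:n], probs[n:]
        if np.any(p <= 1e-6) or np.any(q <= 1e-6):
            continue
        ratios = np.concatenate([-np.log(p) / fwd, np.log(q) / bwd])
        spread = (ratios.max() - ratios.min()) / ratios.mean()
        if spread >= min_spread:
            return p, q, DurationProfile(fwd, bwd)
    raise RuntimeError("rejection sampling failed to find a violating assignment")
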