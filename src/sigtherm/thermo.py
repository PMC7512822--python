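"""Fluctuation-theorem layer: detailed balance, average entropy production
rates (AEPR), the step-conservation test, and channel capacity.

Each signaling step j has a forward flux f_j = k_j [driver] [X_mj] [ATP]
and a backward flux b_j = k_-j [Ph] [X_mj*]; the log-flux ratio
log(f_j / b_j) is the step affinity and vanishes exactly at detailed
balance.  Two AEPR estimators are provided:

* probability-based — per-step magnitudes -log p_mj / tau_mj and
  log p_mj* / tau_-mj; at the maximum-entropy coding optimum every one of
  these equals the multiplier beta, so the AEPR is conserved across the
  cascade.  Per-step signs are folded into magnitudes: forward and
  backward estimates are both reported positive, and the conserved
  quantity is their common magnitude.
* trajectory-based — a finite-window time average of the instantaneous
  entropy production rate.  Deterministic trajectories use
  sigma(t) = (f - b) log(f / b) >= 0; stochastic trajectories use the
  per-jump estimator sum log[a_mu(x) / a_rev(x')] / T.  Both vanish at
  detailed balance, and since this linear cascade has no reaction cycles
  every exactly stationary state is flux-balanced step by step.

Channel capacity is C = K * <zeta>: information transmitted per unit time
equals the conserved AEPR up to the unit constant K (1 for nats,
log2(e) for bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CascadeSpec,
    ConcentrationState,
    DurationProfile,
    ThermoReport,
    Trajectory,
)

__all__ = [
    "BITS",
    "InfiniteAffinityError",
    "detailed_balance_residual",
    "aepr_from_probabilities",
    "aepr_from_trajectory",
    "conservation_test",
    "ConservationDiagnostic",
    "channel_capacity",
    "entropy_production_of_step",
    "run_conservation_check",
]

BITS = float(np.log2(np.e))  # K converting nats/time to bits/time


class InfiniteAffinityError(ZeroDivisionError):
    """One of the step fluxes is zero, so the log-flux ratio diverges."""


def _step_fluxes(spec: CascadeSpec, inactive, active, j: int) -> tuple[float, float]:
    """Forward and backward flux of step j (2 <= j <= n) at a state."""
    n = spec.n_steps
    if not 2 <= j <= n:
        raise IndexError(f"step index j must satisfy 2 <= j <= {n}, got {j}")
    t = j - 1  # 0-based index of the species being activated
    driver = inactive[0] if t == 1 else active[t - 1]
    f = spec.forward_rates[t - 1] * spec.atp * driver * inactive[t]
    b = spec.backward_rates[t - 1] * spec.phosphatase_levels[t - 1] * active[t]
    return float(f), float(b)


def detailed_balance_residual(spec: CascadeSpec, state: ConcentrationState, j: int) -> float:
    """log(forward flux / backward flux) of step j at the given state.

    Zero iff the step is in detailed balance.  Raises
    :class:`InfiniteAffinityError` when either flux vanishes (the affinity
    is then infinite).
    """
    f, b = _step_fluxes(spec, state.inactive, state.active, j)
    if b == 0.0:
        raise InfiniteAffinityError(
            f"backward flux of step {j} is zero (X_m{j}* = 0 or k_- Ph = 0): "
            "infinite-affinity condition"
        )
    if f == 0.0:
        raise InfiniteAffinityError(f"forward flux of step {j} is zero")
    return float(np.log(f / b))


def aepr_from_probabilities(
    p_forward, p_backward, durations: DurationProfile, K: float = 1.0
) -> ThermoReport:
    """Per-step AEPR magnitudes from occurrence probabilities and durations.

    Forward magnitude -log p_mj / tau_mj and backward magnitude
    log p_mj* / tau_-mj (both positive for probabilities in (0,1) under the
    sign convention tau > 0 > tau_-).  The conservation spread is the
    relative max-min spread over all 2n values; it is zero exactly when the
    probabilities are of maximum-entropy form.
    """
    p = np.asarray(p_forward, dtype=float)
    q = np.asarray(p_backward, dtype=float)
    if np.any((p <= 0) | (p >= 1)) or np.any((q <= 0) | (q >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if len(p) != len(durations) or len(q) != len(durations):
        raise ValueError("probability and duration lengths must agree")
    zf = -np.log(p) / durations.forward
    zb = np.log(q) / durations.backward
    per_step = np.concatenate([zf, zb])
    mean = float(per_step.mean())
    spread = float((per_step.max() - per_step.min()) / mean)
    return ThermoReport(
        aepr_per_step=per_step,
        aepr_mean=mean,
        conservation_spread=spread,
        capacity=K * mean,
        K=K,
    )


def _instantaneous_epr(spec, inactive, active, j):
    f, b = _step_fluxes(spec, inactive, active, j)
    if f <= 0.0 or b <= 0.0:
        raise InfiniteAffinityError(
            f"zero flux of step {j} inside the averaging window"
        )
    return (f - b) * np.log(f / b)


def _window_average_deterministic(traj, spec, j, i0, i1):
    t = traj.times[i0 : i1 + 1]
    sig = np.array(
        [
            _instantaneous_epr(spec, traj.inactive[i], traj.active[i], j)
            for i in range(i0, i1 + 1)
        ]
    )
    return float(np.trapezoid(sig, t) / (t[-1] - t[0]))


def _window_sum_stochastic(traj, spec, j, i0, i1):
    """Summed per-jump entropy production of step j over events in
    (i0, i1]; the state at index i-1 is the pre-jump state."""
    total = 0.0
    t_idx = j - 1
    vol = spec.volume
    for i in range(max(i0, 1), i1 + 1):
        d_act = traj.active[i, t_idx] - traj.active[i - 1, t_idx]
        if d_act == 0:
            continue
        f0, b0 = _step_fluxes(spec, traj.inactive[i - 1], traj.active[i - 1], j)
        f1, b1 = _step_fluxes(spec, traj.inactive[i], traj.active[i], j)
        # activation propensity = f / volume (bimolecular); deactivation = b
        if d_act > 0:  # forward jump x -> x'
            if b1 <= 0 or f0 <= 0:
                raise InfiniteAffinityError(
                    f"zero propensity around a forward jump of step {j}"
                )
            total += np.log((f0 / vol) / b1)
        else:  # backward jump
            if f1 <= 0 or b0 <= 0:
                raise InfiniteAffinityError(
                    f"zero propensity around a backward jump of step {j}"
                )
            total += np.log(b0 / (f1 / vol))
    return total


def aepr_from_trajectory(
    traj: Trajectory,
    spec: CascadeSpec,
    j: int,
    window: tuple[float, float],
    return_se: bool = False,
    n_blocks: int = 100,
):
    """Finite-window time average of the entropy production rate of step j.

    Deterministic trajectories average the instantaneous flux-affinity
    product (f - b) log(f / b) with the trapezoid rule.  Stochastic
    trajectories sum the per-jump log-propensity ratios
    log[a_mu(x) / a_rev(x')] over the window and divide by its length;
    this estimator has expectation zero in any stationary state of the
    (cycle-free, hence reversible) cascade and is positive under driving.

    With ``return_se=True`` a block standard error is attached: the window
    is split into ``n_blocks`` contiguous sub-windows and the spread of the
    block means estimates the uncertainty of the window mean.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not (t1 > t0):
        raise ValueError("window must satisfy t1 > t0")
    if t0 < traj.times[0] - 1e-12 or t1 > traj.times[-1] + 1e-12:
        raise ValueError("window must lie within the trajectory span")
    i0 = int(np.searchsorted(traj.times, t0, side="left"))
    i1 = int(np.searchsorted(traj.times, t1, side="right")) - 1
    if i1 <= i0:
        raise ValueError("window contains no trajectory samples")

    if traj.method == "deterministic":
        value = _window_average_deterministic(traj, spec, j, i0, i1)
    else:
        value = _window_sum_stochastic(traj, spec, j, i0, i1) / (t1 - t0)
    if not return_se:
        return value

    edges = np.linspace(t0, t1, n_blocks + 1)
    block_means = []
    for a, b in zip(edges[:-1], edges[1:]):
        ia = int(np.searchsorted(traj.times, a, side="left"))
        ib = int(np.searchsorted(traj.times, b, side="right")) - 1
        if ib <= ia:
            continue
        if traj.method == "deterministic":
            block_means.append(_window_average_deterministic(traj, spec, j, ia, ib))
        else:
            block_means.append(_window_sum_stochastic(traj, spec, j, ia, ib) / (b - a))
    block_means = np.asarray(block_means)
    se = float(block_means.std(ddof=1) / np.sqrt(len(block_means)))
    return value, se


@dataclass
class ConservationDiagnostic:
    """Outcome of the AEPR conservation test."""

    passed: bool
    spread: float
    rel_tol: float
    per_step: np.ndarray
    offenders: list[int]  # indices into per_step deviating most from the mean

    def __bool__(self) -> bool:  # allows `if conservation_test(...)`
        return self.passed

    def __str__(self) -> str:
        head = "PASS" if self.passed else "FAIL"
        msg = (
            f"AEPR conservation {head}: spread {self.spread:.3e} "
            f"(rel_tol {self.rel_tol:.3e})\nper-step AEPR: "
            + ", ".join(f"{v:.6g}" for v in self.per_step)
        )
        if not self.passed:
            msg += f"\noffending step indices: {self.offenders}"
        return msg


def conservation_test(report: ThermoReport, rel_tol: float) -> ConservationDiagnostic:
    """True iff the per-step AEPR spread is within ``rel_tol`` (inclusive).

    The diagnostic carries the per-step values; on failure, the steps whose
    relative deviation from the mean exceeds rel_tol/2 are flagged.
    """
    per_step = report.aepr_per_step
    passed = report.conservation_spread <= rel_tol
    offenders: list[int] = []
    if not passed:
        dev = np.abs(per_step - report.aepr_mean) / report.aepr_mean
        offenders = [int(i) for i in np.nonzero(dev > rel_tol / 2)[0]]
    return ConservationDiagnostic(
        passed=bool(passed),
        spread=float(report.conservation_spread),
        rel_tol=float(rel_tol),
        per_step=per_step.copy(),
        offenders=offenders,
    )


def channel_capacity(report: ThermoReport, K: float = 1.0) -> float:
    """Channel capacity C = K * <zeta>: K times the mean AEPR."""
    if report.aepr_mean < 0:
        raise ValueError("mean AEPR must be non-negative")
    if K <= 0:
        raise ValueError("K must be positive")
    return float(K * report.aepr_mean)


def entropy_production_of_step(
    report: ThermoReport, durations: DurationProfile, j: int
) -> float:
    """Entropy produced by the forward phase of step j: S_mj = tau_mj * <zeta>.

    ``j`` is a 0-based index into the duration profile.  At the coding
    optimum this equals -log p_mj.
    """
    if not 0 <= j < len(durations):
        raise IndexError(f"step index {j} out of range for {len(durations)} steps")
    return float(durations.forward[j] * report.aepr_mean)


def run_conservation_check(
    spec: CascadeSpec,
    t_max: float = 120.0,
    pulse=None,
    rel_tol: float = 1e-9,
    rise_fraction: float = 0.05,
    n_points: int = 4000,
) -> ConservationDiagnostic:
    """End-to-end pipeline: simulate -> extract durations -> maxent -> test.

    Runs a deterministic simulation of the cascade under a ligand pulse
    (default: onset 0.5, duration 2 time units), measures the signed step
    durations of the downstream activated species (steps 2..n), solves the
    maximum-entropy coding problem for those durations, and tests the
    conservation of the per-step AEPR.
    """
    from . import kinetics

    if pulse is None:
        pulse = kinetics.LigandPulse(onset=0.5, duration=2.0)
    net = kinetics.build_network(spec)
    init = ConcentrationState(spec.initial_inactive, spec.initial_active, 0.0)
    times = np.linspace(0.0, t_max, n_points)
    traj = kinetics.simulate_deterministic(net, init, times, pulse=pulse)
    n = spec.n_steps
    durations = kinetics.extract_durations(
        traj,
        steady_levels=np.zeros(n),
        rise_fraction=rise_fraction,
        species=range(1, n),
    )
    from .coding import maxent_analytic

    sol = maxent_analytic(durations)
    report = aepr_from_probabilities(sol.p_forward, sol.p_backward, durations)
    return conservation_test(report, rel_tol)
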