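"""Mass-action kinetics of the cascade: exact SSA, ODE integration, and
extraction of occurrence probabilities and step durations from trajectories.

The reaction scheme is strictly linear.  For each step ``j = 2 .. n`` there
is one activation and one deactivation:

    driver_j + X_mj + ATP  ->  driver_j + X_mj* + ADP     (rate k_m,j-1)
    Ph_m,j-1 + X_mj*       ->  Ph_m,j-1 + X_mj + Pi       (rate k_-m,j-1)

where ``driver_j`` is the activated upstream species ``X_m,j-1*`` except
for the receptor step ``j = 2``, which is driven by the ligand ``X_m1``
itself.  ATP and the phosphatases are chemostatted, so each reaction
conserves ``X_mj + X_mj*`` separately, and the trajectory conserves total
signaling material exactly.

The ligand stimulus may be a sustained level (default) or a finite pulse:
the pulse multiplies the receptor-activation propensity by a {0,1} time
gate, leaving molecule conservation intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import (
    CascadeSpec,
    ConcentrationState,
    DurationProfile,
    Trajectory,
    species_labels,
    validate_spec,
)

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "LigandPulse",
    "build_network",
    "simulate_stochastic",
    "simulate_deterministic",
    "extract_durations",
    "occurrence_probabilities",
    "activation_order",
    "DurationExtractionError",
    "trajectory_to_tsv",
    "trajectory_from_tsv",
]


@dataclass(frozen=True)
class LigandPulse:
    """Finite stimulation window: the receptor-activation propensity is
    multiplied by 1 inside [onset, onset + duration) and 0 outside."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("pulse requires onset >= 0 and duration > 0")

    def gate(self, t: float) -> float:
        return 1.0 if self.onset <= t < self.onset + self.duration else 0.0

    @property
    def switch_times(self) -> tuple[float, float]:
        return (self.onset, self.onset + self.duration)


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: stoichiometries over dynamic species plus a
    constant multiplier collecting the chemostatted factors."""

    reactants: dict  # label -> stoichiometric count (dynamic species only)
    products: dict
    rate_constant: float
    chemostat_factor: float  # e.g. [ATP] or [Ph]
    kind: str  # 'activation' | 'deactivation'
    step: int  # 1-based index j of the species being (de)activated


class ReactionNetwork:
    """The 2(n-1) reactions of a cascade plus fast index arrays.

    Species are indexed 0..n-1 (inactive) and n..2n-1 (active).
    """

    def __init__(self, spec: CascadeSpec) -> None:
        spec = validate_spec(spec)
        self.spec = spec
        n = spec.n_steps
        inact_labels, act_labels = species_labels(n, spec.cascade_id)
        self.species_index = {lbl: i for i, lbl in enumerate(inact_labels + act_labels)}
        self.reactions: list[Reaction] = []
        # columnar arrays for the propensity loop
        self._driver = np.empty(2 * (n - 1) if n > 1 else 0, dtype=int)
        self._substrate = np.empty_like(self._driver)
        self._target = np.empty_like(self._driver)  # 0-based step of species changed
        self._coef = np.empty(len(self._driver), dtype=float)
        self._is_fwd = np.empty(len(self._driver), dtype=bool)
        r = 0
        for t in range(1, n):  # 0-based target species index
            j = t + 1  # 1-based species number being activated
            driver_idx = 0 if t == 1 else n + (t - 1)  # ligand X_m1 or X_m,t*
            driver_lbl = inact_labels[0] if t == 1 else act_labels[t - 1]
            self.reactions.append(
                Reaction(
                    reactants={driver_lbl: 1, inact_labels[t]: 1},
                    products={driver_lbl: 1, act_labels[t]: 1},
                    rate_constant=float(spec.forward_rates[t - 1]),
                    chemostat_factor=float(spec.atp),
                    kind="activation",
                    step=j,
                )
            )
            self._driver[r] = driver_idx
            self._substrate[r] = t
            self._target[r] = t
            self._coef[r] = spec.forward_rates[t - 1] * spec.atp
            self._is_fwd[r] = True
            r += 1
            self.reactions.append(
                Reaction(
                    reactants={act_labels[t]: 1},
                    products={inact_labels[t]: 1},
                    rate_constant=float(spec.backward_rates[t - 1]),
                    chemostat_factor=float(spec.phosphatase_levels[t - 1]),
                    kind="deactivation",
                    step=j,
                )
            )
            self._driver[r] = -1  # unimolecular
            self._substrate[r] = n + t
            self._target[r] = t
            self._coef[r] = spec.backward_rates[t - 1] * spec.phosphatase_levels[t - 1]
            self._is_fwd[r] = False
            r += 1

    def __len__(self) -> int:
        return len(self.reactions)

    @property
    def n_steps(self) -> int:
        return self.spec.n_steps

    def propensities(
        self, inactive: np.ndarray, active: np.ndarray, t: float,
        pulse: LigandPulse | None, volume: float = 1.0,
    ) -> np.ndarray:
        """Propensity of every reaction at a state (copy numbers or
        concentrations; ``volume`` divides the bimolecular terms)."""
        x = np.concatenate([inactive, active])
        a = np.empty(len(self._coef))
        for r in range(len(a)):
            if self._is_fwd[r]:
                a[r] = self._coef[r] * x[self._driver[r]] * x[self._substrate[r]] / volume
            else:
                a[r] = self._coef[r] * x[self._substrate[r]]
        if pulse is not None and len(a) > 0:
            # reaction 0 is always the ligand-driven receptor activation
            a[0] *= pulse.gate(t)
        return a


def build_network(spec: CascadeSpec) -> ReactionNetwork:
    """Build the reaction network for a validated spec (2(n-1) reactions)."""
    return ReactionNetwork(spec)


def simulate_stochastic(
    network: ReactionNetwork,
    initial: ConcentrationState,
    t_max: float,
    seed: int,
    pulse: LigandPulse | None = None,
    max_events: int = 2_000_000,
) -> Trajectory:
    """Exact Gillespie direct-method simulation with integer copy numbers.

    Records the state after every event.  A ligand pulse makes the first
    propensity piecewise-constant in time; the sampler then advances to the
    next gate switch whenever the drawn waiting time would overshoot it,
    which keeps the algorithm exact (the exponential clock is memoryless).
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    inact = np.asarray(initial.inactive, dtype=float)
    act = np.asarray(initial.active, dtype=float)
    if np.any(inact != np.round(inact)) or np.any(act != np.round(act)):
        raise ValueError("stochastic simulation requires integer copy numbers")
    inact = inact.astype(np.int64)
    act = act.astype(np.int64)
    rng = np.random.default_rng(seed)
    volume = network.spec.volume
    switches = [] if pulse is None else [s for s in pulse.switch_times]

    times = [float(initial.time)]
    rec_in = [inact.copy()]
    rec_ac = [act.copy()]
    t = float(initial.time)
    for _ in range(max_events):
        a = network.propensities(inact.astype(float), act.astype(float), t, pulse, volume)
        a0 = a.sum()
        next_switch = next((s for s in switches if s > t), None)
        if a0 <= 0:
            if next_switch is None or next_switch >= t_max:
                break
            t = next_switch
            continue
        dt = rng.exponential(1.0 / a0)
        if next_switch is not None and t + dt > next_switch:
            t = next_switch  # propensities change here; redraw (memoryless)
            continue
        if t + dt > t_max:
            break
        t += dt
        r = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0), side="right"))
        tgt = network._target[r]
        if network._is_fwd[r]:
            inact[tgt] -= 1
            act[tgt] += 1
        else:
            inact[tgt] += 1
            act[tgt] -= 1
        times.append(t)
        rec_in.append(inact.copy())
        rec_ac.append(act.copy())
    else:
        raise RuntimeError(f"event budget exceeded ({max_events} events before t_max)")
    if times[-1] < t_max:  # hold the final state to t_max for time averaging
        times.append(float(t_max))
        rec_in.append(inact.copy())
        rec_ac.append(act.copy())
    return Trajectory(
        np.array(times), np.array(rec_in, dtype=float), np.array(rec_ac, dtype=float),
        method="stochastic", seed=seed,
    )


def simulate_deterministic(
    network: ReactionNetwork,
    initial: ConcentrationState,
    times,
    pulse: LigandPulse | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Mass-action ODE solution on the requested time grid.

    With a ligand pulse the integration is split at the gate switch times so
    the discontinuity never degrades the error control.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < 0:
        raise ValueError("times[0] must be >= 0")
    n = network.n_steps
    y0 = np.concatenate([initial.inactive, initial.active]).astype(float)

    volume = network.spec.volume  # ODE in the same units as the SSA state

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        a = network.propensities(y[:n], y[n:], t, pulse, volume=volume)
        dy = np.zeros_like(y)
        for r in range(len(a)):
            tgt = network._target[r]
            s = 1.0 if network._is_fwd[r] else -1.0
            dy[tgt] -= s * a[r]
            dy[n + tgt] += s * a[r]
        return dy

    # segment boundaries: pulse switches that fall inside the span
    t0, t1 = float(times[0]), float(times[-1])
    cuts = [t0]
    if pulse is not None:
        cuts += [s for s in pulse.switch_times if t0 < s < t1]
    cuts.append(t1)

    out = np.empty((len(times), 2 * n))
    idx0 = 0
    y = y0.copy()
    for a_t, b_t in zip(cuts[:-1], cuts[1:]):
        mask = (times >= a_t) & (times <= b_t)
        t_eval = times[mask]
        if len(t_eval) == 0 or t_eval[-1] < b_t:
            t_eval = np.append(t_eval, b_t)
            extra = True
        else:
            extra = False
        if a_t == b_t:
            sol_y = np.tile(y[:, None], (1, len(t_eval)))
        else:
            # midpoint evaluation of the gate is safe within a segment
            sol = solve_ivp(
                rhs, (a_t, b_t), y, t_eval=t_eval, method="LSODA",
                rtol=rtol, atol=atol, max_step=(b_t - a_t),
            )
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            sol_y = sol.y
        y = sol_y[:, -1].copy()
        k = len(t_eval) - (1 if extra else 0)
        out[idx0 : idx0 + k] = sol_y[:, :k].T
        idx0 += k
    # handle times exactly at interior cuts counted twice
    if idx0 != len(times):  # pragma: no cover - defensive
        raise RuntimeError("time grid bookkeeping error")
    return Trajectory(times, out[:, :n], out[:, n:], method="deterministic", seed=None)


def occurrence_probabilities(state: ConcentrationState) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence probabilities p_mj = X_mj / X and p_mj* = X_mj* / X."""
    total = state.total
    if total <= 0:
        raise ValueError("total signaling material must be positive")
    return state.inactive / total, state.active / total


class DurationExtractionError(RuntimeError):
    """A species never leaves its steady band, or the trajectory is truncated
    before it returns."""

    def __init__(self, message: str, step: int) -> None:
        super().__init__(message)
        self.step = step


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(ypad, kernel, mode="valid")[: len(y)]


def _cross_up(t, y, thresh, lo, hi):
    """First time in index range [lo, hi] where y rises strictly above thresh
    (linear interpolation between samples)."""
    for i in range(lo, hi + 1):
        if y[i] > thresh:
            if i == lo:
                return float(t[i])
            if y[i] != y[i - 1]:
                frac = (thresh - y[i - 1]) / (y[i] - y[i - 1])
                return float(t[i - 1] + frac * (t[i] - t[i - 1]))
            return float(t[i])
    return None


def _cross_down(t, y, thresh, lo, hi):
    """First time in index range [lo, hi] where y falls to or below thresh."""
    for i in range(lo, hi + 1):
        if y[i] <= thresh:
            if i == lo:
                return float(t[i])
            if y[i] != y[i - 1]:
                frac = (y[i - 1] - thresh) / (y[i - 1] - y[i])
                return float(t[i - 1] + frac * (t[i] - t[i - 1]))
            return float(t[i])
    return None


def _pulse_landmarks(t, y, steady, rise_fraction, band_frac, step_label):
    band = band_frac * abs(steady)
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    excess = peak - steady
    if excess <= band or excess <= 0:
        raise DurationExtractionError(
            f"species of step {step_label} never leaves its steady band", step_label
        )
    thresh = steady + max(band, rise_fraction * excess)
    t_on = _cross_up(t, y, thresh, 0, ipk)
    if t_on is None:
        raise DurationExtractionError(
            f"species of step {step_label} never leaves its steady band", step_label
        )
    t_ret = _cross_down(t, y, thresh, ipk, len(y) - 1) if ipk < len(y) else None
    if t_ret is None:
        raise DurationExtractionError(
            f"trajectory truncated before species of step {step_label} returns "
            "to its steady band", step_label,
        )
    return t_on, float(t[ipk]), t_ret


def extract_durations(
    traj: Trajectory,
    steady_levels,
    rise_fraction: float = 0.05,
    band_frac: float = 0.02,
    species=None,
    smooth_window: int = 11,
) -> DurationProfile:
    """Measure the signed step durations of each activated species.

    For each analyzed species the forward duration ``tau_mj`` runs from the
    onset of the concentration rise (first crossing above the steady level
    by ``rise_fraction`` of the peak excess, or by the steady band
    ``band_frac * steady``, whichever is larger) to the time of the peak,
    and the backward duration ``tau_-mj`` is minus the time from the peak
    back down to that same threshold.

    Parameters
    ----------
    steady_levels :
        Steady-state level of each activated species X_mj*, length n.
    species :
        0-based indices of the steps to analyze (default: all).
    smooth_window :
        Moving-average window (in samples) applied to stochastic
        trajectories before threshold crossing, to suppress single-event
        chatter around the threshold.  Ignored for deterministic input.
    """
    if not 0 < rise_fraction < 1:
        raise ValueError("rise_fraction must lie in (0, 1)")
    steady_levels = np.asarray(steady_levels, dtype=float)
    n = traj.n_steps
    if len(steady_levels) != n:
        raise ValueError("steady_levels must have one entry per step")
    if species is None:
        species = range(n)
    t = traj.times
    fwd, bwd = [], []
    for s in species:
        y = traj.active[:, s]
        if traj.method == "stochastic":
            y = _moving_average(y, smooth_window)
        t_on, t_pk, t_ret = _pulse_landmarks(
            t, y, steady_levels[s], rise_fraction, band_frac, s + 1
        )
        fwd.append(t_pk - t_on)
        bwd.append(-(t_ret - t_pk))
    return DurationProfile(np.array(fwd), np.array(bwd))


def activation_order(
    traj: Trajectory,
    steady_levels,
    rise_fraction: float = 0.05,
    band_frac: float = 0.02,
    species=None,
    smooth_window: int = 11,
) -> list[str]:
    """Chronological event sequence of the cascade.

    Each activated species contributes its starred label at the onset of its
    concentration rise; the corresponding unstarred label enters at the time
    of the starred peak, when recovery of the inactive pool begins (the two
    are mirror images because each step conserves X_mj + X_mj*).  Labels are
    returned sorted by event time, reproducing the event-sequence notation
    of the cascade (e.g. ``X_m2* X_m3* X_m2 X_m3``).
    """
    steady_levels = np.asarray(steady_levels, dtype=float)
    n = traj.n_steps
    if species is None:
        species = range(n)
    inact_labels, act_labels = species_labels(n)
    t = traj.times
    events: list[tuple[float, str]] = []
    for s in species:
        y = traj.active[:, s]
        if traj.method == "stochastic":
            y = _moving_average(y, smooth_window)
        t_on, t_pk, _ = _pulse_landmarks(
            t, y, steady_levels[s], rise_fraction, band_frac, s + 1
        )
        events.append((t_on, act_labels[s]))
        events.append((t_pk, inact_labels[s]))
    events.sort(key=lambda e: e[0])
    return [lbl for _, lbl in events]


# -- tidy TSV export/import ---------------------------------------------------

def trajectory_to_tsv(traj: Trajectory, path) -> None:
    """Write a trajectory as tidy TSV with columns time, species, value."""
    n = traj.n_steps
    inact_labels, act_labels = species_labels(n)
    frames = []
    for labels, block in ((inact_labels, traj.inactive), (act_labels, traj.active)):
        for s, lbl in enumerate(labels):
            frames.append(
                pd.DataFrame({"time": traj.times, "species": lbl, "value": block[:, s]})
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def trajectory_from_tsv(path, method: str = "deterministic") -> Trajectory:
    """Read a tidy TSV written by :func:`trajectory_to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="time", columns="species", values="value").sort_index()
    labels = list(wide.columns)
    def _num(lbl: str) -> int:
        return int("".join(c for c in lbl if c.isdigit()))

    starred = sorted([l for l in labels if l.endswith("*")], key=_num)
    plain = sorted([l for l in labels if not l.endswith("*")], key=_num)
    times = wide.index.to_numpy(dtype=float)
    return Trajectory(
        times, wide[plain].to_numpy(float), wide[starred].to_numpy(float), method=method
    )
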