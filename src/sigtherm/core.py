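"""Domain types for a linear phosphorylation cascade.

A cascade of ``n`` signaling species ``X_m1 .. X_mn`` (cascade label ``m``)
is driven by a chemostatted ATP/ADP/Pi reservoir.  The ligand ``X_m1``
activates the receptor ``X_m2`` into its phosphorylated form ``X_m2*``;
each activated species ``X_mj*`` then activates the next species in the
chain, while a constant phosphatase pool ``Ph_mj`` deactivates it.  The
types here carry the kinetic model (:class:`CascadeSpec`), simulated time
courses (:class:`Trajectory`), the signed step durations measured from a
time course (:class:`DurationProfile`), and the outputs of the coding and
thermodynamic layers (:class:`CodingSolution`, :class:`ThermoReport`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "CascadeSpec",
    "ConcentrationState",
    "Trajectory",
    "DurationProfile",
    "CodingSolution",
    "ThermoReport",
    "SpecValidationError",
    "validate_spec",
    "read_spec",
    "write_spec",
    "read_durations",
    "write_durations",
    "species_labels",
]


class SpecValidationError(ValueError):
    """A cascade specification violates one of its invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SpecValidationError(f"{name} must be a one-dimensional sequence")
    return arr


@dataclass
class CascadeSpec:
    """Full kinetic description of one linear cascade.

    Parameters
    ----------
    n_steps :
        Number of signaling species ``n`` (the ligand counts as step 1).
    forward_rates :
        Activation rate coefficients ``k_mj`` for steps ``j = 1 .. n-1``
        (step ``j`` activates species ``j+1``).
    backward_rates :
        Deactivation rate coefficients ``k_-mj``, same length.
    phosphatase_levels :
        Constant phosphatase concentrations ``Ph_mj``, one per reaction
        pair (length ``n-1``); phosphatases are catalysts, never consumed.
    atp, adp, pi :
        Chemostatted reservoir concentrations, held fixed.
    initial_inactive, initial_active :
        Concentrations (or copy numbers) of ``X_mj`` and ``X_mj*`` at t=0,
        each of length ``n``.
    volume :
        System size Omega used by the stochastic path to convert
        bimolecular rate coefficients into propensities.
    seed :
        Default RNG seed carried with the spec (may be None).
    cascade_id :
        Cascade label ``m``; carried through species names only.
    """

    n_steps: int
    forward_rates: Sequence[float]
    backward_rates: Sequence[float]
    phosphatase_levels: Sequence[float]
    atp: float
    adp: float
    pi: float
    initial_inactive: Sequence[float]
    initial_active: Sequence[float]
    volume: float = 1.0
    seed: int | None = None
    cascade_id: str = "m"

    def __post_init__(self) -> None:
        self.n_steps = int(self.n_steps)
        self.forward_rates = _as_float_array(self.forward_rates, "forward_rates")
        self.backward_rates = _as_float_array(self.backward_rates, "backward_rates")
        self.phosphatase_levels = _as_float_array(
            self.phosphatase_levels, "phosphatase_levels"
        )
        self.initial_inactive = _as_float_array(self.initial_inactive, "initial_inactive")
        self.initial_active = _as_float_array(self.initial_active, "initial_active")

    @property
    def total_material(self) -> float:
        """Total signaling concentration X = sum_j (X_mj + X_mj*)."""
        return float(self.initial_inactive.sum() + self.initial_active.sum())


def validate_spec(spec: CascadeSpec) -> CascadeSpec:
    """Check every invariant of a :class:`CascadeSpec`.

    Returns the spec unchanged if valid, otherwise raises
    :class:`SpecValidationError` naming the first violated invariant.
    """
    n = spec.n_steps
    if n < 1:
        raise SpecValidationError(f"n_steps must be >= 1, got {n}")
    for name in ("forward_rates", "backward_rates", "phosphatase_levels"):
        arr = getattr(spec, name)
        if len(arr) != n - 1:
            raise SpecValidationError(
                f"length mismatch: {name} has length {len(arr)}, expected n_steps-1 = {n - 1}"
            )
        if np.any(arr <= 0):
            j = int(np.argmax(arr <= 0))
            raise SpecValidationError(f"positivity: {name}[{j}] = {arr[j]} must be > 0")
    for name in ("atp", "adp", "pi", "volume"):
        v = getattr(spec, name)
        if not v > 0:
            raise SpecValidationError(f"positivity: {name} = {v} must be > 0")
    for name in ("initial_inactive", "initial_active"):
        arr = getattr(spec, name)
        if len(arr) != n:
            raise SpecValidationError(
                f"length mismatch: {name} has length {len(arr)}, expected n_steps = {n}"
            )
        if np.any(arr < 0):
            raise SpecValidationError(f"negativity: {name} has a negative entry")
    if not spec.total_material > 0:
        raise SpecValidationError("zero total X: sum of initial concentrations must be > 0")
    return spec


def species_labels(n_steps: int, cascade_id: str = "m") -> tuple[list[str], list[str]]:
    """Names of the inactive and active species, e.g. ``X_m2`` / ``X_m2*``."""
    inact = [f"X_{cascade_id}{j + 1}" for j in range(n_steps)]
    act = [f"X_{cascade_id}{j + 1}*" for j in range(n_steps)]
    return inact, act


# -- config file round-trip ---------------------------------------------------

_CONFIG_KEYS = (
    "n_steps",
    "forward_rates",
    "backward_rates",
    "phosphatase_levels",
    "atp",
    "adp",
    "pi",
    "initial_inactive",
    "initial_active",
    "volume",
    "seed",
)


def write_spec(spec: CascadeSpec, path) -> None:
    """Serialize a validated spec to a flat YAML config file."""
    d = asdict(spec)
    out = {}
    for k in _CONFIG_KEYS:
        v = d[k]
        if isinstance(v, np.ndarray):
            v = [float(x) for x in v]
        out[k] = v
    out["cascade_id"] = spec.cascade_id
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def read_spec(path) -> CascadeSpec:
    """Read a YAML config file written by :func:`write_spec` (or by hand)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kwargs = {k: d[k] for k in _CONFIG_KEYS if k in d}
    if "cascade_id" in d:
        kwargs["cascade_id"] = d["cascade_id"]
    return validate_spec(CascadeSpec(**kwargs))


def write_durations(profile: "DurationProfile", path) -> None:
    """Write a duration profile as two-column TSV (tau_forward, tau_backward)."""
    with open(path, "w") as fh:
        fh.write("tau_forward\ttau_backward\n")
        for f, b in zip(profile.forward, profile.backward):
            fh.write(f"{float(f)!r}\t{float(b)!r}\n")


def read_durations(path) -> "DurationProfile":
    """Read a duration profile written by :func:`write_durations`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return DurationProfile(data[:, 0], data[:, 1])


@dataclass
class ConcentrationState:
    """Concentrations of all species at one instant."""

    inactive: np.ndarray
    active: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.inactive = np.asarray(self.inactive, dtype=float)
        self.active = np.asarray(self.active, dtype=float)
        if self.inactive.shape != self.active.shape:
            raise ValueError("inactive and active must have equal length")
        if self.time < 0:
            raise ValueError("time must be non-negative")

    @property
    def total(self) -> float:
        return float(self.inactive.sum() + self.active.sum())


class Trajectory:
    """Time-ordered record of species concentrations.

    Stored columnar for efficiency: ``times`` of shape (T,), ``inactive``
    and ``active`` of shape (T, n).  Indexing yields
    :class:`ConcentrationState` views.
    """

    def __init__(
        self,
        times: np.ndarray,
        inactive: np.ndarray,
        active: np.ndarray,
        method: str,
        seed: int | None = None,
    ) -> None:
        self.times = np.asarray(times, dtype=float)
        self.inactive = np.asarray(inactive, dtype=float)
        self.active = np.asarray(active, dtype=float)
        if method not in ("stochastic", "deterministic"):
            raise ValueError("method must be 'stochastic' or 'deterministic'")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        self.method = method
        self.seed = seed

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i: int) -> ConcentrationState:
        return ConcentrationState(self.inactive[i], self.active[i], float(self.times[i]))

    def __iter__(self) -> Iterator[ConcentrationState]:
        for i in range(len(self)):
            yield self[i]

    @property
    def n_steps(self) -> int:
        return self.inactive.shape[1]

    def totals(self) -> np.ndarray:
        """Total signaling material at every recorded time."""
        return self.inactive.sum(axis=1) + self.active.sum(axis=1)


@dataclass
class DurationProfile:
    """Signed durations of each signaling step.

    ``forward[j]`` (> 0) is the duration of the concentration rise of the
    j-th activated species; ``backward[j]`` (< 0) is the signed duration of
    its decay back to the steady level.  The net span of step j is
    ``forward[j] - backward[j] > 0``.
    """

    forward: np.ndarray
    backward: np.ndarray

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if self.forward.shape != self.backward.shape or self.forward.ndim != 1:
            raise ValueError("forward and backward must be 1-d arrays of equal length")
        if np.any(self.forward <= 0):
            raise ValueError("forward durations must be strictly positive")
        if np.any(self.backward >= 0):
            raise ValueError("backward durations must be strictly negative")

    def __len__(self) -> int:
        return len(self.forward)

    @property
    def span(self) -> np.ndarray:
        """Per-step net span tau_mj - tau_-mj (always positive)."""
        return self.forward - self.backward


@dataclass
class CodingSolution:
    """Occurrence probabilities and multipliers at (or near) the coding optimum.

    ``beta`` is the Lagrange multiplier of the total-duration constraint and
    carries the dimension of an entropy production rate; ``alpha`` is the
    multiplier of the normalization constraint (equal to -X at the optimum).
    """

    p_forward: np.ndarray
    p_backward: np.ndarray
    beta: float
    alpha: float
    entropy: float
    total_duration: float
    event_count_log: float

    def __post_init__(self) -> None:
        self.p_forward = np.asarray(self.p_forward, dtype=float)
        self.p_backward = np.asarray(self.p_backward, dtype=float)

    @property
    def normalization(self) -> float:
        """Sum of all occurrence probabilities (1 at a valid solution)."""
        return float(self.p_forward.sum() + self.p_backward.sum())

    def to_dict(self) -> dict:
        return {
            "p_forward": [float(x) for x in self.p_forward],
            "p_backward": [float(x) for x in self.p_backward],
            "beta": float(self.beta),
            "alpha": float(self.alpha),
            "entropy": float(self.entropy),
            "total_duration": float(self.total_duration),
            "event_count_log": float(self.event_count_log),
        }


@dataclass
class ThermoReport:
    """Per-step average entropy production rates and derived quantities.

    ``aepr_per_step`` holds the 2n per-step AEPR magnitudes (n forward
    followed by n backward); ``conservation_spread`` is their relative
    max-min spread, zero exactly when the AEPR is conserved across steps.
    """

    aepr_per_step: np.ndarray
    aepr_mean: float
    conservation_spread: float
    capacity: float
    K: float = 1.0

    def __post_init__(self) -> None:
        self.aepr_per_step = np.asarray(self.aepr_per_step, dtype=float)

    @property
    def n_steps(self) -> int:
        return len(self.aepr_per_step) // 2

    @property
    def aepr_forward(self) -> np.ndarray:
        return self.aepr_per_step[: self.n_steps]

    @property
    def aepr_backward(self) -> np.ndarray:
        return self.aepr_per_step[self.n_steps :]

    def to_dict(self) -> dict:
        return {
            "aepr_per_step": [float(x) for x in self.aepr_per_step],
            "aepr_mean": float(self.aepr_mean),
            "conservation_spread": float(self.conservation_spread),
            "capacity": float(self.capacity),
            "K": float(self.K),
        }
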