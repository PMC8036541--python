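"""Canonical-ensemble samplers used as the within-replica stage of each cycle.

Metropolis Monte Carlo is the default propagator (a quench is then simply
sampling at the baseline temperature); BAOAB Langevin dynamics is available
for potentials that expose an analytic gradient.  Every replica owns an
independent random stream, so a full multi-replica run is bit-reproducible
from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB

__all__ = [
    "ReplicaState",
    "CycleSchedule",
    "propagate",
    "quench",
    "tune_step_size",
    "resample_velocities",
]


@dataclass
class ReplicaState:
    """Coordinates + bookkeeping of one replica.

    ``potential_energy`` is refreshed from the potential after every
    propagation call.  ``rng`` is this replica's private random stream.
    """

    coordinates: np.ndarray
    rung_index: int
    potential_energy: float
    velocities: np.ndarray | None = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def copy(self) -> "ReplicaState":
        return replace(
            self,
            coordinates=self.coordinates.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
        )


@dataclass(frozen=True)
class CycleSchedule:
    """Per-cycle step counts: sampling sweeps then quench sweeps.

    ``step_size`` is the MC displacement in nm (or Langevin timestep in ps);
    None means use per-temperature tuned step sizes.
    """

    sampling_steps: int
    quench_steps: int
    step_size: float | None = None

    def __post_init__(self):
        if self.sampling_steps <= 0:
            raise ValueError("sampling_steps must be > 0")
        if self.quench_steps < 0:
            raise ValueError("quench_steps must be >= 0")


def propagate(
    state: ReplicaState,
    potential,
    temperature: float,
    steps: int,
    *,
    method: str = "mc",
    step_size: float = 0.2,
    mass: float = 1.0,
    friction: float = 5.0,
) -> ReplicaState:
    """Propagate a replica for ``steps`` MC sweeps or Langevin steps at T.

    MC satisfies detailed balance with respect to exp(-V / k_B T); Langevin
    (BAOAB) targets the same distribution for small timesteps.  Returns the
    same state object with coordinates and energy updated; ``steps=0`` is a
    no-op.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return state
    if method == "mc":
        beta = 1.0 / (KB * temperature)
        x = state.coordinates
        e = state.potential_energy
        for _ in range(steps):
            x, e, _, _ = potential.mc_sweep(x, e, beta, step_size, state.rng)
        state.coordinates = x
        state.potential_energy = potential.energy(x)
    elif method == "langevin":
        _baoab(state, potential, temperature, steps, step_size, mass, friction)
        state.potential_energy = potential.energy(state.coordinates)
    else:
        raise ValueError(f"unknown propagation method {method!r}")
    if not np.isfinite(state.potential_energy):
        raise FloatingPointError(
            f"non-finite energy after propagation; state dump: rung={state.rung_index} "
            f"x={state.coordinates!r}"
        )
    return state


def _baoab(state, potential, temperature, steps, dt, mass, friction):
    """BAOAB splitting of underdamped Langevin dynamics."""
    kbt = KB * temperature
    x = np.asarray(state.coordinates, dtype=float)
    if state.velocities is None:
        state.velocities = resample_velocities(x.shape, temperature, mass, state.rng)
    v = state.velocities
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(kbt / mass * (1.0 - c1 * c1))
    f = -potential.gradient(x)
    for _ in range(steps):
        v = v + 0.5 * dt * f / mass
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * state.rng.standard_normal(x.shape)
        x = x + 0.5 * dt * v
        if potential.period is not None:
            x = (x + 0.5 * potential.period) % potential.period - 0.5 * potential.period
        f = -potential.gradient(x)
        v = v + 0.5 * dt * f / mass
    state.coordinates = x
    state.velocities = v


def resample_velocities(shape, temperature, mass, rng) -> np.ndarray:
    """Maxwell-Boltzmann velocities at T (nm/ps, unit-mass convention)."""
    sigma = np.sqrt(KB * temperature / mass)
    return sigma * rng.standard_normal(shape)


def quench(
    state: ReplicaState,
    potential,
    t_base: float,
    schedule: CycleSchedule,
    *,
    method: str = "mc",
    step_size: float = 0.2,
    velocity_handling: str = "resample",
) -> ReplicaState:
    """Cool a replica to the baseline temperature before an exchange attempt.

    MC: simply sample ``quench_steps`` sweeps at ``t_base``.  Langevin: the
    thermostat target becomes ``t_base`` and velocities are resampled at
    ``t_base`` on entry (or rescaled, per ``velocity_handling``).  The rung
    index is left unchanged.
    """
    if schedule.quench_steps == 0:
        return state
    if method == "langevin" and state.velocities is not None:
        if velocity_handling == "resample":
            state.velocities = resample_velocities(
                state.coordinates.shape, t_base, 1.0, state.rng
            )
        elif velocity_handling == "rescale":
            ke = float(np.sum(state.velocities**2))
            if ke > 0:
                target = state.velocities.size * KB * t_base
                state.velocities *= np.sqrt(target / ke)
        else:
            raise ValueError(f"unknown velocity handling {velocity_handling!r}")
    return propagate(
        state, potential, t_base, schedule.quench_steps, method=method, step_size=step_size
    )


def tune_step_size(
    potential,
    temperature: float,
    x0: np.ndarray,
    rng: np.random.Generator,
    *,
    target: tuple[float, float] = (0.3, 0.5),
    initial: float = 0.2,
    rounds: int = 20,
    trials_per_round: int = 120,
    max_step: float | None = None,
) -> float:
    """Burn-in MC step-size adaptation toward 30-50% acceptance, then frozen.

    Multiplicative update per round on ~``trials_per_round`` Metropolis trials
    (a many-particle sweep already contains many trials, so such systems need
    few sweeps).  The returned value is used for the rest of the run so
    detailed balance holds during production.
    """
    beta = 1.0 / (KB * temperature)
    x = np.array(x0, dtype=float).copy()
    e = potential.energy(x)
    step = float(initial)
    x, e, acc, per_sweep = potential.mc_sweep(x, e, beta, step, rng)
    sweeps = max(1, int(np.ceil(trials_per_round / max(per_sweep, 1))))
    for _ in range(rounds):
        acc = trials = 0
        for _ in range(sweeps):
            x, e, a, t = potential.mc_sweep(x, e, beta, step, rng)
            acc += a
            trials += t
        rate = acc / max(trials, 1)
        if rate < target[0]:
            step *= 0.8
        elif rate > target[1]:
            step *= 1.25
        if max_step is not None:
            step = min(step, max_step)
    return step
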