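"""Replica-exchange schedulers.

Two families are implemented on a shared geometric temperature ladder:

* **T-REMD** — neighbour exchanges in temperature space with the standard
  Metropolis criterion ``min(1, exp((beta_i - beta_j)(E_i - E_j)))``.
* **TIGER2 family** — every cycle all replicas sample at their rung
  temperature, are quenched to the baseline temperature, and exchanges are
  attempted between the current baseline replica and the other replicas in
  ascending ladder order with ``min(1, exp(-dE / k_B T_base))``; each
  accepted attempt displaces the previous baseline state into the baseline
  ensemble (multi-acceptance), and afterwards the non-baseline replicas are
  reassigned to the remaining rungs by ascending exchange energy.

The variants differ only in the energy driving the exchange decision:
``tiger2`` uses the full potential energy, ``tiger2h`` the implicit-solvent
reduced energy (solute terms plus implicit bulk term), ``tiger2hs`` the
hybrid energy over the solute plus a fixed-size shell of nearest explicit
solvent particles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .propagators import CycleSchedule, ReplicaState, propagate, quench, tune_step_size

logger = logging.getLogger(__name__)

__all__ = [
    "TemperatureLadder",
    "ExchangeDecision",
    "BaselineFrame",
    "BaselineEnsemble",
    "ProtocolError",
    "build_ladder",
    "tremd_exchange",
    "tiger_exchange",
    "run_protocol",
]

PROTOCOLS = ("tremd", "tiger2", "tiger2h", "tiger2hs")


class ProtocolError(ValueError):
    """Protocol/system incompatibility (e.g. tiger2hs without solvent)."""


@dataclass(frozen=True)
class TemperatureLadder:
    """Geometric (exponential) ladder of sampling temperatures."""

    tmin: float
    tmax: float
    m: int
    temps: tuple[float, ...]

    @property
    def t_base(self) -> float:
        return self.temps[0]


def build_ladder(tmin: float, tmax: float, m: int) -> TemperatureLadder:
    """temps[i] = tmin * (tmax/tmin)^(i/(m-1)): exponential scale, m rungs."""
    if m < 2:
        raise ValueError("ladder needs at least 2 rungs")
    if not (0 < tmin < tmax):
        raise ValueError("need 0 < tmin < tmax")
    i = np.arange(m)
    temps = tmin * (tmax / tmin) ** (i / (m - 1))
    temps[0], temps[-1] = tmin, tmax  # exact endpoints
    return TemperatureLadder(tmin=tmin, tmax=tmax, m=m, temps=tuple(temps))


@dataclass(frozen=True)
class ExchangeDecision:
    cycle: int
    candidate_rung: int
    delta_e: float
    probability: float
    accepted: bool


@dataclass(frozen=True)
class BaselineFrame:
    coordinates: np.ndarray
    exchange_energy: float
    cycle_index: int
    source_rung: int


@dataclass
class BaselineEnsemble:
    """Accepted baseline-temperature conformations with full provenance."""

    frames: list[BaselineFrame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    decisions: list[ExchangeDecision] = field(default_factory=list)
    rung_traces: np.ndarray | None = None  # (n_cycles, n_replicas) rung of each replica

    def coordinates(self) -> np.ndarray:
        return np.array([f.coordinates for f in self.frames])

    def energies(self) -> np.ndarray:
        return np.array([f.exchange_energy for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


def tremd_exchange(states, ladder: TemperatureLadder, parity: int, rng) -> list:
    """Alternating-parity neighbour swaps of rung assignments.

    Pair (i, i+1) for i of the given parity swaps with probability
    ``min(1, exp((beta_i - beta_{i+1})(E_i - E_{i+1})))``.  The rung multiset
    is conserved.
    """
    by_rung = _states_by_rung(states, ladder.m)
    for i in range(parity % 2, ladder.m - 1, 2):
        a, b = by_rung[i], by_rung[i + 1]
        beta_i = 1.0 / (KB * ladder.temps[i])
        beta_j = 1.0 / (KB * ladder.temps[i + 1])
        log_p = (beta_i - beta_j) * (a.potential_energy - b.potential_energy)
        if np.log(rng.random()) < min(0.0, log_p):
            a.rung_index, b.rung_index = i + 1, i
            by_rung[i], by_rung[i + 1] = b, a
    return states


def _states_by_rung(states, m):
    by_rung = {s.rung_index: s for s in states}
    if sorted(by_rung) != list(range(m)):
        raise ValueError("states must occupy each rung exactly once")
    return by_rung


def tiger_exchange(states, exchange_energies, t_base: float, rng, cycle: int = 0):
    """One TIGER2 global-exchange step on quenched replicas.

    Candidates are visited in ascending rung order; each attempt compares the
    candidate's exchange energy against the current baseline comparator with
    the Metropolis criterion at ``t_base``.  On acceptance the displaced
    baseline state joins the accepted list and the candidate becomes the new
    comparator.  Finally the non-baseline replicas are reassigned to rungs
    1..M-1 by ascending exchange energy (lowest energy, lowest temperature).

    Returns ``(states, accepted_frames, decisions)``; rung indices are
    updated in place and their multiset is conserved.
    """
    if len(states) != len(exchange_energies):
        raise ValueError("one exchange energy per state required")
    m = len(states)
    by_rung = _states_by_rung(states, m)
    energy_of = {id(s): float(e) for s, e in zip(states, exchange_energies)}
    kbt = KB * t_base
    baseline = by_rung[0]
    accepted_frames: list[BaselineFrame] = []
    decisions: list[ExchangeDecision] = []
    for rung in range(1, m):
        cand = by_rung[rung]
        delta_e = energy_of[id(cand)] - energy_of[id(baseline)]
        p = min(1.0, float(np.exp(-delta_e / kbt)))
        u = rng.random()  # in [0, 1): p = 1 (dE <= 0) always accepts
        accepted = u < p
        decisions.append(
            ExchangeDecision(
                cycle=cycle, candidate_rung=rung, delta_e=delta_e, probability=p,
                accepted=accepted,
            )
        )
        logger.debug(
            "cycle %d rung %d dE=%.4f p=%.4f accepted=%s", cycle, rung, delta_e, p, accepted
        )
        if accepted:
            accepted_frames.append(
                BaselineFrame(
                    coordinates=baseline.coordinates.copy(),
                    exchange_energy=energy_of[id(baseline)],
                    cycle_index=cycle,
                    source_rung=baseline.rung_index,
                )
            )
            baseline = cand
    baseline.rung_index = 0
    others = [s for s in states if s is not baseline]
    others.sort(key=lambda s: (energy_of[id(s)], id(s)))
    for rank, s in enumerate(others):
        s.rung_index = rank + 1
    return states, accepted_frames, decisions


def run_protocol(
    protocol: str,
    potential,
    ladder: TemperatureLadder,
    schedule: CycleSchedule,
    n_cycles: int,
    master_seed: int,
    *,
    system=None,
    shell=None,
    hybrid_model=None,
    x0=None,
    method: str = "mc",
    tune: bool = True,
    record_rung_traces: bool = False,
) -> BaselineEnsemble:
    """Run ``n_cycles`` of sample -> quench -> exchange and collect the baseline ensemble.

    The exchange-decision energy is the full potential for ``tiger2``, the
    implicit-solvent reduced energy for ``tiger2h``, and the hybrid
    solute+shell energy for ``tiger2hs`` (the latter two require ``system``;
    ``tiger2hs`` additionally requires explicit solvent and a
    :class:`~tigersim.hybrid_solvent.ShellSpec`).  The run is
    bit-reproducible given ``master_seed``.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    exchange_fn = _make_exchange_energy_fn(protocol, potential, system, shell, hybrid_model)

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(ladder.m + 2)
    tune_rng = np.random.default_rng(children[0])
    exchange_rng = np.random.default_rng(children[1])

    x_init = np.asarray(potential.initial_coordinates() if x0 is None else x0, dtype=float)
    if schedule.step_size is not None:
        step_sizes = [schedule.step_size] * ladder.m
    elif tune:
        sys_obj = getattr(potential, "system", None)
        max_step = sys_obj.box_length / 2.0 if sys_obj is not None else None
        step_sizes = [
            tune_step_size(potential, t, x_init, tune_rng, max_step=max_step)
            for t in ladder.temps
        ]
    else:
        step_sizes = [0.2] * ladder.m
    base_step = step_sizes[0]

    states = [
        ReplicaState(
            coordinates=x_init.copy(),
            rung_index=i,
            potential_energy=potential.energy(x_init),
            rng=np.random.default_rng(children[2 + i]),
        )
        for i in range(ladder.m)
    ]

    ensemble = BaselineEnsemble(
        metadata={
            "protocol": protocol,
            "ladder": {"tmin": ladder.tmin, "tmax": ladder.tmax, "m": ladder.m},
            "schedule": {
                "sampling_steps": schedule.sampling_steps,
                "quench_steps": schedule.quench_steps,
                "step_size": schedule.step_size,
            },
            "master_seed": master_seed,
            "step_sizes": list(map(float, step_sizes)),
            "n_cycles": n_cycles,
        }
    )
    traces = np.empty((n_cycles, ladder.m), dtype=int) if record_rung_traces else None

    for cycle in range(n_cycles):
        for s in states:
            propagate(
                s, potential, ladder.temps[s.rung_index], schedule.sampling_steps,
                method=method, step_size=step_sizes[s.rung_index],
            )
        if protocol == "tremd":
            tremd_exchange(states, ladder, parity=cycle % 2, rng=exchange_rng)
            base = next(s for s in states if s.rung_index == 0)
            ensemble.frames.append(
                BaselineFrame(
                    coordinates=base.coordinates.copy(),
                    exchange_energy=base.potential_energy,
                    cycle_index=cycle,
                    source_rung=0,
                )
            )
        else:
            for s in states:
                quench(s, potential, ladder.t_base, schedule, method=method, step_size=base_step)
            energies = [exchange_fn(s) for s in states]
            states, accepted, decisions = tiger_exchange(
                states, energies, ladder.t_base, exchange_rng, cycle=cycle
            )
            ensemble.frames.extend(accepted)
            final_base = next(s for s in states if s.rung_index == 0)
            ensemble.frames.append(
                BaselineFrame(
                    coordinates=final_base.coordinates.copy(),
                    exchange_energy=exchange_fn(final_base),
                    cycle_index=cycle,
                    source_rung=0,
                )
            )
            ensemble.decisions.extend(decisions)
        if traces is not None:
            for ridx, s in enumerate(states):
                traces[cycle, ridx] = s.rung_index
    if traces is not None:
        ensemble.rung_traces = traces
    return ensemble


def _make_exchange_energy_fn(protocol, potential, system, shell, hybrid_model):
    if protocol in ("tremd", "tiger2"):
        return lambda s: float(potential.energy(s.coordinates))
    from .hybrid_solvent import HybridEnergyModel, ShellSpec, hybrid_energy

    if system is None:
        system = getattr(potential, "system", None)
    if system is None:
        raise ProtocolError(f"{protocol} requires a particle system with solvent bookkeeping")
    model = hybrid_model if hybrid_model is not None else HybridEnergyModel()
    if protocol == "tiger2h":
        shell = ShellSpec(r=0.0, n=0)
    else:  # tiger2hs
        if len(system.solvent) == 0:
            raise ProtocolError("tiger2hs requires explicit solvent particles")
        if shell is None:
            raise ProtocolError("tiger2hs requires a ShellSpec")
    return lambda s: hybrid_energy(s.coordinates, potential, shell, model)
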