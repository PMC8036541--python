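"""Run configuration, trajectory I/O and end-to-end workflows.

Trajectories are text formats only: multi-model PDB (one bead per pseudo-atom
record, chain IDs A/B and S for solvent, coordinates in Angstrom at the file
boundary) or whitespace XYZ-per-frame, with an optional per-frame energy
sidecar CSV.  The mutant-panel workflow chains fixture generation, restrained
TIGER2h docking, distance-PCA on the wild type, projection of every mutant
onto the wild-type axes, and shared-bin-edge landscapes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conf_analysis as ca
from .constants import KB
from .hybrid_solvent import ShellSpec
from .propagators import CycleSchedule
from .restraints import make_rigid_body_restraints
from .tiger_engine import BaselineEnsemble, build_ladder, run_protocol
from .toy_systems import DimerPotential, DimerSystem, MutationEdit, apply_mutation, make_dimer_fixture

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TrajectoryError",
    "PanelReport",
    "read_trajectory",
    "write_trajectory",
    "write_energy_sidecar",
    "read_energy_sidecar",
    "write_run_outputs",
    "workflow_mutant_panel",
]


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory file."""


@dataclass
class RunConfig:
    """Declarative description of one sampling run; round-trips through YAML."""

    fixture_seed: int = 1
    n_solvent: int = 0
    protocol: str = "tiger2h"
    tmin: float = 280.0
    tmax: float = 450.0
    n_rungs: int = 6
    sampling_steps: int = 15
    quench_steps: int = 8
    step_size: float | None = None
    n_cycles: int = 400
    master_seed: int = 2024
    rigid_body_restraints: bool = True
    skip_terminal: int = 2
    restraint_k: float = 25.0
    shell_r: float = 0.41
    shell_n: int | None = None
    implicit_per_excluded: float = 0.0
    # the literature protocol counts one extra replica that only evaluates
    # hybrid energies; with the flag set, n_rungs includes that service replica
    hybrid_energy_replica: bool = False
    analysis_bins: int = 30
    analysis_kt_temperature: float = 280.0
    out_dir: str | None = None

    @property
    def sampling_rungs(self) -> int:
        return self.n_rungs - 1 if self.hybrid_energy_replica else self.n_rungs

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# trajectory I/O


def write_trajectory(path, frames, types, chain_ids, fmt: str | None = None) -> None:
    """Write frames (n_frames, n_particles, 3) in nm to multi-model PDB or XYZ."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix == ".xyz" else "pdb")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if fmt == "pdb":
        _write_pdb(path, frames, types, chain_ids)
    elif fmt == "xyz":
        _write_xyz(path, frames, types)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str | None = None):
    """Read a trajectory; returns (frames nm, types, chain_ids)."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix == ".xyz" else "pdb")
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _write_pdb(path, frames, types, chain_ids):
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = frames.shape[1]
    stack = struc.AtomArrayStack(frames.shape[0], n)
    stack.coord = frames * 10.0  # nm -> Angstrom
    stack.chain_id = np.asarray(list(chain_ids), dtype="U4")
    stack.res_id = np.arange(1, n + 1)
    stack.res_name = np.asarray([f"B{t}"[:3] for t in types], dtype="U5")
    stack.atom_name = np.asarray([str(t)[:4] for t in types], dtype="U6")
    stack.element = np.asarray(["C"] * n, dtype="U2")
    stack.hetero = np.ones(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _read_pdb(path):
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise TrajectoryError(f"{path}: malformed PDB trajectory ({exc})") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    types = [str(t) for t in stack.atom_name]
    chain_ids = [str(c) for c in stack.chain_id]
    return coords / 10.0, types, chain_ids


def _write_xyz(path, frames, types):
    with open(path, "w") as fh:
        for k, frame in enumerate(frames):
            fh.write(f"{frame.shape[0]}\nframe {k}\n")
            for t, (x, y, z) in zip(types, frame):
                fh.write(f"{t} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz(path):
    frames, types = [], None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise TrajectoryError(
                f"{path}:{i + 1}: truncated frame (need {n} atom lines, found {len(block)})"
            )
        frame, frame_types = [], []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(f"{path}:{i + 3 + j}: malformed atom record {line!r}")
            frame_types.append(parts[0])
            try:
                frame.append([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise TrajectoryError(f"{path}:{i + 3 + j}: non-numeric coordinate") from exc
        if types is None:
            types = frame_types
        elif frame_types != types:
            raise TrajectoryError(f"{path}:{i + 1}: inconsistent atom ordering across frames")
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    chain_ids = ["A"] * len(types)
    return np.asarray(frames, dtype=float), types, chain_ids


def write_energy_sidecar(path, energies, cycles=None, rungs=None) -> None:
    df = pd.DataFrame({"frame": np.arange(len(energies)), "energy": energies})
    if cycles is not None:
        df["cycle"] = cycles
    if rungs is not None:
        df["source_rung"] = rungs
    df.to_csv(path, index=False)


def read_energy_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_outputs(out_dir, config: RunConfig, ensemble: BaselineEnsemble,
                      system: DimerSystem | None = None) -> Path:
    """Persist one run: config copy, metadata, baseline trajectory + CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    sched = ensemble.metadata.get("schedule", {})
    per_replica_steps = ensemble.metadata.get("n_cycles", 0) * (
        sched.get("sampling_steps", 0) + sched.get("quench_steps", 0)
    )
    meta = dict(ensemble.metadata)
    meta["n_frames"] = len(ensemble)
    # the per-replica vs aggregate accounting of total sampling is ambiguous
    # in the literature protocol; report both
    meta["total_steps_per_replica"] = per_replica_steps
    meta["total_steps_aggregate"] = per_replica_steps * meta.get("ladder", {}).get("m", 1)
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    pd.DataFrame(
        {
            "cycle": [f.cycle_index for f in ensemble.frames],
            "source_rung": [f.source_rung for f in ensemble.frames],
            "exchange_energy": [f.exchange_energy for f in ensemble.frames],
        }
    ).to_csv(out / "baseline.csv", index=False)
    if ensemble.decisions:
        pd.DataFrame(
            {
                "cycle": [d.cycle for d in ensemble.decisions],
                "candidate_rung": [d.candidate_rung for d in ensemble.decisions],
                "delta_e": [d.delta_e for d in ensemble.decisions],
                "p": [d.probability for d in ensemble.decisions],
                "accepted": [d.accepted for d in ensemble.decisions],
            }
        ).to_csv(out / "exchanges.csv", index=False)
    if system is not None and len(ensemble):
        coords = ensemble.coordinates().reshape(len(ensemble), -1, 3)
        coords = coords % system.box_length  # wrap into the periodic box
        chain_ids = ["A"] * len(system.chain_a) + ["B"] * len(system.chain_b) + [
            "S"
        ] * len(system.solvent)
        write_trajectory(out / "baseline.pdb", coords, system.types, chain_ids)
    return out


# ---------------------------------------------------------------------------
# mutant panel workflow


@dataclass
class PanelReport:
    axes: ca.PrincipalAxes
    landscapes: dict[str, ca.Landscape]
    summary: pd.DataFrame
    wt_minimum_bin: tuple[int, int]
    ensembles: dict[str, BaselineEnsemble] = field(default_factory=dict)


def _run_docking(config: RunConfig, system: DimerSystem) -> BaselineEnsemble:
    restraints = (
        make_rigid_body_restraints(system, config.skip_terminal, config.restraint_k)
        if config.rigid_body_restraints
        else []
    )
    potential = DimerPotential(system, restraints=restraints)
    ladder = build_ladder(config.tmin, config.tmax, config.sampling_rungs)
    schedule = CycleSchedule(config.sampling_steps, config.quench_steps, config.step_size)
    shell = None
    hybrid_model = None
    if config.protocol in ("tiger2h", "tiger2hs"):
        from .hybrid_solvent import HybridEnergyModel

        hybrid_model = HybridEnergyModel(
            implicit_per_excluded=config.implicit_per_excluded
        )
    if config.protocol == "tiger2hs":
        n = config.shell_n if config.shell_n is not None else len(system.solvent)
        shell = ShellSpec(r=config.shell_r, n=n)
    return run_protocol(
        config.protocol,
        potential,
        ladder,
        schedule,
        config.n_cycles,
        config.master_seed,
        system=system,
        shell=shell,
        hybrid_model=hybrid_model,
    )


def workflow_mutant_panel(config: RunConfig, mutations: dict[str, list[MutationEdit]] | None = None,
                          out_dir=None) -> PanelReport:
    """WT docking -> WT axes -> mutants on the same landscape.

    ``mutations`` maps construct name to the list of edits defining it (an
    empty dict reports the wild type only).  Every construct runs with the
    same master seed and protocol; all ensembles are projected on the
    wild-type principal axes and binned on the wild-type bin edges.  The
    summary table reports each construct's occupancy of the WT minimum bin
    (with a one-bin neighbourhood) and its minimax barrier from its own
    minimum to the WT minimum.
    """
    mutations = mutations or {}
    stage = "fixture"
    try:
        wt_system = make_dimer_fixture(config.fixture_seed, config.n_solvent)
        systems = {"WT": wt_system}
        for name, edits in mutations.items():
            sys_i = wt_system
            for edit in edits:
                sys_i = apply_mutation(sys_i, edit)
            systems[name] = sys_i

        stage = "sampling:WT"
        ensembles = {}
        for name, sys_i in systems.items():
            stage = f"sampling:{name}"
            logger.info("running %s docking for construct %s", config.protocol, name)
            ensembles[name] = _run_docking(config, sys_i)

        stage = "analysis"
        kt = KB * config.analysis_kt_temperature
        wt_frames = ensembles["WT"].coordinates().reshape(len(ensembles["WT"]), -1, 3)
        wt_feats = ca.interchain_distance_features(
            wt_frames, wt_system.chain_a, wt_system.chain_b, box_length=wt_system.box_length
        )
        axes = ca.fit_pca(wt_feats, n_components=2)
        wt_scores = ca.project(wt_feats, axes)
        wt_landscape = ca.boltzmann_landscape(wt_scores, bins=config.analysis_bins, kt=kt)
        wt_min = ca.minimum_bin(wt_landscape)
        shared_range = wt_landscape.axes_range

        landscapes = {"WT": wt_landscape}
        rows = []
        for name, ens in ensembles.items():
            if name != "WT":
                frames = ens.coordinates().reshape(len(ens), -1, 3)
                feats = ca.interchain_distance_features(
                    frames, wt_system.chain_a, wt_system.chain_b,
                    normalize=False, box_length=wt_system.box_length,
                )
                scores = ca.project(feats, axes)
                landscapes[name] = ca.boltzmann_landscape(
                    scores, bins=config.analysis_bins, kt=kt, axes_range=shared_range
                )
            land = landscapes[name]
            # occupancy relative to *all* frames of the construct, so mass
            # that leaves the wild-type score range counts against it
            in_range = land.n_frames / land.n_total if land.n_total else 0.0
            occupancy = ca.bin_occupancy(land, wt_min, neighborhood=1) * in_range
            try:
                own_min = ca.minimum_bin(land)
                barrier = ca.barrier_height(land, own_min, wt_min)
            except (ca.DisconnectedBasinsError, ValueError):
                barrier = float("nan")
            rows.append(
                {
                    "construct": name,
                    "n_frames": len(ens),
                    "wt_min_bin_occupancy": occupancy,
                    "barrier_to_wt_min": barrier,
                }
            )
        summary = pd.DataFrame(rows)
        report = PanelReport(
            axes=axes, landscapes=landscapes, summary=summary, wt_minimum_bin=wt_min,
            ensembles=ensembles,
        )
    except Exception as exc:
        raise RuntimeError(f"mutant panel failed at stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "panel_summary.csv", index=False)
        (out / "axes.json").write_text(json.dumps(report.axes.to_dict()))
        for name, land in landscapes.items():
            _write_landscape_csv(out / f"landscape_{name}.csv", land)
            ca.plot_landscape(land, out / f"landscape_{name}.png", title=name,
                              highlight_bin=wt_min)
    return report


def _write_landscape_csv(path, land: ca.Landscape) -> None:
    nx, ny = land.probability.shape
    ii, jj = np.meshgrid(range(nx), range(ny), indexing="ij")
    pd.DataFrame(
        {
            "bin_x": ii.ravel(),
            "bin_y": jj.ravel(),
            "x_lo": land.edges_x[ii.ravel()],
            "y_lo": land.edges_y[jj.ravel()],
            "p": land.probability.ravel(),
            "delta_g": land.delta_g.ravel(),
        }
    ).to_csv(path, index=False)
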