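"""Hybrid explicit/implicit exchange-energy machinery.

TIGER2hs drives exchange decisions with a reduced energy: the solute plus a
fixed-size shell of the N explicit solvent particles nearest to any solute
atom, with the excluded bulk replaced by a mean-field implicit term.  The
shell size N is determined once from the nearest-solute radial distribution
of an equilibrium trajectory and then held fixed, because a shell whose size
fluctuates between states biases the exchange energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShellSpec",
    "HybridEnergyModel",
    "select_shell",
    "hybrid_energy",
    "shell_size_from_rdf",
    "nearest_solute_distances",
    "calibrate_implicit_constant",
]


@dataclass(frozen=True)
class ShellSpec:
    """Shell cutoff distance r (nm) and the fixed particle count N it implies."""

    r: float
    n: int

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("shell size N must be >= 0")


@dataclass(frozen=True)
class HybridEnergyModel:
    """Implicit bulk term: a constant per excluded solvent particle.

    ``implicit_per_excluded`` (kcal/mol per particle) is a mean-field stand-in
    for the bulk-solvation free energy of the particles left out of the shell;
    zero by default.  ``use_minimum_image=False`` evaluates the hybrid energy
    without periodic wrapping (droplet convention).
    """

    implicit_per_excluded: float = 0.0
    use_minimum_image: bool = True


def nearest_solute_distances(solute_xyz, solvent_xyz, box_length=None) -> np.ndarray:
    """Per-solvent-particle distance to its nearest solute atom (minimum image)."""
    solute_xyz = np.asarray(solute_xyz, dtype=float)
    solvent_xyz = np.asarray(solvent_xyz, dtype=float)
    d = solvent_xyz[:, None, :] - solute_xyz[None, :, :]
    if box_length is not None:
        d -= box_length * np.round(d / box_length)
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    return r.min(axis=1)


def select_shell(solute_xyz, solvent_xyz, n: int, box_length=None) -> np.ndarray:
    """Indices of the N solvent particles nearest to the solute.

    Distance is to the nearest solute atom (not the centre of mass); ties are
    broken deterministically by particle index (stable sort).
    """
    solvent_xyz = np.asarray(solvent_xyz, dtype=float)
    if n < 0 or n > solvent_xyz.shape[0]:
        raise ValueError(f"shell size {n} outside [0, {solvent_xyz.shape[0]}]")
    if n == 0:
        return np.array([], dtype=int)
    d = nearest_solute_distances(solute_xyz, solvent_xyz, box_length)
    order = np.argsort(d, kind="stable")
    return np.sort(order[:n])


def hybrid_energy(coordinates, potential, shell: ShellSpec, model: HybridEnergyModel) -> float:
    """Hybrid exchange energy of a configuration (kcal/mol).

    Explicit terms (bonds, restraints and pair wells) are evaluated over the
    solute plus the selected shell only; every excluded solvent particle
    contributes ``model.implicit_per_excluded``.  Used only for exchange
    decisions, never for propagation.  With the shell covering all solvent
    and a zero implicit constant this equals the full potential energy
    exactly.
    """
    system = potential.system
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    n_solvent = len(system.solvent)
    if shell.n > n_solvent:
        raise ValueError(f"shell size {shell.n} exceeds solvent count {n_solvent}")
    solute = system.solute
    box = system.box_length if model.use_minimum_image else None
    local = select_shell(coords[solute], coords[system.solvent], shell.n, box)
    shell_idx = system.solvent[local]
    kept = np.concatenate([solute, shell_idx])

    mi_saved = potential.use_minimum_image
    potential.use_minimum_image = model.use_minimum_image
    try:
        e = potential.group_internal_energy(coords, kept)
    finally:
        potential.use_minimum_image = mi_saved
    e += potential.restraint_energy(coords)
    e += model.implicit_per_excluded * (n_solvent - shell.n)
    return float(e)


def shell_size_from_rdf(frames, r: float, bin_width: float = 0.005, box_length=None) -> ShellSpec:
    """Determine the fixed shell size N(r) from a trajectory.

    For each frame and each solvent particle the nearest-solute-atom distance
    is computed and histogrammed with the given bin width (default 0.005 nm);
    ``N(r)`` is the across-frame mean cumulative count up to the bin
    containing ``r``, rounded half-to-even.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    frames = list(frames)
    if not frames:
        raise ValueError("trajectory must contain at least one frame")
    cut_bin = int(np.floor(r / bin_width + 1e-9)) + 1  # count d < cut_bin*bin_width
    counts = []
    for solute_xyz, solvent_xyz in frames:
        d = nearest_solute_distances(solute_xyz, solvent_xyz, box_length)
        n_bins = max(cut_bin, int(np.ceil(d.max() / bin_width)) + 1) if d.size else cut_bin
        hist, _ = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width))
        counts.append(hist[:cut_bin].sum())
    n = int(np.round(np.mean(counts)))  # round half to even
    return ShellSpec(r=float(r), n=n)


def calibrate_implicit_constant(potential, frames, shell: ShellSpec) -> float:
    """Mean per-particle solute interaction of excluded solvent over a trajectory.

    Provides a fixture-calibrated value for
    :attr:`HybridEnergyModel.implicit_per_excluded`: the average pair energy
    between one excluded solvent particle and the solute+shell region.
    """
    system = potential.system
    n_solvent = len(system.solvent)
    n_excluded = n_solvent - shell.n
    if n_excluded <= 0:
        return 0.0
    totals = []
    for coords in frames:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        solute = system.solute
        box = system.box_length
        local = select_shell(coords[solute], coords[system.solvent], shell.n, box)
        shell_idx = system.solvent[local]
        kept = np.concatenate([solute, shell_idx])
        excluded = np.setdiff1d(system.solvent, shell_idx)
        e_cross = potential.pair_energy_between(coords, excluded, kept)
        e_excl = potential.group_internal_energy(coords, excluded)
        totals.append((e_cross + e_excl) / n_excluded)
    return float(np.mean(totals))
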