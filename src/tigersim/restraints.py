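"""Harmonic restraint terms.

Backbone-dihedral restraints implement rigid-body-like docking (the chain
keeps its internal conformation while translating/rotating freely), and
flat-bottom distance restraints stand in for hydrogen-bond restraints that
preserve secondary structure.

Convention: restraint energy is ``k * delta^2`` (no 1/2 factor), with the
dihedral deviation in degrees and the distance deviation in nm; pass
``half_factor=True`` for the ``k/2 * delta^2`` convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DihedralRestraint",
    "DistanceRestraint",
    "dihedral_angle",
    "restraint_energy",
    "make_rigid_body_restraints",
]


@dataclass(frozen=True)
class DihedralRestraint:
    atoms: tuple[int, int, int, int]
    theta0: float  # degrees
    k: float  # kcal/mol/deg^2

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if len(self.atoms) != 4:
            raise ValueError("dihedral restraint needs exactly 4 atom indices")


@dataclass(frozen=True)
class DistanceRestraint:
    atoms: tuple[int, int]
    d0: float  # nm
    k: float  # kcal/mol/nm^2
    flat_bottom: float = 0.0  # nm

    def __post_init__(self):
        if self.k < 0 or self.flat_bottom < 0:
            raise ValueError("force constant and flat bottom must be >= 0")
        if len(self.atoms) != 2:
            raise ValueError("distance restraint needs exactly 2 atom indices")


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees in (-180, 180] (atan2 convention)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(-y, x))
    return 180.0 if ang == -180.0 else float(ang)


def wrap_angle(delta: float) -> float:
    """Wrap an angular deviation in degrees to (-180, 180]."""
    wrapped = (delta + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def dihedral_angles(coords, quads) -> np.ndarray:
    """Vectorised signed dihedral angles (degrees) for an array of 4-index quads."""
    p = coords[np.asarray(quads, dtype=int)]  # (k, 4, 3)
    b0 = p[:, 1] - p[:, 0]
    b1 = p[:, 2] - p[:, 1]
    b2 = p[:, 3] - p[:, 2]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(-y, x))
    return np.where(ang == -180.0, 180.0, ang)


def pack_restraints(restraints):
    """Split a restraint list into vectorisable arrays.

    Returns ``(quads, theta0, k_dih, pairs, d0, flat, k_dist)``; empty arrays
    when a kind is absent.
    """
    dih = [r for r in restraints if isinstance(r, DihedralRestraint)]
    dist = [r for r in restraints if isinstance(r, DistanceRestraint)]
    other = [r for r in restraints if not isinstance(r, (DihedralRestraint, DistanceRestraint))]
    if other:
        raise TypeError(f"unknown restraint type {type(other[0]).__name__}")
    quads = np.array([r.atoms for r in dih], dtype=int).reshape(-1, 4)
    theta0 = np.array([r.theta0 for r in dih])
    k_dih = np.array([r.k for r in dih])
    pairs = np.array([r.atoms for r in dist], dtype=int).reshape(-1, 2)
    d0 = np.array([r.d0 for r in dist])
    flat = np.array([r.flat_bottom for r in dist])
    k_dist = np.array([r.k for r in dist])
    return quads, theta0, k_dih, pairs, d0, flat, k_dist


def packed_restraint_energy(coords, packed, half_factor: bool = False) -> float:
    quads, theta0, k_dih, pairs, d0, flat, k_dist = packed
    e = 0.0
    if len(quads):
        delta = (dihedral_angles(coords, quads) - theta0 + 180.0) % 360.0 - 180.0
        e += float(np.sum(k_dih * delta * delta))
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        delta = np.maximum(0.0, np.abs(d - d0) - flat)
        e += float(np.sum(k_dist * delta * delta))
    return 0.5 * e if half_factor else e


def restraint_energy(coords, restraints, half_factor: bool = False) -> float:
    """Total restraint energy at the given (n, 3) coordinates in kcal/mol."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    for res in restraints:
        if any(not (0 <= int(i) < n) for i in res.atoms):
            raise IndexError(f"restraint atom index out of range: {res.atoms}")
    return packed_restraint_energy(coords, pack_restraints(restraints), half_factor)


def chain_dihedral_quads(chain_indices) -> list[tuple[int, int, int, int]]:
    """Consecutive 4-bead index quads along a chain (n beads -> n-3 dihedrals)."""
    c = list(int(i) for i in chain_indices)
    return [tuple(c[i : i + 4]) for i in range(len(c) - 3)]


def make_rigid_body_restraints(system, skip_terminal: int = 2, k: float = 25.0):
    """One dihedral restraint per internal chain dihedral at the current value.

    The first and last ``skip_terminal`` dihedrals of each chain are omitted
    (the chain termini stay flexible).  Default force constant
    25 kcal/mol/deg^2.
    """
    if skip_terminal < 0:
        raise ValueError("skip_terminal must be >= 0")
    coords = system.positions
    restraints = []
    for chain in (system.chain_a, system.chain_b):
        quads = chain_dihedral_quads(chain)
        if len(quads) - 2 * skip_terminal < 1:
            raise ValueError(
                f"chain of {len(chain)} beads too short for skip_terminal={skip_terminal}"
            )
        kept = quads[skip_terminal : len(quads) - skip_terminal] if skip_terminal else quads
        for quad in kept:
            theta0 = dihedral_angle(*(coords[i] for i in quad))
            restraints.append(DihedralRestraint(atoms=quad, theta0=theta0, k=k))
    return restraints
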