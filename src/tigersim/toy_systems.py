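"""Synthetic energy models with analytically known reference behaviour.

These stand in for all-atom protein/solvent systems at desk scale: a 1D
double well and an N-dimensional harmonic oscillator (closed-form Boltzmann
statistics), a periodic dihedral chain whose conformers separate in dPCA
space, and a coarse-grained two-chain "patchy dimer" with designated
attractive interface beads, an explicit soft-sphere solvent bath and
per-bead-type mutation edits.

Units: kcal/mol, nm, K (see :mod:`tigersim.constants`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .constants import KB

__all__ = [
    "PotentialSpec",
    "Potential",
    "DoubleWell1D",
    "HarmonicND",
    "DihedralChain",
    "DimerSystem",
    "DimerPotential",
    "MutationEdit",
    "make_double_well",
    "make_harmonic",
    "make_dihedral_chain",
    "make_dimer_fixture",
    "apply_mutation",
    "alanine_like_edit",
    "aspartate_like_edit",
    "double_well_populations",
]

_POTENTIAL_KINDS = ("double_well_1d", "harmonic_nd", "dihedral_chain", "patchy_dimer")


@dataclass(frozen=True)
class PotentialSpec:
    """Declarative description of a toy potential.

    ``kind`` selects the functional form; ``parameters`` holds every named
    constant that form requires (checked in :meth:`build`).
    """

    kind: str
    parameters: dict

    def __post_init__(self):
        if self.kind not in _POTENTIAL_KINDS:
            raise ValueError(f"unknown potential kind {self.kind!r}")

    def build(self) -> "Potential":
        """Instantiate the evaluable potential this spec describes."""
        if self.kind == "double_well_1d":
            return DoubleWell1D(**self.parameters)
        if self.kind == "harmonic_nd":
            return HarmonicND(**self.parameters)
        if self.kind == "dihedral_chain":
            return DihedralChain(**self.parameters)
        raise ValueError(
            "patchy_dimer potentials are built from a DimerSystem via DimerPotential"
        )


class Potential:
    """Base class for evaluable potentials.

    Subclasses provide ``energy(x)`` (kcal/mol) on flat coordinate vectors
    and may provide ``gradient(x)`` for Langevin dynamics.  ``mc_sweep``
    performs one Metropolis sweep (one single-coordinate trial move per
    degree of freedom) and may be overridden for efficiency.
    """

    dimension: int = 1
    #: period of each coordinate in model units, or None for open coordinates
    period: float | None = None
    #: inclusive box bounds for open coordinates, or None for unbounded
    bounds: tuple[float, float] | None = None

    def energy(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} has no analytic gradient")

    def initial_coordinates(self) -> np.ndarray:
        return np.zeros(self.dimension)

    def mc_sweep(self, x, energy, beta, step, rng):
        """One Metropolis sweep of single-coordinate moves.

        Returns ``(x, energy, n_accepted, n_trials)``; ``x`` is modified in
        place.
        """
        n = x.size
        disp = rng.uniform(-step, step, size=n)
        logu = np.log(rng.random(n))
        acc = 0
        for i in range(n):
            old = x[i]
            new = old + disp[i]
            if self.period is not None:
                new = (new + 0.5 * self.period) % self.period - 0.5 * self.period
            elif self.bounds is not None and not (self.bounds[0] <= new <= self.bounds[1]):
                continue
            x[i] = new
            e_new = self.energy(x)
            if logu[i] < -beta * (e_new - energy):
                energy = e_new
                acc += 1
            else:
                x[i] = old
        return x, energy, acc, n


class DoubleWell1D(Potential):
    """V(x) = barrier * (x^2 - 1)^2 + asymmetry * x / 2 on x in [-2.5, 2.5] nm.

    Minima sit near x = -1 and x = +1 for small asymmetry; the barrier
    parameter is the symmetric barrier height at x = 0 in kcal/mol.
    """

    dimension = 1
    bounds = (-2.5, 2.5)

    def __init__(self, barrier: float, asymmetry: float = 0.0):
        if barrier <= 0:
            raise ValueError(f"barrier must be positive, got {barrier}")
        self.barrier = float(barrier)
        self.asymmetry = float(asymmetry)

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float)
        v = self.barrier * (x * x - 1.0) ** 2 + 0.5 * self.asymmetry * x
        out = float(np.sum(v)) if v.ndim else float(v)
        if not np.isfinite(out):
            raise FloatingPointError(f"non-finite double-well energy at x={x!r}")
        return out

    def energy_grid(self, x: np.ndarray) -> np.ndarray:
        """Vectorised V(x) on an array of positions (for quadrature)."""
        x = np.asarray(x, dtype=float)
        return self.barrier * (x * x - 1.0) ** 2 + 0.5 * self.asymmetry * x

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return 4.0 * self.barrier * x * (x * x - 1.0) + 0.5 * self.asymmetry

    def initial_coordinates(self):
        return np.array([-1.0])


class HarmonicND(Potential):
    """V(x) = sum_i 0.5 * k_i * x_i^2; coordinate variance at T is k_B*T/k_i."""

    def __init__(self, k, ndim: int | None = None):
        k = np.atleast_1d(np.asarray(k, dtype=float))
        if ndim is not None and k.size == 1:
            k = np.full(ndim, k[0])
        if np.any(k <= 0):
            raise ValueError("spring constants must be positive")
        self.k = k
        self.dimension = k.size

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float)
        return float(0.5 * np.sum(self.k * x * x))

    def gradient(self, x):
        return self.k * np.asarray(x, dtype=float)


class DihedralChain(Potential):
    """Periodic chain of dihedral-like angles with two minima per angle.

    Each coordinate is an angle in degrees with
    ``V_i = a * (1 - cos(2 * theta_i)) / 2 + b * (1 - cos(theta_i)) / 2``:
    minima at 0 and 180 deg, the ``b`` term biasing the 0-deg conformer.
    Conformers (sign patterns of cos theta) separate cleanly in dPCA space.
    """

    period = 360.0

    def __init__(self, n_angles: int, barrier: float = 3.0, bias: float = 0.5):
        if n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        self.dimension = int(n_angles)
        self.barrier = float(barrier)
        self.bias = float(bias)

    def energy(self, x) -> float:
        th = np.deg2rad(np.asarray(x, dtype=float))
        v = 0.5 * self.barrier * (1.0 - np.cos(2.0 * th)) + 0.5 * self.bias * (
            1.0 - np.cos(th)
        )
        return float(np.sum(v))

    def gradient(self, x):
        th = np.deg2rad(np.asarray(x, dtype=float))
        dv = self.barrier * np.sin(2.0 * th) + 0.5 * self.bias * np.sin(th)
        return dv * np.pi / 180.0


def make_double_well(barrier: float, asymmetry: float = 0.0) -> PotentialSpec:
    """Double-well spec; ``barrier`` > 0 kcal/mol, signed ``asymmetry`` tilt."""
    if barrier <= 0:
        raise ValueError(f"barrier must be positive, got {barrier}")
    return PotentialSpec("double_well_1d", {"barrier": barrier, "asymmetry": asymmetry})


def make_harmonic(k, ndim: int | None = None) -> PotentialSpec:
    params = {"k": k if np.ndim(k) else float(k)}
    if ndim is not None:
        params["ndim"] = int(ndim)
    return PotentialSpec("harmonic_nd", params)


def make_dihedral_chain(n_angles: int, barrier: float = 3.0, bias: float = 0.5) -> PotentialSpec:
    return PotentialSpec(
        "dihedral_chain", {"n_angles": n_angles, "barrier": barrier, "bias": bias}
    )


def double_well_populations(spec_or_potential, temperature: float, n_grid: int = 10_000):
    """Quadrature Boltzmann populations of the two wells of a 1D double well.

    Trapezoid quadrature of exp(-V/kT) over each half-domain (the barrier top
    at x=0 splits the wells).  Returns ``(p_left, p_right)``.  This is the
    oracle for every downstream sampler test.
    """
    pot = spec_or_potential.build() if isinstance(spec_or_potential, PotentialSpec) else spec_or_potential
    lo, hi = pot.bounds
    beta = 1.0 / (KB * temperature)
    xs = np.linspace(lo, hi, n_grid)
    w = np.exp(-beta * pot.energy_grid(xs))
    left = np.trapezoid(np.where(xs <= 0, w, 0.0), xs)
    right = np.trapezoid(np.where(xs > 0, w, 0.0), xs)
    z = left + right
    return left / z, right / z


# ---------------------------------------------------------------------------
# patchy dimer


@dataclass
class DimerSystem:
    """Coarse-grained two-chain dimer with explicit solvent bath.

    ``positions`` is the (n, 3) coordinate array ordered chain A, chain B,
    solvent; ``types`` the per-particle type labels.  ``interaction_matrix``
    maps unordered type pairs to ``(depth kcal/mol, radius nm)`` for the
    softened truncated-shifted LJ well.  Periodic cubic box of side
    ``box_length`` with minimum-image distances.
    """

    positions: np.ndarray
    types: list[str]
    chain_a: np.ndarray  # particle indices
    chain_b: np.ndarray
    solvent: np.ndarray
    interface_beads: np.ndarray  # indices within a chain (same for A and B)
    interaction_matrix: dict[tuple[str, str], tuple[float, float]]
    box_length: float
    bond_length: float = 0.4
    bond_k: float = 100.0  # kcal/mol/nm^2

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        for key, (depth, radius) in list(self.interaction_matrix.items()):
            if tuple(sorted(key)) != tuple(key):
                raise ValueError(f"interaction matrix keys must be sorted pairs: {key}")
            if radius <= 0:
                raise ValueError(f"non-positive interaction radius for {key}")
        if set(self.chain_a) & set(self.chain_b):
            raise ValueError("chains must be index-disjoint")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def solute(self) -> np.ndarray:
        return np.concatenate([self.chain_a, self.chain_b])

    def pair_parameters(self, type_i: str, type_j: str) -> tuple[float, float]:
        key = tuple(sorted((type_i, type_j)))
        try:
            return self.interaction_matrix[key]
        except KeyError:
            raise KeyError(f"no interaction parameters for type pair {key}") from None

    def copy(self) -> "DimerSystem":
        new = copy.copy(self)
        new.positions = self.positions.copy()
        new.types = list(self.types)
        new.interaction_matrix = dict(self.interaction_matrix)
        return new


def _pair_tables(system: DimerSystem):
    """Per-particle (depth, radius) lookup tables as dense arrays."""
    labels = sorted(set(system.types))
    index = {t: i for i, t in enumerate(labels)}
    nt = len(labels)
    depth = np.zeros((nt, nt))
    radius = np.ones((nt, nt))
    for i, ti in enumerate(labels):
        for j, tj in enumerate(labels):
            d, r = system.pair_parameters(ti, tj)
            depth[i, j] = d
            radius[i, j] = r
    tcode = np.array([index[t] for t in system.types])
    return depth, radius, tcode


def _pair_well_sq(r2, depth, r02, shift=None):
    """Pair well evaluated on squared distances (see :func:`pair_well`)."""
    a2 = 0.36 * r02
    s2 = (r02 + a2) / (r2 + a2)
    s6 = s2 * s2 * s2
    u = np.abs(depth) * s6 * s6 - 2.0 * depth * s6
    if shift is None:
        sc2 = (r02 + a2) / (4.0 * r02 + a2)
        sc6 = sc2 * sc2 * sc2
        shift = np.abs(depth) * sc6 * sc6 - 2.0 * depth * sc6
    return np.where(r2 < 4.0 * r02, u - shift, 0.0)


def pair_well(r, depth, r0):
    """Softened truncated-shifted LJ-style well.

    ``u(r) = |eps| s^12 - 2 eps s^6 - u_c`` with
    ``s = sqrt(r0^2 + a^2) / sqrt(r^2 + a^2)``, ``a = 0.6 r0``, cutoff
    ``rc = 2 r0``.  Finite everywhere (bounded at contact); for ``depth > 0``
    a well of depth ~ ``depth`` at ``r = r0``; for ``depth < 0`` purely
    repulsive; identically zero beyond the cutoff and for ``depth == 0``.
    """
    r = np.asarray(r, dtype=float)
    depth = np.asarray(depth, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    return _pair_well_sq(r * r, depth, r0 * r0)


class DimerPotential(Potential):
    """Full potential of a :class:`DimerSystem` on flat coordinates.

    Energy terms: harmonic bonds along each chain, softened LJ-style
    nonbonded wells over all pairs (intra-chain pairs separated by fewer
    than three bonds excluded), plus any restraint terms.  Nonbonded
    distances use the minimum-image convention unless disabled.
    """

    def __init__(self, system: DimerSystem, restraints=(), use_minimum_image: bool = True):
        self.system = system
        self.restraints = list(restraints)
        self.use_minimum_image = use_minimum_image
        self.dimension = system.n_particles * 3
        self._depth, self._radius, self._tcode = _pair_tables(system)
        self._bonds = self._build_bonds()
        self._excluded = self._build_exclusions()
        self._restraints_by_particle = self._index_restraints()
        # dense per-pair parameter matrices and per-particle bond partners
        tc = self._tcode
        self._depth_mat = self._depth[tc[:, None], tc[None, :]]
        self._r02_mat = self._radius[tc[:, None], tc[None, :]] ** 2
        a2 = 0.36 * self._r02_mat
        sc6 = ((self._r02_mat + a2) / (4.0 * self._r02_mat + a2)) ** 3
        self._shift_mat = np.abs(self._depth_mat) * sc6 * sc6 - 2.0 * self._depth_mat * sc6
        n = system.n_particles
        self._bond_partners = [
            np.array([b if a == i else a for a, b in self._bonds if a == i or b == i], dtype=int)
            for i in range(n)
        ]
        self._chain_moves = []
        for chain in (system.chain_a, system.chain_b):
            others = np.setdiff1d(np.arange(n), chain)
            self._chain_moves.append(
                (chain, others, np.ix_(chain, others))
            )
        self._build_kernel_tables()

    def _build_kernel_tables(self):
        """Padded per-particle arrays consumed by the compiled sweep kernel."""
        n = self.system.n_particles
        maxb = max((p.size for p in self._bond_partners), default=0)
        self._k_bondp = np.zeros((n, max(maxb, 1)), dtype=np.int64)
        self._k_bondn = np.zeros(n, dtype=np.int64)
        for i, partners in enumerate(self._bond_partners):
            self._k_bondn[i] = partners.size
            self._k_bondp[i, : partners.size] = partners
        quads, theta0, kdih, pairs, d0, flat, kdist = self._packed_restraints
        self._k_quads = np.ascontiguousarray(quads, dtype=np.int64).reshape(-1, 4)
        self._k_theta0 = np.asarray(theta0, dtype=float)
        self._k_kdih = np.asarray(kdih, dtype=float)
        self._k_pairs = np.ascontiguousarray(pairs, dtype=np.int64).reshape(-1, 2)
        self._k_d0 = np.asarray(d0, dtype=float)
        self._k_flat = np.asarray(flat, dtype=float)
        self._k_kdist = np.asarray(kdist, dtype=float)
        pq = [[] for _ in range(n)]
        for q, quad in enumerate(self._k_quads):
            for idx in quad:
                pq[int(idx)].append(q)
        pp = [[] for _ in range(n)]
        for p, pair in enumerate(self._k_pairs):
            for idx in pair:
                pp[int(idx)].append(p)
        maxq = max((len(v) for v in pq), default=0)
        maxp = max((len(v) for v in pp), default=0)
        self._k_pquads = np.zeros((n, max(maxq, 1)), dtype=np.int64)
        self._k_pquadn = np.zeros(n, dtype=np.int64)
        for i, v in enumerate(pq):
            self._k_pquadn[i] = len(v)
            self._k_pquads[i, : len(v)] = v
        self._k_ppairs = np.zeros((n, max(maxp, 1)), dtype=np.int64)
        self._k_ppairn = np.zeros(n, dtype=np.int64)
        for i, v in enumerate(pp):
            self._k_ppairn[i] = len(v)
            self._k_ppairs[i, : len(v)] = v

    def _build_bonds(self):
        bonds = []
        for chain in (self.system.chain_a, self.system.chain_b):
            bonds.extend(zip(chain[:-1], chain[1:]))
        return np.array(bonds, dtype=int).reshape(-1, 2)

    def _build_exclusions(self):
        """Mask of intra-chain pairs within two bonds (1-2 and 1-3)."""
        n = self.system.n_particles
        excl = np.zeros((n, n), dtype=bool)
        for chain in (self.system.chain_a, self.system.chain_b):
            for off in (1, 2):
                for a, b in zip(chain[:-off], chain[off:]):
                    excl[a, b] = excl[b, a] = True
        np.fill_diagonal(excl, True)
        return excl

    def _index_restraints(self):
        from .restraints import pack_restraints

        self._packed_restraints = pack_restraints(self.restraints)
        by_particle: dict[int, tuple] = {}
        touched: dict[int, list] = {}
        for res in self.restraints:
            for idx in res.atoms:
                touched.setdefault(int(idx), []).append(res)
        for idx, res_list in touched.items():
            by_particle[idx] = pack_restraints(res_list)
        return by_particle

    # -- geometry helpers ---------------------------------------------------

    def _mi(self, dvec):
        if self.use_minimum_image:
            box = self.system.box_length
            dvec = dvec - box * np.round(dvec / box)
        return dvec

    def distances_from(self, coords, i):
        d = self._mi(coords - coords[i])
        return np.sqrt(np.einsum("ij,ij->i", d, d))

    # -- energy terms -------------------------------------------------------

    def bond_energy(self, coords) -> float:
        if len(self._bonds) == 0:
            return 0.0
        d = coords[self._bonds[:, 0]] - coords[self._bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        return float(self.system.bond_k * np.sum((r - self.system.bond_length) ** 2))

    def nonbonded_matrix(self, coords):
        """Full symmetric matrix of pair well energies (excluded pairs zero)."""
        d = coords[:, None, :] - coords[None, :, :]
        d = self._mi(d)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        np.fill_diagonal(r2, 1.0)
        u = _pair_well_sq(r2, self._depth_mat, self._r02_mat, self._shift_mat)
        u[self._excluded] = 0.0
        return u

    def nonbonded_energy(self, coords) -> float:
        return float(0.5 * np.sum(self.nonbonded_matrix(coords)))

    def pair_energy_between(self, coords, idx_a, idx_b) -> float:
        """Sum of nonbonded pair energies between two disjoint index sets."""
        u = self.nonbonded_matrix(coords)
        return float(np.sum(u[np.ix_(idx_a, idx_b)]))

    def group_internal_energy(self, coords, idx) -> float:
        """Nonbonded energy among a group plus bond terms wholly inside it."""
        u = self.nonbonded_matrix(coords)
        e = 0.5 * float(np.sum(u[np.ix_(idx, idx)]))
        idx_set = set(int(i) for i in idx)
        for a, b in self._bonds:
            if int(a) in idx_set and int(b) in idx_set:
                d = coords[a] - coords[b]
                r = float(np.linalg.norm(d))
                e += self.system.bond_k * (r - self.system.bond_length) ** 2
        return e

    def restraint_energy(self, coords) -> float:
        from .restraints import packed_restraint_energy

        return packed_restraint_energy(coords, self._packed_restraints)

    def energy(self, x) -> float:
        coords = np.asarray(x, dtype=float).reshape(-1, 3)
        e = self.bond_energy(coords) + self.nonbonded_energy(coords) + self.restraint_energy(coords)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite dimer energy")
        return e

    def initial_coordinates(self):
        return self.system.positions.ravel().copy()

    # -- efficient MC -------------------------------------------------------

    def _particle_energy(self, coords, i):
        d = self._mi(coords - coords[i])
        r2 = np.einsum("ij,ij->i", d, d)
        r2[i] = 1.0
        u = _pair_well_sq(r2, self._depth_mat[i], self._r02_mat[i], self._shift_mat[i])
        u[self._excluded[i]] = 0.0
        e = float(u.sum())
        nb = self._bond_partners[i]
        if nb.size:
            rb = np.sqrt(np.einsum("ij,ij->i", coords[nb] - coords[i], coords[nb] - coords[i]))
            e += self.system.bond_k * float(np.sum((rb - self.system.bond_length) ** 2))
        if i in self._restraints_by_particle:
            from .restraints import packed_restraint_energy

            e += packed_restraint_energy(coords, self._restraints_by_particle[i])
        return e

    def mc_sweep(self, x, energy, beta, step, rng):
        from ._kernels import particle_sweep

        coords = x.reshape(-1, 3)
        n = self.system.n_particles
        disp = rng.uniform(-step, step, size=(n, 3))
        logu = np.log(rng.random(n))
        de, acc = particle_sweep(
            coords, self.system.box_length, self.use_minimum_image,
            self._depth_mat, self._r02_mat, self._shift_mat, self._excluded,
            self._k_bondp, self._k_bondn, self.system.bond_k, self.system.bond_length,
            self._k_quads, self._k_theta0, self._k_kdih, self._k_pquads, self._k_pquadn,
            self._k_pairs, self._k_d0, self._k_flat, self._k_kdist,
            self._k_ppairs, self._k_ppairn,
            beta, disp, logu,
        )
        energy += de
        # rigid-body chain moves: translation and rotation per chain
        trials = n
        for chain, others, ix in self._chain_moves:
            for mode in ("translate", "rotate"):
                e_old = self._chain_cross_energy(coords, chain, others, ix)
                old = coords[chain].copy()
                if mode == "translate":
                    coords[chain] = old + rng.uniform(-2 * step, 2 * step, size=3)
                else:
                    coords[chain] = _random_rotation_about_centroid(old, step, rng)
                e_new = self._chain_cross_energy(coords, chain, others, ix)
                trials += 1
                if np.log(rng.random()) < -beta * (e_new - e_old):
                    energy += e_new - e_old
                    acc += 1
                else:
                    coords[chain] = old
        return x, energy, acc, trials

    def _chain_cross_energy(self, coords, chain, others, ix=None):
        """Energy between a chain and everything else.

        Intra-chain bonded, nonbonded and restraint terms are invariant
        under rigid chain moves (the box is sized so intra-chain pairs never
        wrap), so only cross terms are needed.
        """
        if ix is None:
            ix = np.ix_(chain, others)
        d = coords[chain][:, None, :] - coords[others][None, :, :]
        d = self._mi(d)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        u = _pair_well_sq(r2, self._depth_mat[ix], self._r02_mat[ix], self._shift_mat[ix])
        return float(np.sum(u))


def _random_rotation_about_centroid(points, step, rng):
    """Small random rotation of a point set about its centroid."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-2.0, 2.0) * step  # radians scaled by MC step
    c, s = np.cos(angle), np.sin(angle)
    ax, ay, az = axis
    rot = np.array(
        [
            [c + ax * ax * (1 - c), ax * ay * (1 - c) - az * s, ax * az * (1 - c) + ay * s],
            [ay * ax * (1 - c) + az * s, c + ay * ay * (1 - c), ay * az * (1 - c) - ax * s],
            [az * ax * (1 - c) - ay * s, az * ay * (1 - c) + ax * s, c + az * az * (1 - c)],
        ]
    )
    centroid = points.mean(axis=0)
    return (points - centroid) @ rot.T + centroid


# default patchy-dimer interaction table: chain core C, interface I, solvent S
_DEFAULT_MATRIX = {
    ("C", "C"): (0.10, 0.45),
    ("C", "I"): (0.10, 0.45),
    ("I", "I"): (2.00, 0.50),
    ("C", "S"): (0.30, 0.35),
    ("I", "S"): (0.30, 0.35),
    ("S", "S"): (0.20, 0.30),
}

_CHAIN_LENGTH = 10
_INTERFACE = (4, 5, 6)


def make_dimer_fixture(seed: int, n_solvent: int, box_length: float = 8.0) -> DimerSystem:
    """Deterministic two-chain patchy dimer with ``n_solvent`` bath particles.

    Two identical 10-bead chains lie parallel along x, interface beads
    (within-chain indices 4, 5, 6) facing each other across the I-I well
    radius, so the as-built pose is the designed bound state.  Solvent is
    placed uniformly in the periodic box, rejecting hard overlaps.
    """
    if n_solvent < 0:
        raise ValueError("n_solvent must be >= 0")
    rng = np.random.default_rng(seed)
    bond = 0.4
    r0_ii = _DEFAULT_MATRIX[("I", "I")][1]
    center = box_length / 2.0
    # slight zig-zag in z so chain dihedrals are well defined (non-collinear)
    zig = 0.06 * np.where(np.arange(_CHAIN_LENGTH) % 2 == 0, 1.0, -1.0)
    spacing = np.sqrt(bond**2 - (2 * 0.06) ** 2)
    xs = (np.arange(_CHAIN_LENGTH) - (_CHAIN_LENGTH - 1) / 2.0) * spacing
    chain_a_pos = np.column_stack(
        [center + xs, np.full(_CHAIN_LENGTH, center - r0_ii / 2), center + zig]
    )
    chain_b_pos = np.column_stack(
        [center + xs, np.full(_CHAIN_LENGTH, center + r0_ii / 2), center + zig]
    )
    types = []
    for _ in range(2):
        types.extend("I" if i in _INTERFACE else "C" for i in range(_CHAIN_LENGTH))
    positions = [chain_a_pos, chain_b_pos]
    solvent_pos = []
    placed = np.vstack(positions)
    min_sep = 0.25
    while len(solvent_pos) < n_solvent:
        cand = rng.uniform(0.0, box_length, size=3)
        d = placed - cand
        d -= box_length * np.round(d / box_length)
        if np.min(np.linalg.norm(d, axis=1)) > min_sep:
            solvent_pos.append(cand)
            placed = np.vstack([placed, cand])
    if solvent_pos:
        positions.append(np.array(solvent_pos))
        types.extend(["S"] * n_solvent)
    all_pos = np.vstack(positions)
    n_chain = _CHAIN_LENGTH
    return DimerSystem(
        positions=all_pos,
        types=types,
        chain_a=np.arange(n_chain),
        chain_b=np.arange(n_chain, 2 * n_chain),
        solvent=np.arange(2 * n_chain, 2 * n_chain + n_solvent),
        interface_beads=np.array(_INTERFACE),
        interaction_matrix=dict(_DEFAULT_MATRIX),
        box_length=box_length,
    )


@dataclass(frozen=True)
class MutationEdit:
    """Retype one bead (per homodimer-symmetric position) of the dimer.

    ``bead_index`` is a global particle index in either chain; the edit is
    applied to the same within-chain position of both chains.  ``matrix_row``
    supplies ``(depth, radius)`` against every existing type (and the new
    type itself).
    """

    bead_index: int
    new_type: str
    matrix_row: dict[str, tuple[float, float]] = field(default_factory=dict)


def apply_mutation(system: DimerSystem, edit: MutationEdit) -> DimerSystem:
    """Return a new system with the edit applied symmetrically to both chains."""
    in_a = edit.bead_index in set(int(i) for i in system.chain_a)
    in_b = edit.bead_index in set(int(i) for i in system.chain_b)
    if not (in_a or in_b):
        raise IndexError(f"bead index {edit.bead_index} is not in either chain")
    chain = system.chain_a if in_a else system.chain_b
    pos_in_chain = int(np.where(chain == edit.bead_index)[0][0])
    new = system.copy()
    for ch in (new.chain_a, new.chain_b):
        new.types[int(ch[pos_in_chain])] = edit.new_type
    existing = sorted(set(new.types) | set(edit.matrix_row))
    for other in existing:
        key = tuple(sorted((edit.new_type, other)))
        if other in edit.matrix_row:
            new.interaction_matrix[key] = tuple(edit.matrix_row[other])
        elif key not in new.interaction_matrix:
            raise KeyError(f"mutation row missing parameters against type {other!r}")
    return new


def alanine_like_edit(system: DimerSystem, bead_index: int) -> MutationEdit:
    """Interface-deletion edit: all wells of this bead set to zero depth."""
    old_type = system.types[bead_index]
    row = {
        other: (0.0, system.pair_parameters(old_type, other)[1])
        for other in sorted(set(system.types))
    }
    row["A"] = (0.0, 0.4)
    return MutationEdit(bead_index=bead_index, new_type="A", matrix_row=row)


def aspartate_like_edit(system: DimerSystem, bead_index: int) -> MutationEdit:
    """Sign-flipped cross-term edit: the bead's wells become repulsive bumps."""
    row = {}
    for other in sorted(set(system.types)):
        depth, radius = system.pair_parameters(system.types[bead_index], other)
        row[other] = (-depth, radius)
    old_self = system.pair_parameters(system.types[bead_index], system.types[bead_index])
    row["D"] = (-old_self[0], old_self[1])
    return MutationEdit(bead_index=bead_index, new_type="D", matrix_row=row)
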