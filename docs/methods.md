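# Methods

## Sampling schemes

Four protocols share one geometric temperature ladder
`T_i = T_min (T_max/T_min)^(i/(M−1))` and one cycle structure
(sample → [quench] → exchange):

* **tremd** — standard parallel tempering. Each cycle every replica samples at
  its rung temperature; alternating-parity neighbour pairs `(i, i+1)` then
  swap rungs with probability `min(1, exp((β_i − β_{i+1})(E_i − E_{i+1})))`.
  The baseline ensemble collects the rung-0 state each cycle. This criterion
  satisfies detailed balance on the product ensemble, so the baseline marginal
  is exactly Boltzmann at `T_min`.
* **tiger2** — after sampling, every replica is quenched (propagated at the
  baseline temperature). Exchanges are attempted between the current baseline
  replica and the other replicas in ascending ladder order with
  `min(1, exp(−(E_cand − E_base)/k_B T_base))`; an accepted candidate becomes
  the new baseline comparator and the displaced baseline state is appended to
  the baseline ensemble (multi-acceptance), as is the cycle's final baseline
  state. Afterwards the non-baseline replicas are reassigned to rungs 1..M−1
  by ascending exchange energy (lowest energy → lowest temperature). Ties
  (ΔE = 0) accept with probability 1.
* **tiger2h** — identical scheduling; the exchange decision uses the reduced
  implicit-solvent energy: solute internal terms (bonds, pair wells,
  restraints) plus a mean-field bulk term. Propagation always runs on the full
  potential; the reduced energy is used *only* for exchange decisions.
* **tiger2hs** — the exchange energy is the hybrid solute+shell energy: all
  explicit pair terms among the solute and the N solvent particles nearest any
  solute atom, plus `c · (n_solvent − N)` for the excluded bulk. With N = all
  solvent and c = 0 this equals the full potential exactly, so tiger2hs
  reproduces tiger2's decision stream bit for bit at equal seeds (a tested
  reduction property).

### Accuracy of the TIGER2 exchange rule

The baseline-temperature Metropolis rule applied to *quenched* energies is an
approximation, and the package quantifies it rather than hiding it. After a
quench both the baseline's and the candidate's energies are distributed at
`T_base` given their conformational basin; applying `exp(−ΔE/k_B T_base)` on
top of that double-counts the Boltzmann weight and tilts the baseline ensemble
toward low-energy basins. On the tilted double well (barrier 2, asymmetry
0.8 kcal/mol, 8 rungs 280–600 K) the effect is fully exposed: the left-well
population comes out ≈ 0.89 against the quadrature value 0.790, stable across
seeds, quench lengths (2–60 sweeps) and reassignment variants, while T-REMD on
the same framework reproduces 0.790 and TIGER2 on the *symmetric* well gives
0.5 as required. In solvated all-atom systems the exchange energy carries
fluctuations from thousands of solvent degrees of freedom that are much larger
than conformational energy gaps, which randomises the acceptance and damps
this bias — one reason shell size matters for hybrid schemes and why the
fixed-N shell exists at all. The acceptance test asserting exact Boltzmann
statistics for tiger2 on the tilted well therefore fails by design of the
scheme itself; correctness claims that genuinely hold (T-REMD exactness,
symmetric-well tiger2, the reduction property) are asserted in the unit suite.

## Propagators

Metropolis Monte Carlo is the default within-replica propagator: one sweep is
one single-coordinate (or single-particle) trial per degree of freedom, with
uniform displacements. The quench is then simply MC at the baseline
temperature. Step sizes are tuned per rung during burn-in to a 30–50%
acceptance window and frozen before production, and are capped at half the box
for particle systems. BAOAB Langevin dynamics (unit mass, friction 5 ps⁻¹) is
available for potentials with analytic gradients; at quench onset velocities
are resampled from the Maxwell–Boltzmann distribution at the target
temperature by default (`rescale` is selectable, since the genuine MD
implementations do not document the choice).

Every replica owns an rng stream spawned from the master seed
(`numpy` SeedSequence), with separate streams for tuning and exchange draws,
so a run is bit-reproducible from one integer and tiger2/tiger2hs consume
identical draw sequences (required for the reduction property).

The dimer's sequential-sweep inner loop (pair wells, bonds, dihedral and
distance restraints) is compiled with numba; whole-chain rigid translation and
rotation moves are part of the MC move set so the docking pose can diffuse at
a realistic rate. Intra-chain terms are invariant under rigid chain moves (the
box is sized so intra-chain pairs never wrap), so chain moves only re-evaluate
cross terms.

## Toy systems

* `double_well_1d`: `V(x) = barrier·(x²−1)² + asymmetry·x/2` on
  x ∈ [−2.5, 2.5] nm. Trapezoid quadrature of `exp(−V/kT)` over each
  half-domain is the population oracle for every sampler test.
* `harmonic_nd`: `V = Σ ½k_i x_i²`; coordinate variance `k_B T/k` and
  equipartition `⟨V⟩ = d/2 k_B T` are the closed-form checks.
* `dihedral_chain`: periodic angles with
  `V_i = ½·barrier·(1−cos 2θ_i) + ½·bias·(1−cos θ_i)` — two minima per angle
  whose conformers separate cleanly in dPCA space.
* `patchy_dimer`: two identical 10-bead chains (bond length 0.4 nm, harmonic
  bonds k = 100 kcal mol⁻¹ nm⁻²), three contiguous interface beads per chain
  (type I), optional soft-sphere solvent (type S) in a periodic 8 nm box with
  minimum-image distances. Non-bonded pairs interact through a softened
  truncated-shifted Lennard-Jones-style well
  `u(r) = |ε|s¹² − 2εs⁶ − u_c`, `s² = (r₀²+a²)/(r²+a²)`, `a = 0.6 r₀`,
  cutoff `2r₀` — finite at contact (bounded everywhere), minimum ≈ −ε at r₀
  for ε > 0, and purely repulsive for ε < 0 so a sign-flipped ("charge-like")
  mutation produces a bump rather than an unphysical hole at r = 0. Defaults:
  I–I (2.0 kcal/mol, 0.5 nm), C–C and C–I (0.1, 0.45), solvent–solute
  (0.3, 0.35), solvent–solvent (0.2, 0.30). The as-built pose aligns the
  interface beads across the I–I well radius, so the designed ground state is
  the bound dimer; a grid scan over rigid-body separations verifies that any
  pose with the chains more than two interaction radii apart is strictly
  higher in energy. Chains carry a small z zig-zag so all backbone dihedrals
  are well defined.

Mutations are per-bead type edits applied symmetrically to both chains of the
homodimer, with a replacement row of interaction parameters; the
interface-deletion ("alanine-like") edit zeroes every well depth of the bead,
the sign-flip ("aspartate-like") edit negates them.

What the generator does *not* emulate: real force fields, water structure,
electrostatics, zinc coordination, or sequence detail. Passing tests
demonstrate the correctness of the algorithms and the analysis pipeline on
systems with known answers — not the thermodynamics of any real protein.

## Hydration shell and hybrid energy

Shell size determination follows the radial-distribution procedure: for each
frame, each solvent particle's distance to its *nearest solute atom* (never
the centre of mass) is histogrammed in 0.005 nm bins; `N(r)` is the
across-frame mean cumulative count up to the bin containing `r`, rounded
half-to-even. The histogram count can differ from the exact cumulative count
by at most the content of the bin containing `r` (≤ 1 on the fixtures, a
tested property). N is determined once from a pre-run and held fixed: a shell
whose size varies between states biases exchange energies toward states that
bind more solvent. Shell membership itself is recomputed per evaluation as
the N nearest solvent particles (stable-sort index tie-break).

The implicit bulk term is deliberately minimal — a constant per excluded
particle, with `calibrate_implicit_constant` estimating the mean per-particle
interaction of excluded solvent from a fixture trajectory. It exercises the
algorithmic role of an implicit remainder without modelling continuum
electrostatics. A droplet convention (`use_minimum_image=False`) evaluates
hybrid energies without periodic wrapping.

## Restraints

Dihedral restraints use `E = k·Δ²` with Δ in degrees wrapped to (−180°, 180°]
(no ½ factor — the convention implied by force constants quoted in
kcal mol⁻¹ deg⁻²; `half_factor=True` selects the other convention). The
rigid-body set restrains every internal chain dihedral at its current value
with k = 25 kcal mol⁻¹ deg⁻², omitting the first and last two dihedrals per
chain by default, which keeps chains internally rigid while leaving rigid-body
motion free (tested: restrained internal RMSD < 50% of unrestrained at equal
seeds; in practice far lower). Hydrogen-bond-like restraints are flat-bottom
distance harmonics (default flat bottom 0.05 nm, distance-only — donor/
acceptor geometry is not modelled).

## Conformational analysis

dPCA maps each angle to (cos θ, sin θ) with no further normalisation.
Inter-chain distance features take all |A|·|B| pairwise distances and z-score
each feature by the *fitting* ensemble's mean and standard deviation
(zero-variance features are kept, scaled by 1, and flagged); z-scoring is the
default reading of "normalized", with min-max available by normalising
externally. PCA is a mean-centred covariance eigendecomposition
(scikit-learn, full SVD) with each component's sign fixed so its
largest-magnitude loading is positive; an independent `numpy.linalg.eigh`
oracle checks eigenvalues and subspaces in the tests.

Landscapes histogram the first two score columns (30×30 bins by default) and
apply Boltzmann inversion `ΔG = −kT ln(p/p_max)` referenced to the modal bin;
empty bins are masked, never pseudo-counted; kT defaults to 280 K (the
baseline temperature of both sampling protocols). Cross-ensemble comparison
("principal-axis injection") projects a second ensemble using the reference
ensemble's feature normalisation, mean and components, and bins it on the
reference bin edges; occupancy of the reference minimum is reported relative
to *all* frames of the construct so probability mass leaving the reference
score range counts against it. `barrier_height` is the minimax path barrier
over 8-connected unmasked bins (union-find over bins sorted by ΔG), with
`barrier(A→B) − barrier(B→A) = ΔG(B) − ΔG(A)` as a tested identity and a
threshold-connectivity BFS plus exhaustive small-grid DFS as independent
oracles. Disconnected basins raise rather than returning a number.

## Desk-scale problem sizes

Chosen once as the package's study conditions: Boltzmann-correctness runs use
the 8-rung 280–600 K ladder with 25-sweep sampling and 25-sweep quench for
2000–3000 cycles (the quench is lengthened relative to the 2:1 MD ratio so an
MC quench genuinely relaxes at the baseline temperature); the ergodicity
comparison uses barrier 6 kcal/mol, 400 cycles, against single-temperature MC
at an identical total energy-evaluation budget; the docking panel runs TIGER2h
on the vacuum dimer with 6 rungs 280–450 K, 15-sweep sampling/8-sweep quench,
400 cycles per construct; the reduction check uses the 200-solvent fixture for
20 cycles. The "+1 hybrid-energy replica" accounting of the literature
protocols is modelled as a config flag (`hybrid_energy_replica`) that reserves
one replica as an energy service rather than a sampling rung.

## Numerical choices and edge cases

Energies are refreshed from the potential after every propagation call (the
sweep kernels track deltas only). Exchange draws are always consumed, so
decision streams align across protocols. ΔG reference is the modal bin (the
global minimum is 0 by construction). A fully-out-of-range projected ensemble
yields an all-masked landscape (occupancy 0) instead of an error. PDB output
is standard 3-decimal Angstrom fields (1 nm = 10 Å) with coordinates wrapped
into the box; XYZ keeps 6 decimals in nm. Truncated or inconsistent
trajectory files raise errors naming the offending line rather than reading
short.

## Known limitations

The TIGER2-family exactness caveat above is the main one. The implicit bulk
term is a constant per particle, not a solvation model. H-bond restraints are
distance-only. The dimer analysis uses topology chain labels (no automatic
A↔B symmetrisation — the `symmetrize` flag in feature construction, off by
default, since homodimer relabelling symmetry is not assumed). The MC
"time" axis is sweeps, not physical time; reported per-replica and aggregate
step totals in `run_meta.json` cover both accountings of total sampling
effort.
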