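# Methods

This note documents the models, conventions, numerical choices and known
limitations of `halomd`. Everything quantitative claimed here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Scope and design stance

`halomd` re-creates, inside one Python process, the pipeline a
distributed MD engine uses to evaluate semilocal (message-passing)
potentials: spatial decomposition with ghost-atom halos, per-domain
neighbor graphs, pruning to the T-hop receptive field, partial-force
assembly with a global reduction, and fixed-shape buffering with a
collective resize protocol. The "processors" are a loop index — domains
are evaluated strictly sequentially and each evaluation sees only its own
`DomainView`, so the no-mid-step-communication contract is enforced by
construction rather than by an actual message-passing runtime. What the
package can therefore demonstrate is *algorithmic* correctness of every
contract (exactness of the halo rule, pruning, reduction, buffering);
what it cannot demonstrate is anything about wall-clock scaling, device
memory, or compiler behaviour — those are represented only by the
analytic cost model and by observable event counters.

## Units and geometry

Internal units are Å, eV, fs, amu (so 1 eV/Å on 1 amu gives
9.648533e-3 Å/fs²; k_B = 8.617333e-5 eV/K). `UnitsSpec` converts only at
I/O boundaries (model archives). Boxes are orthorhombic with half-open
`[0, L)` extents along periodic dimensions; an atom exactly on an
internal domain boundary belongs to the higher domain (half-open
convention), so the partition property is exact. Non-periodic dimensions
(the slab's z) are geometrically unbounded; the stored box length is a
bounding extent used only for domain splitting. Triclinic cells and
variable-cell dynamics are out of scope.

Two neighbor-search paths exist deliberately:

* the **global path** uses the minimum-image convention and requires
  `L ≥ 2(cutoff + skin)` per periodic dimension (rejected otherwise,
  naming the dimension);
* the **domain path** materialises periodic images explicitly as ghosts
  and builds its graphs without periodicity.

Both are backed by a scipy k-d tree; the O(N²) enumeration used in tests
is an independent oracle, not the implementation.

## Decomposition and halos

`R_comm = T·(cutoff + skin)`, *including* the skin: per-domain graphs are
built at `cutoff + skin` and pruned to `cutoff` afterwards, so halo
validity must cover skin-extended edges between rebuilds. (The necessary
condition is only `R_comm ≥ T·R`; including the skin is the choice that
keeps the graph-then-prune order correct, and it also covers atom drift
of up to skin/2 between rebuilds.) The halo is rectangular: a ghost is
any atom image inside the domain box expanded by `R_comm` on every side.
This is a superset of the Euclidean-ball rule (corner ghosts up to
√3·R_comm away) and is what axis-aligned communication layers ship in
practice; the brute-force 27-image oracle in the tests checks exactly
this rule. Only one image shell is supported: `R_comm` must be smaller
than every periodic box edge, and larger values are rejected with an
explicit error rather than silently mishandled.

Between rebuilds, ghost coordinates are re-gathered every step from the
authoritative local copies through a stored (source index, integer image
shift) map; positions are re-wrapped and the decomposition rebuilt only
when some atom has moved more than skin/2 (wrapping mid-interval would
invalidate the stored shifts). The domain grid for P processors is the
factorisation of P minimising total domain surface area, with a
lexicographic tie-break.

## Pruning

Stage 1 drops every edge longer than the model cutoff. Stage 2 marks the
T-hop neighborhood of local atoms by pseudo-message passing: T rounds in
which every already-marked node sends to its neighbors. All edges
between kept nodes are retained, including edges among depth-T nodes —
a safe over-approximation, since whether those edges could also be
dropped depends on model internals. The defining contract — pruning
never changes any local energy or any local-relevant partial force — is
asserted at 1e-12 relative on random systems for both model families.
Both built-in models also vanish identically beyond the cutoff
(truncation for LJ, the envelope for the GNN), so evaluating the
unpruned skin graph gives the same answer; pruning is a cost
optimisation whose exactness is testable, exactly as intended.

## Potentials

**Lennard-Jones** (strictly local, T = 1):
`U_i = ½ Σ_j 4ε[(σ/d)¹² − (σ/d)⁶]` truncated at the cutoff, with an
optional energy shift (default on for MD so the energy is continuous at
the cutoff; forces are discontinuous there by the usual truncation
amount, which bounds but does not eliminate rare energy jumps at shell
crossings). Defaults ε = 0.0103 eV, σ = 3.4 Å (argon-like). Zero
separation raises an explicit overlap error.

**ToyMPGNN** (receptive order T = number of layers): species embedding
`h⁰ = E[Z]`; K Gaussian radial basis functions of the edge length times
a cosine envelope `½(1 + cos(πd/R))` that vanishes at R with zero slope
(checked numerically); messages `m_i = W_m Σ_j h_j ⊙ filter(d_ij)`
(continuous-filter, invariant form); residual update
`h ← h + W₂ tanh(W₁ m + b₁) + b₂`; linear readout per atom. Energies are
permutation/translation/rotation invariant because only distances enter,
and `U_i` depends on exactly the T-hop neighborhood — the property the
halo rule and partial-force decomposition rely on, asserted directly
(locality, extensivity, invariance tests). Defaults: width 8, K = 6,
cutoff 5 Å, seeded scaled-normal weights with a readout scale of
0.05 eV giving per-atom energies of order 0.01–0.1 eV; the negative
halo control uses a readout scale of 1.0 so its forces sit at the
~0.1 eV/Å magnitude of production potentials. The init seed is part of
the model archive, so every experiment is reproducible.

Everything is float64. Forces are analytic: closed form for LJ, a
hand-derived reverse-mode sweep through the GNN (seeded with the local
mask, so each domain gets exactly the partial forces
`−∂(Σ_{i local} U_i)/∂r_k`); both are validated against central finite
differences (h = 1e-5 Å) at 1e-5 relative and agree in practice to
~1e-10.

## Domain evaluation and buffering

`evaluate_domain` builds the domain graph at `cutoff + skin`, prunes,
then evaluates on arrays padded to the buffer capacities: padded edges
carry a zero mask (and a harmless nonzero length), padded nodes are
non-local with no real edges, so padding contributes exact zeros —
results are bitwise independent of capacity, which a test asserts by
comparing a tight and a generously padded evaluation. Exceeding any
capacity raises a typed `BufferOverflow` carrying the required sizes;
nothing is ever truncated or silently resized. The driver then applies
the collective protocol: every overflown buffer grows to
max(required, 1.25 × capacity) and every peer at ≥ 90 % occupancy is
pre-enlarged in the same step, after which the whole evaluation is
retried. Capacities only grow, so resize events decay to zero for
systems at equilibrium — observable in the per-step event log, standing
in for recompilation counts. The 1.25 growth factor and 90 % near-full
margin are configurable choices (no canonical values exist).

The deployed force strategy is the T-halo + partial-force-reduction
design; the alternative (2T-halo, forces computed entirely locally)
is exercised indirectly since the global oracle plays that role at
P = 1. `reduce_forces` checks that every atom receives at least one
contribution and rejects unknown global ids.

## MD

Velocity Verlet (NVE) and Langevin (NVT, BAOAB splitting; zero friction
reduces exactly to Verlet, and trajectories are deterministic given the
seed). Langevin stands in for more elaborate thermostats deliberately:
it is ergodic, seed-deterministic and not the point of the package.
Masses are per-species (argon-like 39.948 amu default in the demos).
NVE on a 500-atom LJ crystal at ~30 K with dt = 1 fs conserves energy to
better than 1e-4 relative over 1,000 steps, the drift shrinks faster
than linearly when dt is halved, and trajectories are independent of the
domain grid to well below 1e-8 Å over 100 steps — the MD-level
restatement of oracle equivalence.

## Fixtures

The three built-in systems emulate the canonical benchmark trio at desk
scale; all builders are pure functions of their arguments and record
their seed.

* **fcc crystal**: conventional-cell basis, lattice constant 4.065 Å by
  default; 4n³ atoms; replication reproduces the printed capacity
  figures (470,596 = 4·49³; 296,352; 108,000; 171,500) exactly. For
  force-bearing experiments the perfect lattice is jittered by 0.1 Å
  (a thermal-like snapshot), since symmetric lattices have identically
  zero forces.
* **mock solvated box**: exactly 3,492 atoms in a 33 Å cubic periodic
  box — a connected 166-atom serpentine "peptide" chain, 1,108 rigid
  3-site water-like molecules on a jittered 3 Å grid, and 2 monatomic
  counterions (166 + 3·1,108 + 2 = 3,492; the two ions are needed
  because 3,492 − 166 is not divisible by 3). Construction guarantees
  ≥ 0.8 Å minimum separation; at a 5 Å cutoff atoms have ~54 neighbors,
  a liquid-water-like graph load. Replication gives 27,936 (2³) and
  94,284 (3³) atoms.
* **mock water slab**: a 20 × 20 × 50 Å liquid region of 540 molecules
  (1,620 atoms — a free constant of the mock, recorded in metadata),
  periodic in x, y only, with a configurable vacuum above; replication
  acts in x, y.

The mocks reproduce only what the decomposition, pruning and scaling
logic depend on — atom counts, heterogeneous species, dense liquid-like
geometry, mixed periodicity. They are *not* water: no realistic
structure, no equilibration, no meaningful energetics. Consequently,
passing tests show the evaluation pipeline is exact on systems with
realistic graph loads; they say nothing about the physical fidelity of
any potential on real water or proteins.

## Cost model

`S = ((L + 2TR)/(P^(−1/d) L + 2TR))^d`, `ε = S/P`, with L the *system*
edge per periodic dimension (the per-domain edge `P^(−1/d) L` is
derived — worth stating because either convention appears in the
literature). Non-periodic dimensions are excluded from d; a slab has
d = 2 and its thickness contributes a constant that cancels. The model
counts work only (no latency terms) and measured scaling can exceed it
when runtimes benefit from effects a linear cost model ignores, so it is
asserted only as a formula plus an empirical hook: the measured
per-domain workload (local + ghost atoms from an actual decomposition of
an fcc crystal) matches the (L_dom + 2TR)^d factor within 10 %.

## Force matching

Loss: `L(θ) = (λ_E/S) Σ_α |ΔU_α|² + (λ_F/S) Σ_α (3N_α)^{-1} Σ ‖Δf‖²` —
the energy term per *sample*, the force term per *component*, exactly
this asymmetric normalisation (a per-atom energy variant exists but is
off by default; with mixed system sizes the per-sample form lets large
systems dominate, which is the printed convention). λ_E = λ_F = 1 by
default. Optimisation is full-batch Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8) with validation-split selection of the returned parameters and
a 7:2:1 train/validation/test split by seeded shuffle. Gradients are
central finite differences of the scalar loss with respect to the small
parameter vectors (two log-parameters for LJ; the readout weights for
the GNN family) — they therefore flow through exactly the deployment
energy/force code, and no autodiff framework is needed at these
dimensionalities.

Synthetic training data: perturbed copies of a base configuration
(default: a 32-atom fcc cell at 5.26 Å, near the LJ-argon equilibrium
spacing) labelled with the exact energies/forces of the generating
potential. The default perturbation is 0.2 Å — large enough that the
sampled pair distances spread over a genuine band; at much smaller
perturbations all distances collapse onto the first-shell value and
(ε, σ) become jointly ill-determined, a real identifiability failure,
not an optimiser artefact. Under these conditions LJ (ε, σ) is recovered
to ≤ 1 % (typically ~0.01 %) from 50 noise-free configurations.

For the GNN, exact parameter recovery of a generic random readout is
*not* attainable by first-order optimisation: with a single species the
hidden features are strongly collinear (condition numbers of 1e3–1e4 in
the linear design), and the per-atom readout bias is near-degenerate
with the constant part of the embedding (both add N·const to each
energy and nothing to forces). The recovery experiment therefore does
what any identifiable experiment design must: the generating model has
two filters probing distinct distance ranges, messages kept off tanh
saturation, data spanning cluster sizes 2–18 (so coordination varies),
and the bias frozen. Under those conditions the readout weights are
recovered to ≤ 5 % (typically ~1 %). The general degeneracy is a
documented limitation, not hidden.

## Model archive and I/O

The archive is a zip holding one JSON metadata document (format version,
model kind, units, cutoff, receptive order, species table, array shapes,
init seed) plus each parameter array as a raw little-endian float64
buffer — parameters and declared architecture only, never serialized
code, so the format is language-neutral. Loading an unknown version is a
versioned error; declared units (e.g. nm) are converted on load, and an
Å/eV archive round-trips evaluations bit-for-bit. Extended XYZ (with
`Lattice`, `Properties`, `pbc`, and a `species_names` key for exact
species-code round-trips) is the interchange and trajectory format;
LAMMPS data files are supported in atomic style for orthorhombic boxes
only, with 1-based ids mapped to the 0-based internals. Readers reject
malformed input with line-numbered errors rather than guessing.

## Problem sizes used in validation

Oracle equivalence runs the full cross product {jittered fcc 500 atoms,
solvated mock 3,492, slab 1,620} × {LJ, GNN T = 1, 2, 3} ×
P ∈ {1, 2, 3, 4, 8} × skin ∈ {0, 2.5 Å}. The GNN uses a 4 Å cutoff in
this sweep so the T = 3 receptive radius (12 Å; halo 19.5 Å with skin)
stays within the one-image-shell limit of the slab's 20 Å periodic
edges; the LJ σ is 3.4 Å on the crystal and 0.9 Å on the bonded water
mocks so pair forces stay at physical magnitude in every fixture.
Tolerances: 1e-8 relative on U_total, 1e-8 eV/Å absolute per force
component (measured deviations are ~1e-15). MD validation uses 500 atoms
for 1,000 steps; the buffer protocol is demonstrated on a 108-atom
crystal over 500 steps starting from capacity-1 buffers.

## Known limitations

* Sequential emulation only — no MPI, devices, threads, or real
  compilation; "recompilation" is an event counter.
* One ghost-image shell (`R_comm` < box edge); small periodic cells with
  very deep models are rejected, not handled.
* Truncated LJ has the usual force discontinuity at the cutoff.
* The toy GNN is invariant (distance-only); equivariant features,
  production architectures, and chemical accuracy are non-goals.
* FD loss gradients scale to a handful of trainable parameters —
  adequate for the recovery experiments, not for training full networks.
* The cost model has no communication term and is an estimate of
  attainable scaling, not a wall-clock predictor.
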