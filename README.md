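# halomd

Desk-scale, single-process re-creation of the evaluation pipeline used to
deploy **semilocal machine-learning potentials** inside a spatially
decomposed MD engine — for people building or validating such deployment
layers who want every contract exercised and checked without GPUs, MPI,
or a compiler toolchain in the loop.

## The problem

A semilocal potential writes the total energy as a sum of per-atom terms,

    U(r) = Σ_i U_i(r_i, 𝒜_i),

where the environment 𝒜_i of atom *i* contains every atom reachable by at
most *T* graph hops over edges shorter than a cutoff *R* (receptive radius
*T·R*; *T* = number of message-passing layers for a GNN, *T* = 1 for a pair
potential). Production MD engines parallelize by splitting space into
non-overlapping domains, giving each processor its local atoms plus *ghost*
copies of everything within a halo width `R_comm` of its boundary. The core
correctness rules this package implements and verifies are:

* **Halo rule** — with `R_comm ≥ T·(R + skin)` each domain's subgraph
  contains the full T-hop environment of all its local atoms, so summing
  local energies over domains gives the exact total energy.
* **Partial forces** — the force on an atom decomposes as
  `f_i = −∂U_i/∂r_i − Σ_j ∂U_j/∂r_i`; each domain computes the
  contributions of its *local* energies to the force on *every* atom of
  its subgraph (ghosts included), and a final reduction keyed by global
  atom id reconstructs the exact forces with no mid-step communication.
* **Graph pruning** — skin edges longer than *R* are dropped, then
  pseudo-messages sent from local atoms for *T* rounds mark exactly the
  T-hop neighborhood; everything else is discarded before the (costly)
  model evaluation, provably without changing any local energy or force.
* **Growth-only buffering** — dynamically shaped arrays are padded to
  fixed capacities; overflows raise a typed signal and all overflown or
  near-full buffers grow collectively before a retry, so "recompilation"
  events are observable and decay to zero at equilibrium.
* **Analytic scaling model** — speedup `S = ((L + 2TR)/(P^(−1/d) L + 2TR))^d`
  and efficiency `ε = S/P` for a system of edge L split over P processors
  in d periodic dimensions.

Two built-in differentiable models exercise everything: a truncated
Lennard-Jones pair potential (T = 1) and a small invariant message-passing
GNN with continuous radial filters (T = number of layers, hand-derived
reverse-mode gradients). A global single-graph evaluation under the
minimum-image convention is the built-in oracle; domain-decomposed results
are required to match it to 1e-8 (relative energy, absolute eV/Å forces).
Force-matching training (per-sample energy + per-component force loss,
Adam with β₁ = 0.9, β₂ = 0.999, ε = 1e-8) closes the loop from labelled
data to an exported, self-contained model archive.

## Worked example

```python
import numpy as np
from halomd import (ToyMPGNN, build_solvated_box_mock, make_domain_grid,
                    evaluate_system, evaluate_global)

system = build_solvated_box_mock(seed=0)         # 3,492 atoms, 33 Å box
pot = ToyMPGNN(n_species=4, T=2, cutoff=4.0, seed=7)
grid = make_domain_grid(8, system.box)           # -> (2, 2, 2)

dd  = evaluate_system(system, pot, grid, skin=2.5)   # decomposed pipeline
ref = evaluate_global(system, pot, skin=2.5)         # single-graph oracle

print(f"U_total (decomposed): {dd.energy:.10f} eV")
print(f"U_total (global):     {ref.energy:.10f} eV")
print(f"max force deviation:  {np.max(np.abs(dd.forces - ref.forces)):.3e} eV/Å")
```

prints

```
U_total (decomposed): 76.1353665279 eV
U_total (global):     76.1353665279 eV
max force deviation:  1.943e-16 eV/Å
```

i.e. eight "processors", each seeing only its own domain plus a
`R_comm = T·(cutoff+skin) = 13 Å` halo of ghost atoms, reproduce the global
energy and forces to machine precision — the package's central claim.

The same pipeline is scriptable from the shell:

```bash
halomd check --fixture solvated --P 8 --potential gnn --T 2 --cutoff 4
halomd plan --cutoff 5 --T 3 --L 100 --d 3 --P 1,8,64     # scaling table
halomd generate --kind fcc --a 4.065 --n 5 --out fcc.xyz  # fixtures
```

## Layout

| module | contents |
|---|---|
| `halomd.system` | `ParticleSystem`, wrapping, minimum image, replication |
| `halomd.fixtures` | fcc crystal, mock solvated box, mock water slab |
| `halomd.neighbors` | cell-tree neighbor graphs, skin rebuild criterion |
| `halomd.decomposition` | domain grids, ghost-atom halos (`R_comm`) |
| `halomd.pruning` | edge pruning + T-hop pseudo-message node marking |
| `halomd.potentials` | `LennardJones`, `ToyMPGNN`, analytic gradients |
| `halomd.runtime` | per-domain evaluation, partial-force reduction, buffers |
| `halomd.md` | velocity-Verlet / Langevin MD over the domain runtime |
| `halomd.scaling` | analytic speedup / parallel-efficiency model |
| `halomd.training` | force-matching loss, Adam, synthetic training data |
| `halomd.io` | extended XYZ, LAMMPS data (atomic), model archives |
| `halomd.cli` | `halomd generate / check / run / plan / train / export` |

See `docs/methods.md` for the models, conventions, numerical choices and
known limitations.
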