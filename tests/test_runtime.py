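import numpy as np
import pytest

from halomd import (
    BufferOverflow,
    BufferState,
    DomainGrid,
    LennardJones,
    ParticleSystem,
    ToyMPGNN,
    build_fcc,
    collective_resize,
    compute_r_comm,
    decompose,
    evaluate_domain,
    evaluate_global,
    evaluate_system,
    make_domain_grid,
    reduce_forces,
)
from halomd.runtime import PartialForceBlock
from conftest import random_cluster


def lj_pair_force(eps, sig, d):
    s6 = (sig / d) ** 6
    return -24 * eps / d * (s6 - 2 * s6**2)  # force on the far atom, along +x


class TestEvaluateDomain:
    def test_single_isolated_atom(self):
        s = ParticleSystem(
            positions=np.array([[5.0, 5.0, 5.0]]),
            species=np.zeros(1, int),
            box=np.full(3, 10.0),
            periodic=np.full(3, False),
        )
        (view,) = decompose(s, DomainGrid(1, 1, 1), r_comm=5.0)
        pot = ToyMPGNN(n_species=1, T=2, seed=0)
        block = evaluate_domain(view, pot)
        np.testing.assert_array_equal(block.forces, 0.0)
        iso = pot.atomic_energies(
            __import__("halomd").neighbors.build_graph_open(s.positions, 5.0),
            s.species,
        )
        assert block.local_energies[0] == iso[0]

    def test_dimer_split_across_two_domains(self):
        """Each domain reports the analytic pair force on both global ids."""
        eps, sig, d = 0.0103, 3.4, 3.9
        s = ParticleSystem(
            positions=np.array([[10.0 - d / 2, 10.0, 10.0], [10.0 + d / 2, 10.0, 10.0]]),
            species=np.zeros(2, int),
            box=np.full(3, 20.0),
            periodic=np.full(3, False),
        )
        lj = LennardJones(epsilon=eps, sigma=sig, cutoff=5.0, shift=False)
        views = decompose(s, DomainGrid(2, 1, 1), r_comm=5.0)
        f_pair = lj_pair_force(eps, sig, d)
        for view, local_gid in zip(views, (0, 1)):
            block = evaluate_domain(view, lj)
            assert set(block.global_ids.tolist()) == {0, 1}
            by_gid = dict(zip(block.global_ids.tolist(), block.forces[:, 0]))
            sign = -1.0 if local_gid == 0 else 1.0
            # half the pair energy is local, so half the pair force appears,
            # split antisymmetrically over the two copies
            assert by_gid[local_gid] == pytest.approx(sign * f_pair / 2, rel=1e-12)
            assert by_gid[1 - local_gid] == pytest.approx(-sign * f_pair / 2, rel=1e-12)

    def test_ghost_contributions_match_global_gradient(self, rng):
        """Summed ghost contributions reproduce the cross-boundary terms of
        the partial-force decomposition (checked against the global oracle
        per atom via the reduction)."""
        pot = ToyMPGNN(n_species=1, T=2, cutoff=4.0, seed=3)
        s = random_cluster(150, 22.0, rng, periodic=True)
        ref = evaluate_global(s, pot)
        views = decompose(s, DomainGrid(2, 2, 1), r_comm=compute_r_comm(2, 4.0))
        blocks = [evaluate_domain(v, pot) for v in views]
        forces = reduce_forces(blocks, s.n_atoms)
        np.testing.assert_allclose(forces, ref.forces, atol=1e-10)


class TestReduceForces:
    def test_p1_pass_through(self, rng, lj):
        s = random_cluster(50, 14.0, rng, periodic=True)
        (view,) = decompose(s, DomainGrid(1, 1, 1), r_comm=5.0)
        block = evaluate_domain(view, lj)
        forces = reduce_forces([block], s.n_atoms)
        ref = evaluate_global(s, lj)
        np.testing.assert_allclose(forces, ref.forces, atol=1e-12)

    def test_total_force_vanishes(self, rng, lj, gnn2):
        s = random_cluster(120, 20.0, rng, periodic=True)
        for pot in (lj, gnn2):
            res = evaluate_system(s, pot, DomainGrid(2, 2, 1))
            assert np.all(np.abs(res.forces.sum(axis=0)) <= 1e-9)

    def test_missing_contribution_detected(self):
        block = PartialForceBlock(
            global_ids=np.array([0, 1]),
            forces=np.zeros((2, 3)),
            local_ids=np.array([0]),
            local_energies=np.zeros(1),
        )
        with pytest.raises(ValueError, match="no force contribution"):
            reduce_forces([block], 3)

    def test_out_of_range_id_rejected(self):
        block = PartialForceBlock(
            global_ids=np.array([0, 5]),
            forces=np.zeros((2, 3)),
            local_ids=np.array([0]),
            local_energies=np.zeros(1),
        )
        with pytest.raises(IndexError):
            reduce_forces([block], 3)


class TestOracleEquivalence:
    @pytest.mark.parametrize("P", [2, 4, 8])
    @pytest.mark.parametrize("potname", ["lj", "gnn"])
    def test_decomposed_matches_global(self, P, potname, rng, lj, gnn2):
        pot = {"lj": lj, "gnn": gnn2}[potname]
        s = random_cluster(200, 26.0, rng, periodic=True)
        ref = evaluate_global(s, pot, skin=2.5)
        res = evaluate_system(s, pot, make_domain_grid(P, s.box), skin=2.5)
        assert abs(res.energy - ref.energy) <= 1e-8 * abs(ref.energy)
        assert np.max(np.abs(res.forces - ref.forces)) <= 1e-8

    def test_grid_111_equals_global(self, fcc108, lj):
        ref = evaluate_global(fcc108, lj)
        res = evaluate_system(fcc108, lj, DomainGrid(1, 1, 1))
        assert res.energy == pytest.approx(ref.energy, rel=1e-12)
        np.testing.assert_allclose(res.forces, ref.forces, atol=1e-12)

    def test_forces_match_finite_differences(self, fcc108, rng):
        """Reduced forces vs central differences of U_total."""
        pot = ToyMPGNN(n_species=1, T=2, cutoff=5.0, seed=9)
        grid = DomainGrid(2, 1, 1)
        fcc108 = fcc108.copy()
        # break the lattice symmetry so forces are non-trivial
        fcc108.positions = fcc108.positions + rng.normal(scale=0.05, size=(108, 3))
        res = evaluate_system(fcc108, pot, grid)
        h = 1e-5
        scale = np.max(np.abs(res.forces))
        for i in (0, 53):
            for k in range(3):
                sp, sm = fcc108.copy(), fcc108.copy()
                sp.positions[i, k] += h
                sm.positions[i, k] -= h
                fd = -(
                    evaluate_system(sp, pot, grid).energy
                    - evaluate_system(sm, pot, grid).energy
                ) / (2 * h)
                assert abs(res.forces[i, k] - fd) <= 1e-5 * max(scale, 1e-6)

    def test_undersized_halo_breaks_forces(self, fcc108):
        """Negative control: R_comm = (T-1)·cutoff on a T=2 model must
        produce wrong forces — the halo rule is load-bearing."""
        pot = ToyMPGNN(n_species=1, T=2, cutoff=5.0, seed=10)
        ref = evaluate_global(fcc108, pot)
        bad = evaluate_system(
            fcc108, pot, DomainGrid(2, 2, 2), r_comm=(pot.T - 1) * pot.cutoff
        )
        assert np.max(np.abs(bad.forces - ref.forces)) > 1e-6

    def test_result_independent_of_domain_evaluation_order(self, rng, gnn2):
        s = random_cluster(100, 20.0, rng, periodic=True)
        views = decompose(s, DomainGrid(2, 2, 1), r_comm=compute_r_comm(2, 5.0))
        blocks = [evaluate_domain(v, gnn2) for v in views]
        f_fwd = reduce_forces(blocks, s.n_atoms)
        f_rev = reduce_forces(blocks[::-1], s.n_atoms)
        np.testing.assert_allclose(f_fwd, f_rev, atol=1e-13)


class TestBuffering:
    def test_overflow_signal_carries_required_sizes(self, fcc108, lj):
        views = decompose(fcc108, DomainGrid(1, 1, 1), r_comm=5.0)
        buf = BufferState()  # capacity 1 everywhere
        with pytest.raises(BufferOverflow) as exc:
            evaluate_domain(views[0], lj, buf)
        assert exc.value.required["atoms"] == views[0].n_atoms
        assert exc.value.required["kept_nodes"] > 1

    def test_padding_does_not_change_results(self, rng, gnn2):
        s = random_cluster(60, 16.0, rng, periodic=True)
        views = decompose(s, DomainGrid(2, 1, 1), r_comm=compute_r_comm(2, 5.0))
        small = evaluate_domain(views[0], gnn2)
        big = BufferState(
            capacities={"atoms": 10_000, "edges": 50_000, "kept_nodes": 9_000, "kept_edges": 40_000}
        )
        padded = evaluate_domain(views[0], gnn2, big)
        np.testing.assert_array_equal(small.forces + 0.0, padded.forces + 0.0)
        np.testing.assert_array_equal(small.local_energies, padded.local_energies)

    def test_no_overflow_leaves_states_unchanged(self):
        states = [BufferState(capacities={"edges": 10})]
        out = collective_resize(states, {})
        assert out[0].capacities == {"edges": 10}
        assert out[0].resize_events == 0

    def test_collective_resize_grows_overflown_and_near_full(self):
        a = BufferState(capacities={"edges": 100})
        b = BufferState(capacities={"edges": 100})
        b.last_required = {"edges": 95}  # >= 90% full
        c = BufferState(capacities={"edges": 100})
        c.last_required = {"edges": 10}
        collective_resize([a, b, c], {0: {"edges": 500}})
        assert a.capacities["edges"] >= 500
        assert b.capacities["edges"] == 125  # grew by the 1.25 factor
        assert c.capacities["edges"] == 100  # untouched
        assert (a.resize_events, b.resize_events, c.resize_events) == (1, 1, 0)

    def test_capacity_one_start_retries_to_identical_results(self, fcc108, lj):
        grid = DomainGrid(2, 1, 1)
        bufs = [BufferState() for _ in range(grid.n_domains)]
        res = evaluate_system(fcc108, lj, grid, buffers=bufs)
        ref = evaluate_system(fcc108, lj, grid)
        assert res.resize_events >= 1
        assert res.energy == ref.energy
        np.testing.assert_array_equal(res.forces + 0.0, ref.forces + 0.0)
        # second call: capacities warm, no further resizes
        res2 = evaluate_system(fcc108, lj, grid, buffers=bufs)
        assert res2.resize_events == 0

    def test_growth_only(self):
        buf = BufferState()
        buf.grow_to({"edges": 100})
        assert buf.capacities["edges"] >= 100
        cap = buf.capacities["edges"]
        buf.grow_to({"edges": 10})
        assert buf.capacities["edges"] >= cap  # capacities never shrink
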