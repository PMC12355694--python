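import numpy as np
import pytest

from halomd import (
    LennardJones,
    ToyMPGNN,
    build_fcc,
    fm_loss,
    generate_training_data,
    train,
)
from halomd.training import GNNReadoutFamily, LJFamily, LossWeights, TrainingSet


def hand_made_set(n_atoms, u_err, f_err, lam=None):
    """Single-sample set with controlled prediction errors, built from an
    isolated dimer-free system so the LJ prediction is exactly zero."""
    from halomd import ParticleSystem

    pos = np.zeros((n_atoms, 3))
    pos[:, 0] = np.arange(n_atoms) * 50.0  # far beyond any cutoff
    sys_ = ParticleSystem(
        positions=pos + 100.0,
        species=np.zeros(n_atoms, int),
        box=np.full(3, 50.0 * n_atoms + 200.0),
        periodic=np.full(3, False),
    )
    return TrainingSet(
        systems=[sys_],
        energies=np.array([-u_err]),  # prediction is 0, so ΔU = u_err
        forces=[np.full((n_atoms, 3), -f_err)],
        split=np.array(["train"]),
    )


class TestFmLoss:
    def test_zero_at_generating_parameters(self):
        true = LennardJones(epsilon=0.0103, sigma=3.4, shift=False)
        data = generate_training_data(true, 5, 0.2, seed=0)
        fam = LJFamily(shift=False)
        theta_true = np.log([0.0103, 3.4])
        assert fm_loss(theta_true, fam, data, LossWeights()) == pytest.approx(
            0.0, abs=1e-20
        )

    def test_energy_term_hand_value(self):
        # 1 sample, 1 atom, ΔU = 2 eV, zero force error, λ_E = λ_F = 1 → L = 4
        data = hand_made_set(1, u_err=2.0, f_err=0.0)
        fam = LJFamily(shift=False)
        loss = fm_loss(fam.initial_theta(), fam, data, LossWeights(1.0, 1.0))
        assert loss == pytest.approx(4.0, rel=1e-12)

    def test_force_term_hand_value(self):
        # 2 atoms, zero ΔU, every force component off by 1 → L = λ_F (1/6)·6
        for lam_f in (1.0, 0.5):
            data = hand_made_set(2, u_err=0.0, f_err=1.0)
            fam = LJFamily(shift=False)
            loss = fm_loss(fam.initial_theta(), fam, data, LossWeights(1.0, lam_f))
            assert loss == pytest.approx(lam_f, rel=1e-12)

    def test_nonnegative_and_zero_iff_exact(self):
        data = hand_made_set(3, u_err=0.0, f_err=0.0)
        fam = LJFamily(shift=False)
        assert fm_loss(fam.initial_theta(), fam, data, LossWeights()) == 0.0
        data2 = hand_made_set(3, u_err=0.1, f_err=0.0)
        assert fm_loss(fam.initial_theta(), fam, data2, LossWeights()) > 0.0

    def test_rejects_empty_subset(self):
        data = hand_made_set(1, 0.0, 0.0)
        fam = LJFamily(shift=False)
        with pytest.raises(ValueError):
            fm_loss(fam.initial_theta(), fam, data, LossWeights(), subset=np.array([], int))


class TestGenerateTrainingData:
    def test_zero_perturbation_gives_identical_configs(self):
        true = LennardJones(shift=False)
        data = generate_training_data(true, 4, 0.0, seed=1)
        for s in data.systems[1:]:
            np.testing.assert_array_equal(s.positions, data.systems[0].positions)

    def test_labels_match_direct_evaluation(self):
        from halomd import evaluate_global

        true = LennardJones(shift=False)
        data = generate_training_data(true, 6, 0.2, seed=2)
        for i, s in enumerate(data.systems):
            res = evaluate_global(s, true)
            assert data.energies[i] == res.energy
            np.testing.assert_array_equal(data.forces[i], res.forces[s.global_ids])

    def test_split_ratio_70_20_10(self):
        true = LennardJones(shift=False)
        data = generate_training_data(true, 100, 0.1, seed=3)
        counts = {t: int(np.sum(data.split == t)) for t in ("train", "validation", "test")}
        assert counts == {"train": 70, "validation": 20, "test": 10}

    def test_label_noise_recorded(self):
        true = LennardJones(shift=False)
        data = generate_training_data(
            true, 3, 0.1, seed=4, energy_noise=0.01, force_noise=0.02
        )
        assert data.label_noise == {"energy_sigma": 0.01, "force_sigma": 0.02}


class TestTrain:
    def test_zero_epochs_returns_initial_theta(self):
        true = LennardJones(shift=False)
        data = generate_training_data(true, 5, 0.2, seed=5)
        fam = LJFamily(shift=False)
        theta0 = fam.initial_theta()
        res = train(fam, data, optimizer_config={"epochs": 0})
        np.testing.assert_array_equal(res.theta, theta0)

    def test_lj_parameter_recovery_within_one_percent(self):
        true = LennardJones(epsilon=0.0103, sigma=3.4, cutoff=5.0, shift=False)
        data = generate_training_data(true, 50, 0.2, seed=1)
        fam = LJFamily(cutoff=5.0, shift=False)
        res = train(fam, data, LossWeights(), {"epochs": 400, "lr": 0.1})
        eps, sig = LJFamily.physical(res.theta)
        assert abs(eps - 0.0103) / 0.0103 <= 0.01
        assert abs(sig - 3.4) / 3.4 <= 0.01

    def test_loss_decreases_over_first_epochs(self):
        true = LennardJones(epsilon=0.0103, sigma=3.4, cutoff=5.0, shift=False)
        data = generate_training_data(true, 20, 0.2, seed=6)
        fam = LJFamily(shift=False)
        res = train(fam, data, LossWeights(), {"epochs": 12, "lr": 0.05})
        losses = [h["train_loss"] for h in res.history]
        assert losses[4] < losses[0]
        assert losses[-1] < losses[0]

    def test_force_only_weights_leave_energy_gauge_free(self):
        """With λ_E = 0, a constant per-atom energy offset is invisible
        to the loss: forces fit while total energies may stay shifted."""
        true = LennardJones(epsilon=0.02, sigma=3.0, cutoff=5.0, shift=True)
        base = build_fcc(4.4, 3)
        data = generate_training_data(true, 20, 0.15, seed=7, base_system=base)
        # candidate family differs only by the shift convention → constant
        # per-pair energy offset, identical forces
        fam = LJFamily(cutoff=5.0, shift=False)
        theta = np.log([0.02, 3.0])
        w_force_only = LossWeights(lam_E=0.0, lam_F=1.0)
        assert fm_loss(theta, fam, data, w_force_only) == pytest.approx(0.0, abs=1e-18)
        w_both = LossWeights(1.0, 1.0)
        assert fm_loss(theta, fam, data, w_both) > 1e-6  # offset visible to λ_E

    @staticmethod
    def _identifiable_gnn():
        """1-layer GNN whose two filters probe distinct distance ranges
        and whose messages stay off tanh saturation, so the readout
        weights are identifiable from energy+force data."""
        m = ToyMPGNN(n_species=1, width=2, T=1, n_rbf=4, cutoff=5.0, seed=0)
        p = m.params
        p["embed"] = np.array([[1.0, 1.0]])
        p["Wf0"] = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
        p["bf0"] = np.zeros(2)
        p["Wm0"] = np.diag([0.35, 0.6])
        p["W10"] = np.eye(2)
        p["b10"] = np.zeros(2)
        p["W20"] = np.eye(2)
        p["b20"] = np.zeros(2)
        p["w_out"] = np.array([0.05, -0.03])
        p["b_out"] = np.array([0.02])
        return m

    @staticmethod
    def _cluster_training_set(true, seed=8):
        """Random clusters of varying size: diverse coordination numbers
        decorrelate the two filter channels."""
        from halomd import ParticleSystem, evaluate_global
        from halomd.training import TrainingSet

        rng = np.random.default_rng(seed)
        systems, energies, forces = [], [], []
        for m in list(range(2, 12)) + [14, 18]:
            for _rep in range(2):
                pos = []
                while len(pos) < m:
                    c = rng.uniform(0, 2.2 * m ** (1 / 3) + 3, size=3)
                    if all(np.linalg.norm(c - p) > 2.2 for p in pos):
                        pos.append(c)
                s = ParticleSystem(
                    np.array(pos), np.zeros(m, int),
                    np.full(3, 60.0), np.full(3, False),
                )
                res = evaluate_global(s, true)
                systems.append(s)
                energies.append(res.energy)
                forces.append(res.forces[s.global_ids])
        split = np.array(["train"] * len(systems))
        split[::5] = "validation"
        return TrainingSet(systems, np.array(energies), forces, split)

    def test_gnn_readout_recovery_within_five_percent(self):
        true = self._identifiable_gnn()
        data = self._cluster_training_set(true)
        start = self._identifiable_gnn()
        start.params["w_out"] = np.array([0.02, -0.01])
        fam = GNNReadoutFamily(start, train_bias=False)
        res = train(fam, data, LossWeights(), {"epochs": 400, "lr": 0.005})
        target = true.params["w_out"]
        err = np.abs(res.theta - target) / np.abs(target)
        assert np.max(err) <= 0.05
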