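"""Force-matching training.

The loss over S samples α with reference energies U^ref and forces
f^ref is

    L(θ) = (λ_E / S) Σ_α |U_θ(α) − U^ref_α|²
         + (λ_F / S) Σ_α (1 / 3N_α) Σ_i ‖f_θ,α,i − f^ref_α,i‖²

— note the asymmetric normalisation: the energy term is per-sample (not
per-atom) while the force term is averaged over all 3N_α components.
A per-atom energy variant is available (off by default) for mixed-size
data sets.

Optimisation uses Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on small
parameter vectors; gradients are central finite differences of the
scalar loss, so they flow through exactly the same energy/force code
used at deployment. The best parameters are selected on the validation
split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighbors import build_neighbor_graph
from .potentials import LennardJones, SemilocalPotential, ToyMPGNN
from .runtime import assemble_forces, evaluate_global
from .system import ParticleSystem

__all__ = [
    "TrainingSet",
    "LossWeights",
    "LJFamily",
    "GNNReadoutFamily",
    "TrainResult",
    "fm_loss",
    "train",
    "generate_training_data",
]


@dataclass
class LossWeights:
    """Relative weights of the energy (1/eV²) and force (Å²/eV²) terms."""

    lam_E: float = 1.0
    lam_F: float = 1.0

    def __post_init__(self) -> None:
        if self.lam_E < 0 or self.lam_F < 0 or (self.lam_E == 0 and self.lam_F == 0):
            raise ValueError("loss weights must be >= 0 and not both zero")


@dataclass
class TrainingSet:
    """Labelled configurations with a recorded train/val/test split."""

    systems: list[ParticleSystem]
    energies: np.ndarray  # (S,), eV
    forces: list[np.ndarray]  # per sample (N_α, 3), eV/Å
    split: np.ndarray  # (S,) strings in {train, validation, test}
    label_noise: dict = field(default_factory=dict)
    _graphs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        s = len(self.systems)
        if not (len(self.forces) == s and len(self.energies) == s == len(self.split)):
            raise ValueError("inconsistent sample counts")
        for sys_, f in zip(self.systems, self.forces):
            if f.shape != (sys_.n_atoms, 3):
                raise ValueError("force label shape mismatch")

    def indices(self, tag: str) -> np.ndarray:
        return np.flatnonzero(self.split == tag)

    def graph(self, i: int, cutoff: float):
        key = (i, cutoff)
        if key not in self._graphs:
            self._graphs[key] = build_neighbor_graph(self.systems[i], cutoff)
        return self._graphs[key]


class LJFamily:
    """Two-parameter LJ family; θ = (log ε, log σ) keeps both positive
    and on comparable scales."""

    def __init__(self, cutoff: float = 5.0, shift: bool = False):
        self.cutoff = cutoff
        self.shift = shift

    def initial_theta(self, epsilon: float = 0.02, sigma: float = 3.0) -> np.ndarray:
        return np.log([epsilon, sigma])

    def with_params(self, theta: np.ndarray) -> LennardJones:
        eps, sig = np.exp(theta)
        return LennardJones(epsilon=eps, sigma=sig, cutoff=self.cutoff, shift=self.shift)

    @staticmethod
    def physical(theta: np.ndarray) -> tuple[float, float]:
        return float(np.exp(theta[0])), float(np.exp(theta[1]))


class GNNReadoutFamily:
    """A :class:`ToyMPGNN` with everything frozen except the readout
    layer.

    With ``train_bias=True`` θ = concat(w_out, b_out); with
    ``train_bias=False`` only the weight vector is optimised. The
    per-atom readout bias is near-collinear with the constant part of
    the species embedding (both add N·const to every total energy and
    nothing to forces), so recovery experiments typically freeze it.
    """

    def __init__(self, base: ToyMPGNN, train_bias: bool = True):
        self.base = base
        self.cutoff = base.cutoff
        self.train_bias = train_bias

    def initial_theta(self) -> np.ndarray:
        w = self.base.params["w_out"]
        if self.train_bias:
            return np.concatenate([w, self.base.params["b_out"]])
        return w.copy()

    def with_params(self, theta: np.ndarray) -> ToyMPGNN:
        params = {k: v.copy() for k, v in self.base.params.items()}
        theta = np.asarray(theta, dtype=np.float64)
        if self.train_bias:
            params["w_out"] = theta[:-1]
            params["b_out"] = theta[-1:]
        else:
            params["w_out"] = theta
        return ToyMPGNN.from_arrays(self.base.metadata(), params)


def _predict(potential: SemilocalPotential, data: TrainingSet, i: int):
    graph = data.graph(i, potential.cutoff)
    sys_ = data.systems[i]
    local = np.ones(sys_.n_atoms, dtype=bool)
    energies, edge_grads = potential.energies_and_edge_grads(
        graph, sys_.species, local
    )
    forces = assemble_forces(graph, edge_grads, sys_.n_atoms)
    return float(energies.sum()), forces


def fm_loss(
    theta: np.ndarray,
    potential_family,
    data: TrainingSet,
    weights: LossWeights,
    subset: np.ndarray | None = None,
    per_atom_energy: bool = False,
) -> float:
    """Force-matching loss over ``subset`` (default: every sample)."""
    idx = subset if subset is not None else np.arange(len(data.systems))
    if len(idx) == 0:
        raise ValueError("loss over an empty sample set")
    potential = potential_family.with_params(np.asarray(theta, dtype=np.float64))
    s = len(idx)
    total = 0.0
    for i in idx:
        u, f = _predict(potential, data, int(i))
        n = data.systems[int(i)].n_atoms
        du = u - data.energies[int(i)]
        if per_atom_energy:
            du = du / n
        total += weights.lam_E / s * du * du
        df = f - data.forces[int(i)]
        total += weights.lam_F / s * float(np.sum(df * df)) / (3.0 * n)
    return total


@dataclass
class TrainResult:
    theta: np.ndarray
    history: list[dict]
    diverged: bool = False
    last_good_theta: np.ndarray | None = None


def _fd_gradient(f, theta: np.ndarray, h_rel: float) -> np.ndarray:
    g = np.zeros_like(theta)
    for k in range(len(theta)):
        h = h_rel * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        g[k] = (f(tp) - f(tm)) / (2.0 * h)
    return g


def train(
    potential_family,
    data: TrainingSet,
    weights: LossWeights | None = None,
    optimizer_config: dict | None = None,
    theta0: np.ndarray | None = None,
) -> TrainResult:
    """Adam optimisation of the force-matching loss with validation-based
    parameter selection."""
    weights = weights or LossWeights()
    cfg = {
        "lr": 0.05,
        "epochs": 200,
        "beta1": 0.9,
        "beta2": 0.999,
        "eps": 1e-8,
        "fd_step": 1e-6,
    }
    cfg.update(optimizer_config or {})
    train_idx = data.indices("train")
    if len(train_idx) == 0:
        raise ValueError("train split is empty")
    val_idx = data.indices("validation")
    theta = (
        np.asarray(theta0, dtype=np.float64).copy()
        if theta0 is not None
        else potential_family.initial_theta()
    )

    def train_loss(t):
        return fm_loss(t, potential_family, data, weights, subset=train_idx)

    def val_loss(t):
        if len(val_idx) == 0:
            return train_loss(t)
        return fm_loss(t, potential_family, data, weights, subset=val_idx)

    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    history: list[dict] = []
    best_theta = theta.copy()
    best_val = val_loss(theta)
    last_good = theta.copy()
    for epoch in range(int(cfg["epochs"])):
        g = _fd_gradient(train_loss, theta, cfg["fd_step"])
        m = cfg["beta1"] * m + (1.0 - cfg["beta1"]) * g
        v = cfg["beta2"] * v + (1.0 - cfg["beta2"]) * g * g
        mhat = m / (1.0 - cfg["beta1"] ** (epoch + 1))
        vhat = v / (1.0 - cfg["beta2"] ** (epoch + 1))
        theta = theta - cfg["lr"] * mhat / (np.sqrt(vhat) + cfg["eps"])
        tl = train_loss(theta)
        if not np.isfinite(tl):
            return TrainResult(
                theta=best_theta, history=history, diverged=True, last_good_theta=last_good
            )
        last_good = theta.copy()
        vl = val_loss(theta)
        history.append({"epoch": epoch, "train_loss": tl, "validation_loss": vl})
        if vl < best_val:
            best_val = vl
            best_theta = theta.copy()
    return TrainResult(theta=best_theta, history=history)


def generate_training_data(
    true_potential: SemilocalPotential,
    n_configs: int,
    perturbation: float,
    seed: int,
    base_system: ParticleSystem | None = None,
    energy_noise: float = 0.0,
    force_noise: float = 0.0,
) -> TrainingSet:
    """Perturbed copies of a base configuration labelled with the exact
    energies/forces of ``true_potential`` (optionally plus Gaussian label
    noise with recorded σ), split 7:2:1 by a seeded shuffle."""
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    if base_system is None:
        from .fixtures import build_fcc

        base_system = build_fcc(5.26, 2)  # 32 atoms, near the LJ-argon minimum
    rng = np.random.default_rng(seed)
    systems, energies, forces = [], [], []
    for _ in range(n_configs):
        sys_i = base_system.copy()
        sys_i.positions = sys_i.positions + rng.normal(
            scale=perturbation, size=sys_i.positions.shape
        )
        res = evaluate_global(sys_i, true_potential)
        u = res.energy + (rng.normal(scale=energy_noise) if energy_noise else 0.0)
        f = res.forces[sys_i.global_ids]
        if force_noise:
            f = f + rng.normal(scale=force_noise, size=f.shape)
        systems.append(sys_i)
        energies.append(u)
        forces.append(f)
    order = rng.permutation(n_configs)
    n_train = int(0.7 * n_configs)
    n_val = int(0.2 * n_configs)
    split = np.empty(n_configs, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_val]] = "validation"
    split[order[n_train + n_val :]] = "test"
    return TrainingSet(
        systems=systems,
        energies=np.asarray(energies, dtype=np.float64),
        forces=forces,
        split=split.astype(str),
        label_noise={"energy_sigma": energy_noise, "force_sigma": force_noise},
    )
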