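"""Snapshot-ensemble training with a cyclic (shifted-cosine) learning rate.

One model is trained through E annealing cycles; the learning rate restarts
at S0 at the first optimizer step of each cycle and anneals towards zero
following

    S(t) = S0/2 * ( cos( pi * mod(t-1, ceil(T/E)) / ceil(T/E) ) + 1 ),

where t counts mini-batch optimization steps and T is the total number of
steps. The model converges into a local minimum at the end of each cycle —
where the full-data latent-mean embedding is harvested as a snapshot — and
the learning-rate restart kicks it out again, so a single training run
yields an ensemble of diverse embeddings. The conventional baseline trains
E independent, differently initialized models at a fixed learning rate and
costs E times the model builds for the same number of gradient steps.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np

from ._errors import TrainingError, ValidationError
from .io_preprocess import MultimodalDataset
from .vae_model import MultimodalVAE, VAEConfig, build_model

__all__ = [
    "ScheduleConfig",
    "EmbeddingSnapshot",
    "EnsembleOfEmbeddings",
    "learning_rate",
    "train_snapshot_ensemble",
    "train_conventional_ensemble",
    "save_ensemble",
    "load_ensemble",
]


@dataclasses.dataclass
class ScheduleConfig:
    """Cyclic learning-rate schedule parameters.

    ``total_iterations`` is bound to a dataset as
    ``n_cycles * epochs_per_cycle * ceil(n_cells / batch_size)``; leave it
    ``None`` and it is filled in by the trainer.
    """

    initial_lr: float = 0.02
    n_cycles: int = 50
    epochs_per_cycle: int = 1
    batch_size: int = 64
    total_iterations: Optional[int] = None
    reset_optimizer_per_cycle: bool = False
    #: gradients are rescaled to this global L2 norm when they exceed it
    max_grad_norm: float = 100.0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValidationError("initial_lr must be > 0")
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        if self.epochs_per_cycle < 1 or self.batch_size < 1:
            raise ValidationError("epochs_per_cycle and batch_size must be >= 1")

    def bind(self, n_cells: int) -> "ScheduleConfig":
        steps_per_epoch = math.ceil(n_cells / self.batch_size)
        return dataclasses.replace(
            self,
            total_iterations=self.n_cycles * self.epochs_per_cycle * steps_per_epoch,
        )


@dataclasses.dataclass
class EmbeddingSnapshot:
    cycle_index: int
    embedding: np.ndarray
    train_loss_at_harvest: float


@dataclasses.dataclass
class EnsembleOfEmbeddings:
    snapshots: list[EmbeddingSnapshot]
    mode: str  # "snapshot" | "conventional"
    seed: int
    cell_ids: list[str]
    total_gradient_steps: int
    n_models_built: int
    loss_trace: list[float] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in {"snapshot", "conventional"}:
            raise ValidationError(f"unknown ensemble mode {self.mode!r}")
        shapes = {s.embedding.shape for s in self.snapshots}
        if len(shapes) > 1:
            raise ValidationError("snapshot embeddings have inconsistent shapes")

    @property
    def size(self) -> int:
        return len(self.snapshots)


def learning_rate(t: int, cfg: ScheduleConfig) -> float:
    """Evaluate the shifted-cosine cyclic schedule at optimizer step ``t`` (1-based)."""
    if cfg.total_iterations is None:
        raise ValidationError("schedule not bound: total_iterations is None")
    T, E = cfg.total_iterations, cfg.n_cycles
    if not 1 <= t <= T:
        raise ValidationError(f"iteration t={t} outside 1..{T}")
    cycle_len = math.ceil(T / E)
    phase = (t - 1) % cycle_len
    return cfg.initial_lr / 2.0 * (math.cos(math.pi * phase / cycle_len) + 1.0)


class _Adam:
    """Standard Adam with externally supplied per-step learning rate."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def reset(self) -> None:
        for k in self.m:
            self.m[k][:] = 0.0
            self.v[k][:] = 0.0
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            params[k] -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _train_one_model(
    dataset: MultimodalDataset,
    vae_cfg: VAEConfig,
    sched: ScheduleConfig,
    seed: int,
    harvest_each_cycle: bool,
    fixed_lr: Optional[float] = None,
) -> tuple[list[EmbeddingSnapshot], list[float], int]:
    """Train one VAE; harvest the full-data mu embedding at each cycle end
    (snapshot mode) or once at the end (conventional member)."""
    n = dataset.n_cells
    sched = sched.bind(n)
    ss = np.random.SeedSequence(seed)
    init_seed, shuffle_seed, eps_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    model = build_model(dataclasses.replace(vae_cfg, seed=init_seed))
    opt = _Adam(model.params)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    eps_rng = np.random.default_rng(eps_seed)

    x_full = {m: np.asarray(v, dtype=model.dtype) for m, v in dataset.modalities.items()}
    latent = vae_cfg.latent_dim

    snapshots: list[EmbeddingSnapshot] = []
    loss_trace: list[float] = []
    t = 0
    for cycle in range(1, sched.n_cycles + 1):
        if sched.reset_optimizer_per_cycle and cycle > 1:
            opt.reset()
        cycle_losses: list[float] = []
        for _ in range(sched.epochs_per_cycle):
            for idx in _epoch_batches(n, sched.batch_size, shuffle_rng):
                t += 1
                lr = fixed_lr if fixed_lr is not None else learning_rate(t, sched)
                xb = {m: v[idx] for m, v in x_full.items()}
                eps = eps_rng.standard_normal((len(idx), latent)).astype(model.dtype)
                lb, grads = model.loss_and_gradients(xb, eps)
                if not np.isfinite(lb.total):
                    raise TrainingError(f"non-finite loss at iteration {t}")
                _clip_gradients(grads, sched.max_grad_norm)
                opt.step(model.params, grads, lr)
                cycle_losses.append(lb.total)
        loss_trace.extend(cycle_losses)
        if harvest_each_cycle or cycle == sched.n_cycles:
            mu, _ = model.encode_arrays(x_full)
            snapshots.append(
                EmbeddingSnapshot(
                    cycle_index=cycle,
                    embedding=np.asarray(mu, dtype=np.float64),
                    train_loss_at_harvest=float(np.mean(cycle_losses)),
                )
            )
    return snapshots, loss_trace, t


def train_snapshot_ensemble(
    dataset: MultimodalDataset,
    vae_cfg: VAEConfig,
    sched: ScheduleConfig,
    seed: int = 0,
) -> EnsembleOfEmbeddings:
    """Train ONE model for E annealing cycles, harvesting E embedding snapshots."""
    snaps, trace, steps = _train_one_model(
        dataset, vae_cfg, sched, seed, harvest_each_cycle=True
    )
    return EnsembleOfEmbeddings(
        snapshots=snaps,
        mode="snapshot",
        seed=seed,
        cell_ids=list(dataset.cell_ids),
        total_gradient_steps=steps,
        n_models_built=1,
        loss_trace=trace,
    )


def train_conventional_ensemble(
    dataset: MultimodalDataset,
    vae_cfg: VAEConfig,
    n_models: int,
    epochs: int = 1,
    fixed_lr: float = 0.02,
    batch_size: int = 64,
    seed: int = 0,
) -> EnsembleOfEmbeddings:
    """Baseline ensemble: ``n_models`` independently initialized models, each
    trained ``epochs`` epochs at a constant learning rate; one embedding each."""
    if n_models < 1:
        raise ValidationError("n_models must be >= 1")
    member_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_models)
    ]
    sched = ScheduleConfig(
        initial_lr=fixed_lr, n_cycles=1, epochs_per_cycle=epochs, batch_size=batch_size
    )
    snapshots: list[EmbeddingSnapshot] = []
    trace: list[float] = []
    steps = 0
    for i, mseed in enumerate(member_seeds):
        snaps, member_trace, member_steps = _train_one_model(
            dataset, vae_cfg, sched, mseed, harvest_each_cycle=False, fixed_lr=fixed_lr
        )
        snap = snaps[-1]
        snap.cycle_index = i + 1
        snapshots.append(snap)
        trace.extend(member_trace)
        steps += member_steps
    return EnsembleOfEmbeddings(
        snapshots=snapshots,
        mode="conventional",
        seed=seed,
        cell_ids=list(dataset.cell_ids),
        total_gradient_steps=steps,
        n_models_built=n_models,
        loss_trace=trace,
    )


def save_ensemble(ensemble: EnsembleOfEmbeddings, out_dir: str | Path) -> None:
    """Write one CSV per snapshot plus a manifest.json with run metadata."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for snap in ensemble.snapshots:
        cols = [f"latent_{j + 1}" for j in range(snap.embedding.shape[1])]
        pd.DataFrame(snap.embedding, index=ensemble.cell_ids, columns=cols).to_csv(
            out / f"snapshot_{snap.cycle_index:03d}.csv"
        )
    manifest = {
        "mode": ensemble.mode,
        "seed": ensemble.seed,
        "n_snapshots": ensemble.size,
        "total_gradient_steps": ensemble.total_gradient_steps,
        "n_models_built": ensemble.n_models_built,
        "losses_at_harvest": [s.train_loss_at_harvest for s in ensemble.snapshots],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ensemble(in_dir: str | Path) -> EnsembleOfEmbeddings:
    import pandas as pd

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    snapshots = []
    cell_ids: list[str] = []
    for i, f in enumerate(sorted(in_dir.glob("snapshot_*.csv"))):
        df = pd.read_csv(f, index_col=0)
        cell_ids = [str(c) for c in df.index]
        snapshots.append(
            EmbeddingSnapshot(
                cycle_index=i + 1,
                embedding=df.to_numpy(dtype=float),
                train_loss_at_harvest=manifest["losses_at_harvest"][i]
                if i < len(manifest.get("losses_at_harvest", []))
                else float("nan"),
            )
        )
    return EnsembleOfEmbeddings(
        snapshots=snapshots,
        mode=manifest["mode"],
        seed=manifest["seed"],
        cell_ids=cell_ids,
        total_gradient_steps=manifest["total_gradient_steps"],
        n_models_built=manifest["n_models_built"],
    )
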