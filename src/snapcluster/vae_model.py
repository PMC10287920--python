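"""Multimodal variational autoencoder for joint embedding of omics modalities.

Each modality passes through its own encoder — a learnable point-wise
(per-feature) scaling layer followed by one fully connected hidden layer —
and the hidden outputs of all modalities are concatenated and mapped by a
shared fully connected layer to mean and log-variance heads over a
``latent_dim``-dimensional latent space. The decoder mirrors the encoder:
latent vector to per-modality hidden layers (same widths) to a linear
reconstruction of each modality.

The training objective is, per mini-batch,

    L = sum_m  mean_i || x_m,i - xhat_m,i ||^2  +  KL[ N(mu, sigma^2) || N(0, I) ]

with the Gaussian KL averaged over cells and computed once on the shared
latent (a flag restores the variant where KL is repeated inside the modality
sum, which with one shared latent simply rescales it by the number of
modalities). The model is implemented directly on numpy arrays with analytic
gradients, which keeps the whole pipeline dependency-light and exactly
reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from ._errors import ValidationError
from .io_preprocess import MultimodalDataset

__all__ = [
    "ModalitySpec",
    "VAEConfig",
    "LossBreakdown",
    "MultimodalVAE",
    "build_model",
    "encode",
    "reparameterize",
    "loss",
]

#: conventional encoder hidden widths by modality kind
DEFAULT_HIDDEN = {"rna": 185, "adt": 30, "atac": 185}


def default_hidden_width(name: str) -> int:
    """Pick the conventional hidden width for a modality by its name.

    Surface-protein (ADT) panels have orders of magnitude fewer features
    than RNA or ATAC-derived matrices, so they get a narrower encoder.
    """
    lowered = name.lower()
    for key, width in DEFAULT_HIDDEN.items():
        if key in lowered:
            return width
    return 185


@dataclasses.dataclass
class ModalitySpec:
    name: str
    n_features: int
    encoder_hidden: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValidationError(f"modality {self.name!r}: n_features must be >= 1")
        if self.encoder_hidden is None:
            self.encoder_hidden = default_hidden_width(self.name)
        if self.encoder_hidden < 1:
            raise ValidationError(f"modality {self.name!r}: encoder_hidden must be >= 1")


@dataclasses.dataclass
class VAEConfig:
    modality_specs: list[ModalitySpec]
    latent_dim: int = 100
    # tanh keeps hidden activations bounded, which is what lets training run
    # stably at the default initial learning rate of 0.02 without any
    # normalization layers; relu is available but needs a smaller rate
    activation: str = "tanh"
    seed: int = 0
    kl_in_modality_sum: bool = False
    reconstruction_reduction: str = "mean"  # per-cell mean, or "sum" over cells
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if not self.modality_specs:
            raise ValidationError("at least one modality spec required")
        if self.latent_dim < 2:
            raise ValidationError("latent_dim must be >= 2")
        if self.activation not in {"relu", "tanh"}:
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.reconstruction_reduction not in {"mean", "sum"}:
            raise ValidationError("reconstruction_reduction must be 'mean' or 'sum'")
        names = [s.name for s in self.modality_specs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate modality names in config")

    @classmethod
    def for_dataset(cls, dataset: MultimodalDataset, **kwargs) -> "VAEConfig":
        specs = [
            ModalitySpec(name=m, n_features=dataset.n_features(m))
            for m in dataset.modality_names
        ]
        return cls(modality_specs=specs, **kwargs)


@dataclasses.dataclass
class LossBreakdown:
    total: float
    reconstruction_per_modality: dict[str, float]
    kl: float


#: log-variance values are clamped to +/- this before exponentiation
_LOGVAR_LIMIT = 15.0


def _act(a: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(a, 0.0) if kind == "relu" else np.tanh(a)


def _act_grad(a: np.ndarray, h: np.ndarray, kind: str) -> np.ndarray:
    # h = act(a) is reused to avoid recomputing tanh
    return (a > 0).astype(a.dtype) if kind == "relu" else 1.0 - h * h


class MultimodalVAE:
    """The model object: parameter store plus forward/backward passes.

    Parameters live in ``self.params`` (a flat name -> array dict) so a
    generic optimizer can walk them. Construction is fully determined by the
    config seed.
    """

    def __init__(self, config: VAEConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        L = config.latent_dim
        H = sum(s.encoder_hidden for s in config.modality_specs)
        self.hidden_total = H
        p: dict[str, np.ndarray] = {}
        for s in config.modality_specs:
            d, h = s.n_features, s.encoder_hidden
            p[f"pw:{s.name}"] = np.ones(d, dtype=self.dtype)
            p[f"enc_W:{s.name}"] = (
                rng.standard_normal((d, h)) * np.sqrt(2.0 / d)
            ).astype(self.dtype)
            p[f"enc_b:{s.name}"] = np.zeros(h, dtype=self.dtype)
            p[f"dec_W1:{s.name}"] = (
                rng.standard_normal((L, h)) * np.sqrt(2.0 / L)
            ).astype(self.dtype)
            p[f"dec_b1:{s.name}"] = np.zeros(h, dtype=self.dtype)
            p[f"dec_W2:{s.name}"] = (
                rng.standard_normal((h, d)) * np.sqrt(1.0 / h)
            ).astype(self.dtype)
            p[f"dec_b2:{s.name}"] = np.zeros(d, dtype=self.dtype)
        p["mu_W"] = (rng.standard_normal((H, L)) * np.sqrt(1.0 / H)).astype(self.dtype)
        p["mu_b"] = np.zeros(L, dtype=self.dtype)
        p["lv_W"] = (rng.standard_normal((H, L)) * np.sqrt(1.0 / H)).astype(self.dtype)
        p["lv_b"] = np.zeros(L, dtype=self.dtype)
        self.params = p

    # ------------------------------------------------------------------ #

    @property
    def modality_names(self) -> list[str]:
        return [s.name for s in self.config.modality_specs]

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def _check_inputs(self, x: dict[str, np.ndarray]) -> None:
        for s in self.config.modality_specs:
            if s.name not in x:
                raise ValidationError(f"missing modality {s.name!r} in input")
            if x[s.name].shape[1] != s.n_features:
                raise ValidationError(
                    f"modality {s.name!r}: expected {s.n_features} features, "
                    f"got {x[s.name].shape[1]}"
                )

    def encode_arrays(
        self, x: dict[str, np.ndarray]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic encoder pass: returns (mu, logvar)."""
        self._check_inputs(x)
        cache = self._forward_encoder(x)
        return cache["mu"], cache["lv"]

    def _forward_encoder(self, x: dict[str, np.ndarray]) -> dict:
        cfg = self.config
        p = self.params
        cache: dict = {"x": {}, "u": {}, "a": {}, "h": {}}
        hs = []
        for s in cfg.modality_specs:
            xm = np.asarray(x[s.name], dtype=self.dtype)
            u = xm * p[f"pw:{s.name}"]
            a = u @ p[f"enc_W:{s.name}"] + p[f"enc_b:{s.name}"]
            h = _act(a, cfg.activation)
            cache["x"][s.name] = xm
            cache["u"][s.name] = u
            cache["a"][s.name] = a
            cache["h"][s.name] = h
            hs.append(h)
        hcat = np.concatenate(hs, axis=1)
        cache["hcat"] = hcat
        cache["mu"] = hcat @ p["mu_W"] + p["mu_b"]
        lv_raw = hcat @ p["lv_W"] + p["lv_b"]
        # clamp log-variance so exp() cannot overflow during training
        cache["lv_raw"] = lv_raw
        cache["lv"] = np.clip(lv_raw, -_LOGVAR_LIMIT, _LOGVAR_LIMIT)
        return cache

    def _forward_decoder(self, z: np.ndarray) -> dict:
        cfg = self.config
        p = self.params
        cache: dict = {"c": {}, "g": {}, "xhat": {}}
        for s in cfg.modality_specs:
            c = z @ p[f"dec_W1:{s.name}"] + p[f"dec_b1:{s.name}"]
            g = _act(c, cfg.activation)
            cache["c"][s.name] = c
            cache["g"][s.name] = g
            cache["xhat"][s.name] = g @ p[f"dec_W2:{s.name}"] + p[f"dec_b2:{s.name}"]
        return cache

    def decode_arrays(self, z: np.ndarray) -> dict[str, np.ndarray]:
        return self._forward_decoder(np.asarray(z, dtype=self.dtype))["xhat"]

    # ------------------------------------------------------------------ #

    def loss_and_gradients(
        self, x: dict[str, np.ndarray], eps: Optional[np.ndarray] = None
    ) -> tuple[LossBreakdown, dict[str, np.ndarray]]:
        """One training pass: reparameterized forward, loss, and dL/dparams.

        ``eps`` is the standard-normal noise used for reparameterization;
        pass ``None`` for a deterministic (z = mu) pass.
        """
        cfg = self.config
        p = self.params
        enc = self._forward_encoder(x)
        mu, lv = enc["mu"], enc["lv"]
        n = mu.shape[0]
        sigma = np.exp(0.5 * lv)
        if eps is None:
            z = mu
        else:
            eps = np.asarray(eps, dtype=self.dtype)
            if eps.shape != mu.shape:
                raise ValidationError("eps shape must match (n_cells, latent_dim)")
            z = mu + sigma * eps
        dec = self._forward_decoder(z)

        scale = 1.0 / n if cfg.reconstruction_reduction == "mean" else 1.0
        kl_weight = float(len(cfg.modality_specs)) if cfg.kl_in_modality_sum else 1.0

        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dz = np.zeros_like(z)
        recon: dict[str, float] = {}
        for s in cfg.modality_specs:
            name = s.name
            diff = dec["xhat"][name] - enc["x"][name]
            recon[name] = float(scale * np.sum(diff * diff))
            dxhat = (2.0 * scale) * diff
            g = dec["g"][name]
            grads[f"dec_W2:{name}"] = g.T @ dxhat
            grads[f"dec_b2:{name}"] = dxhat.sum(axis=0)
            dg = dxhat @ p[f"dec_W2:{name}"].T
            dc = dg * _act_grad(dec["c"][name], g, cfg.activation)
            grads[f"dec_W1:{name}"] = z.T @ dc
            grads[f"dec_b1:{name}"] = dc.sum(axis=0)
            dz += dc @ p[f"dec_W1:{name}"].T

        kl = float(kl_weight * scale * 0.5 * np.sum(mu * mu + sigma * sigma - 1.0 - lv))
        dmu = dz + (kl_weight * scale) * mu
        if eps is None:
            dlv = (kl_weight * scale * 0.5) * (sigma * sigma - 1.0)
        else:
            dlv = dz * (0.5 * sigma * eps) + (kl_weight * scale * 0.5) * (
                sigma * sigma - 1.0
            )

        dlv *= np.abs(enc["lv_raw"]) < _LOGVAR_LIMIT  # clip pass-through

        hcat = enc["hcat"]
        grads["mu_W"] = hcat.T @ dmu
        grads["mu_b"] = dmu.sum(axis=0)
        grads["lv_W"] = hcat.T @ dlv
        grads["lv_b"] = dlv.sum(axis=0)
        dh = dmu @ p["mu_W"].T + dlv @ p["lv_W"].T

        offset = 0
        for s in cfg.modality_specs:
            name = s.name
            h_w = s.encoder_hidden
            dhm = dh[:, offset : offset + h_w]
            offset += h_w
            da = dhm * _act_grad(enc["a"][name], enc["h"][name], cfg.activation)
            grads[f"enc_W:{name}"] = enc["u"][name].T @ da
            grads[f"enc_b:{name}"] = da.sum(axis=0)
            du = da @ p[f"enc_W:{name}"].T
            grads[f"pw:{name}"] = (du * enc["x"][name]).sum(axis=0)

        total = float(sum(recon.values()) + kl)
        return LossBreakdown(total=total, reconstruction_per_modality=recon, kl=kl), grads

    # ------------------------------------------------------------------ #

    def save(self, path: str | Path) -> None:
        """Serialize parameters (npz) with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.params)
        sidecar = path.with_suffix(".json")
        cfg = dataclasses.asdict(self.config)
        sidecar.write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MultimodalVAE":
        path = Path(path)
        cfg_raw = json.loads(path.with_suffix(".json").read_text())
        cfg_raw["modality_specs"] = [ModalitySpec(**s) for s in cfg_raw["modality_specs"]]
        model = cls(VAEConfig(**cfg_raw))
        with np.load(path if path.suffix == ".npz" else f"{path}.npz") as data:
            for k in model.params:
                model.params[k] = data[k]
        return model


def build_model(config: VAEConfig) -> MultimodalVAE:
    """Construct a seeded, reproducible model from a validated config."""
    return MultimodalVAE(config)


def encode(model: MultimodalVAE, dataset: MultimodalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Full-dataset encoder pass; rows follow the dataset's cell order."""
    names = set(model.modality_names)
    if set(dataset.modality_names) != names:
        raise ValidationError(
            f"dataset modalities {dataset.modality_names} do not match "
            f"model modalities {sorted(names)}"
        )
    mu, lv = model.encode_arrays(dataset.modalities)
    if not (np.isfinite(mu).all() and np.isfinite(lv).all()):
        raise ValidationError("non-finite values in encoder output")
    return mu, lv


def reparameterize(mu: np.ndarray, logvar: np.ndarray, seed: int) -> np.ndarray:
    """Sample z = mu + exp(logvar/2) * eps with seeded standard-normal eps."""
    mu = np.asarray(mu)
    logvar = np.asarray(logvar)
    if mu.shape != logvar.shape:
        raise ValidationError("mu and logvar shapes differ")
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    return mu + np.exp(0.5 * logvar) * eps


def loss(
    x: dict[str, np.ndarray],
    xhat: dict[str, np.ndarray],
    mu: np.ndarray,
    logvar: np.ndarray,
    kl_in_modality_sum: bool = False,
    reduction: str = "mean",
) -> LossBreakdown:
    """Standalone loss: per-modality squared reconstruction error plus Gaussian KL.

    Reconstruction per modality is the per-cell mean (default) of the squared
    Euclidean norm of the residual rows; KL is the matching mean of
    ``0.5 * sum_j (mu^2 + sigma^2 - 1 - log sigma^2)`` on the shared latent.
    """
    if set(x) != set(xhat):
        raise ValidationError("x and xhat have different modality names")
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if mu.shape != logvar.shape:
        raise ValidationError("mu and logvar shapes differ")
    n = mu.shape[0]
    scale = 1.0 / n if reduction == "mean" else 1.0
    recon: dict[str, float] = {}
    for name in x:
        a, b = np.asarray(x[name], dtype=float), np.asarray(xhat[name], dtype=float)
        if a.shape != b.shape:
            raise ValidationError(f"modality {name!r}: x and xhat shapes differ")
        if a.shape[0] != n:
            raise ValidationError(f"modality {name!r}: row count does not match mu")
        recon[name] = float(scale * np.sum((a - b) ** 2))
    sigma2 = np.exp(logvar)
    kl = float(0.5 * scale * np.sum(mu * mu + sigma2 - 1.0 - logvar))
    if kl_in_modality_sum:
        kl *= len(x)
    return LossBreakdown(
        total=float(sum(recon.values()) + kl),
        reconstruction_per_modality=recon,
        kl=kl,
    )
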