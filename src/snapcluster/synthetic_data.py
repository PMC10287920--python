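"""Synthetic multimodal single-cell data with known cell-type structure.

The generator emulates the *normalized* scale of CITE-seq / TEA-seq style
inputs rather than raw counts: every modality is a Gaussian matrix in which
an ``informative_fraction`` of features carry cell-type-specific mean shifts
of magnitude ``separation`` (in units of the within-type SD), and all
modalities share the SAME cell-type assignment — the cross-modality signal
an integration method is supposed to exploit. Optional dropout zeroes
entries independently, mimicking sparsity. A split-signal mode assigns each
modality a coarsening of the type labels (``modality_type_groups``) so that
no single modality can resolve every type contrast but their union can.

The default shape preset ("tea-seq-like") uses three modalities with very
different feature counts (RNA 2000, ADT 40, ATAC 2000) and nine cell types,
a desk-scale mirror of trimodal PBMC data.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from ._errors import ValidationError
from .io_preprocess import MultimodalDataset

__all__ = ["SyntheticSpec", "generate", "skewed_proportions", "subsample", "tea_seq_like"]

TEA_SEQ_LIKE_DIMS = {"rna": 2000, "adt": 40, "atac": 2000}


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one simulated multimodal dataset.

    separation is the SD of between-type mean shifts on informative
    features, in units of the within-type noise SD (0 = no class signal).
    """

    n_cells: int = 500
    type_proportions: Optional[np.ndarray] = None  # default: uniform over k
    k: int = 9
    modality_dims: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(TEA_SEQ_LIKE_DIMS)
    )
    separation: float = 3.0
    informative_fraction: float = 0.1
    dropout_rate: float = 0.0
    seed: int = 0
    modality_type_groups: Optional[dict[str, list[int]]] = None

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.k < 1:
            raise ValidationError("n_cells and k must be >= 1")
        if self.type_proportions is None:
            self.type_proportions = np.full(self.k, 1.0 / self.k)
        self.type_proportions = np.asarray(self.type_proportions, dtype=float)
        if self.type_proportions.size != self.k:
            raise ValidationError("type_proportions length must equal k")
        if abs(self.type_proportions.sum() - 1.0) > 1e-9 or (
            self.type_proportions < 0
        ).any():
            raise ValidationError("type_proportions must be a simplex vector")
        if not self.modality_dims or min(self.modality_dims.values()) < 1:
            raise ValidationError("modality_dims must map names to counts >= 1")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if not (0 < self.informative_fraction <= 1):
            raise ValidationError("informative_fraction must be in (0, 1]")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.modality_type_groups is not None:
            for m, groups in self.modality_type_groups.items():
                if m not in self.modality_dims:
                    raise ValidationError(f"groups given for unknown modality {m!r}")
                if len(groups) != self.k:
                    raise ValidationError(
                        f"modality {m!r}: group vector must have length k={self.k}"
                    )


def skewed_proportions(k: int, imbalance: float = 1.0) -> np.ndarray:
    """Geometric-decay type proportions p_j proportional to imbalance**(-j).

    imbalance=1 gives the uniform simplex; larger values skew abundance
    toward the leading (major) types.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if imbalance < 1:
        raise ValidationError("imbalance must be >= 1")
    p = imbalance ** (-np.arange(k, dtype=float))
    return p / p.sum()


def generate(spec: SyntheticSpec) -> MultimodalDataset:
    """Draw one dataset: shared type assignment, per-modality Gaussian matrices."""
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    types = rng.choice(k, size=spec.n_cells, p=spec.type_proportions)
    cell_ids = [f"cell_{i + 1:05d}" for i in range(spec.n_cells)]
    labels = [f"type_{t + 1}" for t in types]

    modalities: dict[str, np.ndarray] = {}
    feature_ids: dict[str, list[str]] = {}
    for name, d in spec.modality_dims.items():
        groups = (
            np.asarray(spec.modality_type_groups[name])
            if spec.modality_type_groups is not None
            and name in spec.modality_type_groups
            else np.arange(k)
        )
        n_groups = int(groups.max()) + 1
        n_inf = max(1, int(round(spec.informative_fraction * d)))
        informative = rng.choice(d, size=n_inf, replace=False)
        means = np.zeros((n_groups, d))
        means[:, informative] = spec.separation * rng.standard_normal(
            (n_groups, n_inf)
        )
        x = means[groups[types]] + rng.standard_normal((spec.n_cells, d))
        if spec.dropout_rate > 0:
            x[rng.random((spec.n_cells, d)) < spec.dropout_rate] = 0.0
        modalities[name] = x
        feature_ids[name] = [f"{name}_f{j + 1}" for j in range(d)]

    return MultimodalDataset(modalities, cell_ids, feature_ids, labels)


def subsample(dataset: MultimodalDataset, n_keep: int, seed: int = 0) -> MultimodalDataset:
    """Uniform random cell subset, consistent across modalities and labels."""
    if not (1 <= n_keep <= dataset.n_cells):
        raise ValidationError(
            f"n_keep must be in 1..{dataset.n_cells}, got {n_keep}"
        )
    idx = np.random.default_rng(seed).choice(dataset.n_cells, size=n_keep, replace=False)
    return dataset.select_cells(idx)


def tea_seq_like(
    n_cells: int = 500,
    k: int = 9,
    separation: float = 3.0,
    dropout_rate: float = 0.0,
    imbalance: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> MultimodalDataset:
    """Convenience preset: trimodal RNA/ADT/ATAC-shaped dataset."""
    props = skewed_proportions(k, imbalance) if imbalance > 1 else None
    spec = SyntheticSpec(
        n_cells=n_cells,
        k=k,
        type_proportions=props,
        separation=separation,
        dropout_rate=dropout_rate,
        seed=seed,
        **kwargs,
    )
    return generate(spec)
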