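"""Hard clustering of embeddings: seeded k-means and kNN spectral clustering.

k is supplied by the caller (conventionally the number of annotated cell
types); no model selection is performed. Labels are 1-based and compacted,
i.e. they densely use 1..k' for some k' <= k.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

from ._errors import ValidationError
from .snapshot_trainer import EnsembleOfEmbeddings

__all__ = [
    "Partition",
    "kmeans_cluster",
    "spectral_cluster",
    "cluster_ensemble",
    "write_partition",
    "read_partition",
]


@dataclasses.dataclass
class Partition:
    """Hard assignment of n cells to classes 1..k."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a nonempty 1-D vector")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValidationError("labels must lie in 1..k")

    @property
    def n_cells(self) -> int:
        return int(self.labels.size)

    @classmethod
    def from_zero_based(cls, labels: np.ndarray, k: Optional[int] = None) -> "Partition":
        labels = np.asarray(labels, dtype=int) + 1
        return cls(labels=labels, k=int(labels.max()) if k is None else k)

    def compact(self) -> "Partition":
        """Relabel so classes densely use 1..k' (sorted original order kept)."""
        uniq = np.unique(self.labels)
        remap = {old: new + 1 for new, old in enumerate(uniq)}
        return Partition(
            labels=np.array([remap[v] for v in self.labels]), k=len(uniq)
        )


def _validate_embedding(embedding: np.ndarray, k: int) -> np.ndarray:
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[0] == 0:
        raise ValidationError("embedding must be a nonempty 2-D matrix")
    if not np.isfinite(embedding).all():
        raise ValidationError("embedding contains non-finite values")
    if k > embedding.shape[0]:
        raise ValidationError(f"k={k} exceeds n_cells={embedding.shape[0]}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    return embedding


def kmeans_cluster(embedding: np.ndarray, k: int, seed: int = 0) -> Partition:
    """Seeded Lloyd k-means, best of 10 random starts (max 300 iters, tol 1e-6)."""
    embedding = _validate_embedding(embedding, k)
    if k == 1:
        return Partition(labels=np.ones(embedding.shape[0], dtype=int), k=1)
    km = KMeans(
        n_clusters=k, n_init=10, max_iter=300, tol=1e-6, random_state=seed % (2**31)
    ).fit(embedding)
    return Partition.from_zero_based(km.labels_, k=k).compact()


def spectral_cluster(
    embedding: np.ndarray, k: int, n_neighbors: int = 30, seed: int = 0
) -> Partition:
    """Spectral clustering on a symmetrized binary kNN affinity graph.

    Embedding rows in the k smallest eigenvectors of the symmetric normalized
    Laplacian are row-normalized and clustered with seeded k-means. If the
    graph splits into more connected components than k, an error is raised;
    with <= k components the component-indicator eigenvectors separate them
    automatically.
    """
    embedding = _validate_embedding(embedding, k)
    n = embedding.shape[0]
    if n_neighbors >= n:
        raise ValidationError("n_neighbors must be < n_cells")
    if k == 1:
        return Partition(labels=np.ones(n, dtype=int), k=1)
    adj = kneighbors_graph(embedding, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize; binary weights
    n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp > k:
        raise ValidationError(
            f"affinity graph has {n_comp} connected components > k={k}; "
            "increase n_neighbors"
        )
    deg = np.asarray(adj.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    # dense normalized adjacency: desk-scale n makes dense eigh robust and exact
    norm_adj = adj.toarray() * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(norm_adj)
    spec = eigvecs[:, -k:]  # top-k of normalized adjacency == bottom-k of Laplacian
    norms = np.linalg.norm(spec, axis=1, keepdims=True)
    spec = spec / np.maximum(norms, 1e-12)
    km = KMeans(
        n_clusters=k, n_init=10, max_iter=300, tol=1e-6, random_state=seed % (2**31)
    ).fit(spec)
    return Partition.from_zero_based(km.labels_, k=k).compact()


def cluster_ensemble(
    ensemble: EnsembleOfEmbeddings,
    algo: str = "kmeans",
    k: int = 2,
    seed: int = 0,
    n_neighbors: int = 30,
) -> list[Partition]:
    """Cluster every snapshot independently with sub-seeds derived from ``seed``."""
    if ensemble.size == 0:
        raise ValidationError("empty ensemble")
    if algo not in {"kmeans", "spectral"}:
        raise ValidationError(f"unknown clustering algorithm {algo!r}")
    sub_seeds = np.random.default_rng(seed).integers(2**31, size=ensemble.size)
    partitions: list[Partition] = []
    for i, snap in enumerate(ensemble.snapshots):
        try:
            if algo == "kmeans":
                partitions.append(kmeans_cluster(snap.embedding, k, int(sub_seeds[i])))
            else:
                partitions.append(
                    spectral_cluster(snap.embedding, k, n_neighbors, int(sub_seeds[i]))
                )
        except ValidationError as exc:
            raise ValidationError(f"snapshot {i + 1}: {exc}") from exc
    return partitions


def write_partition(path: str | Path, partition: Partition, cell_ids: list[str]) -> None:
    """Two-column TSV (cell_id, cluster)."""
    if len(cell_ids) != partition.n_cells:
        raise ValidationError("cell id count does not match partition length")
    lines = ["cell_id\tcluster"] + [
        f"{c}\t{l}" for c, l in zip(cell_ids, partition.labels)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_partition(path: str | Path) -> tuple[Partition, list[str]]:
    """Read a two-column TSV; non-integer cluster names are mapped to 1..k."""
    path = Path(path)
    cell_ids: list[str] = []
    raw: list[str] = []
    for i, ln in enumerate(path.read_text().splitlines()):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{i + 1}: expected 2 tab-separated columns")
        if i == 0 and parts[0].lower() in {"cell_id", "cell"}:
            continue
        cell_ids.append(parts[0])
        raw.append(parts[1])
    try:
        labels = np.array([int(v) for v in raw])
    except ValueError:
        name_map = {name: j + 1 for j, name in enumerate(dict.fromkeys(raw))}
        labels = np.array([name_map[v] for v in raw])
    return Partition(labels=labels, k=int(labels.max())).compact(), cell_ids
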