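"""Reading, writing and preprocessing of multimodal cell x feature matrices.

Supports dense CSV/TSV (header row = feature names, first column = cell ids)
and sparse MatrixMarket MTX with ``<stem>_rows.txt`` / ``<stem>_cols.txt``
plain-text name sidecars. Preprocessing implements per-feature prevalence
filtering, rare cell-type removal and per-feature z-score normalization —
the standard cleanup applied to CITE-seq / TEA-seq style inputs before the
modality encoders see them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._errors import UsageError, ValidationError

__all__ = [
    "MultimodalDataset",
    "FilterReport",
    "load_matrix",
    "write_matrix",
    "load_labels",
    "write_labels",
    "filter_low_prevalence",
    "filter_cells_by_feature_count",
    "filter_rare_cell_types",
    "zscore_normalize",
    "assemble_dataset",
    "load_dataset",
    "save_dataset",
    "preprocess_dataset",
]


@dataclasses.dataclass
class MultimodalDataset:
    """Aligned per-modality matrices over one shared cell axis.

    Parameters
    ----------
    modalities
        Ordered mapping modality name -> (n_cells, n_features) float array.
        All matrices share the same cell order.
    cell_ids
        Shared cell identifiers, one per row.
    feature_ids
        Per-modality feature (column) names.
    labels
        Optional cell-type annotation per cell, used for evaluation and for
        fixing k in clustering.
    """

    modalities: dict[str, np.ndarray]
    cell_ids: list[str]
    feature_ids: dict[str, list[str]]
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValidationError("dataset needs at least one modality")
        n = len(self.cell_ids)
        for name, mat in self.modalities.items():
            mat = np.asarray(mat)
            self.modalities[name] = mat
            if mat.ndim != 2 or mat.shape[0] != n:
                raise ValidationError(
                    f"modality {name!r}: expected {n} rows, got shape {mat.shape}"
                )
            if mat.shape[1] == 0:
                raise ValidationError(f"modality {name!r} has zero features")
            if name not in self.feature_ids:
                raise ValidationError(f"missing feature ids for modality {name!r}")
            if len(self.feature_ids[name]) != mat.shape[1]:
                raise ValidationError(
                    f"modality {name!r}: {len(self.feature_ids[name])} feature ids "
                    f"for {mat.shape[1]} columns"
                )
        if self.labels is not None and len(self.labels) != n:
            raise ValidationError(
                f"{len(self.labels)} labels for {n} cells"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def modality_names(self) -> list[str]:
        return list(self.modalities.keys())

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    def n_features(self, modality: str) -> int:
        return self.modalities[modality].shape[1]

    def select_cells(self, index: np.ndarray) -> "MultimodalDataset":
        """Return a dataset restricted to (or reordered by) a cell index array."""
        index = np.asarray(index)
        return MultimodalDataset(
            modalities={m: x[index] for m, x in self.modalities.items()},
            cell_ids=[self.cell_ids[i] for i in index],
            feature_ids={m: list(v) for m, v in self.feature_ids.items()},
            labels=None if self.labels is None else [self.labels[i] for i in index],
        )

    def select_modalities(self, names: Sequence[str]) -> "MultimodalDataset":
        missing = [n for n in names if n not in self.modalities]
        if missing:
            raise ValidationError(f"unknown modalities: {missing}")
        return MultimodalDataset(
            modalities={n: self.modalities[n] for n in names},
            cell_ids=list(self.cell_ids),
            feature_ids={n: list(self.feature_ids[n]) for n in names},
            labels=None if self.labels is None else list(self.labels),
        )


@dataclasses.dataclass
class FilterReport:
    """Bookkeeping for one filtering step."""

    modality: str
    features_removed: int = 0
    cells_removed: int = 0
    cell_types_removed: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features_removed < 0 or self.cells_removed < 0:
            raise ValidationError("filter counts must be non-negative")


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing MTX name sidecar: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def load_matrix(
    path: str | Path,
    fmt: str = "csv",
    orientation: str = "cells_by_features",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Load a matrix with row/column names, returned cells x features.

    ``fmt`` is one of ``csv``, ``tsv``, ``mtx``. For MTX, name sidecars
    ``<stem>_rows.txt`` and ``<stem>_cols.txt`` must sit next to the file.
    ``orientation`` declares how the file on disk is laid out; the returned
    matrix is always cells x features.
    """
    path = Path(path)
    if fmt not in {"csv", "tsv", "mtx"}:
        raise ValidationError(f"unknown format {fmt!r}")
    if orientation not in {"cells_by_features", "features_by_cells"}:
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")

    if fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            mat = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric value in {path}: {exc}") from exc
        row_names = [str(i) for i in df.index]
        col_names = [str(c) for c in df.columns]
    else:
        stem = path.with_suffix("")
        row_names = _read_sidecar(Path(f"{stem}_rows.txt"))
        col_names = _read_sidecar(Path(f"{stem}_cols.txt"))
        sparse = scipy.io.mmread(str(path))
        mat = np.asarray(scipy.sparse.coo_matrix(sparse).todense(), dtype=float)
        if mat.shape != (len(row_names), len(col_names)):
            raise ValidationError(
                f"{path}: matrix shape {mat.shape} does not match sidecar names "
                f"({len(row_names)} rows, {len(col_names)} cols)"
            )

    if mat.shape[0] != len(row_names) or mat.shape[1] != len(col_names):
        raise ValidationError(
            f"{path}: names ({len(row_names)}x{len(col_names)}) do not match "
            f"matrix shape {mat.shape}"
        )
    if orientation == "features_by_cells":
        mat = mat.T
        row_names, col_names = col_names, row_names
    return mat, row_names, col_names


def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
    fmt: str = "csv",
) -> None:
    """Write a cells x features matrix in the dialects :func:`load_matrix` reads."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(row_names), len(col_names)):
        raise ValidationError("names do not match matrix shape")
    if fmt in {"csv", "tsv"}:
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(matrix, index=list(row_names), columns=list(col_names)).to_csv(
            path, sep=sep
        )
    elif fmt == "mtx":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix))
        Path(f"{stem}_rows.txt").write_text("\n".join(row_names) + "\n")
        Path(f"{stem}_cols.txt").write_text("\n".join(col_names) + "\n")
    else:
        raise ValidationError(f"unknown format {fmt!r}")


def load_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (cell_id, label); a header line is optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    out: dict[str, str] = {}
    for i, ln in enumerate(path.read_text().splitlines()):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{i + 1}: expected 2 tab-separated columns")
        if i == 0 and parts[0].lower() in {"cell_id", "cell"}:
            continue
        out[parts[0]] = parts[1]
    return out


def write_labels(path: str | Path, cell_ids: Sequence[str], labels: Sequence[str]) -> None:
    lines = ["cell_id\tlabel"] + [f"{c}\t{l}" for c, l in zip(cell_ids, labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def filter_low_prevalence(
    matrix: np.ndarray,
    min_fraction: float = 0.01,
    feature_names: Optional[Sequence[str]] = None,
    modality: str = "",
) -> tuple[np.ndarray, Optional[list[str]], FilterReport]:
    """Drop features observed (nonzero) in strictly fewer than ``min_fraction`` of cells.

    The comparison is strict ``<``: a feature present in exactly the threshold
    fraction of cells is kept. Column order of survivors is preserved.
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValidationError("empty matrix")
    if not (0 < min_fraction <= 1):
        raise ValidationError("min_fraction must be in (0, 1]")
    frac = (matrix != 0).mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValidationError(
            "all features removed by prevalence filter; lower min_fraction"
        )
    report = FilterReport(modality=modality, features_removed=int((~keep).sum()))
    kept_names = (
        None
        if feature_names is None
        else [n for n, k in zip(feature_names, keep) if k]
    )
    return matrix[:, keep], kept_names, report


def filter_cells_by_feature_count(
    dataset: MultimodalDataset, min_features_per_cell: int
) -> tuple[MultimodalDataset, FilterReport]:
    """Optional symmetric filter: drop cells with too few detected features overall."""
    detected = sum(
        (np.asarray(x) != 0).sum(axis=1) for x in dataset.modalities.values()
    )
    keep = np.flatnonzero(detected >= min_features_per_cell)
    if keep.size == 0:
        raise ValidationError("cell filter removed every cell")
    report = FilterReport(modality="*", cells_removed=dataset.n_cells - keep.size)
    return dataset.select_cells(keep), report


def filter_rare_cell_types(
    dataset: MultimodalDataset, min_cells: int = 50
) -> tuple[MultimodalDataset, FilterReport]:
    """Remove all cells of any type annotated on fewer than ``min_cells`` cells."""
    if dataset.labels is None:
        raise UsageError("filter_rare_cell_types requires dataset labels")
    labels = np.asarray(dataset.labels)
    types, counts = np.unique(labels, return_counts=True)
    removed_types = [str(t) for t, c in zip(types, counts) if c < min_cells]
    keep = np.flatnonzero(~np.isin(labels, removed_types))
    if keep.size == 0:
        raise ValidationError("rare-type filter removed every cell")
    report = FilterReport(
        modality="*",
        cells_removed=dataset.n_cells - keep.size,
        cell_types_removed=removed_types,
    )
    if not removed_types:
        return dataset, report
    return dataset.select_cells(keep), report


def zscore_normalize(matrix: np.ndarray) -> np.ndarray:
    """Per-feature z-score: each column to mean 0 and unit sample (n-1) SD.

    Zero-variance columns map to all-zeros so feature dimensions stay
    predictable for the encoders.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValidationError("z-score needs a 2-D matrix with at least 2 cells")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    out = matrix - mean
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def assemble_dataset(
    matrices: dict[str, tuple[np.ndarray, Sequence[str], Sequence[str]]],
    labels: Optional[dict[str, str]] = None,
) -> MultimodalDataset:
    """Assemble a validated dataset from named (matrix, cell_ids, feature_ids) triples.

    All modalities must cover the same cell-id set; rows are realigned to the
    first modality's cell order when ids are permuted. Labels, if given, are a
    cell_id -> type mapping and must cover every cell.
    """
    if not matrices:
        raise ValidationError("no modalities given")
    names = list(matrices.keys())
    ref_ids = [str(c) for c in matrices[names[0]][1]]
    ref_set = set(ref_ids)
    if len(ref_set) != len(ref_ids):
        raise ValidationError(f"duplicate cell ids in modality {names[0]!r}")

    aligned: dict[str, np.ndarray] = {}
    feature_ids: dict[str, list[str]] = {}
    for name in names:
        mat, cids, fids = matrices[name]
        cids = [str(c) for c in cids]
        if set(cids) != ref_set:
            diff = sorted(set(cids) ^ ref_set)
            raise ValidationError(
                f"cell-id mismatch between {names[0]!r} and {name!r}: "
                f"symmetric difference {diff}"
            )
        pos = {c: i for i, c in enumerate(cids)}
        order = np.array([pos[c] for c in ref_ids])
        aligned[name] = np.asarray(mat, dtype=float)[order]
        feature_ids[name] = [str(f) for f in fids]

    label_list: Optional[list[str]] = None
    if labels is not None:
        missing = [c for c in ref_ids if c not in labels]
        if missing:
            raise ValidationError(f"labels missing for cells: {missing[:5]}")
        label_list = [labels[c] for c in ref_ids]
    return MultimodalDataset(aligned, ref_ids, feature_ids, label_list)


def save_dataset(dataset: MultimodalDataset, out_dir: str | Path, fmt: str = "csv") -> None:
    """Write one matrix file per modality plus ``labels.tsv`` if present."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"csv": "csv", "tsv": "tsv", "mtx": "mtx"}[fmt]
    for name, mat in dataset.modalities.items():
        write_matrix(
            out / f"{name}.{ext}", mat, dataset.cell_ids, dataset.feature_ids[name], fmt
        )
    if dataset.labels is not None:
        write_labels(out / "labels.tsv", dataset.cell_ids, dataset.labels)


def load_dataset(
    paths: dict[str, str | Path],
    fmt: str = "csv",
    orientation: str = "cells_by_features",
    labels_path: Optional[str | Path] = None,
) -> MultimodalDataset:
    """Load several modality files and an optional labels TSV into one dataset."""
    matrices = {
        name: load_matrix(p, fmt=fmt, orientation=orientation)
        for name, p in paths.items()
    }
    labels = None if labels_path is None else load_labels(labels_path)
    return assemble_dataset(matrices, labels)


def preprocess_dataset(
    dataset: MultimodalDataset,
    min_prevalence: Optional[float] = 0.01,
    min_cells_per_type: Optional[int] = 50,
    min_features_per_cell: Optional[int] = None,
    zscore: bool = True,
) -> tuple[MultimodalDataset, list[FilterReport]]:
    """Standard preprocessing chain: rare-type filter, prevalence filter,
    optional cell filter, then per-modality z-scoring.

    Any step can be disabled by passing ``None`` (or ``zscore=False``).
    """
    reports: list[FilterReport] = []
    if min_cells_per_type is not None and dataset.labels is not None:
        dataset, rep = filter_rare_cell_types(dataset, min_cells_per_type)
        reports.append(rep)
    if min_features_per_cell is not None:
        dataset, rep = filter_cells_by_feature_count(dataset, min_features_per_cell)
        reports.append(rep)
    modalities: dict[str, np.ndarray] = {}
    feature_ids: dict[str, list[str]] = {}
    for name, mat in dataset.modalities.items():
        fids: Sequence[str] | None = dataset.feature_ids[name]
        if min_prevalence is not None:
            mat, fids, rep = filter_low_prevalence(
                mat, min_prevalence, feature_names=fids, modality=name
            )
            reports.append(rep)
        if zscore:
            mat = zscore_normalize(mat)
        modalities[name] = mat
        feature_ids[name] = list(fids)  # type: ignore[arg-type]
    out = MultimodalDataset(
        modalities, list(dataset.cell_ids), feature_ids,
        None if dataset.labels is None else list(dataset.labels),
    )
    return out, reports
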