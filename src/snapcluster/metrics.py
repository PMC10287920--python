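"""Clustering concordance metrics: pair-counting ARI, log2-entropy NMI, and
major/minor cell-type splits.

ARI is computed from the four pair counts (N11, N00, N01, N10) over the
C(n,2) cell pairs:

    ARI = 2 (N00 N11 - N01 N10) /
          [ (N00 + N01)(N01 + N11) + (N00 + N10)(N10 + N11) ],

which is algebraically the chance-corrected (Hubert-Arabie) index. NMI uses
mutual information and entropies in bits; the default normalization is
2 I(U;V) / (H(U) + H(V)), with an alternative single-I variant
I(U;V) / (H(U) + H(V)) available as ``variant="as_printed"``.

Major cell types are those whose per-type cell count is at or above the
median count; minor types fall below it.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from ._errors import ValidationError
from .clustering import Partition

__all__ = [
    "PairCounts",
    "MetricReport",
    "pair_counts",
    "ari",
    "nmi",
    "split_major_minor",
    "evaluate",
]


@dataclasses.dataclass
class PairCounts:
    N11: int
    N00: int
    N01: int
    N10: int

    def __post_init__(self) -> None:
        if min(self.N11, self.N00, self.N01, self.N10) < 0:
            raise ValidationError("pair counts must be non-negative")


@dataclasses.dataclass
class MetricReport:
    ari: float
    nmi: float
    n_cells: int
    nmi_as_printed: Optional[float] = None
    per_split: Optional[dict[str, dict[str, float]]] = None


def _as_codes(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    cu, cv = _as_codes(u), _as_codes(v)
    table = np.zeros((cu.max() + 1, cv.max() + 1), dtype=np.int64)
    np.add.at(table, (cu, cv), 1)
    return table


def pair_counts(U: Sequence, V: Sequence) -> PairCounts:
    """Classify all C(n,2) item pairs by same/different class in U and V."""
    U, V = np.asarray(U), np.asarray(V)
    if U.shape != V.shape:
        raise ValidationError("label vectors differ in length")
    n = U.size
    if n < 2:
        raise ValidationError("need at least 2 items")
    table = _contingency(U, V)

    def comb2(x: np.ndarray) -> int:
        x = x.astype(np.int64)
        return int((x * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    n11 = comb2(table)
    n01 = comb2(table.sum(axis=1)) - n11  # same in U, different in V
    n10 = comb2(table.sum(axis=0)) - n11  # different in U, same in V
    n00 = total - n11 - n01 - n10
    return PairCounts(N11=n11, N00=n00, N01=n01, N10=n10)


def ari(U: Sequence, V: Sequence) -> float:
    """Adjusted Rand index from pair counts (1 = identical up to relabel)."""
    c = pair_counts(U, V)
    denom = (c.N00 + c.N01) * (c.N01 + c.N11) + (c.N00 + c.N10) * (c.N10 + c.N11)
    if denom == 0:
        return 1.0 if (c.N01 == 0 and c.N10 == 0) else 0.0
    return 2.0 * (c.N00 * c.N11 - c.N01 * c.N10) / denom


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_information_bits(U: np.ndarray, V: np.ndarray) -> float:
    table = _contingency(U, V).astype(float)
    n = table.sum()
    pu = table.sum(axis=1) / n
    pv = table.sum(axis=0) / n
    pij = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log2(pij / np.outer(pu, pv))
    return float(np.nansum(terms))


def nmi(U: Sequence, V: Sequence, variant: str = "sum2") -> float:
    """Normalized mutual information in bits.

    ``sum2`` (default): 2 I / (H(U)+H(V)), 1 for identical partitions.
    ``as_printed``: I / (H(U)+H(V)), 0.5 for identical partitions.
    Two trivial (single-class) partitions score 1.0 by convention.
    """
    if variant not in {"sum2", "as_printed"}:
        raise ValidationError(f"unknown NMI variant {variant!r}")
    U, V = np.asarray(U), np.asarray(V)
    if U.shape != V.shape:
        raise ValidationError("label vectors differ in length")
    hu, hv = _entropy_bits(U), _entropy_bits(V)
    if hu + hv == 0:
        return 1.0
    mi = _mutual_information_bits(U, V)
    num = 2.0 * mi if variant == "sum2" else mi
    return float(num / (hu + hv))


def split_major_minor(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of cells in major vs minor cell types.

    A type is major when its cell count is >= the median per-type count;
    otherwise minor (possibly empty, e.g. when all types are equally sized).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("labels are empty")
    types, counts = np.unique(labels, return_counts=True)
    median = np.median(counts)
    major_types = set(types[counts >= median])
    is_major = np.isin(labels, list(major_types))
    return np.flatnonzero(is_major), np.flatnonzero(~is_major)


def evaluate(
    partition: Partition,
    reference: Sequence,
    with_split: bool = False,
    both_nmi: bool = False,
) -> MetricReport:
    """Score a partition against reference cell-type labels.

    With ``with_split``, ARI/NMI are also computed on the major and minor
    cell subsets separately, reusing the partition's cluster ids restricted
    to each subset (no re-clustering). An empty minor set is omitted.
    """
    reference = np.asarray(reference)
    if reference.size != partition.n_cells:
        raise ValidationError("reference length does not match partition")
    report = MetricReport(
        ari=ari(reference, partition.labels),
        nmi=nmi(reference, partition.labels),
        n_cells=partition.n_cells,
        nmi_as_printed=nmi(reference, partition.labels, "as_printed")
        if both_nmi
        else None,
    )
    if with_split:
        major, minor = split_major_minor(reference)
        per_split: dict[str, dict[str, float]] = {}
        for name, idx in (("major", major), ("minor", minor)):
            if idx.size < 2:
                continue
            per_split[name] = {
                "ari": ari(reference[idx], partition.labels[idx]),
                "nmi": nmi(reference[idx], partition.labels[idx]),
                "n_cells": int(idx.size),
            }
        report.per_split = per_split
    return report
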