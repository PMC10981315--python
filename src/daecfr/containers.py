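"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np


class Catalog:
    """Ordered collection of unique entity identifiers with positional lookup.

    The order is significant: it fixes the row/column layout of every matrix
    built downstream, so two catalogs compare equal only when their identifier
    sequences match exactly.
    """

    __slots__ = ("ids", "index")

    def __init__(self, ids: Iterable[str]) -> None:
        ids = tuple(str(i) for i in ids)
        index: dict[str, int] = {}
        for pos, name in enumerate(ids):
            if name in index:
                raise ValueError(f"duplicate identifier {name!r}")
            index[name] = pos
        self.ids = ids
        self.index = index

    def position(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise KeyError(f"identifier {name!r} not in catalog") from None

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def __contains__(self, name: object) -> bool:
        return name in self.index

    def __getitem__(self, pos: int) -> str:
        return self.ids[pos]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Catalog) and self.ids == other.ids

    def __hash__(self) -> int:
        return hash(self.ids)

    def __repr__(self) -> str:
        return f"Catalog(n={len(self.ids)})"


@dataclass
class AssociationMatrix:
    """Binary entity-by-entity association matrix with identifier catalogs."""

    values: np.ndarray
    mirnas: Catalog
    diseases: Catalog

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if self.values.shape != (len(self.mirnas), len(self.diseases)):
            raise ValueError(
                f"shape {self.values.shape} does not match catalogs "
                f"({len(self.mirnas)}, {len(self.diseases)})"
            )
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8, copy=False)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.values.copy(), self.mirnas, self.diseases)


#: matrix roles recognised by :class:`SimilarityMatrix`
SIMILARITY_KINDS = (
    "KM", "KD", "FM", "SD1", "SD2", "SS", "SM", "SD", "LSM", "LSD",
)

_SYMMETRY_TOL = 1e-10


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity class.

    ``kind`` tags which stage of the pipeline produced the matrix; values
    must lie in [0, 1] and the matrix must be symmetric within 1e-10.
    """

    values: np.ndarray
    catalog: Catalog
    kind: str = "FM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.catalog)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {self.values.shape}")
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite values")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric (max |S-S^T| = {asym:.3g})")
        lo, hi = (self.values.min(), self.values.max()) if n else (0.0, 0.0)
        if lo < -1e-12 or hi > 1 + 1e-12:
            raise ValueError(f"similarity values outside [0, 1]: min={lo}, max={hi}")

    def __len__(self) -> int:
        return len(self.catalog)

    def row(self, pos: int) -> np.ndarray:
        return self.values[pos]


class TreeNumberMap:
    """Disease identifier -> set of dot-separated hierarchy codes."""

    __slots__ = ("entries",)

    def __init__(self, entries: Mapping[str, Iterable[str]] | None = None) -> None:
        self.entries: dict[str, frozenset[str]] = {}
        if entries:
            for disease, numbers in entries.items():
                numbers = frozenset(str(t) for t in numbers)
                for t in numbers:
                    validate_tree_number(t)
                if numbers:
                    self.entries[str(disease)] = numbers

    def get(self, disease: str) -> frozenset[str]:
        return self.entries.get(disease, frozenset())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, disease: object) -> bool:
        return disease in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TreeNumberMap) and self.entries == other.entries


def validate_tree_number(token: str) -> None:
    """Raise ValueError unless ``token`` is dot-separated alphanumeric."""
    segments = token.split(".")
    if not segments or any(not seg or not seg.isalnum() for seg in segments):
        raise ValueError(f"malformed tree number {token!r}")


@dataclass
class PairSet:
    """Labeled (miRNA index, disease index) pairs.

    ``pairs`` is an (n, 2) integer array; ``labels`` the parallel 0/1 vector.
    Pairs must be unique.
    """

    pairs: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.int8).reshape(-1)
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if len(self.pairs) and len(np.unique(self.pairs, axis=0)) != len(self.pairs):
            raise ValueError("duplicate pairs in PairSet")
        if len(self.labels) and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.pairs)

    def subset(self, idx: np.ndarray) -> "PairSet":
        return PairSet(self.pairs[idx], self.labels[idx])

    def as_tuples(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}
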