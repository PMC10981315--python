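"""Readers/writers for association lists, similarity matrices, hierarchy maps,
rankings and run configuration.

All external formats are plain delimited text (tab by default, comma via the
``delimiter`` argument) so that artifacts stay inspectable and diffable.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    AssociationMatrix,
    Catalog,
    SimilarityMatrix,
    TreeNumberMap,
    validate_tree_number,
)

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "mirna", "mi-rna", "mi_rna", "mirna_id", "mirnaid",
    "disease", "disease_id", "diseaseid",
    "tree", "tree_number", "treenumber", "mesh", "id", "name",
    "rank", "score", "label",
}


def _iter_records(path: str | Path, delimiter: str):
    """Yield (line_number, fields) skipping blanks, comments and a header row."""
    path = Path(path)
    first_data = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split(delimiter)]
            if first_data:
                first_data = False
                if all(f.lower() in _HEADER_TOKENS for f in fields):
                    continue
            yield lineno, fields


def read_association_list(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Build the binary association matrix from a two-column pair list.

    Catalogs are ordered by first appearance; duplicate pairs collapse to a
    single association.
    """
    mirna_ids: list[str] = []
    disease_ids: list[str] = []
    m_index: dict[str, int] = {}
    d_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for lineno, fields in _iter_records(path, delimiter):
        if len(fields) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
            )
        m, d = fields
        if m not in m_index:
            m_index[m] = len(mirna_ids)
            mirna_ids.append(m)
        if d not in d_index:
            d_index[d] = len(disease_ids)
            disease_ids.append(d)
        pairs.add((m_index[m], d_index[d]))
    if not pairs:
        raise ValueError(f"{path}: no associations")
    values = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    rows, cols = zip(*pairs)
    values[list(rows), list(cols)] = 1
    logger.info(
        "loaded %d miRNAs, %d diseases, %d associations from %s",
        len(mirna_ids), len(disease_ids), len(pairs), path,
    )
    return AssociationMatrix(values, Catalog(mirna_ids), Catalog(disease_ids))


def write_association_list(path: str | Path, A: AssociationMatrix, delimiter: str = "\t") -> None:
    """Serialize the ones of ``A`` back to a two-column pair list."""
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(("mirna", "disease")) + "\n")
        for i, j in np.argwhere(A.values == 1):
            fh.write(f"{A.mirnas[i]}{delimiter}{A.diseases[j]}\n")


def read_similarity_matrix(
    path: str | Path,
    catalog: Catalog,
    kind: str = "FM",
    delimiter: str = "\t",
) -> SimilarityMatrix:
    """Read a headered square similarity matrix, reordered to ``catalog``.

    Identifiers absent from the file get similarity 0 to every other entity
    (and 1 to themselves), which downstream triggers the kernel-only
    integration fallback for those rows.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity matrix is not square: {df.shape}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if set(df.index) != set(df.columns):
        raise ValueError(f"{path}: row and column identifiers differ")
    df = df[df.index]  # align column order with row order
    try:
        raw = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in similarity matrix") from exc
    if not np.isfinite(raw).all():
        raise ValueError(f"{path}: non-numeric cell in similarity matrix")
    asym = np.abs(raw - raw.T).max() if raw.size else 0.0
    if asym > 1e-8:
        raise ValueError(f"{path}: asymmetric similarity matrix (max |S-S^T| = {asym:.3g})")
    raw = 0.5 * (raw + raw.T)
    if raw.size and (raw.min() < -1e-9 or raw.max() > 1 + 1e-9):
        warnings.warn(
            f"{path}: similarity values outside [0, 1] clipped "
            f"(min={raw.min():.3g}, max={raw.max():.3g})",
            stacklevel=2,
        )
    raw = np.clip(raw, 0.0, 1.0)
    file_pos = {name: k for k, name in enumerate(df.index)}
    n = len(catalog)
    values = np.zeros((n, n))
    present = [i for i, name in enumerate(catalog) if name in file_pos]
    if present:
        src = [file_pos[catalog[i]] for i in present]
        values[np.ix_(present, present)] = raw[np.ix_(src, src)]
    np.fill_diagonal(values, np.where(np.diag(values) == 0, 1.0, np.diag(values)))
    missing = n - len(present)
    if missing:
        logger.info("%s: %d catalog identifiers missing from file, zero-filled", path, missing)
    return SimilarityMatrix(values, catalog, kind=kind)


def write_similarity_matrix(path: str | Path, S: SimilarityMatrix, delimiter: str = "\t") -> None:
    df = pd.DataFrame(S.values, index=list(S.catalog.ids), columns=list(S.catalog.ids))
    df.to_csv(path, sep=delimiter)


def read_tree_numbers(path: str | Path, delimiter: str = "\t") -> TreeNumberMap:
    """Read (disease-id, tree-number) lines, aggregating per disease."""
    entries: dict[str, set[str]] = {}
    for lineno, fields in _iter_records(path, delimiter):
        if len(fields) != 2:
            raise ValueError(
                f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
            )
        disease, token = fields
        try:
            validate_tree_number(token)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        entries.setdefault(disease, set()).add(token)
    return TreeNumberMap(entries)


def write_tree_numbers(path: str | Path, tree_map: TreeNumberMap, delimiter: str = "\t") -> None:
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(("disease", "tree_number")) + "\n")
        for disease in tree_map:
            for token in sorted(tree_map.get(disease)):
                fh.write(f"{disease}{delimiter}{token}\n")


def write_ranking(path: str | Path, ranking, delimiter: str = "\t") -> None:
    """Write a ranked candidate table; scores printed with 4 decimals.

    ``ranking`` is any iterable of (rank, miRNA-id, disease-id, score) rows,
    or an object exposing ``.rows`` of (rank, miRNA-id, score) plus a
    ``.disease`` attribute (the evaluation module's ranking table).
    """
    if hasattr(ranking, "rows") and hasattr(ranking, "disease"):
        rows = [(r, m, ranking.disease, s) for r, m, s in ranking.rows]
    else:
        rows = [tuple(r) for r in ranking]
    last = math.inf
    for row in rows:
        if len(row) != 4:
            raise ValueError("ranking rows must be (rank, mirna, disease, score)")
        if row[3] > last + 1e-12:
            raise ValueError("ranking scores must be non-increasing")
        last = row[3]
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(("rank", "mirna", "disease", "score")) + "\n")
        for rank, mirna, disease, score in rows:
            fh.write(f"{rank}{delimiter}{mirna}{delimiter}{disease}{delimiter}{score:.4f}\n")


def read_ranking(path: str | Path, delimiter: str = "\t") -> list[tuple[int, str, str, float]]:
    rows = []
    for lineno, fields in _iter_records(path, delimiter):
        if len(fields) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 fields")
        rows.append((int(fields[0]), fields[1], fields[2], float(fields[3])))
    return rows


_ALLOWED_L = (8, 16, 32, 64)


@dataclass
class Config:
    """Run parameters with pipeline defaults; see ``load_config``."""

    c: float = -8.0                      # logistic-transform slope
    L: int = 8                           # autoencoder latent width
    k_clusters: int = 23
    per_cluster: int = 240
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    batch_size: int = 100
    epochs: int = 100
    learning_rate: float = 1e-3
    hidden: int = 256
    delta: float = 0.5                   # semantic contribution decay
    gamma_prime: float = 1.0
    log_base: str = "e"                  # information-content log: "e" or "10"
    threshold: float = 0.5
    transform: bool = True               # logistic similarity transform on/off
    feature_mode: str = "combined"       # combined | association-only | similarity-only
    leakage_safe: bool = False
    resample_per_repeat: bool = True
    kmeans_n_init: int = 10
    kmeans_algorithm: str = "lloyd"      # lloyd | minibatch
    classifier: str = "logistic-regression"
    lr_strength: float = 1.0             # inverse-regularization C of the classifier
    max_iter: int = 1000
    assoc_path: str = ""
    fm_path: str = ""
    tree_path: str = ""
    out_dir: str = "."

    def __post_init__(self) -> None:
        if not (-15 <= self.c <= -1):
            raise ValueError(f"c={self.c} outside [-15, -1]")
        if self.L < 1:
            raise ValueError("L must be positive")
        if self.k_clusters < 1 or self.per_cluster < 1:
            raise ValueError("k_clusters and per_cluster must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.feature_mode not in ("combined", "association-only", "similarity-only"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.kmeans_algorithm not in ("lloyd", "minibatch"):
            raise ValueError(f"unknown kmeans_algorithm {self.kmeans_algorithm!r}")
        if self.log_base not in ("e", "10"):
            raise ValueError(f"log_base must be 'e' or '10', got {self.log_base!r}")
        if self.lr_strength <= 0:
            raise ValueError("lr_strength must be > 0")


_BOOL_FIELDS = {"transform", "leakage_safe", "resample_per_repeat"}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Parse a flat ``key = value`` config file and apply defaults.

    Lines starting with ``#`` and blank lines are ignored. Keyword overrides
    win over file values. An unknown key is an error.
    """
    field_types = {f.name: f.type for f in dataclasses.fields(Config)}
    kwargs: dict = {}
    if path is not None:
        for lineno, raw in enumerate(Path(path).open(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in field_types:
                raise ValueError(f"{path}: line {lineno}: unknown parameter {key!r}")
            kwargs[key] = _parse_value(key, value)
    kwargs.update(overrides)
    config = Config(**kwargs)
    if config.L not in _ALLOWED_L:
        warnings.warn(f"L={config.L} outside the usual grid {_ALLOWED_L}", stacklevel=2)
    return config


def _parse_value(key: str, value: str):
    if key in _BOOL_FIELDS:
        low = value.lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean {key}={value!r}")
    proto = getattr(Config, key)
    if isinstance(proto, bool):  # pragma: no cover - caught by _BOOL_FIELDS
        raise AssertionError
    if isinstance(proto, int):
        return int(value)
    if isinstance(proto, float):
        return float(value)
    return value


def write_config(path: str | Path, config: Config) -> None:
    with Path(path).open("w") as fh:
        for f in dataclasses.fields(Config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


def write_metrics(path: str | Path, metrics: dict, delimiter: str = "\t") -> None:
    with Path(path).open("w") as fh:
        fh.write(delimiter.join(("metric", "value")) + "\n")
        for name, value in metrics.items():
            fh.write(f"{name}{delimiter}{value:.4f}\n" if isinstance(value, float)
                     else f"{name}{delimiter}{value}\n")


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, row_ids: Sequence[str],
                     delimiter: str = "\t") -> None:
    """Persist a latent/feature matrix with row identifiers."""
    df = pd.DataFrame(np.asarray(matrix), index=list(row_ids))
    df.to_csv(path, sep=delimiter, header=True)
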