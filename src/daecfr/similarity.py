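"""Similarity computations.

Covers the Gaussian interaction-profile kernel, hierarchy-based semantic
similarity of diseases (two contribution models and their mean), integration
with functional/semantic similarity, and the logistic contrast transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, Catalog, SimilarityMatrix, TreeNumberMap

__all__ = [
    "DiseaseDAGForest",
    "gip_kernel",
    "build_dag_forest",
    "semantic_contribution_m1",
    "semantic_contribution_m2",
    "semantic_similarity_m1",
    "semantic_similarity_m2",
    "mean_semantic",
    "integrate",
    "logistic_transform",
    "transformed_similarities",
    "DEFAULT_OFFSET",
]

#: offset of the logistic transform; maps similarity 0 to exactly 1e-4
DEFAULT_OFFSET = math.log(9999.0)


def _finalize(values: np.ndarray, catalog: Catalog, kind: str) -> SimilarityMatrix:
    """Symmetrize, set unit diagonal and wrap."""
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, catalog, kind=kind)


def gip_kernel(
    A: AssociationMatrix,
    axis: str,
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian kernel over binary interaction profiles.

    ``axis='mirna'`` uses rows of the association matrix as profiles,
    ``axis='disease'`` uses rows of its transpose. The bandwidth is
    ``gamma_prime`` divided by the mean squared profile norm.
    """
    if axis in ("mirna", "miRNA", "m"):
        profiles = A.values.astype(np.float64)
        catalog, kind = A.mirnas, "KM"
    elif axis in ("disease", "d"):
        profiles = A.values.T.astype(np.float64)
        catalog, kind = A.diseases, "KD"
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    sq_norms = (profiles * profiles).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError("degenerate interaction profiles: association matrix is all-zero")
    gamma = gamma_prime / mean_sq
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    return _finalize(np.exp(-gamma * d2), catalog, kind)


@dataclass
class DiseaseDAGForest:
    """Per-disease ancestor DAGs derived from hierarchy tree numbers.

    ``nodes[d]`` is N(d): the disease plus every proper dot-prefix of its tree
    numbers, with prefixes resolved to disease identifiers when a catalog
    disease owns that exact tree number. ``edges[d]`` holds child->parent
    pairs. ``dag_count[t]`` counts the DAGs whose node set contains ``t``.
    """

    catalog: Catalog
    nodes: dict[str, frozenset[str]] = field(default_factory=dict)
    edges: dict[str, frozenset[tuple[str, str]]] = field(default_factory=dict)
    dag_count: dict[str, int] = field(default_factory=dict)

    @property
    def n_diseases(self) -> int:
        return len(self.catalog)

    def is_empty(self, disease: str) -> bool:
        return not self.nodes.get(disease)


def build_dag_forest(tree_map: TreeNumberMap, catalog: Catalog) -> DiseaseDAGForest:
    """Construct ancestor DAGs for every catalog disease with tree numbers.

    A disease with several tree numbers gets the union of the prefix chains,
    with the disease itself as the leaf of each chain. Diseases without tree
    numbers get empty DAGs (the integration step then falls back to the
    interaction-profile kernel for them).
    """
    owner: dict[str, str] = {}
    for disease in catalog:
        for token in tree_map.get(disease):
            owner.setdefault(token, disease)

    forest = DiseaseDAGForest(catalog)
    for disease in catalog:
        numbers = tree_map.get(disease)
        nodes: set[str] = set()
        edges: set[tuple[str, str]] = set()
        for token in numbers:
            segments = token.split(".")
            chain = []
            for k in range(1, len(segments) + 1):
                prefix = ".".join(segments[:k])
                chain.append(owner.get(prefix, prefix))
            chain[-1] = disease  # the full tree number is the disease itself
            nodes.update(chain)
            for child, parent in zip(chain[1:], chain[:-1]):
                if child != parent:
                    edges.add((child, parent))
        forest.nodes[disease] = frozenset(nodes)
        forest.edges[disease] = frozenset(edges)
        for node in nodes:
            forest.dag_count[node] = forest.dag_count.get(node, 0) + 1
    return forest


def semantic_contribution_m1(
    forest: DiseaseDAGForest, disease: str, delta: float = 0.5
) -> dict[str, float]:
    """Decay-based contribution of every DAG node toward ``disease``.

    The disease itself contributes 1; an ancestor contributes ``delta`` times
    the maximum contribution among its children inside the disease's DAG.
    """
    nodes = forest.nodes.get(disease)
    if not nodes:
        raise ValueError(f"disease {disease!r} has an empty DAG")
    contrib = {t: 0.0 for t in nodes}
    contrib[disease] = 1.0
    edges = forest.edges[disease]
    # monotone fixpoint; terminates because the DAG is acyclic and values only grow
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            cand = delta * contrib[child]
            if cand > contrib[parent] + 1e-15:
                contrib[parent] = cand
                changed = True
    return contrib


def semantic_contribution_m2(
    forest: DiseaseDAGForest, disease: str, log_base: str = "e"
) -> dict[str, float]:
    """Information-content contribution: -log(DAG frequency of the node).

    Depends only on the node, not on the disease whose DAG it sits in.
    """
    nodes = forest.nodes.get(disease)
    if not nodes:
        raise ValueError(f"disease {disease!r} has an empty DAG")
    log = math.log if log_base == "e" else math.log10
    n = forest.n_diseases
    contrib = {}
    for t in nodes:
        count = forest.dag_count.get(t, 0)
        if count <= 0:
            raise RuntimeError(f"internal inconsistency: dag_count({t!r}) = {count}")
        contrib[t] = -log(count / n)
    return contrib


def _semantic_matrix(
    forest: DiseaseDAGForest,
    contribs: dict[str, dict[str, float]],
    kind: str,
) -> SimilarityMatrix:
    catalog = forest.catalog
    n = len(catalog)
    totals = {d: sum(contribs[d].values()) for d in contribs}
    values = np.zeros((n, n))
    diseases = list(catalog)
    for i in range(n):
        di = diseases[i]
        if di not in contribs:
            continue
        ci, ni = contribs[di], forest.nodes[di]
        for j in range(i + 1, n):
            dj = diseases[j]
            if dj not in contribs:
                continue
            shared = ni & forest.nodes[dj]
            if not shared:
                continue
            denom = totals[di] + totals[dj]
            if denom == 0:
                continue
            cj = contribs[dj]
            num = sum(ci[t] + cj[t] for t in shared)
            values[i, j] = values[j, i] = num / denom
    return _finalize(values, catalog, kind)


def semantic_similarity_m1(
    forest: DiseaseDAGForest, delta: float = 0.5
) -> SimilarityMatrix:
    """Semantic similarity from the decay contribution model (tag SD1)."""
    contribs = {
        d: semantic_contribution_m1(forest, d, delta)
        for d in forest.catalog
        if not forest.is_empty(d)
    }
    return _semantic_matrix(forest, contribs, "SD1")


def semantic_similarity_m2(
    forest: DiseaseDAGForest, log_base: str = "e"
) -> SimilarityMatrix:
    """Semantic similarity from the information-content model (tag SD2)."""
    contribs = {
        d: semantic_contribution_m2(forest, d, log_base)
        for d in forest.catalog
        if not forest.is_empty(d)
    }
    return _semantic_matrix(forest, contribs, "SD2")


def mean_semantic(sd1: SimilarityMatrix, sd2: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise mean of the two semantic similarity models (tag SS)."""
    if sd1.catalog != sd2.catalog:
        raise ValueError("semantic similarity catalogs differ")
    return _finalize(0.5 * (sd1.values + sd2.values), sd1.catalog, "SS")


_INTEGRATED_KIND = {"KM": "SM", "KD": "SD"}


def integrate(K: SimilarityMatrix, S: SimilarityMatrix) -> SimilarityMatrix:
    """Blend kernel and functional/semantic similarity.

    Elementwise mean where ``S`` is nonzero; the kernel value elsewhere.
    """
    if K.catalog != S.catalog:
        raise ValueError("cannot integrate similarities over different catalogs")
    kind = _INTEGRATED_KIND.get(K.kind)
    if kind is None:
        raise ValueError(f"integrate expects a GIP kernel (KM/KD), got kind {K.kind!r}")
    values = np.where(S.values != 0, 0.5 * (K.values + S.values), K.values)
    return _finalize(values, K.catalog, kind)


def logistic_transform(
    S: SimilarityMatrix, c: float, d_param: float = DEFAULT_OFFSET
) -> SimilarityMatrix:
    """Contrast transform ``s -> 1 / (1 + exp(c*s + d))`` with ``c < 0``.

    With the default offset, similarity 0 maps to exactly 1e-4; the map is
    strictly increasing so it preserves the ordering of similarity values.
    """
    if c >= 0:
        raise ValueError(f"logistic transform requires c < 0, got c={c}")
    values = 1.0 / (1.0 + np.exp(c * S.values + d_param))
    values = 0.5 * (values + values.T)
    kind = "LSM" if S.kind in ("SM", "KM", "FM", "LSM") else "LSD"
    return SimilarityMatrix(values, S.catalog, kind=kind)


def transformed_similarities(
    A: AssociationMatrix,
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
    *,
    c: float = -8.0,
    transform: bool = True,
    gamma_prime: float = 1.0,
    delta: float = 0.5,
    log_base: str = "e",
    d_param: float = DEFAULT_OFFSET,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Full similarity stack: kernels -> integration -> optional transform.

    Returns the per-miRNA and per-disease similarity matrices used everywhere
    downstream (LSM/LSD when ``transform`` is on, SM/SD otherwise). ``FM``
    defaults to all-zero (kernel-only fallback); an empty or missing
    ``tree_map`` likewise leaves the disease side kernel-only.
    """
    KM = gip_kernel(A, "mirna", gamma_prime)
    KD = gip_kernel(A, "disease", gamma_prime)
    if FM is None:
        fm_values = np.zeros((A.n_mirnas, A.n_mirnas))
        np.fill_diagonal(fm_values, 1.0)
        FM = SimilarityMatrix(fm_values, A.mirnas, kind="FM")
    elif FM.catalog != A.mirnas:
        raise ValueError("FM catalog does not match association matrix miRNAs")
    if tree_map is None:
        tree_map = TreeNumberMap()
    forest = build_dag_forest(tree_map, A.diseases)
    SS = mean_semantic(
        semantic_similarity_m1(forest, delta),
        semantic_similarity_m2(forest, log_base),
    )
    SM = integrate(KM, FM)
    SD = integrate(KD, SS)
    if transform:
        return logistic_transform(SM, c, d_param), logistic_transform(SD, c, d_param)
    return SM, SD
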