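"""Synthetic datasets with the statistical structure the method assumes.

Planted datasets tie miRNA/disease blocks, functional similarity and the
disease hierarchy together so every pipeline stage carries recoverable
signal; null datasets break all of those links for calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, Catalog, TreeNumberMap

__all__ = [
    "FixtureSpec",
    "generate_dataset",
    "null_dataset",
    "holdout_one_per_disease",
    "generate_toy_dag_cases",
    "generate_association_list",
]


@dataclass
class FixtureSpec:
    """Parameters of the planted generator.

    Besides block structure, entities carry multiplicative association
    propensities with a small high-propensity "hub" tier on the miRNA side.
    Real association catalogs are strongly hub-dominated, and the hub tier is
    what makes the planted signal recoverable by a linear classifier over
    per-side codes (block membership alone is a parity-style interaction that
    an additive model cannot express).
    """

    n_m: int = 200
    n_d: int = 150
    n_blocks: int = 6
    density: float = 0.03
    dag_depth: int = 4
    fm_noise: float = 0.1
    holdout_fraction: float = 0.1
    seed: int = 0
    hub_fraction: float = 0.08
    hub_strength: float = 25.0
    propensity_sigma: float = 0.5
    block_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.n_m < 2 or self.n_d < 2:
            raise ValueError("entity counts must be >= 2")
        if not (0 < self.density < 0.5):
            raise ValueError("density must lie in (0, 0.5)")
        if not (0 <= self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must lie in [0, 1)")
        if self.n_blocks < 1 or self.dag_depth < 2:
            raise ValueError("n_blocks >= 1 and dag_depth >= 2 required")
        if not (0 <= self.hub_fraction <= 1) or self.hub_strength < 1:
            raise ValueError("hub_fraction in [0, 1] and hub_strength >= 1 required")
        if self.propensity_sigma < 0 or self.block_boost < 1:
            raise ValueError("propensity_sigma >= 0 and block_boost >= 1 required")


def _catalogs(spec: FixtureSpec) -> tuple[Catalog, Catalog]:
    mirnas = Catalog([f"m{i:04d}" for i in range(spec.n_m)])
    diseases = Catalog([f"d{j:04d}" for j in range(spec.n_d)])
    return mirnas, diseases


def _pair_probabilities(
    spec: FixtureSpec,
    m_blocks: np.ndarray,
    d_blocks: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-pair association probabilities: propensity product x block boost.

    The raw rates are rescaled so their mean hits the target density, then
    clipped to 0.9; if clipping would swallow most of the mass the density is
    infeasible for the configured propensity spread.
    """
    n_hub = max(1, round(spec.hub_fraction * spec.n_m)) if spec.hub_fraction > 0 else 0
    s = np.ones(spec.n_m)
    if n_hub:
        s[rng.choice(spec.n_m, size=n_hub, replace=False)] = spec.hub_strength
    s = s * rng.lognormal(0.0, spec.propensity_sigma, spec.n_m)
    t = rng.lognormal(0.0, spec.propensity_sigma, spec.n_d)
    same = m_blocks[:, None] == d_blocks[None, :]
    raw = s[:, None] * t[None, :] * np.where(same, spec.block_boost, 1.0)
    probs = np.clip(raw * (spec.density / raw.mean()), 0.0, 0.9)
    if probs.mean() < 0.25 * spec.density:
        raise ValueError(f"density {spec.density} infeasible for the propensity spread")
    return probs


def _block_fm(blocks: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    same = blocks[:, None] == blocks[None, :]
    fm = np.where(same, 0.7, 0.1).astype(np.float64)
    if noise > 0:
        raw = rng.normal(0.0, noise, size=fm.shape)
        fm = fm + 0.5 * (raw + raw.T)
    fm = np.clip(fm, 0.0, 1.0)
    np.fill_diagonal(fm, 1.0)
    return fm


def _block_tree_numbers(
    diseases: Catalog,
    d_blocks: np.ndarray,
    dag_depth: int,
    rng: np.random.Generator,
) -> TreeNumberMap:
    """Random hierarchy whose subtrees align with disease blocks.

    Each block gets a root and a few internal nodes; each disease hangs a
    unique leaf token below a random internal path of depth < dag_depth, so
    diseases sharing a block share ancestors (and some diseases get a second
    path to exercise the multi-tree-number union rule).
    """
    entries: dict[str, set[str]] = {}
    n_blocks = int(d_blocks.max()) + 1 if len(d_blocks) else 0
    internal_paths: list[list[str]] = []
    for b in range(n_blocks):
        root = f"R{b:02d}"
        paths = [[root]]
        for k in range(3):  # a few internal chains of random depth
            depth = int(rng.integers(1, max(2, dag_depth - 1)))
            path = [root] + [f"I{b:02d}N{k}{lvl}" for lvl in range(depth)]
            paths.append(path[: dag_depth - 1])
        internal_paths.append(paths)
    for j, disease in enumerate(diseases):
        b = int(d_blocks[j])
        paths = internal_paths[b]
        base = paths[int(rng.integers(len(paths)))]
        leaf = f"Z{j:04d}"
        numbers = {".".join(base + [leaf])}
        if rng.random() < 0.2:  # second tree number within the same block
            alt = paths[int(rng.integers(len(paths)))]
            numbers.add(".".join(alt + [f"Y{j:04d}"]))
        entries[disease] = numbers
    return TreeNumberMap(entries)


def generate_dataset(
    spec: FixtureSpec,
) -> tuple[AssociationMatrix, np.ndarray, TreeNumberMap, np.ndarray]:
    """Planted-block dataset.

    Returns (A, FM values, tree-number map, held-out positive index pairs);
    the held-out positives are zeroed in A and serve as retrieval ground
    truth. FM is returned as a raw matrix aligned with A's miRNA catalog.
    """
    rng = np.random.default_rng(spec.seed)
    mirnas, diseases = _catalogs(spec)
    m_blocks = rng.integers(0, spec.n_blocks, size=spec.n_m)
    d_blocks = rng.integers(0, spec.n_blocks, size=spec.n_d)
    probs = _pair_probabilities(spec, m_blocks, d_blocks, rng)
    values = (rng.random((spec.n_m, spec.n_d)) < probs).astype(np.int8)

    positives = np.argwhere(values == 1)
    n_hold = int(math.floor(spec.holdout_fraction * len(positives)))
    heldout = np.empty((0, 2), dtype=np.intp)
    if n_hold > 0:
        pick = rng.choice(len(positives), size=n_hold, replace=False)
        heldout = positives[np.sort(pick)].astype(np.intp)
        values[heldout[:, 0], heldout[:, 1]] = 0
    if values.sum() == 0:
        raise ValueError("density infeasible: generated matrix has no positives")

    fm = _block_fm(m_blocks, spec.fm_noise, rng)
    tree_map = _block_tree_numbers(diseases, d_blocks, spec.dag_depth, rng)
    A = AssociationMatrix(values, mirnas, diseases)
    return A, fm, tree_map, heldout


def null_dataset(
    spec: FixtureSpec,
) -> tuple[AssociationMatrix, np.ndarray, TreeNumberMap]:
    """Structure-free control: i.i.d. associations, unrelated FM and hierarchy."""
    rng = np.random.default_rng(spec.seed)
    mirnas, diseases = _catalogs(spec)
    values = (rng.random((spec.n_m, spec.n_d)) < spec.density).astype(np.int8)
    if values.sum() == 0:
        raise ValueError("density infeasible: null matrix has no positives")
    # FM and the hierarchy use block labels drawn independently of A
    m_blocks = rng.integers(0, spec.n_blocks, size=spec.n_m)
    d_blocks = rng.integers(0, spec.n_blocks, size=spec.n_d)
    fm = _block_fm(m_blocks, max(spec.fm_noise, 0.05), rng)
    tree_map = _block_tree_numbers(diseases, d_blocks, spec.dag_depth, rng)
    return AssociationMatrix(values, mirnas, diseases), fm, tree_map


def holdout_one_per_disease(
    A: AssociationMatrix, seed: int = 0
) -> tuple[AssociationMatrix, np.ndarray]:
    """Remove one known positive per disease (where >= 2 exist).

    Returns the thinned matrix and the removed index pairs; used as ground
    truth for case-study retrieval checks.
    """
    rng = np.random.default_rng(seed)
    values = A.values.copy()
    held = []
    for j in range(A.n_diseases):
        rows = np.flatnonzero(values[:, j] == 1)
        if len(rows) >= 2:
            held.append((int(rng.choice(rows)), j))
    heldout = np.array(held, dtype=np.intp).reshape(-1, 2)
    values[heldout[:, 0], heldout[:, 1]] = 0
    return AssociationMatrix(values, A.mirnas, A.diseases), heldout


@dataclass
class ToyDAGCase:
    """Hand-computed semantic-similarity oracle case."""

    name: str
    catalog: Catalog
    tree_map: TreeNumberMap
    expected_sd1: np.ndarray
    expected_sd2: np.ndarray


def generate_toy_dag_cases() -> list[ToyDAGCase]:
    """Small forests with closed-form expected similarity matrices.

    Expected values were derived by hand (decay 0.5, natural log information
    content) and are frozen here independently of the similarity module.
    """
    cases = []

    # four diseases, three sharing parent P, one apart under Q
    catalog = Catalog(["d1", "d2", "d3", "d4"])
    tree_map = TreeNumberMap({
        "d1": {"P.A"}, "d2": {"P.B"}, "d3": {"P.C"}, "d4": {"Q.Z"},
    })
    # D1: leaf 1, P 0.5 -> DV1 = 1.5; shared {P}: (0.5+0.5)/3 = 1/3
    sd1 = np.eye(4)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        sd1[i, j] = sd1[j, i] = 1.0 / 3.0
    # D2: P in 3 of 4 DAGs -> ln(4/3); each leaf in 1 of 4 -> ln 4
    p = math.log(4.0 / 3.0)
    leaf = math.log(4.0)
    sd2 = np.eye(4)
    for i, j in ((0, 1), (0, 2), (1, 2)):
        sd2[i, j] = sd2[j, i] = (2 * p) / (2 * (leaf + p))
    cases.append(ToyDAGCase("shared-parent", catalog, tree_map, sd1, sd2))

    # chain: both diseases two levels below a common grandparent G
    catalog = Catalog(["d1", "d2"])
    tree_map = TreeNumberMap({"d1": {"G.P.A"}, "d2": {"G.P.B"}})
    # N = {leaf, P, G}; D1 = 1, .5, .25 -> DV1 = 1.75; shared {P, G}
    sd1 = np.array([[1.0, 1.5 / 3.5], [1.5 / 3.5, 1.0]])
    # both P and G in 2 of 2 DAGs -> D2 = 0; leaves ln 2; shared contributions 0
    # DV2 = ln 2 > 0, so similarity is 0 off-diagonal
    sd2 = np.eye(2)
    cases.append(ToyDAGCase("chain", catalog, tree_map, sd1, sd2))

    # multi-path: d1 reaches X both directly and through Y; max rule applies
    catalog = Catalog(["d1", "d2"])
    tree_map = TreeNumberMap({"d1": {"X.Y.Z1", "X.Z1"}, "d2": {"X.W"}})
    # N(d1) = {d1, Y', X} with D1(X) = max(.5*1, .5*.5) = .5, D1(Y') = .5
    # DV1(d1) = 2.0; N(d2) = {d2, X}, DV1 = 1.5; shared {X}: (0.5+0.5)/3.5
    sd1 = np.array([[1.0, 1.0 / 3.5], [1.0 / 3.5, 1.0]])
    # X in both DAGs -> 0; X.Y only in d1 -> ln 2; leaves ln 2
    # shared {X} contributes 0; DV2 positive -> off-diagonal 0
    sd2 = np.eye(2)
    cases.append(ToyDAGCase("multi-path", catalog, tree_map, sd1, sd2))

    # disjoint hierarchies
    catalog = Catalog(["d1", "d2"])
    tree_map = TreeNumberMap({"d1": {"A.B"}, "d2": {"C.D"}})
    cases.append(ToyDAGCase("disjoint", catalog, tree_map, np.eye(2), np.eye(2)))

    # one disease with an empty DAG: similarity to everything else is 0
    catalog = Catalog(["d1", "d2"])
    tree_map = TreeNumberMap({"d1": {"A.B"}})
    cases.append(ToyDAGCase("empty-dag", catalog, tree_map, np.eye(2), np.eye(2)))

    return cases


def generate_association_list(
    n_m: int, n_d: int, n_pairs: int, seed: int = 0
) -> list[tuple[str, str]]:
    """Random association list with exact entity and pair counts.

    Every miRNA and disease appears at least once and the distinct pair count
    is exactly ``n_pairs``; used to emulate database-scale inputs whose only
    published characteristics are those counts. Requires n_m >= n_d and
    n_pairs >= n_m.
    """
    if n_m < n_d:
        raise ValueError("generator assumes n_m >= n_d")
    if not (n_m <= n_pairs <= n_m * n_d):
        raise ValueError("n_pairs must lie in [n_m, n_m * n_d]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_d)
    pairs = {(i, int(perm[i % n_d])) for i in range(n_m)}
    while len(pairs) < n_pairs:
        need = n_pairs - len(pairs)
        cand_i = rng.integers(0, n_m, size=2 * need + 16)
        cand_j = rng.integers(0, n_d, size=2 * need + 16)
        for i, j in zip(cand_i, cand_j):
            pairs.add((int(i), int(j)))
            if len(pairs) == n_pairs:
                break
    ordered = sorted(pairs)
    rng.shuffle(ordered)
    return [(f"m{i:04d}", f"d{j:04d}") for i, j in ordered]
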