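"""Class balancing: pair universe construction and k-means negative sampling."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans

from .containers import AssociationMatrix, PairSet, SimilarityMatrix

__all__ = [
    "SamplingPlan",
    "build_pair_universe",
    "pair_cluster_features",
    "kmeans_negative_sample",
    "assemble_training_set",
]


@dataclass
class SamplingPlan:
    """Parameters of the negative-sampling stage.

    ``algorithm='minibatch'`` switches the clustering to mini-batch updates;
    useful at full database scale where exact Lloyd iterations with several
    restarts are unnecessarily slow for a sampling step.
    """

    k_clusters: int = 23
    per_cluster: int = 240
    seed: int = 0
    n_init: int = 10
    algorithm: str = "lloyd"
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.per_cluster < 1:
            raise ValueError("per_cluster must be >= 1")
        if self.algorithm not in ("lloyd", "minibatch"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def build_pair_universe(A: AssociationMatrix) -> tuple[PairSet, PairSet]:
    """Split all (miRNA, disease) index pairs into positives and negatives."""
    pos_idx = np.argwhere(A.values == 1)
    neg_idx = np.argwhere(A.values == 0)
    positives = PairSet(pos_idx, np.ones(len(pos_idx), dtype=np.int8))
    negatives = PairSet(neg_idx, np.zeros(len(neg_idx), dtype=np.int8))
    return positives, negatives


def pair_cluster_features(
    pairs: PairSet, LSM: SimilarityMatrix, LSD: SimilarityMatrix
) -> np.ndarray:
    """Represent each pair (i, j) as [row i of LSM, row j of LSD] (float32)."""
    n_m, n_d = len(LSM), len(LSD)
    idx = pairs.pairs
    if len(idx) and (idx[:, 0].max() >= n_m or idx[:, 1].max() >= n_d):
        raise IndexError("pair index out of bounds for similarity matrices")
    out = np.empty((len(idx), n_m + n_d), dtype=np.float32)
    out[:, :n_m] = LSM.values[idx[:, 0]]
    out[:, n_m:] = LSD.values[idx[:, 1]]
    return out


def kmeans_negative_sample(
    negatives: PairSet, features: np.ndarray, plan: SamplingPlan
) -> PairSet:
    """Cluster the negative universe and draw ``per_cluster`` pairs per group.

    Clusters smaller than ``per_cluster`` contribute all members; the deficit
    is drawn uniformly from not-yet-chosen negatives of the other clusters so
    the result has exactly ``k_clusters * per_cluster`` distinct pairs.
    """
    n = len(negatives)
    target = plan.k_clusters * plan.per_cluster
    if n < target:
        raise ValueError(
            f"insufficient negatives: {n} available, {target} requested"
        )
    if features.shape[0] != n:
        raise ValueError("feature matrix row count does not match negatives")
    if plan.algorithm == "minibatch":
        km = MiniBatchKMeans(
            n_clusters=plan.k_clusters, n_init=plan.n_init,
            max_iter=plan.max_iter, random_state=plan.seed, batch_size=1024,
        )
    else:
        km = KMeans(
            n_clusters=plan.k_clusters, n_init=plan.n_init,
            max_iter=plan.max_iter, random_state=plan.seed,
        )
    assignment = km.fit_predict(features)

    rng = np.random.default_rng(plan.seed)
    chosen: list[np.ndarray] = []
    leftovers: list[np.ndarray] = []
    for cluster in range(plan.k_clusters):
        members = np.flatnonzero(assignment == cluster)
        if len(members) <= plan.per_cluster:
            chosen.append(members)
        else:
            picked = rng.choice(members, size=plan.per_cluster, replace=False)
            chosen.append(picked)
            leftovers.append(np.setdiff1d(members, picked))
    chosen_idx = np.concatenate(chosen) if chosen else np.empty(0, dtype=np.intp)
    deficit = target - len(chosen_idx)
    if deficit > 0:
        pool = np.concatenate(leftovers)
        topup = rng.choice(pool, size=deficit, replace=False)
        chosen_idx = np.concatenate([chosen_idx, topup])
    chosen_idx = np.sort(chosen_idx)
    return PairSet(negatives.pairs[chosen_idx], np.zeros(target, dtype=np.int8))


def assemble_training_set(
    positives: PairSet, sampled_negatives: PairSet, seed: int = 0
) -> PairSet:
    """Concatenate positives and sampled negatives, shuffled under ``seed``."""
    overlap = positives.as_tuples() & sampled_negatives.as_tuples()
    if overlap:
        raise ValueError(f"positives and negatives overlap on {len(overlap)} pairs")
    pairs = np.concatenate([positives.pairs, sampled_negatives.pairs])
    labels = np.concatenate(
        [np.ones(len(positives), dtype=np.int8), np.zeros(len(sampled_negatives), dtype=np.int8)]
    )
    perm = np.random.default_rng(seed).permutation(len(pairs))
    return PairSet(pairs[perm], labels[perm])
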