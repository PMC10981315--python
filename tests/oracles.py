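"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computation paths: semantic
similarity is rebuilt from explicit path enumeration over a networkx graph,
and AUC from pairwise Mann-Whitney comparison.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def dag_node_sets(tree_map, catalog):
    """N(d) per disease via prefix expansion and owner resolution."""
    owner = {}
    for d in catalog:
        for token in tree_map.get(d):
            owner.setdefault(token, d)
    node_sets = {}
    graphs = {}
    for d in catalog:
        g = nx.DiGraph()  # edges child -> parent
        for token in tree_map.get(d):
            segs = token.split(".")
            chain = []
            for k in range(1, len(segs) + 1):
                prefix = ".".join(segs[:k])
                chain.append(owner.get(prefix, prefix))
            chain[-1] = d
            for node in chain:
                g.add_node(node)
            for child, parent in zip(chain[1:], chain[:-1]):
                if child != parent:
                    g.add_edge(child, parent)
        node_sets[d] = set(g.nodes)
        graphs[d] = g
    return node_sets, graphs


def contributions_m1(graphs, d, delta=0.5):
    """D1 via shortest ascending path: max over paths of delta^length."""
    g = graphs[d]
    dist = nx.single_source_shortest_path_length(g, d)
    return {t: delta ** dist[t] for t in g.nodes if t in dist}


def contributions_m2(node_sets, d, n_diseases):
    counts = {}
    for t in node_sets[d]:
        counts[t] = sum(1 for other in node_sets.values() if t in other)
    return {t: -math.log(c / n_diseases) for t, c in counts.items()}


def _pair_similarity(contrib_i, contrib_j):
    shared = set(contrib_i) & set(contrib_j)
    denom = sum(contrib_i.values()) + sum(contrib_j.values())
    if not shared or denom == 0:
        return 0.0
    return sum(contrib_i[t] + contrib_j[t] for t in shared) / denom


def semantic_matrix_oracle(tree_map, catalog, model: str, delta=0.5):
    """Full SD1 or SD2 matrix by direct set-intersection sums."""
    node_sets, graphs = dag_node_sets(tree_map, catalog)
    n = len(catalog)
    contribs = {}
    for d in catalog:
        if not node_sets[d]:
            continue
        if model == "m1":
            contribs[d] = contributions_m1(graphs, d, delta)
        else:
            contribs[d] = contributions_m2(node_sets, d, n)
    values = np.eye(n)
    ids = list(catalog)
    for i in range(n):
        for j in range(i + 1, n):
            if ids[i] in contribs and ids[j] in contribs:
                values[i, j] = values[j, i] = _pair_similarity(
                    contribs[ids[i]], contribs[ids[j]]
                )
    return values


def auc_mann_whitney(scores, labels) -> float:
    """Normalized Mann-Whitney U: ties contribute one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
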