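import numpy as np
import pytest

from dcfmda.containers import (
    AssociationMatrix,
    DiseaseDAG,
    SimilarityMatrix,
    Vocabulary,
)


def chain_dag(*nodes):
    """DAG that is a single root→…→focal chain; focal is nodes[0]."""
    path = list(nodes)[::-1]  # root first
    edges = set(zip(path, path[1:]))
    return DiseaseDAG(nodes[0], frozenset(path), frozenset(edges))


def random_dag(rng, max_nodes=15):
    """Random ancestor DAG: each node gets >=1 parent among later ids.

    Node 0 is the focal disease; nodes are added so every node lies on an
    upward path from the focal node, matching the ancestor-closure shape
    ontology extraction produces.
    """
    n = int(rng.integers(1, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    edges = set()
    # grow upward: each new node i>0 becomes parent of an existing node
    for i in range(1, n):
        child = int(rng.integers(0, i))
        edges.add((names[i], names[child]))
        # occasional extra child link keeps it a DAG (parent has larger id)
        if i >= 2 and rng.random() < 0.3:
            extra = int(rng.integers(0, i))
            if extra != child:
                edges.add((names[i], names[extra]))
    return DiseaseDAG(names[0], frozenset(names), frozenset(edges))


def brute_force_contribution(dag, node):
    """Independent recursive evaluation of the per-node contribution."""
    if node == dag.focal:
        return 1.0
    children = [c for p, c in dag.edges if p == node]
    return max(0.5 * brute_force_contribution(dag, c) for c in children)


def brute_force_semantic_value(dag):
    return sum(brute_force_contribution(dag, t) for t in dag.nodes)


def brute_force_ssd(dag_i, dag_j):
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    num = sum(
        brute_force_contribution(dag_i, t) + brute_force_contribution(dag_j, t)
        for t in shared
    )
    return num / (brute_force_semantic_value(dag_i) + brute_force_semantic_value(dag_j))


def brute_force_auc(scores, labels):
    """Pairwise positive-vs-negative counting, ties worth one half."""
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


def tiny_similarity(labels, values, kind):
    return SimilarityMatrix(Vocabulary(labels), np.asarray(values, dtype=float), kind)


@pytest.fixture(scope="session")
def small_world():
    """One modest synthetic world shared by read-only tests."""
    from dcfmda.synthetic import WorldConfig, generate_world

    return generate_world(WorldConfig(n_mirnas=40, n_diseases=30, rng_seed=7))


@pytest.fixture(scope="session")
def small_bundle(small_world):
    from dcfmda.similarity import build_similarity_bundle

    w = small_world
    return build_similarity_bundle(w.assoc, w.dags, w.gene_network, w.disease_genes)


@pytest.fixture()
def toy_assoc():
    values = np.array([
        [1, 0, 1, 0, 0, 0],
        [0, 1, 0, 0, 0, 0],
        [0, 0, 0, 1, 0, 0],
        [1, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 1, 0],
    ])
    return AssociationMatrix(
        Vocabulary(f"m{i}" for i in range(5)),
        Vocabulary(f"d{j}" for j in range(6)),
        values,
    )
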