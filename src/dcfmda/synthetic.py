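"""Self-consistent synthetic worlds for end-to-end testing without downloads.

A world consists of latent miRNA and disease factors, an association
matrix sampled from a logistic low-rank model, a disease ontology whose
structure follows the disease factors (factor-similar diseases share
deeper ancestors, so semantic similarity carries real signal), a weighted
gene functional network with per-cluster gene pools, and a disease→gene
map.  Everything is deterministic given the seed and writable in exactly
the tab-separated formats the readers parse.

The default configuration is the package's standard study condition for
recovery experiments: 100 miRNAs × 80 diseases, latent rank 5,
association density 0.05 (≈400 positives), label-flip noise 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseGeneMap,
    GeneNetwork,
    Vocabulary,
)

__all__ = ["WorldConfig", "SyntheticWorld", "generate_world", "world_to_files"]


@dataclass(frozen=True)
class WorldConfig:
    n_mirnas: int = 100
    n_diseases: int = 80
    latent_rank: int = 5
    association_density: float = 0.05
    #: multiplier on the standardised factor inner product; controls how
    #: separable true and false associations are
    signal_gain: float = 6.0
    #: miRNAs and diseases are drawn around a small number of latent
    #: functional-family centroids; the spread is the within-family factor
    #: standard deviation relative to the unit between-family scale
    n_mirna_families: int = 10
    n_disease_families: int = 8
    family_spread: float = 0.25
    dag_depth: tuple[int, int] = (3, 4)
    genes_per_disease: tuple[int, int] = (4, 8)
    n_genes: int = 200
    network_edge_density: float = 0.03
    noise_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_mirnas, self.n_diseases) < 2:
            raise ValueError("world needs at least 2 miRNAs and 2 diseases")
        if not 0.0 < self.association_density < 1.0:
            raise ValueError("association_density must be in (0, 1)")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.latent_rank > min(self.n_mirnas, self.n_diseases):
            raise ValueError("latent_rank exceeds matrix dimensions")
        if self.dag_depth[0] < 1 or self.dag_depth[0] > self.dag_depth[1]:
            raise ValueError("dag_depth must be a nondecreasing positive range")
        if self.genes_per_disease[0] < 1:
            raise ValueError("genes_per_disease lower bound must be >= 1")
        if min(self.n_mirna_families, self.n_disease_families) < 1:
            raise ValueError("family counts must be >= 1")
        if self.family_spread < 0:
            raise ValueError("family_spread must be nonnegative")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    mirna_factors: np.ndarray
    disease_factors: np.ndarray
    truth: np.ndarray  # ground-truth association probabilities
    assoc: AssociationMatrix
    dags: dict[str, DiseaseDAG]
    gene_network: GeneNetwork
    disease_genes: DiseaseGeneMap
    leaf_cluster: dict[str, int] = field(default_factory=dict)


def _calibrate_intercept(logits: np.ndarray, density: float) -> float:
    """Bisection for the intercept c with mean sigmoid(logits + c) = density."""
    lo, hi = -40.0, 40.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))) < density:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _two_means(x: np.ndarray, rng) -> np.ndarray:
    """Tiny seeded 2-means; returns a binary cluster label per row."""
    n = x.shape[0]
    centers = x[rng.choice(n, size=2, replace=False)]
    labels = np.zeros(n, dtype=int)
    for it in range(20):
        d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if it > 0 and np.array_equal(new, labels):
            break
        labels = new
        for c in (0, 1):
            if np.any(labels == c):
                centers[c] = x[labels == c].mean(axis=0)
    if labels.min() == labels.max():  # degenerate split: force both clusters
        labels[: n // 2] = 0
        labels[n // 2:] = 1
    return labels


def _build_ontology(diseases, factors, depth, rng):
    """Recursive factor bisection into a rooted tree of disease terms.

    Returns (edges, path_of) with ``path_of[d]`` the root→leaf term path
    for disease d (the leaf term is the disease itself), and a leaf
    cluster id per disease.
    """
    edges: set[tuple[str, str]] = set()
    path_of: dict[str, list[str]] = {}
    leaf_cluster: dict[str, int] = {}
    counter = [0]
    cluster_counter = [0]

    def recurse(idx: np.ndarray, parent: str, level: int):
        if level >= depth or idx.size <= 2:
            cid = cluster_counter[0]
            cluster_counter[0] += 1
            for i in idx:
                d = diseases[i]
                edges.add((parent, d))
                path_of[d] = path_of_node[parent] + [d]
                leaf_cluster[d] = cid
            return
        labels = _two_means(factors[idx], rng)
        for c in (0, 1):
            sub = idx[labels == c]
            if sub.size == 0:
                continue
            term = f"term-{counter[0]}"
            counter[0] += 1
            edges.add((parent, term))
            path_of_node[term] = path_of_node[parent] + [term]
            recurse(sub, term, level + 1)

    path_of_node: dict[str, list[str]] = {"root": ["root"]}
    recurse(np.arange(len(diseases)), "root", 1)
    return edges, path_of, leaf_cluster


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Sample one synthetic world; deterministic given ``cfg.rng_seed``."""
    rng = np.random.default_rng(cfg.rng_seed)
    m, n, r = cfg.n_mirnas, cfg.n_diseases, cfg.latent_rank

    # entities cluster around functional-family centroids: miRNA families
    # and disease families give the planted structure the block character
    # real association data show, and make it identifiable at realistic
    # sparsity (a handful of associations per entity)
    cm = rng.normal(size=(cfg.n_mirna_families, r))
    cd = rng.normal(size=(cfg.n_disease_families, r))
    fam_m = rng.integers(0, cfg.n_mirna_families, m)
    fam_d = rng.integers(0, cfg.n_disease_families, n)
    u = cm[fam_m] + cfg.family_spread * rng.normal(size=(m, r))
    v = cd[fam_d] + cfg.family_spread * rng.normal(size=(n, r))
    logits = cfg.signal_gain * (u @ v.T) / np.sqrt(r)
    c = _calibrate_intercept(logits, cfg.association_density)
    truth = 1.0 / (1.0 + np.exp(-(logits + c)))
    a = (rng.random((m, n)) < truth).astype(np.int8)
    if cfg.noise_rate > 0:
        flips = rng.random((m, n)) < cfg.noise_rate
        a = np.where(flips, 1 - a, a)
    if a.sum() == 0:  # pathological draw at extreme configurations
        raise ValueError("generated world has no positive associations")

    mirnas = Vocabulary(f"hsa-mir-{i + 1}" for i in range(m))
    diseases = Vocabulary(f"disease-{j + 1:03d}" for j in range(n))
    assoc = AssociationMatrix(mirnas, diseases, a)

    depth = int(rng.integers(cfg.dag_depth[0], cfg.dag_depth[1] + 1))
    disease_ids = diseases.identifiers
    edges, path_of, leaf_cluster = _build_ontology(disease_ids, v, depth, rng)
    dags = {}
    for d in disease_ids:
        path = path_of[d]
        dag_edges = set(zip(path, path[1:]))
        dags[d] = DiseaseDAG(d, frozenset(path), frozenset(dag_edges))

    # gene network: per-cluster pools give factor-similar diseases
    # overlapping gene sets, plus a sparse random background
    genes = [f"gene-{g + 1}" for g in range(cfg.n_genes)]
    n_clusters = max(leaf_cluster.values()) + 1
    pool_size = max(cfg.genes_per_disease[1] * 2, cfg.n_genes // max(n_clusters, 1))
    pools = [
        rng.choice(cfg.n_genes, size=min(pool_size, cfg.n_genes), replace=False)
        for _ in range(n_clusters)
    ]
    edge_weights: dict[frozenset, float] = {}
    n_bg = int(cfg.network_edge_density * cfg.n_genes * (cfg.n_genes - 1) / 2)
    for _ in range(n_bg):
        g1, g2 = rng.choice(cfg.n_genes, size=2, replace=False)
        edge_weights[frozenset((genes[g1], genes[g2]))] = float(rng.uniform(0.5, 3.0))
    for pool in pools:  # stronger intra-pool links
        for a_pos in range(len(pool)):
            for b_pos in range(a_pos + 1, len(pool)):
                if rng.random() < 0.3:
                    key = frozenset((genes[pool[a_pos]], genes[pool[b_pos]]))
                    edge_weights[key] = float(rng.uniform(3.0, 6.0))
    net = GeneNetwork(frozenset(genes), edge_weights)

    mapping = {}
    for d in disease_ids:
        lo, hi = cfg.genes_per_disease
        size = int(rng.integers(lo, hi + 1))
        pool = pools[leaf_cluster[d]]
        n_from_pool = max(1, int(round(0.8 * size)))
        picks = set(
            genes[g] for g in rng.choice(pool, size=min(n_from_pool, pool.size),
                                         replace=False)
        )
        while len(picks) < size:
            picks.add(genes[int(rng.integers(cfg.n_genes))])
        mapping[d] = frozenset(picks)
    dg_map = DiseaseGeneMap(mapping)

    return SyntheticWorld(
        cfg, u, v, truth, assoc, dags, net, dg_map, leaf_cluster
    )


def world_to_files(world: SyntheticWorld, out_dir) -> dict[str, Path]:
    """Write the five world files; round-trips losslessly through the readers."""
    from . import io as dio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if world.assoc.values.sum() == 0:
        raise ValueError("refusing to write a world with no associations")
    paths = {
        "associations": out_dir / "associations.tsv",
        "dag_edges": out_dir / "dag_edges.tsv",
        "gene_net": out_dir / "gene_net.tsv",
        "disease_genes": out_dir / "disease_genes.tsv",
        "truth": out_dir / "truth.tsv",
    }
    dio.write_associations(world.assoc, paths["associations"])

    all_edges = sorted(
        {e for dag in world.dags.values() for e in dag.edges}
    )
    with open(paths["dag_edges"], "w") as fh:
        fh.write("parent\tchild\n")
        for parent, child in all_edges:
            fh.write(f"{parent}\t{child}\n")

    with open(paths["gene_net"], "w") as fh:
        fh.write("gene1\tgene2\tlls\n")
        for key in sorted(world.gene_network.raw_weights, key=sorted):
            g1, g2 = sorted(key)
            fh.write(f"{g1}\t{g2}\t{world.gene_network.raw_weights[key]:.6f}\n")

    with open(paths["disease_genes"], "w") as fh:
        fh.write("disease\tgene\n")
        for d in world.assoc.diseases:
            for g in sorted(world.disease_genes.genes_of(d)):
                fh.write(f"{d}\t{g}\n")

    dio.write_matrix(
        world.truth, world.assoc.mirnas.identifiers,
        world.assoc.diseases.identifiers, paths["truth"],
    )
    return paths
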