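"""Similarity construction for miRNAs and diseases.

Five measures feed the predictor:

* **SSD** — disease semantic similarity from shared ontology ancestors,
  with per-level contributions decaying by one half;
* **FSD** — disease functional similarity via best-match-average over a
  weighted gene functional network;
* **FSM** — miRNA functional similarity via best-match-average over the
  semantic similarity of their associated disease sets;
* **GD / GM** — Gaussian interaction-profile kernels over the columns /
  rows of the binary association matrix;
* **ISM / ISD** — the integrated matrices: functional similarity where it
  is informative, the Gaussian kernel as fallback, and for diseases the
  arithmetic mean of semantic and functional similarity.

All matrices are symmetric with entries in [0, 1]; the upper triangle is
computed and mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseGeneMap,
    GeneNetwork,
    SimilarityMatrix,
    Vocabulary,
)

__all__ = [
    "semantic_contribution",
    "semantic_value",
    "disease_semantic_similarity",
    "gene_pair_similarity",
    "gene_to_set_association",
    "disease_functional_similarity",
    "disease_group_similarity",
    "mirna_functional_similarity",
    "gaussian_profile_kernel",
    "gip_disease_kernel",
    "gip_mirna_kernel",
    "semantic_similarity_matrix",
    "functional_disease_matrix",
    "functional_mirna_matrix",
    "integrate_mirna_similarity",
    "integrate_disease_similarity",
    "SimilarityBundle",
    "build_similarity_bundle",
]

#: per-level decay of a node's semantic contribution walking up the DAG
DECAY = 0.5


# ---------------------------------------------------------------------------
# disease semantic similarity (ontology DAGs)

def semantic_contribution(dag: DiseaseDAG) -> dict[str, float]:
    """Contribution of every node in ``dag`` to the focal disease.

    The focal disease contributes 1; any other node contributes the
    maximum over its children *within the DAG* of half the child's
    contribution.  Values are therefore in (0, 1].
    """
    graph = dag.graph()
    contrib: dict[str, float] = {dag.focal: 1.0}
    # walk from the focal disease upward: reverse topological order of the
    # parent→child graph guarantees children are resolved before parents
    for node in nx.topological_sort(graph.reverse(copy=False)):
        if node == dag.focal:
            continue
        children = [c for c in graph.successors(node) if c in contrib]
        if not children:
            # node not on a path to the focal disease; DiseaseDAG validity
            # rules this out, but guard against inconsistent input
            raise ValueError(f"node {node!r} has no path to {dag.focal!r}")
        contrib[node] = max(DECAY * contrib[c] for c in children)
    return contrib


def semantic_value(dag: DiseaseDAG) -> float:
    """Semantic value DD(d): sum of all node contributions (always >= 1)."""
    return float(sum(semantic_contribution(dag).values()))


def disease_semantic_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Semantic similarity of two diseases from their shared ancestors.

    Shared nodes contribute from both DAGs; the sum is normalised by the
    two semantic values, giving 1 for identical DAGs and 0 for disjoint
    node sets.
    """
    c_i = semantic_contribution(dag_i)
    c_j = semantic_contribution(dag_j)
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    num = sum(c_i[t] + c_j[t] for t in shared)
    den = sum(c_i.values()) + sum(c_j.values())
    return float(num / den)


# ---------------------------------------------------------------------------
# disease functional similarity (gene network)

def gene_pair_similarity(net: GeneNetwork, g_i: str, g_j: str) -> float:
    """1 for identical genes, normalised LLS for network edges, else 0."""
    if g_i == g_j:
        return 1.0
    w = net.normalized_weight(g_i, g_j)
    return float(w) if w is not None else 0.0


def gene_to_set_association(net: GeneNetwork, g: str, genes) -> float:
    """Best-match association of gene ``g`` to a non-empty gene set."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene set must be non-empty")
    return max(gene_pair_similarity(net, g, g_i) for g_i in genes)


def disease_functional_similarity(net: GeneNetwork, g1, g2) -> float:
    """Best-match-average similarity between two disease gene sets."""
    g1, g2 = list(g1), list(g2)
    if not g1 or not g2:
        raise ValueError("disease gene sets must be non-empty")
    total = sum(gene_to_set_association(net, g, g2) for g in g1)
    total += sum(gene_to_set_association(net, g, g1) for g in g2)
    return float(total / (len(g1) + len(g2)))


# ---------------------------------------------------------------------------
# miRNA functional similarity (via disease semantic similarity)

def disease_group_similarity(ssd: SimilarityMatrix, d: str, group) -> float:
    """Best-match similarity of disease ``d`` to a non-empty disease group."""
    group = list(group)
    if not group:
        raise ValueError("disease group must be non-empty")
    return max(ssd[d, d_i] for d_i in group)


def mirna_functional_similarity(
    ssd: SimilarityMatrix, assoc: AssociationMatrix, m_i: str, m_j: str
) -> float:
    """Best-match-average similarity of the two miRNAs' disease sets.

    Returns NaN when either miRNA has no associated disease (the measure
    is undefined on empty sets); matrix assembly maps that to 0 so the
    integration step falls back to the Gaussian kernel.
    """
    i = assoc.mirnas.index(m_i)
    j = assoc.mirnas.index(m_j)
    d1 = [assoc.diseases[c] for c in assoc.disease_set_of(i)]
    d2 = [assoc.diseases[c] for c in assoc.disease_set_of(j)]
    if not d1 or not d2:
        return float("nan")
    total = sum(disease_group_similarity(ssd, d, d1) for d in d2)
    total += sum(disease_group_similarity(ssd, d, d2) for d in d1)
    return float(total / (len(d1) + len(d2)))


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels

def gaussian_profile_kernel(
    profiles: np.ndarray,
    labels: Vocabulary,
    kind: str,
    bandwidth_base: float = 1.0,
) -> SimilarityMatrix:
    """RBF kernel over binary interaction profiles.

    K(i, j) = exp(-beta * ||IP(i) - IP(j)||^2) with the bandwidth
    beta = bandwidth_base / mean(||IP(i)||^2), so the kernel width adapts
    to the average number of associations per entity.

    Parameters
    ----------
    profiles
        One profile per row; for diseases these are the columns of the
        association matrix, for miRNAs the rows.
    bandwidth_base
        The unnormalised bandwidth (default 1, the usual convention).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a 2-D array, one profile per row")
    mean_sq = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq == 0.0:
        raise ValueError("all interaction profiles are zero: kernel bandwidth undefined")
    beta = bandwidth_base / mean_sq
    sq = np.sum(profiles**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    k = np.exp(-beta * d2)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(labels, k, kind)


def gip_disease_kernel(assoc: AssociationMatrix, bandwidth_base: float = 1.0) -> SimilarityMatrix:
    """GD: Gaussian kernel over disease profiles (association-matrix columns)."""
    return gaussian_profile_kernel(
        assoc.values.T.astype(float), assoc.diseases, "GD", bandwidth_base
    )


def gip_mirna_kernel(assoc: AssociationMatrix, bandwidth_base: float = 1.0) -> SimilarityMatrix:
    """GM: Gaussian kernel over miRNA profiles (association-matrix rows)."""
    return gaussian_profile_kernel(
        assoc.values.astype(float), assoc.mirnas, "GM", bandwidth_base
    )


# ---------------------------------------------------------------------------
# matrix assembly

def semantic_similarity_matrix(
    dags: dict[str, DiseaseDAG], diseases: Vocabulary
) -> SimilarityMatrix:
    """SSD over an ordered disease vocabulary.

    Diseases with no ontology DAG get zero similarity to everything
    (including themselves); the integration step then falls back to the
    Gaussian kernel for those pairs.
    """
    n = len(diseases)
    vals = np.zeros((n, n))
    contribs = {}
    totals = {}
    for d in diseases:
        if d in dags:
            contribs[d] = semantic_contribution(dags[d])
            totals[d] = sum(contribs[d].values())
    idx = {d: i for i, d in enumerate(diseases)}
    present = [d for d in diseases if d in contribs]
    for a_pos, d_a in enumerate(present):
        for d_b in present[a_pos:]:
            shared = dags[d_a].nodes & dags[d_b].nodes
            if not shared:
                continue
            num = sum(contribs[d_a][t] + contribs[d_b][t] for t in shared)
            s = num / (totals[d_a] + totals[d_b])
            vals[idx[d_a], idx[d_b]] = s
            vals[idx[d_b], idx[d_a]] = s
    return SimilarityMatrix(diseases, vals, "SSD")


def functional_disease_matrix(
    net: GeneNetwork, dg_map: DiseaseGeneMap, diseases: Vocabulary
) -> SimilarityMatrix:
    """FSD over an ordered disease vocabulary.

    Diseases with no recorded gene set get zero rows (excluded from the
    measure); all others get best-match-average similarity.
    """
    n = len(diseases)
    vals = np.zeros((n, n))
    idx = {d: i for i, d in enumerate(diseases)}
    present = [d for d in diseases if d in dg_map]
    for a_pos, d_a in enumerate(present):
        for d_b in present[a_pos:]:
            s = disease_functional_similarity(
                net, dg_map.genes_of(d_a), dg_map.genes_of(d_b)
            )
            vals[idx[d_a], idx[d_b]] = s
            vals[idx[d_b], idx[d_a]] = s
    return SimilarityMatrix(diseases, vals, "FSD")


def functional_mirna_matrix(
    ssd: SimilarityMatrix, assoc: AssociationMatrix
) -> SimilarityMatrix:
    """FSM over the miRNA vocabulary; undefined pairs (an empty disease
    set on either side) are stored as 0 so integration falls back to GM."""
    m = assoc.n_mirnas
    vals = np.zeros((m, m))
    disease_sets = [
        [assoc.diseases[c] for c in assoc.disease_set_of(i)] for i in range(m)
    ]
    # precompute the SSD rows once; inner loops work on index arrays
    ssd_idx = {d: ssd.labels.index(d) for d in assoc.diseases}
    set_idx = [np.array([ssd_idx[d] for d in ds], dtype=int) for ds in disease_sets]
    for i in range(m):
        if disease_sets[i]:
            vals[i, i] = 1.0
        for j in range(i + 1, m):
            if not disease_sets[i] or not disease_sets[j]:
                continue
            sub = ssd.values[np.ix_(set_idx[i], set_idx[j])]
            s = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (
                len(disease_sets[i]) + len(disease_sets[j])
            )
            vals[i, j] = vals[j, i] = s
    return SimilarityMatrix(assoc.mirnas, vals, "FSM")


def integrate_mirna_similarity(
    fsm: SimilarityMatrix, gm: SimilarityMatrix
) -> SimilarityMatrix:
    """ISM: functional similarity where non-zero, Gaussian kernel otherwise."""
    if not fsm.aligned_with(gm):
        raise ValueError("FSM and GM label vocabularies differ")
    vals = np.where(fsm.values != 0.0, fsm.values, gm.values)
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return SimilarityMatrix(fsm.labels, vals, "ISM")


def integrate_disease_similarity(
    fsd: SimilarityMatrix,
    ssd: SimilarityMatrix,
    gd: SimilarityMatrix,
    nonzero_mean: bool = False,
) -> SimilarityMatrix:
    """ISD: mean of functional and semantic similarity, kernel fallback.

    The literal rule averages FSD and SSD whenever either is non-zero,
    halving the surviving term when the other is zero.  With
    ``nonzero_mean=True`` the mean is instead taken over the non-zero
    terms only (off by default).
    """
    if not (fsd.aligned_with(ssd) and ssd.aligned_with(gd)):
        raise ValueError("FSD/SSD/GD label vocabularies differ")
    informative = (fsd.values != 0.0) | (ssd.values != 0.0)
    if nonzero_mean:
        count = (fsd.values != 0.0).astype(float) + (ssd.values != 0.0).astype(float)
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, (fsd.values + ssd.values) / np.maximum(count, 1), 0.0)
    else:
        mean = (fsd.values + ssd.values) / 2.0
    vals = np.where(informative, mean, gd.values)
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(fsd.labels, vals, "ISD")


# ---------------------------------------------------------------------------
# end-to-end bundle

@dataclass
class SimilarityBundle:
    """All five similarity matrices plus the integrated ISM/ISD."""

    ssd: SimilarityMatrix
    fsd: SimilarityMatrix
    fsm: SimilarityMatrix
    gd: SimilarityMatrix
    gm: SimilarityMatrix
    ism: SimilarityMatrix
    isd: SimilarityMatrix

    def reintegrate(self, assoc: AssociationMatrix) -> "SimilarityBundle":
        """Recompute the Gaussian kernels (and hence ISM/ISD fallback
        entries) from a different association matrix, e.g. a training fold
        with held-out positives masked out."""
        gd = gip_disease_kernel(assoc)
        gm = gip_mirna_kernel(assoc)
        return SimilarityBundle(
            ssd=self.ssd,
            fsd=self.fsd,
            fsm=self.fsm,
            gd=gd,
            gm=gm,
            ism=integrate_mirna_similarity(self.fsm, gm),
            isd=integrate_disease_similarity(self.fsd, self.ssd, gd),
        )


def build_similarity_bundle(
    assoc: AssociationMatrix,
    dags: dict[str, DiseaseDAG],
    net: GeneNetwork,
    dg_map: DiseaseGeneMap,
    bandwidth_base: float = 1.0,
    nonzero_mean: bool = False,
) -> SimilarityBundle:
    """Run the full similarity pipeline on one dataset."""
    ssd = semantic_similarity_matrix(dags, assoc.diseases)
    fsd = functional_disease_matrix(net, dg_map, assoc.diseases)
    fsm = functional_mirna_matrix(ssd, assoc)
    gd = gip_disease_kernel(assoc, bandwidth_base)
    gm = gip_mirna_kernel(assoc, bandwidth_base)
    ism = integrate_mirna_similarity(fsm, gm)
    isd = integrate_disease_similarity(fsd, ssd, gd, nonzero_mean=nonzero_mean)
    return SimilarityBundle(ssd, fsd, fsm, gd, gm, ism, isd)
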