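"""Core in-memory containers for miRNA-disease association prediction.

The association matrix, disease ontology sub-DAGs, the weighted gene
functional network, disease-to-gene memberships and labelled similarity
matrices are the data every downstream stage (similarity construction,
model training, evaluation) operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Vocabulary",
    "AssociationMatrix",
    "DiseaseDAG",
    "GeneNetwork",
    "DiseaseGeneMap",
    "SimilarityMatrix",
    "SIMILARITY_KINDS",
]

#: recognised similarity-matrix tags: disease semantic (SSD), disease
#: functional (FSD), miRNA functional (FSM), Gaussian interaction profile
#: for diseases (GD) and miRNAs (GM), and the integrated matrices ISM/ISD.
SIMILARITY_KINDS = ("SSD", "FSD", "FSM", "GD", "GM", "ISM", "ISD")

_SYMMETRY_TOL = 1e-9


class Vocabulary:
    """Ordered, unique identifiers with forward and inverse index maps.

    Order is first-appearance order, which keeps embedding rows and fold
    assignments reproducible across runs reading the same file.
    """

    def __init__(self, identifiers):
        self._ids = list(identifiers)
        self._index = {}
        for pos, ident in enumerate(self._ids):
            if ident in self._index:
                raise ValueError(f"duplicate identifier {ident!r} in vocabulary")
            self._index[ident] = pos

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self):
        return iter(self._ids)

    def __contains__(self, ident) -> bool:
        return ident in self._index

    def __getitem__(self, pos: int) -> str:
        return self._ids[pos]

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self._ids == other._ids

    def index(self, ident: str) -> int:
        try:
            return self._index[ident]
        except KeyError:
            raise KeyError(f"unknown identifier {ident!r}") from None

    @property
    def identifiers(self) -> list[str]:
        return list(self._ids)


@dataclass
class AssociationMatrix:
    """Binary miRNA×disease incidence matrix.

    Rows are miRNAs, columns are diseases; an entry of 1 records an
    experimentally supported association, 0 means *unobserved* (not
    verified-negative).  Rows and columns double as the interaction
    profiles used by the Gaussian-kernel similarity.
    """

    mirnas: Vocabulary
    diseases: Vocabulary
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mirnas), len(self.diseases)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.mirnas)} miRNAs x {len(self.diseases)} diseases"
            )
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("association matrix entries must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def mirna_profile(self, i: int) -> np.ndarray:
        """Interaction profile IP(m_i): the i-th row."""
        return self.values[i, :].astype(float)

    def disease_profile(self, j: int) -> np.ndarray:
        """Interaction profile IP(d_j): the j-th column."""
        return self.values[:, j].astype(float)

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of observed associations, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def disease_set_of(self, i: int) -> list[int]:
        """Column indices of diseases associated with miRNA i."""
        return np.nonzero(self.values[i, :])[0].tolist()

    def mask_pairs(self, pairs) -> "AssociationMatrix":
        """Copy with the given (i, j) entries set to 0 (e.g. a held-out fold)."""
        vals = self.values.copy()
        for i, j in pairs:
            vals[i, j] = 0
        return AssociationMatrix(self.mirnas, self.diseases, vals)


@dataclass
class DiseaseDAG:
    """Ancestor closure of one disease term in the disease ontology.

    ``nodes`` contains the focal disease and all its ancestors; ``edges``
    are the parent→child links among those nodes.  Semantic contributions
    decay by one half per level walking up from the focal term.
    """

    focal: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        self.nodes = frozenset(self.nodes)
        self.edges = frozenset(self.edges)
        if self.focal not in self.nodes:
            raise ValueError(f"focal disease {self.focal!r} missing from node set")
        for parent, child in self.edges:
            if parent not in self.nodes or child not in self.nodes:
                raise ValueError(f"edge ({parent!r}, {child!r}) leaves the node set")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cycle in disease DAG at node {cycle[0][0]!r}")
        # every node must reach the focal disease walking parent→child
        reachable = {self.focal} | nx.ancestors(g, self.focal)
        stray = self.nodes - reachable
        if stray:
            raise ValueError(
                f"nodes {sorted(stray)} are not ancestors of {self.focal!r}"
            )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def children_of(self, node: str) -> list[str]:
        return sorted(child for parent, child in self.edges if parent == node)


@dataclass
class GeneNetwork:
    """Undirected gene functional network with log-likelihood edge scores.

    Raw scores are min-max normalised over all edges to [0, 1] (pluggable
    via ``normalizer``); self-similarity is handled by the pairwise
    similarity rule, not by self-loop edges.
    """

    genes: frozenset[str]
    raw_weights: dict[frozenset, float] = field(default_factory=dict)
    normalizer: str = "minmax"

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        for key, w in self.raw_weights.items():
            if len(key) != 2:
                raise ValueError(f"self-loop edge {set(key)} not allowed")
            if not np.isfinite(w):
                raise ValueError(f"non-finite LLS on edge {set(key)}")
            if not key <= self.genes:
                raise ValueError(f"edge {set(key)} references unknown genes")
        self._normalized = self._normalize()

    def _normalize(self) -> dict[frozenset, float]:
        if not self.raw_weights:
            return {}
        if self.normalizer != "minmax":
            raise ValueError(f"unknown normalizer {self.normalizer!r}")
        vals = np.fromiter(self.raw_weights.values(), dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:  # all edges equally likely: map to full confidence
            return {k: 1.0 for k in self.raw_weights}
        return {k: float((w - lo) / (hi - lo)) for k, w in self.raw_weights.items()}

    def normalized_weight(self, g_i: str, g_j: str) -> float | None:
        """Normalised LLS of edge (g_i, g_j), or None if absent."""
        return self._normalized.get(frozenset((g_i, g_j)))

    @classmethod
    def from_edges(cls, edges, normalizer: str = "minmax") -> "GeneNetwork":
        """Build from an iterable of (gene1, gene2, raw_lls) triples."""
        genes = set()
        weights: dict[frozenset, float] = {}
        for g1, g2, w in edges:
            if g1 == g2:
                raise ValueError(f"self-loop edge on gene {g1!r}")
            key = frozenset((g1, g2))
            if key in weights and weights[key] != float(w):
                raise ValueError(
                    f"edge {g1!r}-{g2!r} listed twice with conflicting scores"
                )
            weights[key] = float(w)
            genes.update((g1, g2))
        return cls(frozenset(genes), weights, normalizer)


@dataclass
class DiseaseGeneMap:
    """Mapping from disease identifier to its non-empty associated gene set."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self):
        clean = {}
        for disease, genes in self.mapping.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"disease {disease!r} has an empty gene set")
            clean[disease] = genes
        self.mapping = clean

    def genes_of(self, disease: str) -> frozenset[str] | None:
        return self.mapping.get(disease)

    def __contains__(self, disease) -> bool:
        return disease in self.mapping


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with row/column labels in [0, 1]."""

    labels: Vocabulary
    values: np.ndarray
    kind: str

    def __post_init__(self):
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if self.values.size and (self.values.min() < -_SYMMETRY_TOL
                                 or self.values.max() > 1 + _SYMMETRY_TOL):
            raise ValueError("similarity entries must lie in [0, 1]")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance ({asym:.3g})")
        np.clip(self.values, 0.0, 1.0, out=self.values)
        if self.kind in ("GD", "GM", "ISM"):
            diag = np.diag(self.values)
            if n and not np.allclose(diag, 1.0, atol=_SYMMETRY_TOL):
                raise ValueError(f"{self.kind} diagonal must be exactly 1")

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label), :]

    def aligned_with(self, other: "SimilarityMatrix") -> bool:
        return self.labels == other.labels
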