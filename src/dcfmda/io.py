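"""Readers and writers for the tab-separated interchange formats.

All inputs are plain TSV: association pair lists, ontology edge lists,
weighted gene-network edge lists, disease→gene membership tables, and
labelled numeric matrices.  Readers reject malformed input with the
offending line number rather than silently coercing; writers emit files
their paired readers parse losslessly.

Identifier normalisation (whitespace trimming, lowercasing, unifying the
"has-mir"/"hsa-mir" prefix misspelling common in published tables) is
applied once, at read time, and logged.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    SIMILARITY_KINDS,
    AssociationMatrix,
    DiseaseDAG,
    DiseaseGeneMap,
    GeneNetwork,
    SimilarityMatrix,
    Vocabulary,
)
from .model import ModelConfig, ModelParams, PredictionMatrix

__all__ = [
    "normalize_id",
    "read_associations",
    "write_associations",
    "read_matrix",
    "write_matrix",
    "read_dag_edges",
    "read_gene_network",
    "read_disease_genes",
    "load_model_config",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger("dcfmda")

_PREFIX_FIX = re.compile(r"^has-(mir|let)")


def normalize_id(ident: str) -> str:
    """Trim, lowercase, and unify the hsa-mir prefix spelling."""
    out = ident.strip().lower()
    out = _PREFIX_FIX.sub(r"hsa-\1", out)
    return out


def _rows(path, n_cols: int, what: str):
    """Yield (lineno, fields) from a TSV, skipping an optional header."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or all(not ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty {what} file")
    start = 0
    first = lines[0].split("\t")
    # a header is any first row whose last column is non-numeric for
    # weighted schemas, or that repeats no identifier downstream; we use
    # the simple convention that headers are announced by known column
    # names in the first field
    if first and first[0].strip().lower() in (
        "mirna", "parent", "gene1", "disease", "child", "gene",
    ):
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
                f"got {len(fields)}"
            )
        yield lineno, [f.strip() for f in fields]


def read_associations(path) -> AssociationMatrix:
    """Parse a two-column miRNA/disease pair list into a binary matrix.

    Vocabularies follow first-appearance order after identifier
    normalisation; duplicate pairs collapse to a single 1 with a warning.
    """
    mirnas: list[str] = []
    diseases: list[str] = []
    m_idx: dict[str, int] = {}
    d_idx: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    seen = set()
    for lineno, (m_raw, d_raw) in _rows(path, 2, "association"):
        m, d = normalize_id(m_raw), normalize_id(d_raw)
        if not m or not d:
            raise ValueError(f"{path}:{lineno}: blank identifier")
        if m != m_raw:
            logger.debug("normalized %r -> %r", m_raw, m)
        if m not in m_idx:
            m_idx[m] = len(mirnas)
            mirnas.append(m)
        if d not in d_idx:
            d_idx[d] = len(diseases)
            diseases.append(d)
        key = (m_idx[m], d_idx[d])
        if key in seen:
            logger.warning("%s:%d: duplicate pair (%s, %s) collapsed",
                           path, lineno, m, d)
            continue
        seen.add(key)
        pairs.append(key)
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for i, j in pairs:
        values[i, j] = 1
    return AssociationMatrix(Vocabulary(mirnas), Vocabulary(diseases), values)


def write_associations(assoc: AssociationMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tdisease\n")
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.mirnas[i]}\t{assoc.diseases[j]}\n")


def read_matrix(path, kind: str | None = None):
    """Read a labelled numeric matrix.

    With ``kind`` one of the similarity tags the result is a validated
    SimilarityMatrix (square, symmetric, [0,1]); otherwise a
    PredictionMatrix with independent row/column label vocabularies.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix cell ({exc})") from None
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite matrix cell")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if kind is not None:
        if kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {kind!r}")
        if rows != cols:
            raise ValueError(f"{path}: similarity matrix labels not square")
        return SimilarityMatrix(Vocabulary(rows), values, kind)
    return PredictionMatrix(Vocabulary(rows), Vocabulary(cols), values)


def write_matrix(values, row_labels, col_labels, path) -> None:
    """Write a labelled matrix as TSV (17 significant digits: lossless
    float round-trip)."""
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_dag_edges(path, diseases) -> dict[str, DiseaseDAG]:
    """Assemble per-disease ancestor closures from a parent→child edge list.

    Diseases absent from the ontology are omitted (their semantic
    similarity row is zero); a cycle anywhere in the ontology is an error.
    """
    g = nx.DiGraph()
    for lineno, (parent, child) in _rows(path, 2, "ontology edge"):
        g.add_edge(normalize_id(parent), normalize_id(child))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"{path}: cycle in ontology at node {cycle[0][0]!r}")
    dags = {}
    for d_raw in diseases:
        d = normalize_id(d_raw)
        if d not in g:
            logger.info("disease %r not in ontology; semantic similarity 0", d)
            continue
        nodes = {d} | nx.ancestors(g, d)
        edges = {(p, c) for p, c in g.edges() if p in nodes and c in nodes}
        dags[d] = DiseaseDAG(d, frozenset(nodes), frozenset(edges))
    return dags


def read_gene_network(path) -> GeneNetwork:
    """Parse a ``gene1 gene2 LLS`` edge list; raw scores may be negative,
    NaN is rejected, conflicting duplicate edges are an error."""
    triples = []
    for lineno, (g1, g2, w) in _rows(path, 3, "gene network"):
        try:
            w = float(w)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric LLS {w!r}") from None
        if np.isnan(w):
            raise ValueError(f"{path}:{lineno}: NaN LLS")
        triples.append((g1, g2, w))
    try:
        return GeneNetwork.from_edges(triples)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_disease_genes(path) -> DiseaseGeneMap:
    """Parse a ``disease gene`` membership table."""
    mapping: dict[str, set[str]] = {}
    for lineno, (d, g) in _rows(path, 2, "disease-gene"):
        mapping.setdefault(normalize_id(d), set()).add(g)
    return DiseaseGeneMap({d: frozenset(gs) for d, gs in mapping.items()})


# ---------------------------------------------------------------------------
# model config and checkpoints

def load_model_config(path) -> ModelConfig:
    """Build a ModelConfig from a YAML mapping of its field names."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: model config must be a mapping")
    known = set(ModelConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("nnmf_tower_sizes", "mlp_tower_sizes"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return ModelConfig(**raw)


def save_checkpoint(models, ism: SimilarityMatrix, isd: SimilarityMatrix,
                    path) -> None:
    """Self-describing archive: parameter arrays (of every ensemble
    member), config, vocabularies, and the similarity matrices needed to
    score new pairs.  ``models`` may be one ModelParams or a list."""
    members = models if isinstance(models, list) else [models]
    first = members[0]
    meta = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in first.config.__dict__.items()
        },
        "n_members": len(members),
        "mirnas": first.mirnas.identifiers,
        "diseases": first.diseases.identifiers,
        "tower_depths": {
            "nnmf_m": len(first.nnmf_m),
            "nnmf_d": len(first.nnmf_d),
            "mlp_m": len(first.mlp_m),
            "mlp_d": len(first.mlp_d),
        },
    }
    arrays = {"ism": ism.values, "isd": isd.values}
    for r, params in enumerate(members):
        arrays[f"m{r}_emb_m"] = params.emb_m
        arrays[f"m{r}_emb_d"] = params.emb_d
        arrays[f"m{r}_fuse_w"] = params.fuse_w
        arrays[f"m{r}_fuse_b"] = params.fuse_b
        for name, tower in (("nnmf_m", params.nnmf_m),
                            ("nnmf_d", params.nnmf_d),
                            ("mlp_m", params.mlp_m),
                            ("mlp_d", params.mlp_d)):
            for l, (w, b) in enumerate(tower):
                arrays[f"m{r}_{name}_w{l}"] = w
                arrays[f"m{r}_{name}_b{l}"] = b
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (members, ism, isd) with ``members`` a
    list of ModelParams (length 1 for a single model)."""
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta"]))
        cfg_raw = meta["config"]
        for key in ("nnmf_tower_sizes", "mlp_tower_sizes"):
            if cfg_raw.get(key) is not None:
                cfg_raw[key] = tuple(cfg_raw[key])
        cfg = ModelConfig(**cfg_raw)
        mirnas = Vocabulary(meta["mirnas"])
        diseases = Vocabulary(meta["diseases"])
        members = []
        for r in range(meta["n_members"]):
            towers = {}
            for name in ("nnmf_m", "nnmf_d", "mlp_m", "mlp_d"):
                towers[name] = [
                    (npz[f"m{r}_{name}_w{l}"], npz[f"m{r}_{name}_b{l}"])
                    for l in range(meta["tower_depths"][name])
                ]
            members.append(ModelParams(
                cfg, mirnas, diseases, npz[f"m{r}_emb_m"], npz[f"m{r}_emb_d"],
                towers["nnmf_m"], towers["nnmf_d"], towers["mlp_m"],
                towers["mlp_d"], npz[f"m{r}_fuse_w"], npz[f"m{r}_fuse_b"],
            ))
        ism = SimilarityMatrix(mirnas, npz["ism"], "ISM")
        isd = SimilarityMatrix(diseases, npz["isd"], "ISD")
    return members, ism, isd
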