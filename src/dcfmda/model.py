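"""Deep collaborative-filtering predictor of miRNA-disease association.

The model fuses two submodels that share one embedding table per entity:

* a **neural matrix-factorisation (NNMF) tower pair**: miRNA and disease
  embeddings are each passed through a two-layer fully connected network
  and combined by elementwise product, generalising the inner product of
  classic matrix factorisation;
* an **MLP tower pair**: the miRNA's row of the integrated miRNA
  similarity matrix and the disease's row of the integrated disease
  similarity matrix are each mapped by a multilayer perceptron (ReLU
  hidden layers, strictly narrowing widths) to a latent vector.

The NNMF product vector, each MLP output concatenated with its raw
embedding, are concatenated and passed through a learned affine output
layer with a sigmoid, yielding a score in (0, 1).  Training minimises
the binary cross-entropy over known associations (label 1) and sampled
unobserved pairs (label 0).

The network is small enough that forward and backward passes are written
directly in numpy; the analytic gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix, Vocabulary

__all__ = [
    "ModelConfig",
    "ModelParams",
    "PredictionMatrix",
    "sample_negatives",
    "init_params",
    "nnmf_forward",
    "mlp_forward",
    "fuse_predict",
    "nnmf_score",
    "bce_loss",
    "loss_and_gradients",
    "fit",
    "train",
    "train_ensemble",
    "member_seed",
    "score_pairs",
    "predict_matrix",
    "spectral_embeddings",
    "params_to_vector",
    "vector_to_params",
]

_EPS = 1e-7  # clipping of predictions inside the log-loss


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the fused predictor.

    ``mlp_tower_sizes`` lists the hidden widths of each MLP tower after
    the input layer; widths must be strictly decreasing and end at the
    embedding dimension.  ``None`` selects [input // 2, k] at build time.
    ``variant`` selects the fusion input: the full concatenation
    ("fused"), the NNMF product alone ("nnmf"), or the two MLP outputs
    alone ("mlp") — the latter two exist for ablation.
    """

    embedding_dim: int = 32
    nnmf_tower_sizes: tuple[int, ...] = None
    mlp_tower_sizes: tuple[int, ...] | None = None
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 256
    negative_ratio: int = 4
    rng_seed: int = 0
    gip_mode: str = "train_only"
    variant: str = "fused"
    #: decoupled (AdamW-style) weight decay per optimisation step,
    #: applied to weights and embeddings but not biases
    weight_decay: float = 1e-4
    #: root-mean-square scale of the embedding initialisation
    init_scale: float = 0.5
    #: "spectral" seeds the shared embeddings with the leading
    #: eigenvector basis of the integrated similarity matrices (plus a
    #: small seeded jitter), so factor training starts from the
    #: similarity geometry; "random" uses plain Gaussian embeddings
    embedding_init: str = "spectral"
    #: number of independently initialised members whose predicted
    #: probabilities are averaged; 1 disables ensembling
    n_models: int = 3

    def __post_init__(self):
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")
        if self.gip_mode not in ("train_only", "full_matrix"):
            raise ValueError(f"unknown gip_mode {self.gip_mode!r}")
        if self.variant not in ("fused", "nnmf", "mlp"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.embedding_init not in ("spectral", "random"):
            raise ValueError(f"unknown embedding_init {self.embedding_init!r}")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.nnmf_tower_sizes is None:
            object.__setattr__(
                self, "nnmf_tower_sizes", (self.embedding_dim, self.embedding_dim)
            )
        else:
            object.__setattr__(self, "nnmf_tower_sizes", tuple(self.nnmf_tower_sizes))
        if self.mlp_tower_sizes is not None:
            sizes = tuple(self.mlp_tower_sizes)
            if any(b >= a for a, b in zip(sizes, sizes[1:])):
                raise ValueError("mlp_tower_sizes must be strictly decreasing")
            if sizes[-1] != self.embedding_dim:
                raise ValueError("mlp_tower_sizes must end at embedding_dim")
            object.__setattr__(self, "mlp_tower_sizes", sizes)

    def mlp_sizes_for(self, input_dim: int) -> tuple[int, ...]:
        if self.mlp_tower_sizes is not None:
            return self.mlp_tower_sizes
        k = self.embedding_dim
        mid = max(input_dim // 2, k)
        sizes = (mid, k) if mid > k else (k,)
        return sizes


@dataclass
class ModelParams:
    """All learnable arrays of the fused model.

    Tower weights are stored as lists of (W, b) with W of shape
    (fan_in, fan_out); every hidden layer uses ReLU.  The fusion layer is
    a weight vector plus scalar bias over the concatenated features.
    """

    config: ModelConfig
    mirnas: Vocabulary
    diseases: Vocabulary
    emb_m: np.ndarray
    emb_d: np.ndarray
    nnmf_m: list[tuple[np.ndarray, np.ndarray]]
    nnmf_d: list[tuple[np.ndarray, np.ndarray]]
    mlp_m: list[tuple[np.ndarray, np.ndarray]]
    mlp_d: list[tuple[np.ndarray, np.ndarray]]
    fuse_w: np.ndarray
    fuse_b: np.ndarray  # shape (1,)

    def arrays(self) -> list[np.ndarray]:
        """All parameter arrays in a fixed, documented order."""
        out = [self.emb_m, self.emb_d]
        for tower in (self.nnmf_m, self.nnmf_d, self.mlp_m, self.mlp_d):
            for w, b in tower:
                out.extend((w, b))
        out.extend((self.fuse_w, self.fuse_b))
        return out

    def decay_flags(self) -> list[bool]:
        """True for arrays subject to weight decay (weights/embeddings,
        not biases); parallel to :meth:`arrays`."""
        flags = [True, True]
        for tower in (self.nnmf_m, self.nnmf_d, self.mlp_m, self.mlp_d):
            flags.extend([True, False] * len(tower))
        flags.extend([True, False])
        return flags

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.config,
            self.mirnas,
            self.diseases,
            self.emb_m.copy(),
            self.emb_d.copy(),
            [(w.copy(), b.copy()) for w, b in self.nnmf_m],
            [(w.copy(), b.copy()) for w, b in self.nnmf_d],
            [(w.copy(), b.copy()) for w, b in self.mlp_m],
            [(w.copy(), b.copy()) for w, b in self.mlp_d],
            self.fuse_w.copy(),
            self.fuse_b.copy(),
        )


@dataclass
class PredictionMatrix:
    """Dense M×N score matrix with labels; entries strictly in (0, 1)."""

    mirnas: Vocabulary
    diseases: Vocabulary
    values: np.ndarray


# ---------------------------------------------------------------------------
# training-set construction

def sample_negatives(
    assoc: AssociationMatrix, positives, ratio: int, seed: int
) -> np.ndarray:
    """Positives plus ``ratio`` times as many unobserved pairs.

    Negatives are drawn uniformly without replacement from the cells of
    the association matrix that are 0 (unobserved; the data contain no
    verified negatives).  Returns an (n, 3) int array of rows
    (miRNA index, disease index, label).
    """
    if ratio < 1:
        raise ValueError("negative sampling ratio must be >= 1")
    positives = [(int(i), int(j)) for i, j in positives]
    for i, j in positives:
        if assoc.values[i, j] != 1:
            raise ValueError(f"pair ({i}, {j}) is not an observed association")
    zero_flat = np.flatnonzero(assoc.values.ravel() == 0)
    n_neg = ratio * len(positives)
    if n_neg > zero_flat.size:
        raise ValueError(
            f"need {n_neg} unobserved pairs but only {zero_flat.size} exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zero_flat, size=n_neg, replace=False)
    neg_i, neg_j = np.unravel_index(chosen, assoc.values.shape)
    pos = np.array([(i, j, 1) for i, j in positives], dtype=np.int64)
    neg = np.stack([neg_i, neg_j, np.zeros_like(neg_i)], axis=1).astype(np.int64)
    return np.concatenate([pos, neg], axis=0)


# ---------------------------------------------------------------------------
# initialisation

def _init_tower(rng, sizes: tuple[int, ...]):
    """He-scaled weights (sqrt(2/fan_in)): keeps ReLU activations and
    gradients on the input scale through the tower."""
    layers = []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        b = np.full(fan_out, 0.01)  # small positive bias avoids dead units
        layers.append((w, b))
    return layers


def spectral_embeddings(
    similarity_values: np.ndarray, k: int, scale: float, rng,
    jitter: float = 0.02,
) -> np.ndarray:
    """Embed entities by the top-k scaled eigenvectors of a similarity matrix.

    Rows of the result inner-product approximately like the similarity
    matrix itself, so factor training starts from the similarity geometry
    instead of noise.  Rescaled to root-mean-square ``scale``; a small
    seeded jitter breaks exact ties between identical rows.
    """
    vals, vecs = np.linalg.eigh(similarity_values)
    order = np.argsort(vals)[::-1][: min(k, vals.size)]
    emb = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))[None, :]
    rms = np.sqrt(np.mean(emb**2))
    if rms > 0:
        emb = emb / rms * scale
    if emb.shape[1] < k:  # fewer entities than dimensions: pad randomly
        pad = rng.normal(0.0, scale, size=(emb.shape[0], k - emb.shape[1]))
        emb = np.hstack([emb, pad])
    return emb + jitter * rng.normal(size=emb.shape)


def init_params(
    cfg: ModelConfig,
    mirnas: Vocabulary,
    diseases: Vocabulary,
    ism: SimilarityMatrix | None = None,
    isd: SimilarityMatrix | None = None,
) -> ModelParams:
    """Seeded initialisation: He-scaled tower weights, near-zero biases,
    and embeddings either from the similarity spectra (when the
    integrated matrices are supplied and ``cfg.embedding_init`` is
    "spectral") or Gaussian with scale ``cfg.init_scale``."""
    rng = np.random.default_rng(cfg.rng_seed)
    k = cfg.embedding_dim
    if cfg.embedding_init == "spectral" and ism is not None and isd is not None:
        emb_m = spectral_embeddings(ism.values, k, cfg.init_scale, rng)
        emb_d = spectral_embeddings(isd.values, k, cfg.init_scale, rng)
    else:
        emb_m = rng.normal(0.0, cfg.init_scale, size=(len(mirnas), k))
        emb_d = rng.normal(0.0, cfg.init_scale, size=(len(diseases), k))
    nnmf_sizes = (k, *cfg.nnmf_tower_sizes)
    mlp_m_sizes = (len(mirnas), *cfg.mlp_sizes_for(len(mirnas)))
    mlp_d_sizes = (len(diseases), *cfg.mlp_sizes_for(len(diseases)))
    nnmf_m = _init_tower(rng, nnmf_sizes)
    nnmf_d = _init_tower(rng, nnmf_sizes)
    mlp_m = _init_tower(rng, mlp_m_sizes)
    mlp_d = _init_tower(rng, mlp_d_sizes)
    z_dim = {
        "fused": cfg.nnmf_tower_sizes[-1] + 4 * k,
        "nnmf": cfg.nnmf_tower_sizes[-1],
        "mlp": 2 * k,
    }[cfg.variant]
    fuse_w = rng.normal(0.0, np.sqrt(1.0 / z_dim), size=z_dim)
    fuse_b = np.zeros(1)
    return ModelParams(
        cfg, mirnas, diseases, emb_m, emb_d, nnmf_m, nnmf_d, mlp_m, mlp_d,
        fuse_w, fuse_b,
    )


# ---------------------------------------------------------------------------
# forward pass

def _tower_forward(layers, x: np.ndarray):
    """ReLU tower forward; returns output and per-layer caches."""
    caches = []
    h = x
    for w, b in layers:
        z = h @ w + b
        a = np.maximum(z, 0.0)
        caches.append((h, z))
        h = a
    return h, caches


def mlp_forward(layers, x: np.ndarray) -> np.ndarray:
    """Map a similarity feature row (or batch of rows) through a ReLU MLP."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != layers[0][0].shape[0]:
        raise ValueError(
            f"input width {x.shape[1]} does not match first layer "
            f"({layers[0][0].shape[0]})"
        )
    out, _ = _tower_forward(layers, x)
    return out[0] if single else out


def nnmf_forward(params: ModelParams, i: int, j: int) -> np.ndarray:
    """Elementwise product p_i ⊙ q_j of the tower-transformed embeddings."""
    m = params.emb_m[i]
    d = params.emb_d[j]
    p, _ = _tower_forward(params.nnmf_m, m[None, :])
    q, _ = _tower_forward(params.nnmf_d, d[None, :])
    return (p * q)[0]


def _forward_batch(params: ModelParams, ii, jj, ism_rows, isd_rows):
    """Batched forward through the full fused model; returns scores and cache."""
    cfg = params.config
    m = params.emb_m[ii]
    d = params.emb_d[jj]
    cache = {"ii": ii, "jj": jj, "m": m, "d": d}
    parts = []
    if cfg.variant in ("fused", "nnmf"):
        p, cache["nnmf_m"] = _tower_forward(params.nnmf_m, m)
        q, cache["nnmf_d"] = _tower_forward(params.nnmf_d, d)
        cache["p"], cache["q"] = p, q
        parts.append(p * q)
    if cfg.variant in ("fused", "mlp"):
        mm, cache["mlp_m"] = _tower_forward(params.mlp_m, ism_rows)
        dd, cache["mlp_d"] = _tower_forward(params.mlp_d, isd_rows)
        cache["ism_rows"], cache["isd_rows"] = ism_rows, isd_rows
        if cfg.variant == "fused":
            parts.extend((mm, m, dd, d))
        else:
            parts.extend((mm, dd))
    z = np.concatenate(parts, axis=1)
    logit = z @ params.fuse_w + params.fuse_b[0]
    yhat = 1.0 / (1.0 + np.exp(-logit))
    cache["z"], cache["logit"], cache["yhat"] = z, logit, yhat
    return yhat, cache


def fuse_predict(
    params: ModelParams, i: int, j: int, ism_row, isd_row
) -> float:
    """Score one miRNA-disease pair through the fused model."""
    yhat, _ = _forward_batch(
        params,
        np.array([i]),
        np.array([j]),
        np.asarray(ism_row, dtype=float)[None, :],
        np.asarray(isd_row, dtype=float)[None, :],
    )
    return float(yhat[0])


def nnmf_score(params: ModelParams, i: int, j: int) -> float:
    """Parameter-free NNMF readout: sigmoid of the summed product vector."""
    return float(1.0 / (1.0 + np.exp(-nnmf_forward(params, i, j).sum())))


# ---------------------------------------------------------------------------
# loss and gradients

def bce_loss(predictions, labels) -> float:
    """Summed binary cross-entropy with predictions clipped to [eps, 1-eps]."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    p = np.clip(predictions, _EPS, 1.0 - _EPS)
    return float(-np.sum(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def _tower_backward(layers, caches, grad_out):
    """Backprop through a ReLU tower; returns per-layer grads and input grad."""
    grads = []
    g = grad_out
    for (w, _b), (h, z) in zip(reversed(layers), reversed(caches)):
        gz = g * (z > 0.0)
        grads.append((h.T @ gz, gz.sum(axis=0)))
        g = gz @ w.T
    grads.reverse()
    return grads, g


def loss_and_gradients(params: ModelParams, samples, ism_vals, isd_vals):
    """Summed BCE loss and analytic gradients for a batch of samples.

    ``samples`` is an (n, 3) array of (i, j, label); ``ism_vals`` and
    ``isd_vals`` are the full integrated similarity matrices (rows are
    gathered per sample).  Returns (loss, grads) with grads a ModelParams
    mirroring the parameter arrays.
    """
    cfg = params.config
    samples = np.asarray(samples)
    ii, jj, yy = samples[:, 0], samples[:, 1], samples[:, 2].astype(float)
    yhat, cache = _forward_batch(params, ii, jj, ism_vals[ii], isd_vals[jj])
    loss = bce_loss(yhat, yy)

    # d loss / d logit through the clipped log-loss and the sigmoid
    inside = (yhat > _EPS) & (yhat < 1.0 - _EPS)
    yc = np.clip(yhat, _EPS, 1.0 - _EPS)
    dl_dyc = -(yy / yc) + (1.0 - yy) / (1.0 - yc)
    dlogit = dl_dyc * inside * yhat * (1.0 - yhat)

    z = cache["z"]
    g_fuse_w = z.T @ dlogit
    g_fuse_b = np.array([dlogit.sum()])
    dz = np.outer(dlogit, params.fuse_w)

    k = cfg.embedding_dim
    nnmf_out = cfg.nnmf_tower_sizes[-1]
    g_emb_m = np.zeros_like(params.emb_m)
    g_emb_d = np.zeros_like(params.emb_d)
    g_nnmf_m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.nnmf_m]
    g_nnmf_d = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.nnmf_d]
    g_mlp_m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.mlp_m]
    g_mlp_d = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params.mlp_d]

    off = 0
    dm_emb = np.zeros_like(cache["m"])
    dd_emb = np.zeros_like(cache["d"])
    if cfg.variant in ("fused", "nnmf"):
        dy = dz[:, off:off + nnmf_out]
        off += nnmf_out
        dp = dy * cache["q"]
        dq = dy * cache["p"]
        g_nnmf_m, dm_tower = _tower_backward(params.nnmf_m, cache["nnmf_m"], dp)
        g_nnmf_d, dd_tower = _tower_backward(params.nnmf_d, cache["nnmf_d"], dq)
        dm_emb += dm_tower
        dd_emb += dd_tower
    if cfg.variant in ("fused", "mlp"):
        dmm = dz[:, off:off + k]
        off += k
        if cfg.variant == "fused":
            dm_emb += dz[:, off:off + k]
            off += k
        ddd = dz[:, off:off + k]
        off += k
        if cfg.variant == "fused":
            dd_emb += dz[:, off:off + k]
            off += k
        g_mlp_m, _ = _tower_backward(params.mlp_m, cache["mlp_m"], dmm)
        g_mlp_d, _ = _tower_backward(params.mlp_d, cache["mlp_d"], ddd)

    np.add.at(g_emb_m, ii, dm_emb)
    np.add.at(g_emb_d, jj, dd_emb)

    grads = ModelParams(
        cfg, params.mirnas, params.diseases, g_emb_m, g_emb_d,
        g_nnmf_m, g_nnmf_d, g_mlp_m, g_mlp_d, g_fuse_w, g_fuse_b,
    )
    return loss, grads


# ---------------------------------------------------------------------------
# flattening helpers (gradient checks, checkpoints)

def params_to_vector(params: ModelParams) -> np.ndarray:
    return np.concatenate([a.ravel() for a in params.arrays()])


def vector_to_params(vec: np.ndarray, template: ModelParams) -> ModelParams:
    out = template.copy()
    pos = 0
    for a in out.arrays():
        a[...] = vec[pos:pos + a.size].reshape(a.shape)
        pos += a.size
    if pos != vec.size:
        raise ValueError("vector length does not match parameter count")
    return out


# ---------------------------------------------------------------------------
# training

class _Adam:
    """Adaptive-moment-estimation optimiser over a list of arrays."""

    def __init__(self, arrays, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def fit(
    params: ModelParams,
    samples: np.ndarray,
    ism: SimilarityMatrix,
    isd: SimilarityMatrix,
    log=None,
) -> ModelParams:
    """Mini-batch Adam training of the summed BCE loss, in place.

    Deterministic given the config seed: batch shuffling uses a dedicated
    generator derived from ``rng_seed``.  Raises on a non-finite loss,
    naming the epoch.
    """
    cfg = params.config
    samples = np.asarray(samples, dtype=np.int64)
    rng = np.random.default_rng((cfg.rng_seed, 0xBA7C))  # batch-order stream
    opt = _Adam(params.arrays(), cfg.learning_rate)
    decay = [
        cfg.weight_decay * cfg.learning_rate if flag else 0.0
        for flag in params.decay_flags()
    ]
    n = samples.shape[0]
    ism_vals, isd_vals = ism.values, isd.values
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            batch = samples[order[start:start + cfg.batch_size]]
            loss, grads = loss_and_gradients(params, batch, ism_vals, isd_vals)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch + 1}"
                )
            epoch_loss += loss
            opt.step(params.arrays(), grads.arrays())
            for arr, d in zip(params.arrays(), decay):
                if d:
                    arr *= 1.0 - d
        if log is not None:
            log(epoch + 1, epoch_loss / n)
    return params


def train(
    assoc_train: AssociationMatrix,
    ism: SimilarityMatrix,
    isd: SimilarityMatrix,
    cfg: ModelConfig,
    samples: np.ndarray | None = None,
    log=None,
) -> ModelParams:
    """Train a fresh model on an association matrix.

    When ``samples`` is omitted, positives are all observed associations
    and negatives are sampled at ``cfg.negative_ratio`` with the config
    seed; pass explicit samples to train on a cross-validation fold.
    """
    if list(ism.labels) != assoc_train.mirnas.identifiers:
        raise ValueError("ISM labels do not match association miRNAs")
    if list(isd.labels) != assoc_train.diseases.identifiers:
        raise ValueError("ISD labels do not match association diseases")
    params = init_params(cfg, assoc_train.mirnas, assoc_train.diseases, ism, isd)
    if cfg.epochs == 0:
        return params
    if samples is None:
        samples = sample_negatives(
            assoc_train, assoc_train.positive_pairs(), cfg.negative_ratio,
            cfg.rng_seed,
        )
    return fit(params, samples, ism, isd, log=log)


def member_seed(base_seed: int, member: int) -> int:
    """Derived seed of one ensemble member, kept below 2**31."""
    return (base_seed * 1009 + member) % (2**31 - 1)


def train_ensemble(
    assoc_train: AssociationMatrix,
    ism: SimilarityMatrix,
    isd: SimilarityMatrix,
    cfg: ModelConfig,
    samples: np.ndarray | None = None,
    log=None,
) -> list[ModelParams]:
    """Train ``cfg.n_models`` members differing only in their derived
    initialisation/batch-order seed; predictions are averaged at use.

    The training set (including sampled negatives) is built once from the
    base seed and shared by every member."""
    if samples is None:
        samples = sample_negatives(
            assoc_train, assoc_train.positive_pairs(), cfg.negative_ratio,
            cfg.rng_seed,
        )
    members = []
    for r in range(cfg.n_models):
        member_cfg = replace(cfg, rng_seed=member_seed(cfg.rng_seed, r))
        members.append(
            train(assoc_train, ism, isd, member_cfg, samples=samples, log=log)
        )
    return members


def score_pairs(
    models: "ModelParams | list[ModelParams]",
    ii: np.ndarray,
    jj: np.ndarray,
    ism: SimilarityMatrix,
    isd: SimilarityMatrix,
) -> np.ndarray:
    """Predicted probabilities for index pairs, averaged over ensemble
    members when a list of parameter sets is given."""
    members = models if isinstance(models, list) else [models]
    ii = np.asarray(ii)
    jj = np.asarray(jj)
    preds = []
    for params in members:
        yhat, _ = _forward_batch(params, ii, jj, ism.values[ii], isd.values[jj])
        preds.append(yhat)
    return np.mean(preds, axis=0)


def predict_matrix(
    models: "ModelParams | list[ModelParams]",
    ism: SimilarityMatrix,
    isd: SimilarityMatrix,
) -> PredictionMatrix:
    """Score every miRNA-disease pair; returns an M×N matrix in (0, 1).

    Accepts a single parameter set or an ensemble (scores averaged)."""
    members = models if isinstance(models, list) else [models]
    first = members[0]
    m, n = len(first.mirnas), len(first.diseases)
    scores = np.zeros((m, n))
    jj_all = np.arange(n)
    for i in range(m):
        scores[i] = score_pairs(members, np.full(n, i), jj_all, ism, isd)
    return PredictionMatrix(first.mirnas, first.diseases, scores)
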