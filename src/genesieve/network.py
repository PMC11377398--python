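"""Annotation-guided sparse network for case-control phenotype prediction.

The model has three layers.  Each input node (one per variant, fed the
additive genotype code) connects to exactly one gene node, as dictated by
the topology map, so a gene node computes a weighted sum of its own
variants plus a bias — a parallel regression per gene.  The gene layer is
fully connected to a single logistic output, making the gene values the
covariates of a final logistic regression.  Total trainable scalars:
n_variants + 2 * n_genes + 1.

Training minimizes mean binary cross-entropy by mini-batch Adam with
per-epoch reshuffling under a single seed, so a run is bit-reproducible.
The default gene activation is linear (matching the parallel-regressions
reading of the architecture); tanh is available for the saturating variant.
Missing genotypes are filled with 0 (homozygous reference) at the model
input — the >= 90 % call-rate floor upstream bounds the distortion — with
per-variant mean imputation as the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

from .association import EncodedMatrix, TopologyMap

__all__ = [
    "TrainConfig",
    "SparseGeneNetParams",
    "build_model",
    "prepare_inputs",
    "gene_values",
    "forward",
    "loss_and_gradients",
    "train",
    "gene_importances",
    "top_gene_list",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 200
    early_stopping: bool = False
    patience: int = 20
    seed: int = 0
    gene_activation: str = "linear"
    l1_variant: float = 0.0
    init_scale: float = 0.05
    fill: str = "zero"  # or "mean"

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if self.gene_activation not in ("linear", "tanh"):
            raise ValueError("gene_activation must be 'linear' or 'tanh'")
        if self.fill not in ("zero", "mean"):
            raise ValueError("fill must be 'zero' or 'mean'")


@dataclass
class SparseGeneNetParams:
    """Flat parameter vectors of the sparse net, plus its wiring.

    ``gene_index[v]`` gives the gene node of variant v; the dense weight
    matrix is never materialized.
    """

    variant_weights: np.ndarray
    gene_biases: np.ndarray
    gene_output_weights: np.ndarray
    output_bias: float
    gene_index: np.ndarray
    gene_ids: list = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return self.variant_weights.size

    @property
    def n_genes(self) -> int:
        return self.gene_biases.size

    @property
    def n_parameters(self) -> int:
        return self.n_variants + 2 * self.n_genes + 1

    def copy(self) -> "SparseGeneNetParams":
        return SparseGeneNetParams(
            self.variant_weights.copy(),
            self.gene_biases.copy(),
            self.gene_output_weights.copy(),
            float(self.output_bias),
            self.gene_index,
            list(self.gene_ids),
        )


def build_model(topology: TopologyMap, config: TrainConfig, seed=None) -> SparseGeneNetParams:
    """Allocate and initialize parameters for a topology.

    Initialization is zero-mean normal with small scale (``init_scale``),
    seeded; biases start at zero.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_v, n_g = topology.n_variants, topology.n_genes
    return SparseGeneNetParams(
        variant_weights=rng.normal(0.0, config.init_scale, n_v),
        gene_biases=np.zeros(n_g),
        gene_output_weights=rng.normal(0.0, config.init_scale, n_g),
        output_bias=0.0,
        gene_index=topology.gene_index.copy(),
        gene_ids=topology.gene_ids,
    )


def prepare_inputs(encoded: EncodedMatrix, fill: str = "zero") -> np.ndarray:
    """Resolve missing genotype codes into a dense float matrix."""
    X = encoded.values.astype(np.float64)
    miss = encoded.values < 0
    if fill == "zero":
        X[miss] = 0.0
    elif fill == "mean":
        for j in np.flatnonzero(miss.any(axis=0)):
            col = X[:, j]
            m = miss[:, j]
            col[m] = col[~m].mean() if (~m).any() else 0.0
    else:
        raise ValueError("fill must be 'zero' or 'mean'")
    return X


def _aggregator(gene_index: np.ndarray, n_genes: int) -> sparse.csr_matrix:
    n_v = gene_index.size
    return sparse.csr_matrix(
        (np.ones(n_v), (np.arange(n_v), gene_index)), shape=(n_v, n_genes)
    )


def gene_values(params: SparseGeneNetParams, X: np.ndarray, activation: str = "linear"):
    """Gene-layer values: act(sum of the gene's weighted variants + bias)."""
    M = _aggregator(params.gene_index, params.n_genes)
    pre = (X * params.variant_weights) @ M + params.gene_biases
    if activation == "tanh":
        return np.tanh(pre)
    return pre


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(params: SparseGeneNetParams, X, activation: str = "linear") -> np.ndarray:
    """Per-sample case scores in (0, 1)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.n_variants:
        raise ValueError(
            f"input has {X.shape[1] if X.ndim == 2 else '?'} variants, "
            f"model expects {params.n_variants}"
        )
    G = gene_values(params, X, activation)
    logit = G @ params.gene_output_weights + params.output_bias
    return np.clip(_sigmoid(logit), 1e-12, 1.0 - 1e-12)


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    s = np.clip(scores, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def loss_and_gradients(
    params: SparseGeneNetParams,
    X: np.ndarray,
    y: np.ndarray,
    activation: str = "linear",
    l1_variant: float = 0.0,
    aggregator=None,
):
    """Mean binary cross-entropy and its gradients over a batch.

    Returns (loss, grads) with grads keyed by parameter group:
    ``w`` variant weights, ``b`` gene biases, ``u`` gene output weights,
    ``c`` output bias.  The gradient of a variant weight flows only through
    its own gene node — the sparsity pattern of the wiring.
    """
    M = aggregator if aggregator is not None else _aggregator(params.gene_index, params.n_genes)
    WX = X * params.variant_weights
    pre = WX @ M + params.gene_biases
    G = np.tanh(pre) if activation == "tanh" else pre
    s = _sigmoid(G @ params.gene_output_weights + params.output_bias)
    loss = _bce(s, y)
    d = (s - y) / y.size  # dL/dlogit for mean BCE
    grad_u = G.T @ d
    grad_c = float(d.sum())
    dG = np.outer(d, params.gene_output_weights)
    dpre = dG * (1.0 - G * G) if activation == "tanh" else dG
    grad_b = dpre.sum(axis=0)
    grad_w = np.einsum("sv,sv->v", X, dpre[:, params.gene_index])
    if l1_variant:
        loss += l1_variant * float(np.abs(params.variant_weights).sum())
        grad_w = grad_w + l1_variant * np.sign(params.variant_weights)
    return loss, {"w": grad_w, "b": grad_b, "u": grad_u, "c": grad_c}


def train(
    params: SparseGeneNetParams,
    encoded,
    labels,
    config: TrainConfig,
    validation=None,
):
    """Mini-batch Adam on binary cross-entropy; returns (params, history).

    ``encoded`` may be an EncodedMatrix or an already-prepared float matrix.
    ``validation`` is an optional (X_val, y_val) pair; with
    ``config.early_stopping`` training stops after ``patience`` epochs
    without a new best validation loss and the best-epoch parameters are
    restored.  History holds per-epoch full-data training loss (and
    validation loss when given).
    """
    X = prepare_inputs(encoded, config.fill) if isinstance(encoded, EncodedMatrix) else np.asarray(encoded, float)
    y = np.asarray(labels, dtype=np.float64)
    if X.shape[0] != y.size:
        raise ValueError("labels do not match sample count")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
        raise ValueError("training needs binary labels with both classes present")
    val = None
    if validation is not None:
        Xv, yv = validation
        Xv = prepare_inputs(Xv, config.fill) if isinstance(Xv, EncodedMatrix) else np.asarray(Xv, float)
        val = (Xv, np.asarray(yv, float))
        if config.early_stopping and np.unique(val[1]).size < 2:
            raise ValueError("validation set needs both classes for early stopping")

    p = params.copy()
    M = _aggregator(p.gene_index, p.n_genes)
    rng = np.random.default_rng(config.seed)
    n = y.size

    # Adam state, one slot per parameter group
    groups = ["w", "b", "u", "c"]
    m_state = {g: 0.0 for g in groups}
    v_state = {g: 0.0 for g in groups}
    t = 0
    b1, b2, eps = 0.9, 0.999, 1e-8

    history = {"train_loss": [], "val_loss": []}
    best_val, best_params, stale = np.inf, None, 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, grads = loss_and_gradients(
                p, X[idx], y[idx], config.gene_activation, config.l1_variant, aggregator=M
            )
            t += 1
            for key, grad, ref in (
                ("w", grads["w"], "variant_weights"),
                ("b", grads["b"], "gene_biases"),
                ("u", grads["u"], "gene_output_weights"),
                ("c", grads["c"], "output_bias"),
            ):
                m_state[key] = b1 * m_state[key] + (1 - b1) * grad
                v_state[key] = b2 * v_state[key] + (1 - b2) * grad**2
                mhat = m_state[key] / (1 - b1**t)
                vhat = v_state[key] / (1 - b2**t)
                step = config.learning_rate * mhat / (np.sqrt(vhat) + eps)
                if ref == "output_bias":
                    p.output_bias = float(p.output_bias - step)
                else:
                    setattr(p, ref, getattr(p, ref) - step)

        history["train_loss"].append(_bce(forward(p, X, config.gene_activation), y))
        if val is not None:
            vloss = _bce(forward(p, val[0], config.gene_activation), val[1])
            history["val_loss"].append(vloss)
            if config.early_stopping:
                if vloss < best_val - 1e-9:
                    best_val, best_params, stale = vloss, p.copy(), 0
                else:
                    stale += 1
                    if stale >= config.patience:
                        break
    if config.early_stopping and best_params is not None:
        p = best_params
    return p, history


def gene_importances(ensemble_params, k: int = 150, magnitude: bool = False) -> pd.DataFrame:
    """Rank genes by the mean of their output-layer weight across an ensemble.

    The gene node's weight into the logistic output is its contribution
    coefficient; averaging across independently trained models smooths run
    to run variation.  ``magnitude`` averages absolute weights instead,
    guarding against sign non-identifiability cancelling means.  Ties break
    by gene_id.  Returns a frame sorted by rank with a ``top`` flag on the
    first ``k`` genes.
    """
    if not ensemble_params:
        raise ValueError("empty ensemble")
    first = ensemble_params[0]
    for p in ensemble_params[1:]:
        if not np.array_equal(p.gene_index, first.gene_index):
            raise ValueError("ensemble members have different topologies")
    W = np.stack([
        np.abs(p.gene_output_weights) if magnitude else p.gene_output_weights
        for p in ensemble_params
    ])
    means = W.mean(axis=0)
    gene_ids = first.gene_ids or [f"gene_{g}" for g in range(first.n_genes)]
    df = pd.DataFrame({"gene_id": gene_ids, "mean_weight": means})
    df = df.sort_values(["mean_weight", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["top"] = df["rank"] <= k
    return df.reset_index(drop=True)


def top_gene_list(importances: pd.DataFrame, k: int = 150) -> list:
    """The k highest-ranked gene symbols, in rank order."""
    if k > len(importances):
        raise ValueError(f"k={k} exceeds the {len(importances)} ranked genes")
    return importances.nsmallest(k, "rank")["gene_id"].tolist()
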