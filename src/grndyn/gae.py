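"""Graph autoencoder for proposing missing edges in a gene regulatory network.

Architecture: a two-layer GraphSAGE encoder (mean aggregation over the
undirected view of the graph) followed by a bilinear inner-product decoder,

    z = ReLU(W1' h + W2' mean_{j in N(i)} h_j)   (twice)
    score(i, j) = sigmoid(z_i^T W3 z_j),

trained with binary cross entropy over a labelled set of edges and non-edges.
Regularization is edge dropout (resampled every epoch before aggregation) and
feature dropout on the first layer's output. The model is small enough that
forward and backward passes are written directly in numpy; optimization is
Adam with Glorot-uniform initialization.

The leave-one-out improvement policy trains one fresh model per candidate
pair, excluding that pair from the labels, and reads off the trained model's
score for it; candidates scoring at or above a threshold join the improved
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.metrics import roc_auc_score

from .network import GeneNetwork
from .simulate import ExpressionDataset

__all__ = [
    "GAEConfig",
    "GAEWeights",
    "EdgeScoreMatrix",
    "TrainingTask",
    "sage_layer",
    "encode",
    "decode",
    "bce_loss",
    "train",
    "improve_graph",
    "split_train",
]

_EPS = 1e-7


@dataclass(frozen=True)
class GAEConfig:
    hidden_dim: int = 200
    learning_rate: float = 1e-4
    epochs: int = 1000
    edge_dropout: float = 0.2
    feature_dropout: float = 0.3
    threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.edge_dropout < 1 and 0 <= self.feature_dropout < 1):
            raise ValueError("dropout probabilities must lie in [0, 1)")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class GAEWeights:
    """Learnable parameters: two SAGE layers plus the bilinear decoder form."""

    W1_1: np.ndarray  # hidden x n_features (self transform, layer 1)
    W2_1: np.ndarray  # hidden x n_features (neighbour transform, layer 1)
    W1_2: np.ndarray  # hidden x hidden
    W2_2: np.ndarray  # hidden x hidden
    W3: np.ndarray  # hidden x hidden bilinear form

    def as_list(self) -> list[np.ndarray]:
        return [self.W1_1, self.W2_1, self.W1_2, self.W2_2, self.W3]

    @staticmethod
    def glorot(n_features: int, hidden: int, rng: np.random.Generator) -> "GAEWeights":
        def g(fan_out: int, fan_in: int) -> np.ndarray:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=(fan_out, fan_in))

        return GAEWeights(
            W1_1=g(hidden, n_features),
            W2_1=g(hidden, n_features),
            W1_2=g(hidden, hidden),
            W2_2=g(hidden, hidden),
            W3=g(hidden, hidden),
        )


@dataclass(frozen=True)
class EdgeScoreMatrix:
    """Decoder scores for every ordered gene pair (self-pairs included)."""

    scores: np.ndarray  # m x m, in [0, 1]
    candidate_mask: np.ndarray  # m x m bool, True for pairs not in the input edge set
    genes: tuple[str, ...] = field(default=())

    def score(self, source: str, target: str) -> float:
        i = self.genes.index(source)
        j = self.genes.index(target)
        return float(self.scores[i, j])


@dataclass(frozen=True)
class TrainingTask:
    """Labelled ordered pairs: positives (label 1), negatives (label 0).

    ``held_out`` is the single candidate excluded from both label sets in the
    leave-one-out policy.
    """

    positives: frozenset[tuple[str, str]]
    negatives: frozenset[tuple[str, str]]
    held_out: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if self.held_out is not None and (
            self.held_out in self.positives or self.held_out in self.negatives
        ):
            raise ValueError("held_out pair must be excluded from the labels")

    @property
    def n_labelled(self) -> int:
        return len(self.positives) + len(self.negatives)


def _undirected_adjacency(
    net: GeneNetwork, kept_edges: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric 0/1 adjacency over the (optionally edge-dropped) edge set.

    Self-loops are excluded: the neighbourhood N(i) never contains i itself
    (the node's own features enter through the W1 term).
    """
    idx = {g: i for i, g in enumerate(net.genes)}
    A = np.zeros((net.m, net.m))
    edges = sorted(net.edges, key=lambda e: (idx[e[0]], idx[e[1]]))
    for k, (s, t) in enumerate(edges):
        if kept_edges is not None and not kept_edges[k]:
            continue
        i, j = idx[s], idx[t]
        if i != j:
            A[i, j] = 1.0
            A[j, i] = 1.0
    return A


def _mean_aggregator(net: GeneNetwork, kept_edges: np.ndarray | None = None) -> np.ndarray:
    A = _undirected_adjacency(net, kept_edges)
    deg = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        N = np.where(deg > 0, A / deg, 0.0)
    return N


def sage_layer(
    H: np.ndarray, net: GeneNetwork, W1: np.ndarray, W2: np.ndarray
) -> np.ndarray:
    """One GraphSAGE mean-aggregation layer.

    ``out_i = ReLU(W1 H_i + W2 mean_{j in N(i)} H_j)`` where N(i) is the set
    of neighbours under the undirected view of the edge set; an empty
    neighbourhood contributes a zero aggregate.
    """
    H = np.asarray(H, dtype=float)
    if H.shape[0] != net.m:
        raise ValueError(f"feature rows ({H.shape[0]}) != gene count ({net.m})")
    if W1.shape[1] != H.shape[1] or W2.shape[1] != H.shape[1]:
        raise ValueError("weight/feature dimension mismatch")
    N = _mean_aggregator(net)
    return np.maximum(H @ W1.T + (N @ H) @ W2.T, 0.0)


def _as_features(X) -> np.ndarray:
    if isinstance(X, ExpressionDataset):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def _forward(
    X: np.ndarray,
    N: np.ndarray,
    w: GAEWeights,
    drop_mask: np.ndarray | None,
):
    """Forward pass, returning intermediates needed for backprop."""
    P1 = X @ w.W1_1.T + (N @ X) @ w.W2_1.T
    H1 = np.maximum(P1, 0.0)
    H1d = H1 if drop_mask is None else H1 * drop_mask
    P2 = H1d @ w.W1_2.T + (N @ H1d) @ w.W2_2.T
    Z = np.maximum(P2, 0.0)
    logits = Z @ w.W3 @ Z.T
    return P1, H1d, P2, Z, logits


def encode(
    X,
    net: GeneNetwork,
    weights: GAEWeights,
    config: GAEConfig,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two SAGE layers mapping node features to embeddings Z (m x hidden).

    In training mode a single dropout realization is applied: each edge is
    dropped with probability ``edge_dropout`` before aggregation and the first
    layer's outputs are zeroed elementwise with probability
    ``feature_dropout`` (inverted-dropout rescaling). Evaluation mode applies
    no dropout.
    """
    X = _as_features(X)
    if X.shape[0] != net.m:
        raise ValueError(f"feature rows ({X.shape[0]}) != gene count ({net.m})")
    if training_mode:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        kept = rng.random(net.n_edges) >= config.edge_dropout
        N = _mean_aggregator(net, kept)
        p = config.feature_dropout
        drop = (rng.random((net.m, config.hidden_dim)) >= p) / (1.0 - p) if p > 0 else None
    else:
        N = _mean_aggregator(net)
        drop = None
    _, _, _, Z, _ = _forward(X, N, weights, drop)
    return Z


def decode(Z: np.ndarray, W3: np.ndarray) -> EdgeScoreMatrix:
    """Bilinear sigmoid decoder: score(i, j) = sigmoid(z_i^T W3 z_j)."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != W3.shape[0]:
        raise ValueError("embedding/bilinear-form dimension mismatch")
    logits = Z @ W3 @ Z.T
    scores = _sigmoid(logits)
    m = Z.shape[0]
    return EdgeScoreMatrix(scores=scores, candidate_mask=np.ones((m, m), bool))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(scores, task: TrainingTask, genes: tuple[str, ...] | None = None) -> float:
    """Mean binary cross entropy over the labelled pairs (scores clamped)."""
    if task.n_labelled == 0:
        raise ValueError("training task has no labelled pairs")
    if isinstance(scores, EdgeScoreMatrix):
        S = scores.scores
        genes = genes or scores.genes
    else:
        S = np.asarray(scores, dtype=float)
    if genes is None:
        raise ValueError("gene ordering required to index the score matrix")
    idx = {g: i for i, g in enumerate(genes)}
    total = 0.0
    for (s, t) in task.positives:
        total -= np.log(np.clip(S[idx[s], idx[t]], _EPS, 1 - _EPS))
    for (s, t) in task.negatives:
        total -= np.log(1.0 - np.clip(S[idx[s], idx[t]], _EPS, 1 - _EPS))
    return float(total / task.n_labelled)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v, strict=True):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _label_arrays(task: TrainingTask, genes: tuple[str, ...]):
    idx = {g: i for i, g in enumerate(genes)}
    rows, cols, labels = [], [], []
    for (s, t) in sorted(task.positives, key=lambda e: (idx[e[0]], idx[e[1]])):
        rows.append(idx[s]); cols.append(idx[t]); labels.append(1.0)
    for (s, t) in sorted(task.negatives, key=lambda e: (idx[e[0]], idx[e[1]])):
        rows.append(idx[s]); cols.append(idx[t]); labels.append(0.0)
    return np.array(rows), np.array(cols), np.array(labels)


def train(
    net: GeneNetwork,
    X,
    task: TrainingTask,
    config: GAEConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GAEWeights, EdgeScoreMatrix]:
    """Train the autoencoder with Adam on the BCE loss.

    Edge dropout is resampled independently every epoch; the returned score
    matrix is computed in evaluation mode (no dropout). Fixed seed gives a
    bit-reproducible result.
    """
    X = _as_features(X)
    if X.shape[0] != net.m:
        raise ValueError(f"feature rows ({X.shape[0]}) != gene count ({net.m})")
    if task.n_labelled == 0:
        raise ValueError("training task has no labelled pairs")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = GAEWeights.glorot(X.shape[1], config.hidden_dim, rng)
    params = w.as_list()
    opt = _Adam(params, config.learning_rate)
    rows, cols, labels = _label_arrays(task, net.genes)
    n_lab = len(labels)
    p_d = config.feature_dropout

    for epoch in range(config.epochs):
        kept = rng.random(net.n_edges) >= config.edge_dropout
        N = _mean_aggregator(net, kept)
        drop = (
            (rng.random((net.m, config.hidden_dim)) >= p_d) / (1.0 - p_d)
            if p_d > 0
            else None
        )
        P1, H1d, P2, Z, logits = _forward(X, N, w, drop)
        probs = _sigmoid(logits[rows, cols])
        clipped = np.clip(probs, _EPS, 1 - _EPS)
        loss = -np.mean(labels * np.log(clipped) + (1 - labels) * np.log(1 - clipped))
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at epoch {epoch}")

        # backprop: d loss / d logits is (sigma - y) / n on labelled pairs
        G = np.zeros_like(logits)
        np.add.at(G, (rows, cols), (probs - labels) / n_lab)
        dW3 = Z.T @ G @ Z
        dZ = G @ Z @ w.W3.T + G.T @ Z @ w.W3
        dP2 = dZ * (P2 > 0)
        dW1_2 = dP2.T @ H1d
        dW2_2 = dP2.T @ (N @ H1d)
        dH1d = dP2 @ w.W1_2 + N.T @ dP2 @ w.W2_2
        dH1 = dH1d if drop is None else dH1d * drop
        dP1 = dH1 * (P1 > 0)
        dW1_1 = dP1.T @ X
        dW2_1 = dP1.T @ (N @ X)
        opt.step(params, [dW1_1, dW2_1, dW1_2, dW2_2, dW3])

    Z = encode(X, net, w, config, training_mode=False)
    scores = _sigmoid(Z @ w.W3 @ Z.T)
    mask = net.adjacency() == 0
    return w, EdgeScoreMatrix(scores=scores, candidate_mask=mask, genes=net.genes)


def improve_graph(
    net: GeneNetwork,
    X,
    config: GAEConfig,
) -> tuple[GeneNetwork, dict[tuple[str, str], float]]:
    """Leave-one-out candidate scoring followed by thresholded edge addition.

    For every ordered pair not in the edge set (self-pairs included) a fresh
    model is trained with that pair held out of the labels — positives are the
    input edges, negatives all remaining non-edges — and the trained model's
    score for the pair is recorded. Pairs scoring >= ``config.threshold`` are
    added to the returned network. One training per candidate, m^2 - |E| in
    total.
    """
    candidates = net.non_edges(include_self=True)
    if not candidates:
        raise ValueError("network is complete; no candidate pairs to score")
    X = _as_features(X)
    scores: dict[tuple[str, str], float] = {}
    positives = frozenset(net.edges)
    cand_set = set(candidates)
    for k, cand in enumerate(candidates):
        negatives = frozenset(cand_set - {cand})
        task = TrainingTask(positives=positives, negatives=negatives, held_out=cand)
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, k)))
        _, score_matrix = train(net, X, task, config, rng=rng)
        scores[cand] = score_matrix.score(*cand)
    added = [c for c in candidates if scores[c] >= config.threshold]
    return net.with_edges(added), scores


def split_train(
    net: GeneNetwork,
    X,
    config: GAEConfig,
    val_frac: float = 0.1,
    test_frac: float = 0.1,
    n_runs: int = 10,
) -> list[float]:
    """Edge-splitting evaluation protocol for larger networks.

    Per run: withhold disjoint validation and test edge sets (removed from the
    graph used for aggregation as well as from the labels) plus equal-size
    sampled non-edge negatives; train on the remaining edges with 1:1 sampled
    negatives; report the AUROC of test-edge scores against test-negative
    scores. Returns one AUROC per run.
    """
    if val_frac < 0 or test_frac < 0 or val_frac + test_frac >= 1:
        raise ValueError("val_frac + test_frac must be < 1 and both nonnegative")
    edges = sorted(net.edges)
    n_test = int(round(test_frac * len(edges)))
    n_val = int(round(val_frac * len(edges)))
    if n_test < 1:
        raise ValueError("too few edges for the requested test fraction")
    X = _as_features(X)
    non_edges = net.non_edges(include_self=True)
    aurocs: list[float] = []
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, run)))
        perm = rng.permutation(len(edges))
        test_e = [edges[i] for i in perm[:n_test]]
        val_e = [edges[i] for i in perm[n_test : n_test + n_val]]
        train_e = [edges[i] for i in perm[n_test + n_val :]]

        neg_perm = rng.permutation(len(non_edges))
        need = n_test + n_val + len(train_e)
        chosen = [non_edges[i] for i in neg_perm[: min(need, len(non_edges))]]
        test_n = chosen[:n_test]
        val_n = chosen[n_test : n_test + n_val]
        train_n = chosen[n_test + n_val :]

        net_train = GeneNetwork(
            net.genes,
            frozenset(train_e),
            {e: s for e, s in net.signs.items() if e in set(train_e)},
        )
        task = TrainingTask(frozenset(train_e), frozenset(train_n))
        _, score_matrix = train(net_train, X, task, config, rng=rng)
        y = [1] * len(test_e) + [0] * len(test_n)
        s = [score_matrix.score(*e) for e in test_e] + [
            score_matrix.score(*e) for e in test_n
        ]
        aurocs.append(float(roc_auc_score(y, s)))
    return aurocs
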