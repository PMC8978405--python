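"""Node embeddings for similarity networks (node2vec).

Two stages: (1) second-order biased random walks over the weighted graph —
the step from ``curr`` given the previous node ``prev`` weights each
neighbor x by ``w(curr, x) * alpha`` with ``alpha = 1/p`` when x == prev,
``1`` when x neighbors prev, and ``1/q`` otherwise; (2) skip-gram with
negative sampling trained on the walk corpus, word2vec-style: dynamic
context windows, noise distribution proportional to corpus frequency^0.75,
learning rate decaying linearly over the run.

The unit diagonal of similarity matrices is not treated as a self-loop:
walks never step from a node to itself.

Node identity, not insertion order, keys all randomness: graphs are
canonicalized to sorted-id order before walking, so permuting the input
node order leaves every per-node vector unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import child_seed
from .similarity import SimilarityGraph

logger = logging.getLogger(__name__)

__all__ = [
    "WalkConfig",
    "SkipGramConfig",
    "WalkCorpus",
    "EmbeddingMatrix",
    "transition_distribution",
    "generate_walks",
    "train_skipgram",
    "embed_graph",
]


@dataclass
class WalkConfig:
    """Biased-walk parameters: return bias p, in-out bias q, r walks of
    length l per node."""

    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


@dataclass
class SkipGramConfig:
    """Skip-gram-with-negative-sampling hyperparameters."""

    dim: int = 100
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1 or self.negatives < 1:
            raise ValueError("window and negatives must be >= 1")


@dataclass
class WalkCorpus:
    """A bag of node-id walks sampled from one similarity graph."""

    walks: list[list[str]]
    source: str


@dataclass
class EmbeddingMatrix:
    """node id -> real vector map produced by the embedding stage.

    ``training_loss`` holds the per-epoch mean skip-gram loss when the
    matrix came out of :func:`train_skipgram`.
    """

    node_ids: list[str]
    vectors: np.ndarray
    training_loss: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("one vector per node required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._index) != len(self.node_ids):
            raise ValueError("duplicate node ids in embedding")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node_id: str) -> np.ndarray:
        return self.vectors[self._index[node_id]]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index


def _adjacency(graph: SimilarityGraph) -> np.ndarray:
    """Walkable weights: the similarity matrix with the diagonal zeroed."""
    adj = graph.weights.copy()
    np.fill_diagonal(adj, 0.0)
    return adj


def transition_distribution(
    prev_node: str | None, curr_node: str, graph: SimilarityGraph, p: float, q: float
) -> np.ndarray:
    """Second-order step distribution out of ``curr_node`` given ``prev_node``.

    Returns a probability vector over ``graph.node_ids`` (zero for
    non-neighbors).  With ``prev_node=None`` the first-order,
    weight-proportional distribution is returned.
    """
    idx = {nid: i for i, nid in enumerate(graph.node_ids)}
    adj = _adjacency(graph)
    ci = idx[curr_node]
    w = adj[ci].copy()
    if not (w > 0).any():
        raise ValueError(f"node {curr_node!r} has no positive-weight neighbor")
    if prev_node is not None:
        pi = idx[prev_node]
        alpha = np.where(adj[pi] > 0, 1.0, 1.0 / q)
        alpha[pi] = 1.0 / p
        w = w * alpha
    total = w.sum()
    if total <= 0:
        raise ValueError(f"no admissible transition out of {curr_node!r}")
    return w / total


@njit(cache=True)
def _walk_kernel(adj, starts, walk_length, p, q, seed):  # pragma: no cover - jitted
    n = adj.shape[0]
    np.random.seed(seed)
    walks = np.full((starts.shape[0], walk_length), -1, dtype=np.int64)
    probs = np.empty(n)
    for wi in range(starts.shape[0]):
        curr = starts[wi]
        walks[wi, 0] = curr
        prev = -1
        for step in range(1, walk_length):
            total = 0.0
            for x in range(n):
                wgt = adj[curr, x]
                if wgt > 0.0 and prev >= 0:
                    if x == prev:
                        wgt /= p
                    elif adj[prev, x] <= 0.0:
                        wgt /= q
                probs[x] = wgt
                total += wgt
            if total <= 0.0:
                break  # stuck: truncate the walk
            r = np.random.random() * total
            acc = 0.0
            nxt = -1
            for x in range(n):
                acc += probs[x]
                if r < acc:
                    nxt = x
                    break
            if nxt < 0:
                nxt = n - 1
            walks[wi, step] = nxt
            prev = curr
            curr = nxt
    return walks


def generate_walks(graph: SimilarityGraph, config: WalkConfig) -> WalkCorpus:
    """Sample ``walks_per_node`` biased walks from every non-isolated node.

    The start-node order is reshuffled on each pass; the first step of a walk
    is weight-proportional, later steps follow the second-order bias.
    Identical seeds yield identical corpora.
    """
    order = np.argsort(np.array(graph.node_ids, dtype=object))
    ids = [graph.node_ids[i] for i in order]
    adj = _adjacency(graph)[np.ix_(order, order)]

    degrees = (adj > 0).sum(axis=1)
    if degrees.sum() == 0:
        raise ValueError("graph has no edges")
    non_isolated = np.flatnonzero(degrees > 0)
    if len(non_isolated) < len(ids):
        skipped = [ids[i] for i in np.flatnonzero(degrees == 0)]
        logger.warning("skipping %d isolated nodes: %s", len(skipped), skipped[:10])

    rng = np.random.default_rng(config.seed)
    starts = np.concatenate(
        [rng.permutation(non_isolated) for _ in range(config.walks_per_node)]
    )
    kernel_seed = int(rng.integers(0, 2**31))
    raw = _walk_kernel(
        adj, starts.astype(np.int64), config.walk_length,
        float(config.p), float(config.q), kernel_seed,
    )
    walks = [[ids[x] for x in row if x >= 0] for row in raw]
    return WalkCorpus(walks=walks, source=graph.kind)


@njit(cache=True)
def _sgns_kernel(
    walks, lengths, W, C, noise_cdf, window, negatives, epochs, lr0, seed
):  # pragma: no cover - jitted
    n_walks = walks.shape[0]
    dim = W.shape[1]
    vocab = W.shape[0]
    total_tokens = 0
    for wi in range(n_walks):
        total_tokens += lengths[wi]
    total_tokens *= epochs
    state = np.uint64(seed * 2862933555777941757 + 3037000493)

    losses = np.zeros(epochs)
    counts = np.zeros(epochs, dtype=np.int64)
    processed = 0
    grad = np.empty(dim)
    lr_min = lr0 * 1e-4
    for ep in range(epochs):
        for wi in range(n_walks):
            L = lengths[wi]
            for i in range(L):
                processed += 1
                lr = lr0 * (1.0 - processed / (total_tokens + 1.0))
                if lr < lr_min:
                    lr = lr_min
                # xorshift64* draws
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state ^= state >> np.uint64(27)
                u = np.uint64(state * np.uint64(2685821657736338717))
                b = 1 + int(u % np.uint64(window))
                center = walks[wi, i]
                lo = i - b if i - b > 0 else 0
                hi = i + b + 1 if i + b + 1 < L else L
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = walks[wi, j]
                    for d in range(dim):
                        grad[d] = 0.0
                    # positive pair
                    dot = 0.0
                    for d in range(dim):
                        dot += W[center, d] * C[ctx, d]
                    if dot > 30.0:
                        dot = 30.0
                    elif dot < -30.0:
                        dot = -30.0
                    f = 1.0 / (1.0 + np.exp(-dot))
                    losses[ep] += -np.log(f + 1e-12)
                    counts[ep] += 1
                    g = (1.0 - f) * lr
                    for d in range(dim):
                        grad[d] += g * C[ctx, d]
                        C[ctx, d] += g * W[center, d]
                    # negative samples
                    for _k in range(negatives):
                        state ^= state >> np.uint64(12)
                        state ^= state << np.uint64(25)
                        state ^= state >> np.uint64(27)
                        u = np.uint64(state * np.uint64(2685821657736338717))
                        r = (np.float64(u >> np.uint64(11))) / 9007199254740992.0
                        neg = np.searchsorted(noise_cdf, r)
                        if neg >= vocab:
                            neg = vocab - 1
                        if neg == ctx:
                            continue
                        dot = 0.0
                        for d in range(dim):
                            dot += W[center, d] * C[neg, d]
                        if dot > 30.0:
                            dot = 30.0
                        elif dot < -30.0:
                            dot = -30.0
                        f = 1.0 / (1.0 + np.exp(-dot))
                        losses[ep] += -np.log(1.0 - f + 1e-12)
                        g = -f * lr
                        for d in range(dim):
                            grad[d] += g * C[neg, d]
                            C[neg, d] += g * W[center, d]
                    for d in range(dim):
                        W[center, d] += grad[d]
    for ep in range(epochs):
        if counts[ep] > 0:
            losses[ep] /= counts[ep]
    return losses


def train_skipgram(
    corpus: WalkCorpus,
    config: SkipGramConfig,
    expected_nodes: list[str] | None = None,
) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on a walk corpus.

    The vocabulary is the sorted set of nodes observed in the corpus; if
    ``expected_nodes`` is given, any expected node absent from the corpus is
    a hard error.  Deterministic under ``config.seed``.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    vocab = sorted({node for walk in corpus.walks for node in walk})
    if expected_nodes is not None:
        missing = sorted(set(expected_nodes) - set(vocab))
        if missing:
            raise ValueError(f"nodes never observed in any walk: {missing[:10]}")
    index = {nid: i for i, nid in enumerate(vocab)}

    max_len = max(len(w) for w in corpus.walks)
    walks = np.zeros((len(corpus.walks), max_len), dtype=np.int64)
    lengths = np.zeros(len(corpus.walks), dtype=np.int64)
    counts = np.zeros(len(vocab))
    for wi, walk in enumerate(corpus.walks):
        lengths[wi] = len(walk)
        for j, node in enumerate(walk):
            k = index[node]
            walks[wi, j] = k
            counts[k] += 1

    noise = counts**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(config.seed)
    W = (rng.random((len(vocab), config.dim)) - 0.5) / config.dim
    C = np.zeros((len(vocab), config.dim))

    losses = _sgns_kernel(
        walks, lengths, W, C, noise_cdf,
        config.window, config.negatives, config.epochs,
        float(config.learning_rate), int(rng.integers(1, 2**31)),
    )
    logger.info("skip-gram epoch losses: %s", np.round(losses, 4).tolist())
    return EmbeddingMatrix(node_ids=vocab, vectors=W, training_loss=losses)


def embed_graph(
    graph: SimilarityGraph,
    walk_config: WalkConfig | None = None,
    sg_config: SkipGramConfig | None = None,
    seed: int | None = None,
) -> EmbeddingMatrix:
    """Walks + skip-gram for one similarity graph.

    When ``seed`` is given it overrides both stage seeds via named child
    seeds, keyed additionally by the graph kind so drug and protein networks
    get independent streams.
    """
    walk_config = walk_config or WalkConfig()
    sg_config = sg_config or SkipGramConfig()
    if seed is not None:
        walk_config = WalkConfig(
            p=walk_config.p, q=walk_config.q,
            walks_per_node=walk_config.walks_per_node,
            walk_length=walk_config.walk_length,
            seed=child_seed(seed, f"walks:{graph.kind}"),
        )
        sg_config = SkipGramConfig(
            dim=sg_config.dim, window=sg_config.window,
            negatives=sg_config.negatives, epochs=sg_config.epochs,
            learning_rate=sg_config.learning_rate,
            seed=child_seed(seed, f"skipgram:{graph.kind}"),
        )
    corpus = generate_walks(graph, walk_config)
    observed = {n for w in corpus.walks for n in w}
    return train_skipgram(corpus, sg_config, expected_nodes=sorted(observed))
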