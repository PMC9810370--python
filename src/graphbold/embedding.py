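"""Connectome embeddings: biased random walks, skip-gram, similarity graph.

Each region of the structural graph is embedded into a low-dimensional
vector space by running second-order (node2vec-style) biased random walks
and training a skip-gram model with negative sampling on the resulting
node-sequence corpus.  Pearson correlation between embedding vectors then
defines an alternative coupling matrix A_CE in which regions with similar
structural neighborhood roles are strongly connected — including long-range
relations that are weak in the raw streamline-count adjacency.

Walk parameters follow the node2vec convention: the return parameter ``p``
penalizes stepping back to the previous node (weight w/p), nodes at
distance 1 from the previous node keep weight w, and nodes at distance 2
are weighted w/q by the in-out parameter ``q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import WeightedAdjacency

__all__ = [
    "EmbeddingConfig",
    "NodeEmbedding",
    "biased_walks",
    "train_embeddings",
    "embedding_similarity",
    "connectome_embedding_adjacency",
]


@dataclass
class EmbeddingConfig:
    """node2vec walk and skip-gram hyperparameters.

    dim/walks_per_node/walk_length/return_p/inout_q follow the reference
    connectome-embedding setup (64, 100, 80, 2.0, 1.0).  The skip-gram
    window, epochs and negative-sample count are not pinned down by that
    setup; common node2vec defaults are used and surfaced here.
    """

    dim: int = 64
    walks_per_node: int = 100
    walk_length: int = 80
    return_p: float = 2.0
    inout_q: float = 1.0
    window: int = 10
    epochs: int = 5
    negative: int = 5
    learning_rate: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.dim, self.walks_per_node, self.walk_length,
               self.window, self.epochs) < 1:
            raise ValueError("counts must be positive")
        if self.return_p <= 0 or self.inout_q <= 0:
            raise ValueError("p and q must be > 0")


@dataclass
class NodeEmbedding:
    """N x dim embedding matrix, row order = region order."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding values")


def biased_walks(A: WeightedAdjacency | np.ndarray,
                 cfg: EmbeddingConfig) -> list[list[int]]:
    """Generate N * walks_per_node biased second-order walks.

    Isolated nodes emit length-1 walks (immediate termination).  The walk
    is reproducible under cfg.seed.
    """
    w = A.weights if isinstance(A, WeightedAdjacency) else np.asarray(A, float)
    if np.any(w < 0):
        raise ValueError("walk weights must be nonnegative")
    N = w.shape[0]
    if not np.any(w > 0):
        raise ValueError("all-zero graph: walk corpus would be empty")
    csr = sp.csr_matrix(w)
    neighbors = [csr.indices[csr.indptr[i]:csr.indptr[i + 1]] for i in range(N)]
    weights = [csr.data[csr.indptr[i]:csr.indptr[i + 1]] for i in range(N)]
    neighbor_sets = [set(nb.tolist()) for nb in neighbors]
    rng = np.random.default_rng(cfg.seed)
    p, q = cfg.return_p, cfg.inout_q

    walks = []
    for start in range(N):
        for _ in range(cfg.walks_per_node):
            walk = [start]
            if len(neighbors[start]) == 0:
                walks.append(walk)
                continue
            # first step: first-order transition
            wt = weights[start]
            cur = int(rng.choice(neighbors[start], p=wt / wt.sum()))
            walk.append(cur)
            while len(walk) < cfg.walk_length:
                nb = neighbors[cur]
                if len(nb) == 0:
                    break
                prev = walk[-2]
                wt = weights[cur].astype(float).copy()
                prev_nb = neighbor_sets[prev]
                for j, cand in enumerate(nb):
                    if cand == prev:
                        wt[j] /= p
                    elif cand not in prev_nb:
                        wt[j] /= q
                cur = int(rng.choice(nb, p=wt / wt.sum()))
                walk.append(cur)
            walks.append(walk)
    return walks


def _skipgram_pairs(walks: list[list[int]], window: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(center, context) index pairs with per-pair sampled window radius."""
    centers, contexts = [], []
    for walk in walks:
        L = len(walk)
        for i, c in enumerate(walk):
            # word2vec-style dynamic window: radius uniform in 1..window
            r = int(rng.integers(1, window + 1))
            for j in range(max(0, i - r), min(L, i + r + 1)):
                if j != i:
                    centers.append(c)
                    contexts.append(walk[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_embeddings(walks: list[list[int]], cfg: EmbeddingConfig,
                     n_nodes: int | None = None) -> NodeEmbedding:
    """Skip-gram with negative sampling over the walk corpus.

    Deterministic under cfg.seed (single-threaded minibatch SGD with a
    linearly decaying learning rate).  Nodes absent from the corpus raise.
    """
    if not walks:
        raise ValueError("empty walk corpus")
    if n_nodes is None:
        n_nodes = max(max(w) for w in walks) + 1
    counts = np.zeros(n_nodes)
    for w in walks:
        for node in w:
            counts[node] += 1
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"nodes absent from walk corpus: {missing.tolist()}")

    rng = np.random.default_rng(cfg.seed + 1)
    centers, contexts = _skipgram_pairs(walks, cfg.window, rng)
    n_pairs = centers.size

    # unigram^(3/4) negative-sampling distribution
    noise = counts ** 0.75
    noise /= noise.sum()

    dim = cfg.dim
    W_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    W_out = np.zeros((n_nodes, dim))

    batch = 4096
    total_steps = cfg.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            idx = order[lo:lo + batch]
            c, o = centers[idx], contexts[idx]
            B = c.size
            neg = rng.choice(n_nodes, size=(B, cfg.negative), p=noise)
            lr = cfg.learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += 1

            vc = W_in[c]                        # (B, d)
            targets = np.concatenate([o[:, None], neg], axis=1)  # (B, 1+neg)
            vt = W_out[targets]                  # (B, 1+neg, d)
            score = np.einsum("bd,bkd->bk", vc, vt)
            sig = 0.5 * (1.0 + np.tanh(0.5 * score))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            err = sig - label                    # d loss / d score
            grad_c = np.einsum("bk,bkd->bd", err, vt)
            grad_t = (err[:, :, None] * vc[:, None, :]).reshape(-1, dim)
            # mean gradient per node: a node occurring many times in one
            # batch must not receive a proportionally larger step
            acc_in = np.zeros_like(W_in)
            cnt_in = np.zeros(n_nodes)
            np.add.at(acc_in, c, grad_c)
            np.add.at(cnt_in, c, 1.0)
            acc_out = np.zeros_like(W_out)
            cnt_out = np.zeros(n_nodes)
            np.add.at(acc_out, targets.ravel(), grad_t)
            np.add.at(cnt_out, targets.ravel(), 1.0)
            W_in -= lr * acc_in / np.maximum(cnt_in, 1.0)[:, None]
            W_out -= lr * acc_out / np.maximum(cnt_out, 1.0)[:, None]
    return NodeEmbedding(W_in)


def embedding_similarity(E: NodeEmbedding | np.ndarray) -> WeightedAdjacency:
    """Pearson correlation between embedding rows; diagonal zeroed.

    Self-similarity is excluded from the transition substrate (the k=0 term
    of a diffusion filter already carries self-influence).
    """
    V = E.vectors if isinstance(E, NodeEmbedding) else np.asarray(E, float)
    if V.shape[1] < 2:
        raise ValueError("need embedding dim >= 2 for correlation")
    sd = V.std(axis=1)
    if np.any(sd < 1e-300):
        raise ValueError(
            f"constant embedding row(s) {np.flatnonzero(sd < 1e-300).tolist()}: "
            "correlation undefined"
        )
    C = np.corrcoef(V)
    np.fill_diagonal(C, 0.0)
    C = 0.5 * (C + C.T)  # enforce exact symmetry against rounding
    return WeightedAdjacency(C, kind="CE")


def connectome_embedding_adjacency(A: WeightedAdjacency,
                                   cfg: EmbeddingConfig) -> WeightedAdjacency:
    """Full pipeline: walks -> skip-gram -> Pearson similarity A_CE.

    Isolated nodes (zero degree in A) receive an all-zero similarity row
    and column instead of failing.
    """
    walks = biased_walks(A, cfg)
    emb = train_embeddings(walks, cfg, n_nodes=A.n_nodes)
    sim = embedding_similarity(emb)
    degree = A.weights.sum(axis=1)
    isolated = degree == 0
    if np.any(isolated):
        w = sim.weights.copy()
        w[isolated, :] = 0.0
        w[:, isolated] = 0.0
        sim = WeightedAdjacency(w, kind="CE")
    return sim
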