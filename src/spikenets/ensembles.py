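"""Ensemble detection by spectral rejection against a configuration-model null.

Pipeline: compare the functional graph W with the expectation <P> of a
weighted configuration model (WCM); eigenvalues of the deviation matrix
B = W - <P> that exceed the null eigenspectrum's upper bound (estimated from
sparse WCM samples) indicate community structure.  Nodes projecting no
further from the origin than their null counterparts are rejected as noise;
the remaining nodes are clustered by k-means in the retained eigenspace many
times, and the repeats are resolved into one partition by consensus
clustering against an explicit permutation null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .datatypes import ConfigError, FunctionalGraph
from .partitions import Partition

REDISTRIBUTE_MODES = ("chunks", "quanta")


@dataclass
class DetectParams:
    """Tunable parameters of :func:`detect_ensembles`.

    ``n_null`` WCM samples estimate the null eigenspectrum bound; clustering
    is repeated ``n_repeats`` times before consensus.  ``conversion`` sets the
    weight-quantisation resolution of the sparse null sampler and
    ``redistribute`` its weight-redistribution scheme (see
    :func:`sample_sparse_wcm`).  All randomness derives from ``seed``.
    """

    n_null: int = 100
    n_repeats: int = 100
    conversion: float = 100.0
    redistribute: str = "chunks"
    consensus_tol: float = 0.05
    consensus_max_iter: int = 20
    consensus_null_samples: int = 20
    consensus_repeats: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_null < 10:
            raise ConfigError("n_null must be at least 10")
        if self.n_repeats < 2:
            raise ConfigError("n_repeats must be at least 2")
        if self.redistribute not in REDISTRIBUTE_MODES:
            raise ConfigError(
                f"unknown redistribute mode {self.redistribute!r}; "
                f"choose from {REDISTRIBUTE_MODES}"
            )


def expected_null_matrix(graph: FunctionalGraph) -> np.ndarray:
    """Expected adjacency of the weighted configuration model.

    ``<P>_ij = s_i s_j / (2m)`` with ``s`` the node strengths and ``m`` the
    total weight.  The diagonal term ``s_i^2 / (2m)`` is retained so that the
    total expected weight equals the data's exactly (``sum <P> = 2m``) and the
    deviation matrix has exact zero row sums.
    """
    s = graph.strengths
    two_m = s.sum()
    if two_m <= 0:
        raise ConfigError("graph has no weight; the null model is undefined")
    return np.outer(s, s) / two_m


def _quantise_largest_remainder(weights: np.ndarray, conversion: float) -> np.ndarray:
    """Integer quanta per edge with the exact total ``round(sum(w)*conversion)``."""
    scaled = weights * conversion
    total = int(round(scaled.sum()))
    base = np.floor(scaled).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        remainders = scaled - base
        top = np.argsort(remainders)[::-1][:short]
        base[top] += 1
    elif short < 0:
        order = np.argsort(scaled - base)
        take = 0
        for idx in order:
            if take == -short:
                break
            if base[idx] > 0:
                base[idx] -= 1
                take += 1
    return base


def sample_sparse_wcm(
    graph: FunctionalGraph,
    seed=0,
    conversion: float = 100.0,
    redistribute: str = "chunks",
) -> FunctionalGraph:
    """One sample of the sparse weighted configuration model.

    Edge presence is Bernoulli with ``p_ij = min(1, k_i k_j / (2M))`` from the
    binary degree sequence ``k`` (``M`` edges), preserving expected degrees
    and sparsity.  The data's total weight, quantised to
    ``round(m * conversion)`` integer quanta, is then redistributed over the
    realised edges with probability proportional to ``s_i s_j / p_ij`` (the
    inverse-inclusion weighting keeps node strengths preserved in
    expectation):

    - ``redistribute="chunks"`` (default) reassigns each data edge's quanta as
      one indivisible chunk, so samples inherit the empirical edge-weight
      distribution (weight disorder) of the data;
    - ``redistribute="quanta"`` scatters individual quanta multinomially,
      giving smoother per-edge weights.

    Total weight is conserved exactly at quantum resolution in every sample.
    """
    if redistribute not in REDISTRIBUTE_MODES:
        raise ConfigError(
            f"unknown redistribute mode {redistribute!r}; "
            f"choose from {REDISTRIBUTE_MODES}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    w = graph.weights
    n = graph.n_nodes
    iu = np.triu_indices(n, k=1)
    w_u = w[iu]
    if not np.any(w_u > 0):
        raise ConfigError("graph has no edges to resample")
    k = (w > 0).sum(axis=1).astype(float)
    two_m_edges = k.sum()
    p = np.minimum(1.0, (k[iu[0]] * k[iu[1]]) / two_m_edges)
    realised = rng.random(p.size) < p
    if not realised.any():
        candidates = np.flatnonzero(p > 0)
        realised[rng.choice(candidates)] = True

    s = graph.strengths
    m = w_u.sum()
    score = np.zeros(p.size)
    np.divide(
        s[iu[0]] * s[iu[1]], p, out=score, where=(p > 0) & realised
    )
    score[~realised] = 0.0
    if score.sum() <= 0:
        score[realised] = 1.0
    probs = score / score.sum()

    quanta_per_edge = _quantise_largest_remainder(w_u[w_u > 0], conversion)
    n_quanta = int(quanta_per_edge.sum())
    quantum = m / n_quanta
    placed = np.zeros(p.size, dtype=np.int64)
    if redistribute == "quanta":
        placed = rng.multinomial(n_quanta, probs)
    else:
        chunks = quanta_per_edge[quanta_per_edge > 0]
        targets = rng.choice(p.size, size=chunks.size, p=probs)
        np.add.at(placed, targets, chunks)

    w_new = np.zeros((n, n))
    w_new[iu] = placed * quantum
    w_new += w_new.T
    meta = {
        "null": "sparse_wcm",
        "redistribute": redistribute,
        "conversion": conversion,
        "n_quanta": n_quanta,
    }
    return FunctionalGraph(w_new, graph.node_ids, meta=meta)


def deviation_matrix(w: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Deviation of the data network from the null expectation, B = W - <P>."""
    w = np.asarray(w, dtype=float)
    p = np.asarray(p, dtype=float)
    if w.shape != p.shape:
        raise ConfigError(f"shape mismatch: {w.shape} vs {p.shape}")
    if not np.allclose(w, w.T, atol=1e-10) or not np.allclose(p, p.T, atol=1e-10):
        raise ConfigError("both matrices must be symmetric")
    return w - p


@dataclass
class NullEnsemble:
    """Eigenspectrum statistics of N sparse-WCM samples.

    Stores each sample's full eigendecomposition so that node-rejection can
    compare data projections with the matching null projections.  The upper
    bound is the mean of the samples' largest deviation eigenvalues; the lower
    bound (mean of the smallest) is retained for diagnostics.
    """

    expected: np.ndarray
    sample_min: np.ndarray
    sample_max: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_max)

    @property
    def upper_bound(self) -> float:
        return float(self.sample_max.mean())

    @property
    def lower_bound(self) -> float:
        return float(self.sample_min.mean())


def null_spectrum_bounds(
    graph: FunctionalGraph,
    n_samples: int = 100,
    seed: int = 0,
    conversion: float = 100.0,
    redistribute: str = "chunks",
) -> NullEnsemble:
    """Estimate the null eigenspectrum from N sparse-WCM samples.

    Each sample's deviation matrix against the expected WCM matrix is
    eigendecomposed; the bounds are the means of the extreme eigenvalues.
    """
    if n_samples < 10:
        raise ConfigError("need at least 10 null samples")
    expected = expected_null_matrix(graph)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = graph.n_nodes
    vals = np.empty((n_samples, n))
    vecs = np.empty((n_samples, n, n))
    for i in range(n_samples):
        sample = sample_sparse_wcm(
            graph, rng, conversion=conversion, redistribute=redistribute
        )
        b_i = sample.weights - expected
        vals[i], vecs[i] = eigh(b_i)
    return NullEnsemble(
        expected=expected,
        sample_min=vals[:, 0].copy(),
        sample_max=vals[:, -1].copy(),
        eigvals=vals,
        eigvecs=vecs,
        seed=seed,
    )


def _embedding(vals: np.ndarray, vecs: np.ndarray, d: int) -> np.ndarray:
    """Spectral embedding of the nodes: top-d eigenvectors scaled by the
    square root of their (non-negative) eigenvalues, so that X Xᵀ reproduces
    the retained part of the matrix."""
    top = np.argsort(vals)[::-1][:d]
    return vecs[:, top] * np.sqrt(np.clip(vals[top], 0.0, None))


def _projection_lengths(vals: np.ndarray, vecs: np.ndarray, d: int) -> np.ndarray:
    """L2 projection length of each node in the top-d spectral embedding."""
    return np.linalg.norm(_embedding(vals, vecs, d), axis=1)


def reject_nodes(
    b: np.ndarray, null: NullEnsemble, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split nodes into signal and noise by their eigenspace projections.

    Each node's projection length across the d retained dimensions of the
    spectral embedding of B is compared with the mean projection length of
    the same node over the null samples' top-d embeddings; nodes at or below
    their null mean are noise.  Returns ``(signal_indices, noise_indices)``.
    """
    if d < 1:
        return np.array([], dtype=int), np.arange(b.shape[0])
    vals, vecs = eigh(b)
    proj = _projection_lengths(vals, vecs, d)
    null_proj = np.mean(
        [
            _projection_lengths(null.eigvals[i], null.eigvecs[i], d)
            for i in range(null.n_samples)
        ],
        axis=0,
    )
    signal = np.flatnonzero(proj > null_proj)
    noise = np.flatnonzero(proj <= null_proj)
    return signal, noise


def partition_quality(b: np.ndarray, labels: np.ndarray) -> float:
    """Modularity-style quality Q = sum of B_ij over same-cluster pairs."""
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


def cluster_eigenspace(
    b: np.ndarray,
    d: int,
    n_repeats: int = 100,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Repeated k-means partitions of the retained eigenspace.

    Nodes are placed in the top ``min(d, n-1)``-dimensional spectral
    embedding of ``b`` (eigenvectors scaled by the square root of their
    eigenvalues).  Each repeat scans k over 2..d+1 (skipping k beyond the
    node count), keeps the k maximising the quality Q, ties broken by the
    smallest k.  Returns the label arrays and their qualities.
    """
    n = b.shape[0]
    if n < 2:
        raise ConfigError("need at least 2 nodes to cluster")
    if d < 1:
        raise ConfigError("need at least 1 retained dimension")
    vals, vecs = eigh(b)
    coords = _embedding(vals, vecs, min(d, n - 1))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ks = [k for k in range(2, d + 2) if k <= n]
    partitions, qualities = [], []
    for _ in range(n_repeats):
        best_labels, best_q = None, -np.inf
        for k in ks:
            km = KMeans(
                n_clusters=k,
                n_init=10,
                random_state=int(rng.integers(2**31)),
            )
            labels = km.fit_predict(coords)
            q = partition_quality(b, labels)
            if q > best_q:
                best_labels, best_q = labels, q
        partitions.append(best_labels)
        qualities.append(best_q)
    return partitions, np.asarray(qualities)


def _coassignment(label_list: list[np.ndarray], n: int) -> np.ndarray:
    c = np.zeros((n, n))
    for lab in label_list:
        c += lab[:, None] == lab[None, :]
    return c / len(label_list)


def _expected_coassignment(label_list: list[np.ndarray], n: int) -> float:
    """Mean co-assignment probability under random relabelling of each
    partition (preserving its cluster sizes)."""
    if n < 2:
        return 0.0
    total = 0.0
    for lab in label_list:
        _, counts = np.unique(lab, return_counts=True)
        total += (counts * (counts - 1)).sum() / (n * (n - 1))
    return total / len(label_list)


def _components(adjacency: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    return labels


def consensus_partition(
    partitions,
    seed: int = 0,
    tol: float = 0.05,
    max_iter: int = 20,
    n_null: int = 20,
    n_repeats: int = 50,
) -> tuple[np.ndarray, bool]:
    """Resolve many clusterings into one by iterative consensus clustering.

    The consensus matrix C holds the fraction of partitions placing each node
    pair together.  Its deviation from the expected co-assignment under a
    label-permutation null is spectrally clustered (same k-means procedure as
    the main pipeline, with the retained dimension set by a permutation-null
    eigenvalue bound); the resulting partitions replace the inputs until C is
    effectively binary (all off-diagonal entries within ``tol`` of 0 or 1).

    Accepts :class:`~spikenets.partitions.Partition` objects or label arrays,
    all over the same nodes in the same order.  Returns ``(labels,
    converged)``; on non-convergence the best current grouping is returned
    with ``converged=False``.
    """
    label_list = [
        p.codes() if isinstance(p, Partition) else np.asarray(p)
        for p in partitions
    ]
    if len(label_list) < 2:
        raise ConfigError("consensus needs at least 2 partitions")
    n = len(label_list[0])
    if any(len(lab) != n for lab in label_list):
        raise ConfigError("all partitions must cover the same nodes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    current = label_list
    c = _coassignment(current, n)
    offdiag = ~np.eye(n, dtype=bool)
    for _ in range(max_iter):
        c = _coassignment(current, n)
        entries = c[offdiag]
        if np.all((entries <= tol) | (entries >= 1 - tol)):
            return _components(c >= 0.5), True
        pbar = _expected_coassignment(current, n)
        dev = c - pbar
        np.fill_diagonal(dev, 0.0)
        null_max = []
        for _ in range(n_null):
            perm = [rng.permutation(lab) for lab in current]
            cp = _coassignment(perm, n)
            dp = cp - pbar
            np.fill_diagonal(dp, 0.0)
            null_max.append(np.linalg.eigvalsh(dp)[-1])
        bound = float(np.mean(null_max))
        vals = np.linalg.eigvalsh(dev)
        d_cons = int((vals > bound).sum())
        if d_cons == 0:
            return np.zeros(n, dtype=int), True
        current, _ = cluster_eigenspace(
            dev, d_cons, n_repeats=n_repeats, seed=int(rng.integers(2**31))
        )
    return _components(c >= 0.5), False


@dataclass
class EnsembleResult:
    """Output of :func:`detect_ensembles`.

    ``signal`` and ``noise`` are disjoint index arrays covering all nodes;
    the consensus partition is defined on the signal nodes.
    """

    d: int
    node_ids: np.ndarray
    signal: np.ndarray
    noise: np.ndarray
    consensus: Partition
    repeats: list = field(default_factory=list)
    repeat_quality: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True
    seed: int = 0

    @property
    def n_ensembles(self) -> int:
        return self.consensus.n_clusters

    def to_json(self) -> str:
        payload = {
            "d": int(self.d),
            "n_ensembles": int(self.n_ensembles),
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "signal": [str(self.node_ids[i]) for i in self.signal],
            "noise": [str(self.node_ids[i]) for i in self.noise],
            "consensus": {
                str(nid): int(lab)
                for nid, lab in zip(self.consensus.node_ids, self.consensus.codes())
            },
            "repeat_quality": [float(q) for q in self.repeat_quality],
        }
        return json.dumps(payload, indent=2)


def detect_ensembles(
    graph: FunctionalGraph, params: DetectParams | None = None
) -> EnsembleResult:
    """Full spectral-rejection ensemble detection on a functional graph.

    Runs the null-spectrum estimate, counts the data deviation eigenvalues
    above the null upper bound (d), rejects weakly-projecting nodes, clusters
    the signal nodes ``n_repeats`` times in the retained eigenspace, and
    resolves the repeats by consensus.  ``d = 0`` yields a single community
    containing every node.
    """
    params = params or DetectParams()
    if graph.total_weight <= 0:
        raise ConfigError("cannot detect ensembles in a graph with no weight")
    ss = np.random.SeedSequence(params.seed)
    seed_null, seed_cluster, seed_consensus = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )
    null = null_spectrum_bounds(
        graph,
        n_samples=params.n_null,
        seed=seed_null,
        conversion=params.conversion,
        redistribute=params.redistribute,
    )
    b = deviation_matrix(graph.weights, null.expected)
    vals = np.linalg.eigvalsh(b)
    d = int((vals > null.upper_bound).sum())
    n = graph.n_nodes
    all_nodes = np.arange(n)

    def single_community(signal, noise):
        ids = graph.node_ids[signal] if len(signal) else graph.node_ids
        return EnsembleResult(
            d=d,
            node_ids=graph.node_ids,
            signal=np.asarray(signal),
            noise=np.asarray(noise),
            consensus=Partition(ids, np.zeros(len(ids), dtype=int)),
            seed=params.seed,
        )

    if d == 0:
        return single_community(all_nodes, np.array([], dtype=int))
    signal, noise = reject_nodes(b, null, d)
    if len(signal) < 2:
        return single_community(all_nodes, np.array([], dtype=int))
    b_signal = b[np.ix_(signal, signal)]
    repeats, qualities = cluster_eigenspace(
        b_signal, d, n_repeats=params.n_repeats, seed=seed_cluster
    )
    labels, converged = consensus_partition(
        repeats,
        seed=seed_consensus,
        tol=params.consensus_tol,
        max_iter=params.consensus_max_iter,
        n_null=params.consensus_null_samples,
        n_repeats=params.consensus_repeats,
    )
    return EnsembleResult(
        d=d,
        node_ids=graph.node_ids,
        signal=signal,
        noise=noise,
        consensus=Partition(graph.node_ids[signal], labels),
        repeats=repeats,
        repeat_quality=qualities,
        converged=converged,
        seed=params.seed,
    )
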