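"""Partitions of a node set and information-theoretic comparisons.

A partition assigns every node to exactly one cluster (clusters are pairwise
disjoint and cover the node set).  Both anatomical region assignments and
detected ensembles are represented this way, so the same machinery compares
them: partition entropy, mutual information, variation of information (VI),
and same-cluster pair fractions.  All information quantities use log base 2
and are reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import xlogy

from .datatypes import ConfigError


@dataclass
class Partition:
    """Disjoint, covering assignment of nodes to clusters.

    ``labels[i]`` is the cluster label of ``node_ids[i]``.  Labels may be any
    hashable values; only the grouping matters.
    """

    node_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids)
        self.labels = np.asarray(self.labels)
        if self.node_ids.size == 0:
            raise ConfigError("a partition must cover at least one node")
        if self.node_ids.shape != self.labels.shape:
            raise ConfigError("node_ids and labels must have the same length")
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ConfigError("node_ids must be unique")

    @classmethod
    def from_sets(cls, clusters) -> "Partition":
        """Build a partition from an iterable of disjoint node collections."""
        nodes, labels = [], []
        for k, members in enumerate(clusters):
            for node in members:
                nodes.append(node)
                labels.append(k)
        return cls(np.asarray(nodes), np.asarray(labels))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def sizes(self) -> np.ndarray:
        """Cluster sizes, sorted descending."""
        _, counts = np.unique(self.labels, return_counts=True)
        return np.sort(counts)[::-1]

    def codes(self) -> np.ndarray:
        """Labels recoded as integers 0..K-1 (ordered by first appearance)."""
        _, first, inverse = np.unique(
            self.labels, return_index=True, return_inverse=True
        )
        order = np.argsort(np.argsort(first))
        return order[inverse]

    def restrict(self, node_ids) -> "Partition":
        """Return the partition restricted to ``node_ids`` (kept in that order)."""
        node_ids = np.asarray(node_ids)
        pos = {nid: i for i, nid in enumerate(self.node_ids.tolist())}
        try:
            idx = np.array([pos[nid] for nid in node_ids.tolist()], dtype=int)
        except KeyError as err:
            raise ConfigError(f"node {err.args[0]!r} is not in the partition") from None
        return Partition(self.node_ids[idx], self.labels[idx])

    def clusters(self) -> dict:
        """Mapping label -> array of member node ids."""
        return {
            lab: self.node_ids[self.labels == lab] for lab in np.unique(self.labels)
        }


def _aligned_codes(a: Partition, b: Partition) -> tuple[np.ndarray, np.ndarray]:
    """Integer label codes of two partitions over the same node set, aligned
    to a common node order.  Raises if the node sets differ."""
    if a.n_nodes != b.n_nodes or set(a.node_ids.tolist()) != set(b.node_ids.tolist()):
        raise ConfigError("partitions must cover the same node set")
    b = b.restrict(a.node_ids)
    return a.codes(), b.codes()


def partition_entropy(p: Partition) -> float:
    """Shannon entropy of the cluster-size distribution, in bits."""
    counts = np.unique(p.labels, return_counts=True)[1].astype(float)
    probs = counts / counts.sum()
    return float(-np.sum(xlogy(probs, probs)) / np.log(2))


def contingency_table(a: Partition, b: Partition) -> np.ndarray:
    """Joint cluster-membership counts N_kl over the shared node set."""
    ca, cb = _aligned_codes(a, b)
    ka, kb = ca.max() + 1, cb.max() + 1
    table = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(table, (ca, cb), 1)
    return table

def mutual_information(a: Partition, b: Partition) -> float:
    """Mutual information between two partitions, in bits."""
    table = contingency_table(a, b).astype(float)
    n = table.sum()
    pij = table / n
    pa = pij.sum(axis=1, keepdims=True)
    pb = pij.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pij > 0, pij / (pa * pb), 1.0)
    return float(np.sum(xlogy(pij, ratio)) / np.log(2))


def variation_of_information(a: Partition, b: Partition) -> float:
    """Variation of information VI = H(A) + H(B) - 2 I(A, B), in bits.

    VI is a metric on the space of partitions: non-negative, zero iff the
    partitions group nodes identically, symmetric, and satisfying the
    triangle inequality.
    """
    ca, cb = _aligned_codes(a, b)
    if np.array_equal(ca, cb):
        return 0.0
    vi = partition_entropy(a) + partition_entropy(b) - 2.0 * mutual_information(a, b)
    return float(max(vi, 0.0))


def same_clustering(a: Partition, b: Partition) -> bool:
    """True if the two partitions induce the same grouping (labels may differ)."""
    ca, cb = _aligned_codes(a, b)
    return bool(np.array_equal(ca, cb))


class SameEnsembleFractions(NamedTuple):
    frac_same: float
    frac_diff: float
    difference: float


def same_ensemble_fractions(
    ensembles: Partition, regions: Partition
) -> SameEnsembleFractions:
    """Fraction of unit pairs co-clustered, split by anatomical relationship.

    Over unordered pairs of the shared node set, returns the fraction of
    same-region pairs that fall in the same ensemble, the fraction of
    different-region pairs that do, and their difference.  A category with no
    pairs yields NaN for that fraction.
    """
    ce, cr = _aligned_codes(ensembles, regions)
    n = len(ce)
    iu = np.triu_indices(n, k=1)
    same_e = (ce[:, None] == ce[None, :])[iu]
    same_r = (cr[:, None] == cr[None, :])[iu]
    frac_same = float(same_e[same_r].mean()) if same_r.any() else float("nan")
    frac_diff = float(same_e[~same_r].mean()) if (~same_r).any() else float("nan")
    return SameEnsembleFractions(frac_same, frac_diff, frac_same - frac_diff)
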