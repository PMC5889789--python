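"""Signed-modularity community detection with consensus clustering.

The quality of a partition of a signed weighted network is scored with the
asymmetric signed modularity

    Q* = Q+ - (v-/(v+ + v-)) Q-,

where the positive part W+ and the magnitude of the negative part W- of the
weight matrix each get a classic modularity term

    Q± = (1/v±) Σ_ij (w±_ij - s±_i s±_j / v±) δ(c_i, c_j),

with s±_i the signed strength of node i and v± the total signed weight
(Q± is defined as 0 when v± = 0).  Positive weights dominate: a community
is rewarded for concentrating positive weight and penalized, with smaller
leverage, for containing negative weight.

Optimization is a Louvain-style two-phase greedy procedure (local moving +
aggregation) run directly on the signed modularity matrix, and is made
stable by consensus clustering: many randomized runs vote through a
co-assignment (agreement) matrix that is itself re-clustered until all runs
agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .network import SimilarityNetwork


class CommunityError(ValueError):
    """Raised for invalid clustering inputs."""


class ConsensusError(RuntimeError):
    """Raised when consensus clustering fails to converge within the cap."""

    def __init__(self, message, n_rounds=None, agreement=None):
        super().__init__(message)
        self.n_rounds = n_rounds
        self.agreement = agreement


@dataclass
class Partition:
    """Community labels (0-based, contiguous) and their quality index Q*."""

    labels: np.ndarray
    q_value: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        k = self.n_communities
        if k and not np.array_equal(np.unique(self.labels), np.arange(k)):
            raise CommunityError("labels must cover 0..K-1 without gaps")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_communities)


@dataclass
class ConsensusResult:
    """Outcome of consensus clustering.

    ``agreement`` is the final-round co-assignment matrix A (A_ij = fraction
    of runs placing i and j together, diagonal 1); the partition's Q* is
    evaluated on the original network, not on the agreement matrix.
    """

    partition: Partition
    agreement: np.ndarray
    n_rounds: int
    runs_per_round: int


def _as_weights(net) -> np.ndarray:
    if isinstance(net, SimilarityNetwork):
        return net.weights
    w = np.asarray(net, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise CommunityError("network must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-12):
        raise CommunityError("network must be symmetric")
    return w


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..K-1 in order of first appearance."""
    _, canon = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty_like(canon)
    nxt = 0
    for i, c in enumerate(canon):
        if c not in order:
            order[c] = nxt
            nxt += 1
        out[i] = order[c]
    return out


def signed_modularity_matrix(w: np.ndarray) -> np.ndarray:
    """The matrix M with Q*(c) = Σ_{ij : c_i = c_j} M_ij.

    M combines the positive and negative modularity matrices, each
    normalized by its total weight, with the negative part downweighted by
    v- / (v+ + v-).
    """
    w = _as_weights(w)
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    vp = wp.sum()
    vn = wn.sum()
    if vp == 0 and vn == 0:
        raise CommunityError("network has no edges")
    m = np.zeros_like(w)
    if vp > 0:
        sp = wp.sum(axis=1)
        m += (wp - np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        m -= (vn / (vp + vn)) * (wn - np.outer(sn, sn) / vn) / vn
    return m


def signed_modularity(net, labels) -> float:
    """Evaluate Q* of a labeling on a signed network."""
    w = _as_weights(net)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(w):
        raise CommunityError(
            f"labels cover {len(labels)} nodes, network has {len(w)}"
        )
    m = signed_modularity_matrix(w)
    return _partition_quality(m, labels)


def _partition_quality(m: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(m[same].sum())


def _local_move(m: np.ndarray, rng: np.random.Generator, tol: float = 1e-12):
    """One local-moving phase on a (possibly aggregated) modularity matrix.

    Each node in shuffled order is moved to the community with the largest
    positive Q* gain (ties broken by the lowest community index), repeated
    until a full sweep makes no move.  Returns contiguous labels.
    """
    n = len(m)
    labels = np.arange(n)
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            a = labels[i]
            s = np.bincount(labels, weights=m[i], minlength=n)
            base = s[a] - m[i, i]  # i's off-diagonal weight into its community
            gains = s - base
            gains[a] = -np.inf
            b = int(np.argmax(gains))
            if gains[b] > tol:
                labels[i] = b
                moved = True
    return _canonical(labels)


def _aggregate(m: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    onehot = np.eye(k)[labels]
    return onehot.T @ m @ onehot


def louvain(net, seed: int = 0) -> Partition:
    """Signed-modularity Louvain: local moving + aggregation to a fixed point.

    The node visit order is shuffled by ``seed``, making individual runs
    randomized but reproducible.  The returned partition carries its Q* on
    the input network.
    """
    w = _as_weights(net)
    if len(w) < 2:
        raise CommunityError("need at least 2 nodes")
    m = signed_modularity_matrix(w)
    rng = np.random.default_rng(seed)

    node_map = np.arange(len(w))
    current = m
    while True:
        local = _local_move(current, rng)
        if local.max() + 1 == len(current):
            break  # every supernode kept its own community: fixed point
        node_map = local[node_map]
        current = _aggregate(current, local)
    labels = _canonical(node_map)
    return Partition(labels=labels, q_value=_partition_quality(m, labels))


def _coassignment(label_rows: np.ndarray) -> np.ndarray:
    """Mean co-assignment matrix over runs (rows are label vectors)."""
    runs, n = label_rows.shape
    agree = np.zeros((n, n))
    for row in label_rows:
        agree += row[:, None] == row[None, :]
    return agree / runs


def consensus_cluster(
    net,
    runs: int = 100,
    tau: float = 0.3,
    seed: int = 0,
    max_rounds: int = 50,
) -> ConsensusResult:
    """Stabilize Louvain by re-clustering the agreement matrix to consensus.

    Each round runs Louvain ``runs`` times with distinct seeds.  If all runs
    return the same partition the procedure has converged; otherwise the
    co-assignment matrix is thresholded (entries below ``tau`` zeroed,
    diagonal removed) and becomes the network for the next round.  The final
    partition's Q* is evaluated on the original network.

    Raises
    ------
    ConsensusError
        If the runs still disagree after ``max_rounds`` rounds; the error
        carries the round count and the last agreement matrix.
    """
    w = _as_weights(net)
    if runs < 2:
        raise CommunityError("need at least 2 runs per round")
    rng = np.random.default_rng(seed)
    current = w
    agreement = None
    for round_idx in range(1, max_rounds + 1):
        seeds = rng.integers(0, 2**31 - 1, size=runs)
        label_rows = np.array([louvain(current, int(s)).labels for s in seeds])
        agreement = _coassignment(label_rows)
        first = label_rows[0]
        if all(adjusted_rand_score(first, row) == 1.0 for row in label_rows[1:]):
            labels = _canonical(first)
            q = signed_modularity(w, labels)
            np.fill_diagonal(agreement, 1.0)
            return ConsensusResult(
                partition=Partition(labels=labels, q_value=q),
                agreement=agreement,
                n_rounds=round_idx,
                runs_per_round=runs,
            )
        thresholded = np.where(agreement < tau, 0.0, agreement)
        np.fill_diagonal(thresholded, 0.0)
        current = thresholded
    raise ConsensusError(
        f"consensus did not converge within {max_rounds} rounds",
        n_rounds=max_rounds,
        agreement=agreement,
    )


def adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same node set."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise CommunityError(
            f"label vectors differ in length: {labels_a.shape} vs {labels_b.shape}"
        )
    return float(adjusted_rand_score(labels_a, labels_b))


def robustness_sweep(
    p_within_values,
    p_between_values,
    noise_values,
    n_nodes: int = 120,
    n_communities: int = 3,
    reps: int = 10,
    runs: int = 20,
    tau: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted-partition recovery across a parameter grid.

    For every (p_within, p_between, noise_sd) cell with p_between <=
    p_within, ``reps`` networks are generated, consensus-clustered, and
    scored against the planted truth.

    Returns
    -------
    pandas.DataFrame
        Columns p_within, p_between, noise_sd, mean_ari, mean_q.
    """
    from .synthetic import PlantedPartitionSpec, generate_planted_network

    rng = np.random.default_rng(seed)
    rows = []
    for p_w in p_within_values:
        for p_b in p_between_values:
            if p_b > p_w:
                continue
            for noise in noise_values:
                aris = []
                qs = []
                for _ in range(reps):
                    spec = PlantedPartitionSpec(
                        n_nodes=n_nodes,
                        n_communities=n_communities,
                        p_within=p_w,
                        p_between=p_b,
                        noise_sd=noise,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    planted_net, truth = generate_planted_network(spec)
                    if np.abs(planted_net.weights).sum() == 0:
                        aris.append(0.0)
                        qs.append(0.0)
                        continue
                    result = consensus_cluster(
                        planted_net,
                        runs=runs,
                        tau=tau,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    aris.append(adjusted_rand(result.partition.labels, truth))
                    qs.append(result.partition.q_value)
                rows.append(
                    {
                        "p_within": p_w,
                        "p_between": p_b,
                        "noise_sd": noise,
                        "mean_ari": float(np.mean(aris)),
                        "mean_q": float(np.mean(qs)),
                    }
                )
    return pd.DataFrame(rows)
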