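"""Signed person-by-person similarity networks.

Each child is a node; the edge between two children is the correlation of
their six-scale residual profiles.  The full signed matrix is retained —
negative correlations are informative to the signed community-detection
algorithm, so no thresholding or sparsification is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SCALES, residual_matrix


class NetworkError(ValueError):
    """Raised for malformed similarity networks or partitions."""


@dataclass
class SimilarityNetwork:
    """A symmetric, zero-diagonal, signed weighted network.

    ``check_bounds`` enforces |w_ij| <= 1 and is set for correlation-built
    networks; planted benchmark networks may carry noise outside [-1, 1].
    """

    node_ids: list
    weights: np.ndarray
    check_bounds: bool = field(default=True, repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        self.weights = w
        n = len(self.node_ids)
        if w.shape != (n, n):
            raise NetworkError(f"weight matrix {w.shape} does not match {n} nodes")
        if not np.allclose(w, w.T, atol=1e-12):
            raise NetworkError("weight matrix is not symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > 1e-12:
            raise NetworkError("diagonal must be zero")
        if self.check_bounds and np.abs(w).max(initial=0.0) > 1.0 + 1e-9:
            raise NetworkError("correlation weights must lie in [-1, 1]")
        # exact symmetry and exact zero diagonal from here on
        self.weights = (w + w.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def build_network(residuals: pd.DataFrame, method: str = "pearson") -> SimilarityNetwork:
    """Correlate every pair of children's six-scale residual profiles.

    Parameters
    ----------
    residuals:
        Output of :func:`efsubtype.preprocess.residualize_age` (``child_id``
        plus one column per scale).
    method:
        ``"pearson"`` (default) or ``"spearman"``.

    Returns
    -------
    SimilarityNetwork
        Signed child-by-child correlation matrix with zero diagonal.
    """
    profiles = residual_matrix(residuals)
    ids = list(residuals["child_id"])
    n = len(ids)
    if n < 3:
        raise NetworkError(f"need at least 3 children, got {n}")
    sd = profiles.std(axis=1)
    for i in np.nonzero(sd < 1e-12)[0]:
        raise NetworkError(f"child '{ids[i]}' has a constant profile")

    if method == "pearson":
        w = np.corrcoef(profiles)
    elif method == "spearman":
        ranks = stats.rankdata(profiles, axis=1)
        w = np.corrcoef(ranks)
    else:
        raise NetworkError(f"unknown correlation method '{method}'")
    w = np.clip(w, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return SimilarityNetwork(node_ids=ids, weights=w)


def reorder_by_partition(net: SimilarityNetwork, labels) -> tuple[SimilarityNetwork, np.ndarray]:
    """Permute the network so communities are contiguous.

    Nodes are sorted by community label (stable within community), which is
    how the clustered correlation matrix is displayed.  Returns the permuted
    network and the permutation applied.
    """
    labels = np.asarray(labels)
    if len(labels) != net.n_nodes:
        raise NetworkError(
            f"partition covers {len(labels)} nodes, network has {net.n_nodes}"
        )
    order = np.argsort(labels, kind="stable")
    w = net.weights[np.ix_(order, order)]
    ids = [net.node_ids[i] for i in order]
    return (
        SimilarityNetwork(node_ids=ids, weights=w, check_bounds=net.check_bounds),
        order,
    )


def write_network_tsv(net: SimilarityNetwork, path) -> None:
    """Write the dense weight matrix as TSV with id header row/column."""
    frame = pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids)
    frame.to_csv(path, sep="\t")


def read_network_tsv(path, check_bounds: bool = True) -> SimilarityNetwork:
    """Read a dense TSV weight matrix written by :func:`write_network_tsv`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityNetwork(
        node_ids=[str(c) for c in frame.columns],
        weights=frame.to_numpy(dtype=float),
        check_bounds=check_bounds,
    )


def write_edge_list(net: SimilarityNetwork, path) -> None:
    """Write the upper-triangle edge list as CSV (i, j, weight)."""
    iu = np.triu_indices(net.n_nodes, k=1)
    frame = pd.DataFrame(
        {
            "i": [net.node_ids[a] for a in iu[0]],
            "j": [net.node_ids[b] for b in iu[1]],
            "weight": net.weights[iu],
        }
    )
    frame.to_csv(path, index=False)
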