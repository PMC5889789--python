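"""Connectome node-degree features and PLS modeling of group membership.

Each participant's structural connectome (symmetric FA-weighted region
matrix) is reduced to a node-degree vector — the count of suprathreshold
edges per region.  Partial least squares (PLS2) regression then finds the
linear combinations of regions that best explain group membership, coded as
a centered one-hot indicator matrix.  The model is evaluated by train/test
RMSE against label-permuted refits, by stratified cross-validation, and the
region loadings are stabilized by a subsampling bootstrap with orthogonal
Procrustes alignment, summarized as bootstrap ratios (mean / SE; |BSR| > 2
is read as reliable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .stats import bonferroni, mann_whitney_u

logger = logging.getLogger(__name__)

#: Bootstrap ratios above this magnitude are flagged as reliable.
BSR_THRESHOLD: float = 2.0

_SE_FLOOR = 1e-12
_BSR_CAP = 1e6


class PlsError(ValueError):
    """Raised for invalid PLS inputs."""


@dataclass
class ConnectomeSet:
    """Per-participant symmetric non-negative weight matrices plus labels."""

    participant_ids: list
    node_labels: list
    matrices: np.ndarray  # (n_participants, n_nodes, n_nodes)
    groups: np.ndarray

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.groups = np.asarray(self.groups)
        n_part = len(self.participant_ids)
        n_nodes = len(self.node_labels)
        if self.matrices.shape != (n_part, n_nodes, n_nodes):
            raise PlsError(
                f"matrices shape {self.matrices.shape} does not match "
                f"{n_part} participants x {n_nodes} nodes"
            )
        if len(self.groups) != n_part:
            raise PlsError("groups must cover every participant")
        if (self.matrices < 0).any():
            raise PlsError("connectome weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass
class PlsModel:
    """A fitted PLS2 model of group membership on node-degree features.

    ``y_explained`` holds the percent of (centered) indicator-matrix
    variance captured by each successive score vector; scores are mutually
    orthogonal by construction.
    """

    x_loadings: np.ndarray  # nodes x components
    scores: np.ndarray  # participants x components
    y_explained: np.ndarray  # percent per component
    group_order: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    kept_columns: np.ndarray
    _sk_model: PLSRegression = field(repr=False)

    @property
    def n_components(self) -> int:
        return self.x_loadings.shape[1]

    def predict_indicator(self, x: np.ndarray) -> np.ndarray:
        """Predict the one-hot group indicator for new degree rows."""
        xs = (np.asarray(x, dtype=float)[:, self.kept_columns] - self.x_mean) / self.x_scale
        return self._sk_model.predict(xs) + self._y_mean

    def __post_init__(self):
        self._y_mean = None  # set by fit_pls


def node_degree(conn: ConnectomeSet, threshold: float = 0.0, weighted: bool = False):
    """Reduce each connectome to per-node degree (or strength) features.

    degree_i = #{j != i : w_ij > threshold}; with ``weighted=True`` the sum
    of suprathreshold weights (node strength) is returned instead.

    Returns
    -------
    pandas.DataFrame
        participants x nodes, indexed by participant id.
    """
    mats = conn.matrices
    for p, m in enumerate(mats):
        if not np.allclose(m, m.T, atol=1e-10):
            raise PlsError(
                f"connectome for participant '{conn.participant_ids[p]}' "
                "is not symmetric"
            )
    above = mats > threshold
    if weighted:
        feat = (mats * above).sum(axis=2)
    else:
        feat = above.sum(axis=2).astype(int)
    return pd.DataFrame(feat, index=conn.participant_ids, columns=conn.node_labels)


def _one_hot(groups: np.ndarray):
    order = list(pd.unique(groups))
    y = np.zeros((len(groups), len(order)))
    for j, g in enumerate(order):
        y[groups == g, j] = 1.0
    return y, order


def fit_pls(x, groups, max_components: int = 3) -> PlsModel:
    """Fit PLS2 of the centered group-indicator matrix on degree features.

    X columns are centered and unit-scaled (constant columns are dropped
    with a warning).  The percent of outcome variance per component is the
    incremental R^2 of projecting the centered indicator matrix onto the
    successive (orthogonal) score vectors, so entries are non-negative and
    sum to at most 100.
    """
    x = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x.to_numpy(dtype=float)
    groups = np.asarray(groups)
    n = len(x)
    if len(groups) != n:
        raise PlsError("groups must cover every row of X")
    if len(pd.unique(groups)) < 2:
        raise PlsError("need at least 2 groups")
    if n <= max_components:
        raise PlsError("need more participants than components")

    sd = x.std(axis=0)
    kept = np.nonzero(sd > 1e-12)[0]
    if len(kept) < x.shape[1]:
        warnings.warn(
            f"dropping {x.shape[1] - len(kept)} constant feature column(s)",
            stacklevel=2,
        )
    if len(kept) == 0:
        raise PlsError("all feature columns are constant")
    x_mean = x[:, kept].mean(axis=0)
    x_scale = sd[kept]
    xs = (x[:, kept] - x_mean) / x_scale

    y, order = _one_hot(groups)
    y_mean = y.mean(axis=0)
    yc = y - y_mean

    n_comp = min(max_components, len(kept), n - 1)
    model = PLSRegression(n_components=n_comp, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when Y residual vanishes
        model.fit(xs, yc)

    scores = model.x_scores_
    ss_y = (yc**2).sum()
    explained = np.empty(n_comp)
    for c in range(n_comp):
        t = scores[:, c]
        tt = float(t @ t)
        if tt < 1e-300 or ss_y < 1e-300:
            explained[c] = 0.0
            continue
        proj = np.outer(t, (t @ yc) / tt)
        explained[c] = 100.0 * (proj**2).sum() / ss_y

    loadings = np.zeros((x.shape[1], n_comp))
    loadings[kept] = model.x_loadings_

    fitted = PlsModel(
        x_loadings=loadings,
        scores=scores,
        y_explained=explained,
        group_order=order,
        x_mean=x_mean,
        x_scale=x_scale,
        kept_columns=kept,
        _sk_model=model,
    )
    fitted._y_mean = y_mean
    return fitted


def retain_components(y_explained, floor: float = 5.0) -> int:
    """Longest leading run of components each explaining >= floor percent.

    This is a prefix rule, not a filter: the count stops at the first
    component that falls below the floor.
    """
    y_explained = np.asarray(y_explained, dtype=float)
    if y_explained.size == 0:
        raise PlsError("y_explained is empty")
    below = np.nonzero(y_explained < floor)[0]
    return int(below[0]) if below.size else int(y_explained.size)


def _indicator_rmse(y_hat: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def _stratified_split(groups, train_frac, rng, max_tries=100):
    n = len(groups)
    classes = pd.unique(groups)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        n_train = int(round(train_frac * n))
        train, test = perm[:n_train], perm[n_train:]
        ok = all(
            (groups[train] == c).any() and (groups[test] == c).any()
            for c in classes
        )
        if ok:
            return train, test
    raise PlsError("could not draw a split containing every class on both sides")


def evaluate_split(
    x,
    groups,
    train_frac: float = 0.6,
    n_perm: int = 1000,
    seed: int = 0,
    max_components: int = 3,
):
    """Train/test RMSE of the PLS model against label-permuted refits.

    The model is fit on a random ``train_frac`` of participants and its
    RMSE on the held-out one-hot indicators is compared with the null
    distribution obtained by refitting on permuted training labels;
    p = (#{null <= observed} + 1) / (n_perm + 1).

    Returns
    -------
    (rmse_test, rmse_null_mean, p_perm)
    """
    x = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x.to_numpy(dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    train, test = _stratified_split(groups, train_frac, rng)

    def _fit_rmse(train_groups):
        model = fit_pls(x[train], train_groups, max_components=max_components)
        y_hat = model.predict_indicator(x[test])
        # evaluate against the indicator coding of the *full* group order
        y_test = np.zeros((len(test), len(model.group_order)))
        for j, g in enumerate(model.group_order):
            y_test[groups[test] == g, j] = 1.0
        return _indicator_rmse(y_hat, y_test)

    observed = _fit_rmse(groups[train])
    null = np.empty(n_perm)
    for b in range(n_perm):
        for _ in range(100):
            shuffled = rng.permutation(groups[train])
            if len(pd.unique(shuffled)) >= 2:
                break
        null[b] = _fit_rmse(shuffled)
    p = (int((null <= observed).sum()) + 1) / (n_perm + 1)
    return float(observed), float(null.mean()), float(p)


def crossval_rmse(x, groups, k_folds: int = 10, seed: int = 0, max_components: int = 3):
    """Stratified k-fold cross-validated indicator RMSE: (mean, SE)."""
    x = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x.to_numpy(dtype=float)
    groups = np.asarray(groups)
    if len(groups) < k_folds:
        raise PlsError("need at least k_folds participants")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    rmses = []
    for train, test in skf.split(x, groups):
        model = fit_pls(x[train], groups[train], max_components=max_components)
        y_hat = model.predict_indicator(x[test])
        y_test = np.zeros((len(test), len(model.group_order)))
        for j, g in enumerate(model.group_order):
            y_test[groups[test] == g, j] = 1.0
        rmses.append(_indicator_rmse(y_hat, y_test))
    rmses = np.asarray(rmses)
    return float(rmses.mean()), float(rmses.std(ddof=1) / np.sqrt(k_folds))


def bootstrap_loadings(
    x,
    groups,
    n_boot: int = 1000,
    frac: float = 1.0,
    seed: int = 0,
    max_components: int = 3,
    reference: PlsModel | None = None,
    replace: bool = True,
):
    """Bootstrap ratios of PLS loadings under resampling with alignment.

    Per draw, ceil(frac * n) participants are resampled (by default an
    n-out-of-n bootstrap with replacement; ``frac=0.6, replace=False``
    gives a 60% subsampling variant instead — note that the heavy overlap
    between such subsamples makes the across-draw SD underestimate the
    loading SE and inflates the ratios), redrawn if a class goes missing.
    The refit loading matrix is aligned to the full-sample reference
    loadings by an orthogonal Procrustes rotation (rotation/reflection
    only, no scaling) to resolve component rotational indeterminacy.
    BSR = mean aligned loading / bootstrap SE, where the SE is the SD of
    the bootstrap distribution, floored at 1e-12; |BSR| is capped at 1e6
    (a capped entry indicates a degenerate, zero-variance loading and is
    flagged with a warning).

    Returns
    -------
    numpy.ndarray
        nodes x components bootstrap-ratio matrix.
    """
    x = np.asarray(x, dtype=float) if not isinstance(x, pd.DataFrame) else x.to_numpy(dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    n = len(x)
    m = int(np.ceil(frac * n))
    if reference is None:
        reference = fit_pls(x, groups, max_components=max_components)
    ref = reference.x_loadings
    n_comp = ref.shape[1]

    draws = np.empty((n_boot, ref.shape[0], n_comp))
    classes = pd.unique(groups)
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.choice(n, size=m, replace=replace)
            if all((groups[idx] == c).any() for c in classes):
                break
        else:
            raise PlsError("could not draw a subsample containing every class")
        model = fit_pls(x[idx], groups[idx], max_components=n_comp)
        boot = model.x_loadings
        if boot.shape[1] < n_comp:  # degenerate subsample: pad missing comps
            boot = np.pad(boot, ((0, 0), (0, n_comp - boot.shape[1])))
        rot, _ = orthogonal_procrustes(boot, ref)
        draws[b] = boot @ rot

    mean = draws.mean(axis=0)
    # the SD of the bootstrap distribution is the SE estimate of the loading
    se = draws.std(axis=0, ddof=1)
    degenerate = se < _SE_FLOOR
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} loading(s) had (near-)zero bootstrap "
            "variance; their ratios are capped",
            stacklevel=2,
        )
    bsr = mean / np.maximum(se, _SE_FLOOR)
    return np.clip(bsr, -_BSR_CAP, _BSR_CAP)


def compare_group_scores(scores, groups, n_components: int | None = None):
    """Pairwise Mann-Whitney tests on participant scores per component.

    Bonferroni correction spans components x group pairs.

    Returns
    -------
    pandas.DataFrame
        component, group_a, group_b, u, p_raw, p_corrected.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if n_components is None:
        n_components = scores.shape[1]
    order = list(pd.unique(groups))
    if len(order) < 2:
        raise PlsError("need at least 2 groups")
    for g in order:
        if (groups == g).sum() < 2:
            raise PlsError(f"group {g!r} has fewer than 2 members")
    pairs = [(a, b) for i, a in enumerate(order) for b in order[i + 1 :]]
    n_tests = n_components * len(pairs)
    rows = []
    for c in range(n_components):
        for a, b in pairs:
            u, p = mann_whitney_u(scores[groups == a, c], scores[groups == b, c])
            rows.append(
                {
                    "component": c + 1,
                    "group_a": a,
                    "group_b": b,
                    "u": u,
                    "p_raw": p,
                    "p_corrected": bonferroni(p, n_tests),
                }
            )
    return pd.DataFrame(rows)


def top_loading_report(
    bootstrap_ratios, node_labels, quantile: float = 0.75
) -> pd.DataFrame:
    """Per component: nodes in the top (1 - quantile) of |BSR|.

    Nodes tied with the quantile boundary are all included.  Each listed
    node carries a ``significant`` flag for |BSR| > 2 (reliability rule).
    """
    bsr = np.asarray(bootstrap_ratios, dtype=float)
    if bsr.ndim == 1:
        bsr = bsr[:, None]
    if bsr.shape[0] != len(node_labels):
        raise PlsError("bootstrap_ratios rows must match node_labels")
    rows = []
    for c in range(bsr.shape[1]):
        mag = np.abs(bsr[:, c])
        cut = np.quantile(mag, quantile)
        for i in np.nonzero(mag >= cut)[0]:
            rows.append(
                {
                    "component": c + 1,
                    "node": node_labels[i],
                    "bsr": float(bsr[i, c]),
                    "significant": bool(mag[i] > BSR_THRESHOLD),
                }
            )
    return pd.DataFrame(rows)
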