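"""Group contrasts, enrichment tests and the bootstrap homogeneity statistic.

Detected subgroups are compared scale-by-scale with nonparametric
Mann-Whitney U tests under Bonferroni correction, characterized by robust
descriptives (median, MAD), and checked for enrichment of diagnosis labels
with Pearson chi-square tests.  The homogeneity statistic asks whether the
data-driven grouping yields more internally similar six-scale profiles than
a label-based grouping: repeatedly subsample m children per group, compute
the mean pairwise profile correlation within each subsample, average over
groups, and compare the two groupings by the bootstrap distribution of the
difference.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import SCALES, residual_matrix

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised for invalid statistical inputs."""


@dataclass
class ContrastResult:
    """One scale x group-pair Mann-Whitney contrast."""

    scale: str
    pair: tuple
    u_statistic: float
    p_raw: float
    p_corrected: float
    median_a: float
    mad_a: float
    median_b: float
    mad_b: float


@dataclass
class HomogeneityResult:
    """Bootstrap comparison of within-group profile similarity.

    ``mean_diff`` > 0 means grouping A is more homogeneous than grouping B.
    The one-sided p is the floored fraction of bootstrap differences <= 0.
    """

    mean_diff: float
    se: float
    p_value: float
    n_reps: int
    subsample_size: int
    groups_a: int
    groups_b: int


def mad(sample) -> float:
    """Median absolute deviation, unscaled: median(|x - median(x)|)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise StatsError("MAD of an empty sample")
    return float(np.median(np.abs(x - np.median(x))))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns U for the first sample (number of pairs with x_i > y_j plus half
    the ties) and the two-sided p, computed by exact enumeration for small
    tie-free samples (n_x * n_y <= 400) and otherwise by the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("Mann-Whitney requires two nonempty samples")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size * y.size <= 400 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Bonferroni-adjusted p, capped at 1."""
    return min(1.0, p_raw * n_tests)


def contrast_groups(
    residuals: pd.DataFrame, labels, scales=SCALES, n_tests: int | None = None
) -> list[ContrastResult]:
    """All scale x group-pair Mann-Whitney contrasts, Bonferroni corrected.

    The correction family defaults to (#scales x #pairs) — 18 for six
    scales and three groups.

    Parameters
    ----------
    labels:
        Group label per row of ``residuals`` (any hashable values).
    """
    labels = np.asarray(labels)
    if len(labels) != len(residuals):
        raise StatsError("labels must cover every row of the residual table")
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise StatsError("need at least 2 groups to contrast")
    for g in groups:
        if (labels == g).sum() < 2:
            raise StatsError(f"group {g!r} has fewer than 2 members")
    profiles = residual_matrix(residuals, scales)
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    if n_tests is None:
        n_tests = len(scales) * len(pairs)

    results = []
    for j, scale in enumerate(scales):
        for a, b in pairs:
            xa = profiles[labels == a, j]
            xb = profiles[labels == b, j]
            u, p = mann_whitney_u(xa, xb)
            results.append(
                ContrastResult(
                    scale=scale,
                    pair=(a, b),
                    u_statistic=u,
                    p_raw=p,
                    p_corrected=bonferroni(p, n_tests),
                    median_a=float(np.median(xa)),
                    mad_a=mad(xa),
                    median_b=float(np.median(xb)),
                    mad_b=mad(xb),
                )
            )
    return results


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    """Contrast results as a tidy DataFrame (one row per contrast)."""
    return pd.DataFrame(
        {
            "scale": [r.scale for r in results],
            "group_a": [r.pair[0] for r in results],
            "group_b": [r.pair[1] for r in results],
            "u": [r.u_statistic for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_corrected": [r.p_corrected for r in results],
            "median_a": [r.median_a for r in results],
            "mad_a": [r.mad_a for r in results],
            "median_b": [r.median_b for r in results],
            "mad_b": [r.mad_b for r in results],
        }
    )


def diagnosis_enrichment(labels, diagnoses, skip_label="none") -> pd.DataFrame:
    """Chi-square test of each diagnosis label's spread across groups.

    For every diagnosis (except ``skip_label``), a 2 x K contingency table
    (carries the label vs not, by group) is tested with a Pearson chi-square
    without continuity correction, df = K - 1.  Rows with any expected cell
    below 1 carry ``low_expected = True``.
    """
    labels = np.asarray(labels)
    diagnoses = np.asarray(diagnoses)
    if labels.shape != diagnoses.shape:
        raise StatsError("labels and diagnoses must align")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    rows = []
    for diag in pd.unique(diagnoses):
        if diag == skip_label:
            continue
        has = diagnoses == diag
        table = np.array(
            [
                [(has & (labels == g)).sum() for g in groups],
                [(~has & (labels == g)).sum() for g in groups],
            ],
            dtype=float,
        )
        chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
        low = bool((expected < 1).any())
        if low:
            warnings.warn(
                f"diagnosis {diag!r}: expected cell below 1; chi-square unreliable",
                stacklevel=2,
            )
        counts = {f"count_{g}": int(table[0, i]) for i, g in enumerate(groups)}
        rows.append(
            {
                "diagnosis": diag,
                "chi2": float(chi2),
                "df": int(dof),
                "p": float(p),
                "low_expected": low,
                **counts,
            }
        )
    return pd.DataFrame(rows)


def diagnosis_partition(diagnoses, skip_label="none"):
    """Turn diagnosis labels into a partition for homogeneity comparison.

    Children with the skipped label (no diagnosis) get label -1, meaning
    they belong to no group and are excluded from the bootstrap.
    """
    diagnoses = np.asarray(diagnoses)
    kept = sorted(set(diagnoses) - {skip_label})
    mapping = {d: i for i, d in enumerate(kept)}
    return np.array([mapping.get(d, -1) for d in diagnoses])


def _mean_pairwise_correlation(profiles: np.ndarray) -> float:
    c = np.corrcoef(profiles)
    iu = np.triu_indices(len(profiles), k=1)
    return float(c[iu].mean())


def _group_indices(labels: np.ndarray, m: int):
    """Member indices per group, dropping groups below the subsample size."""
    kept = []
    for g in np.unique(labels):
        if g < 0:
            continue
        idx = np.nonzero(labels == g)[0]
        if len(idx) < m:
            logger.warning(
                "group %s has %d members (< m=%d); excluded from bootstrap",
                g,
                len(idx),
                m,
            )
            continue
        kept.append(idx)
    return kept


def _bootstrap_mean_corr(
    profiles: np.ndarray, group_idx, m: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(reps)
    for r in range(reps):
        vals = [
            _mean_pairwise_correlation(profiles[rng.choice(idx, size=m, replace=False)])
            for idx in group_idx
        ]
        out[r] = np.mean(vals)
    return out


def _integer_labels(labels) -> np.ndarray:
    """Map arbitrary group labels to integers, preserving -1 as 'no group'."""
    labels = np.asarray(labels)
    if np.issubdtype(labels.dtype, np.integer):
        return labels.astype(np.int64)
    if np.issubdtype(labels.dtype, np.floating):
        return labels.astype(np.int64)
    codes = np.full(len(labels), -1, dtype=np.int64)
    kept = sorted({str(v) for v in labels} - {"-1"})
    mapping = {v: i for i, v in enumerate(kept)}
    for i, v in enumerate(labels):
        codes[i] = mapping.get(str(v), -1)
    return codes


def _partition_stream(seed: int, labels: np.ndarray) -> np.random.Generator:
    # The stream is keyed to the partition's content, not its argument
    # position, so swapping the two partitions flips the sign of the
    # statistic exactly.
    digest = zlib.crc32(np.ascontiguousarray(labels, dtype=np.int64).tobytes())
    return np.random.default_rng([seed, digest])


def homogeneity_bootstrap(
    residuals: pd.DataFrame,
    labels_a,
    labels_b,
    m: int | None = None,
    reps: int = 1000,
    seed: int = 0,
    scales=SCALES,
) -> HomogeneityResult:
    """Bootstrap contrast of within-group profile similarity between groupings.

    Per replicate and grouping, m children are drawn without replacement
    from every group, the mean pairwise profile correlation inside each
    subsample is computed and averaged over groups; the statistic is the
    difference (grouping A minus grouping B).  ``m`` defaults to 65% of the
    smallest group size (rounded up) across both groupings.  Label -1 marks
    children outside any group (e.g. no diagnosis); groups smaller than m
    are excluded with a logged warning.

    Returns
    -------
    HomogeneityResult
        mean difference, its bootstrap SE, and the one-sided p-value
        max(#{d <= 0}, 1) / reps.
    """
    labels_a = _integer_labels(labels_a)
    labels_b = _integer_labels(labels_b)
    profiles = residual_matrix(residuals, scales)
    if len(labels_a) != len(profiles) or len(labels_b) != len(profiles):
        raise StatsError("both label vectors must cover every row of residuals")
    if reps < 1:
        raise StatsError("reps must be >= 1")

    if m is None:
        sizes = [
            (lab == g).sum()
            for lab in (labels_a, labels_b)
            for g in np.unique(lab)
            if g >= 0
        ]
        m = max(3, math.ceil(0.65 * min(sizes)))
    if m < 3:
        raise StatsError(f"subsample size m={m} is too small (need >= 3)")

    idx_a = _group_indices(labels_a, m)
    idx_b = _group_indices(labels_b, m)
    if not idx_a or not idx_b:
        raise StatsError("no group large enough for the requested subsample size")

    corr_a = _bootstrap_mean_corr(
        profiles, idx_a, m, reps, _partition_stream(seed, labels_a)
    )
    corr_b = _bootstrap_mean_corr(
        profiles, idx_b, m, reps, _partition_stream(seed, labels_b)
    )
    d = corr_a - corr_b
    p = max(int((d <= 0).sum()), 1) / reps
    return HomogeneityResult(
        mean_diff=float(d.mean()),
        se=float(d.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        p_value=float(p),
        n_reps=reps,
        subsample_size=m,
        groups_a=len(idx_a),
        groups_b=len(idx_b),
    )


def normality_screen(residuals: pd.DataFrame, labels, scales=SCALES) -> pd.DataFrame:
    """Shapiro-Wilk screen per group and scale.

    Reported to justify nonparametric contrasts; constant samples are
    flagged rather than tested.
    """
    labels = np.asarray(labels)
    profiles = residual_matrix(residuals, scales)
    rows = []
    for g in pd.unique(labels):
        idx = labels == g
        if idx.sum() < 3:
            raise StatsError(f"group {g!r} has fewer than 3 members")
        for j, scale in enumerate(scales):
            x = profiles[idx, j]
            if np.ptp(x) < 1e-12:
                rows.append(
                    {
                        "group": g,
                        "scale": scale,
                        "w": np.nan,
                        "p": np.nan,
                        "constant": True,
                    }
                )
                continue
            w, p = sps.shapiro(x)
            rows.append(
                {
                    "group": g,
                    "scale": scale,
                    "w": float(w),
                    "p": float(p),
                    "constant": False,
                }
            )
    return pd.DataFrame(rows)
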