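"""Cohort-table ingestion, validity filtering, age residualization.

A cohort table is a :class:`pandas.DataFrame` with one row per child and the
following columns (extra columns are preserved and passed through):

``child_id``
    unique identifier.
``age_months``
    age at assessment in months.
``sex``
    ``"male"`` or ``"female"``.
``<scale>`` for each name in :data:`SCALES`
    raw subscale score (residual-scale units in synthetic cohorts).
``t_<scale>`` (optional)
    age-standardized T score in [20, 100]; T >= 60 is the clinical range.
``negative_impression`` (optional)
    boolean validity flag marking a possibly overly negative response style.
``diagnosis`` (optional)
    community-assigned label: ``adhd``, ``asd``, ``learning_deficit``,
    ``other`` or ``none``.
``group_truth`` (optional, synthetic cohorts only)
    the generating latent group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six questionnaire subscales, in canonical order.
SCALES: tuple[str, ...] = (
    "inattention",
    "hyperactivity_impulsivity",
    "learning_problems",
    "executive_function",
    "aggression",
    "peer_relationships",
)

#: T scores at or above this value are conventionally read as clinical-range.
CLINICAL_CUTOFF: float = 60.0


class PreprocessError(ValueError):
    """Raised when a cohort table violates a preprocessing precondition."""


def _require_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise PreprocessError(f"cohort table is missing columns: {missing}")


def filter_validity(table: pd.DataFrame, exclude_negative: bool = True) -> pd.DataFrame:
    """Drop rows flagged for a possibly overly negative response style.

    Parameters
    ----------
    table:
        Cohort table with a boolean ``negative_impression`` column.
    exclude_negative:
        When False the table is returned unchanged (both variants of the
        analysis are supported, with and without the exclusion).

    Returns
    -------
    pandas.DataFrame
        The retained rows, index reset.
    """
    if len(table) == 0:
        raise PreprocessError("cohort table is empty")
    if not exclude_negative:
        return table.reset_index(drop=True)
    _require_columns(table, ["negative_impression"])
    flagged = table["negative_impression"].astype(bool)
    n_removed = int(flagged.sum())
    kept = table.loc[~flagged].reset_index(drop=True)
    logger.info("validity filter removed %d of %d rows", n_removed, len(table))
    if len(kept) == 0:
        raise PreprocessError(
            "validity filter removed every row; nothing left to cluster"
        )
    return kept


def residualize_age(table: pd.DataFrame, scales=SCALES) -> pd.DataFrame:
    """Regress out age from every scale and z-score the residuals.

    Each scale is fit by ordinary least squares on ``age_months`` across all
    children; the residuals are then standardized (mean 0, sd 1) per scale so
    that child-by-child correlations are not dominated by scale-level offsets.
    If age has zero variance the regression is skipped and scores are only
    centered before standardization.

    Returns
    -------
    pandas.DataFrame
        ``child_id`` plus one residual column per scale.
    """
    _require_columns(table, ["child_id", "age_months", *scales])
    n = len(table)
    if n < 3:
        raise PreprocessError(f"need at least 3 children to residualize, got {n}")
    age = table["age_months"].to_numpy(dtype=float)
    scores = table[list(scales)].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise PreprocessError("scale scores contain missing values")

    if np.var(age) > 0:
        design = np.column_stack([np.ones(n), age])
        coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
        resid = scores - design @ coef
    else:
        logger.warning("age has zero variance; centering without regression")
        resid = scores - scores.mean(axis=0)

    sd = resid.std(axis=0)
    for j, scale in enumerate(scales):
        if sd[j] < 1e-12:
            raise PreprocessError(
                f"scale '{scale}' has constant residuals; cannot standardize"
            )
    z = (resid - resid.mean(axis=0)) / sd

    out = pd.DataFrame({"child_id": table["child_id"].to_numpy()})
    for j, scale in enumerate(scales):
        out[scale] = z[:, j]
    return out


def residual_matrix(residuals: pd.DataFrame, scales=SCALES) -> np.ndarray:
    """Return the children-by-scales residual score matrix as an array."""
    _require_columns(residuals, list(scales))
    return residuals[list(scales)].to_numpy(dtype=float)


def clinical_prevalence(
    table: pd.DataFrame, cutoff: float = CLINICAL_CUTOFF, scales=SCALES
) -> pd.DataFrame:
    """Count children with clinical-range T scores on every scale.

    Parameters
    ----------
    cutoff:
        T-score threshold; children with ``T >= cutoff`` are counted.

    Returns
    -------
    pandas.DataFrame
        One row per scale with ``count`` and ``percent`` (of all children,
        rounded to one decimal).
    """
    t_cols = [f"t_{s}" for s in scales]
    _require_columns(table, t_cols)
    n = len(table)
    if n == 0:
        raise PreprocessError("cohort table is empty")
    rows = []
    for scale, col in zip(scales, t_cols):
        t = table[col].to_numpy(dtype=float)
        if np.isnan(t).any():
            raise PreprocessError(f"T scores for '{scale}' contain missing values")
        count = int((t >= cutoff).sum())
        rows.append(
            {"scale": scale, "count": count, "percent": round(100.0 * count / n, 1)}
        )
    return pd.DataFrame(rows)
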