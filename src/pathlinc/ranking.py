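"""Regulator-to-gene correlation and the rank score RS.

For each regulator (lncRNA or TF) every eligible coding gene is correlated
with the regulator's expression across samples (Pearson); the pair's rank
score combines correlation sign and p-value magnitude:

    RS = -log10(p) * r          (default, ``rs_sign="corrected"``)
    RS =  log10(p) * r          (``rs_sign="paper"``)

The default puts strong positive correlates at the top of the list, the GSEA
convention; the alternative preserves the literal printed formula, whose sign
ranks them last, and is kept for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError, ZeroVarianceError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: p-values are clamped below at this floor so RS stays finite at |r| = 1.
P_FLOOR = 1e-300

RS_SIGNS = ("corrected", "paper")


@dataclass
class RankedGeneList:
    """A regulator's coding genes ordered by rank score (descending).

    ``records`` has columns ``gene``, ``r``, ``p``, ``rs`` sorted by ``rs``
    descending with ties broken by gene id ascending.
    """

    regulator_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        expected = ["gene", "r", "p", "rs"]
        if list(self.records.columns) != expected:
            raise ValidationError(
                f"ranked list columns must be {expected}, "
                f"got {list(self.records.columns)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.records["gene"].to_numpy()

    @property
    def rs(self) -> np.ndarray:
        return self.records["rs"].to_numpy(dtype=float)


def pearson_with_p(x, y) -> tuple:
    """Pearson r and its two-sided p (t-distribution, n-2 df).

    p is clamped to ``P_FLOOR`` so downstream log-scores stay finite at
    perfect (anti-)correlation. Raises :class:`ZeroVarianceError` when either
    vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 samples for a correlation p")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant vector has no defined correlation")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-14:  # exact collinearity up to float error
        p = 0.0
    return float(r), float(max(p, P_FLOOR))


def rank_score(r: float, p: float, rs_sign: str = "corrected") -> float:
    """Rank score of one regulator-gene pair from (r, p)."""
    if not -1.0 <= r <= 1.0:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p must be in (0, 1], got {p}")
    if rs_sign not in RS_SIGNS:
        raise ValidationError(f"rs_sign must be one of {RS_SIGNS}")
    rs = -np.log10(p) * r
    return float(rs if rs_sign == "corrected" else -rs)


def _pearson_matrix(X: np.ndarray, y: np.ndarray) -> tuple:
    """Vectorized Pearson r and two-sided t-based p of each row of X vs y.

    Rows with zero variance get r = nan (caller drops them). Equivalent to
    :func:`pearson_with_p` row by row.
    """
    n = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0 - 1e-14, 0.0, p)
    p = np.maximum(p, P_FLOOR)
    bad = sx == 0
    r[bad] = np.nan
    p[bad] = np.nan
    return r, p


def build_ranked_list(
    expr: ExpressionMatrix,
    regulator_id: str,
    rs_sign: str = "corrected",
    samples: str = "all",
) -> RankedGeneList:
    """Correlate one regulator against every coding gene and rank by RS.

    ``samples`` selects the columns used for correlation: ``"all"`` (default)
    or ``"tumor"``. Zero-variance genes are dropped (count logged); the
    regulator itself never appears in the list. Ties in RS are broken by
    gene id ascending so output is deterministic.
    """
    if regulator_id not in expr.values.index:
        raise KeyError(f"unknown regulator {regulator_id!r}")
    if expr.gene_classes[regulator_id] not in ("lncRNA", "TF"):
        raise ValidationError(
            f"{regulator_id!r} has class {expr.gene_classes[regulator_id]!r}; "
            "a regulator must be lncRNA or TF"
        )
    if samples == "all":
        cols = expr.sample_ids
    elif samples == "tumor":
        cols = expr.samples_of_group("tumor")
    else:
        raise ValidationError("samples must be 'all' or 'tumor'")
    if len(cols) < 3:
        raise ValidationError("need at least 3 samples for correlations")

    genes = [g for g in expr.coding_genes if g != regulator_id]
    if not genes:
        raise ValidationError("no eligible coding genes in the matrix")
    X = expr.values.loc[genes, cols].to_numpy(dtype=float)
    y = expr.values.loc[regulator_id, cols].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ZeroVarianceError(
            f"regulator {regulator_id!r} is constant across selected samples"
        )
    r, p = _pearson_matrix(X, y)
    keep = ~np.isnan(r)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d zero-variance gene(s)",
                       regulator_id, n_dropped)
    if not keep.any():
        raise ValidationError("all coding genes had zero variance")
    rs = -np.log10(p[keep]) * r[keep]
    if rs_sign == "paper":
        rs = -rs
    elif rs_sign != "corrected":
        raise ValidationError(f"rs_sign must be one of {RS_SIGNS}")
    records = pd.DataFrame({
        "gene": np.asarray(genes, dtype=object)[keep],
        "r": r[keep],
        "p": p[keep],
        "rs": rs,
    })
    records = records.sort_values(
        ["rs", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return RankedGeneList(regulator_id=regulator_id, records=records)
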