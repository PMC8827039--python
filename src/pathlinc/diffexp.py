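"""Tumor-vs-control differential expression on the log2 matrix.

Per gene: log2 fold change = mean(tumor) - mean(control); Welch's unequal
variance two-sample t-test gives the p-value, adjusted across all tested
genes by Benjamini-Hochberg. A gene passes at the default thresholds iff
adjusted p < 0.05 and |log2FC| > 1 (both strict).

Welch's t is the stated moderated-test substitute used by this package; a
pre-computed external DE table (e.g. a limma topTable export) can be
injected instead via :func:`read_de_table`, bypassing the internal test.
"""

from __future__ import annotations

import logging
from typing import Iterable, Set

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .exceptions import ParseError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "p", "adj_p", "passes"]


def log2_fold_change(expr_row, groups) -> float:
    """mean(tumor) - mean(control) of one gene's log2 values."""
    x = np.asarray(expr_row, dtype=float)
    g = np.asarray(groups, dtype=object)
    if x.shape != g.shape:
        raise ValidationError("expression row and group labels differ in length")
    tumor = x[g == "tumor"]
    control = x[g == "control"]
    if tumor.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    return float(tumor.mean() - control.mean())


def de_test(
    expr: ExpressionMatrix,
    adj_p_cut: float = 0.05,
    abs_log2fc_cut: float = 1.0,
) -> pd.DataFrame:
    """Welch t-test of every gene, BH adjustment, threshold flags.

    Requires at least 3 samples per group. Genes with zero variance in both
    groups are reported with p = 1 (degenerate; logged). Returns a DataFrame
    with columns ``gene``, ``log2fc``, ``p``, ``adj_p``, ``passes``.
    """
    expr.require_group_sizes(3)
    tumor_cols = expr.samples_of_group("tumor")
    control_cols = expr.samples_of_group("control")
    T = expr.values[tumor_cols].to_numpy(dtype=float)
    C = expr.values[control_cols].to_numpy(dtype=float)
    lfc = T.mean(axis=1) - C.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(T, C, axis=1, equal_var=False)
    degenerate = (T.var(axis=1) == 0) & (C.var(axis=1) == 0)
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d gene(s) with zero variance in both groups; p set to 1",
                       n_deg)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    adj = bh_fdr(p)
    passes = (adj < adj_p_cut) & (np.abs(lfc) > abs_log2fc_cut)
    return pd.DataFrame({
        "gene": expr.gene_ids,
        "log2fc": lfc,
        "p": p,
        "adj_p": adj,
        "passes": passes,
    })


def read_de_table(path, adj_p_cut: float = 0.05,
                  abs_log2fc_cut: float = 1.0) -> pd.DataFrame:
    """Load an external DE table (gene, log2fc, p, adj_p) and re-flag it."""
    df = pd.read_csv(path, sep="\t")
    needed = ["gene", "log2fc", "p", "adj_p"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: DE table missing column(s) {missing}")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    out = df[needed].copy()
    out["passes"] = (out["adj_p"] < adj_p_cut) & \
        (out["log2fc"].abs() > abs_log2fc_cut)
    return out


def de_filter(records: pd.DataFrame, ids: Iterable[str]) -> Set[str]:
    """IDs whose DE record passes; ids without a record are non-passing."""
    ids = set(ids)
    known = dict(zip(records["gene"], records["passes"]))
    missing = ids - set(known)
    if missing:
        logger.warning("%d id(s) without a DE record treated as non-passing",
                       len(missing))
    return {i for i in ids if known.get(i, False)}
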