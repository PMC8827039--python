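"""Modified GSEA scoring of regulator ranked lists against pathways.

The enrichment score (ES) is the signed maximal deviation of a weighted
Kolmogorov-Smirnov running sum: walking down a regulator's RS-ranked coding
gene list, pathway members ("hits") add ``|rs|^w / sum_members |rs|^w``
(default weight w = 1) and non-members subtract ``1 / (N - N_hit)``.

A permutation p-value converts ES into the relative enrichment score

    RES = 1 - 2p   if ES > 0
    RES = 2p - 1   if ES < 0
    RES = 0        if ES = 0

so RES spans [-1, 1] and approaches +/-1 as p -> 0. Significance combines an
absolute RES cut (class-specific: lncRNA 0.995, TF 0.990) with a
Benjamini-Hochberg FDR < 0.05 computed within each regulator class.

Two permutation nulls are provided:

* ``"gene_set"`` (default): draw random member sets of the same size from
  the ranked list. This is the powerful, competitive-test null the method's
  thresholds were designed around. Like every competitive gene-set test it
  is anti-conservative when pathway members are co-expressed, so absolute
  RES values should be read as a prioritisation score rather than a
  calibrated error rate (see the methods note).
* ``"regulator"``: permute the regulator's expression vector across samples
  and redo the ranking. Preserves the gene-gene correlation of the coding
  matrix, hence calibrated under member co-expression -- but at small
  sample sizes a permuted regulator can chance-align with a dominant
  pathway factor, which bounds attainable p-values well above the RES
  cuts; use it to audit calibration, not to reproduce the thresholds.

The p estimator is ``(1 + b) / (n_perm + 1)`` with ``b`` the number of null
scores of the same sign as the observed ES and at least as extreme, so p > 0
and RES < 1 strictly.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import NoOverlapError, ValidationError
from .io import ExpressionMatrix, GeneSetCollection
from .ranking import P_FLOOR, RS_SIGNS, RankedGeneList

logger = logging.getLogger(__name__)

NULL_SCHEMES = ("regulator", "gene_set")


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_batch(pos: np.ndarray, w: np.ndarray, n_genes: int) -> np.ndarray:
    """Signed ES for a batch of hit configurations.

    ``pos``: (B, m) hit positions (0-based, ascending within each row);
    ``w``: (B, m) non-negative hit weights aligned with ``pos``. The running
    sum is piecewise linear between hits, so its extrema occur immediately
    after a hit or immediately before one; both candidate sets are evaluated
    in closed form.
    """
    pos = np.atleast_2d(pos)
    w = np.atleast_2d(np.abs(w)).astype(float)
    B, m = pos.shape
    W = w.sum(axis=1, keepdims=True)
    uniform = (W == 0).ravel()
    if uniform.any():  # all-zero weights: fall back to the unweighted statistic
        w = w.copy()
        w[uniform] = 1.0
        W = w.sum(axis=1, keepdims=True)
    P = np.cumsum(w, axis=1) / W
    miss = 1.0 / (n_genes - m) if n_genes > m else 0.0
    k = np.arange(1, m + 1)
    after = P - (pos + 1 - k) * miss
    before = np.concatenate([np.zeros((B, 1)), P[:, :-1]], axis=1) \
        - (pos - k + 1) * miss
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def _member_positions(ranked: RankedGeneList, members: Iterable[str]) -> np.ndarray:
    gene_ids = ranked.gene_ids
    index = {g: i for i, g in enumerate(gene_ids)}
    pos = sorted(index[g] for g in set(members) if g in index)
    n_absent = len(set(members)) - len(pos)
    if n_absent:
        logger.debug("%s: %d member(s) absent from ranked list",
                     ranked.regulator_id, n_absent)
    return np.asarray(pos, dtype=int)


def enrichment_score(ranked: RankedGeneList, members: Iterable[str],
                     weight: float = 1.0) -> float:
    """Signed ES of one gene set against one ranked list.

    Members absent from the list are ignored; if none overlap, raises
    :class:`NoOverlapError` (the pair is skipped upstream).
    """
    pos = _member_positions(ranked, members)
    if pos.size == 0:
        raise NoOverlapError(
            f"no member of the set overlaps the ranked list of "
            f"{ranked.regulator_id!r}"
        )
    n_genes = len(ranked)
    w = np.abs(ranked.rs[pos]) ** weight
    return float(_es_batch(pos[None, :], w[None, :], n_genes)[0])


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

def _p_from_null(es_obs: float, es_null: np.ndarray) -> float:
    """(1 + b) / (n + 1) estimator, b = same-sign nulls at least as extreme."""
    if es_obs == 0.0:
        return 1.0
    b = int(np.sum((np.sign(es_null) == np.sign(es_obs))
                   & (np.abs(es_null) >= abs(es_obs))))
    return (1 + b) / (len(es_null) + 1)


def permutation_pvalue(ranked: RankedGeneList, members: Iterable[str],
                       n_perm: int = 999, seed: Optional[int] = None,
                       weight: float = 1.0,
                       rng: Optional[np.random.Generator] = None) -> float:
    """Gene-set permutation p: random member sets of the same size.

    Deterministic given ``seed`` (or a caller-provided ``rng``).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = _member_positions(ranked, members)
    if pos.size == 0:
        raise NoOverlapError(
            f"no member of the set overlaps the ranked list of "
            f"{ranked.regulator_id!r}"
        )
    n_genes = len(ranked)
    m = pos.size
    rs_abs = np.abs(ranked.rs) ** weight
    es_obs = float(_es_batch(pos[None, :], rs_abs[pos][None, :], n_genes)[0])
    if es_obs == 0.0:
        return 1.0
    # n_perm random m-subsets of the list positions
    idx = np.argsort(rng.random((n_perm, n_genes)), axis=1)[:, :m]
    idx.sort(axis=1)
    es_null = _es_batch(idx, rs_abs[idx], n_genes)
    return _p_from_null(es_obs, es_null)


def _regulator_null_es(
    X: np.ndarray, y: np.ndarray, member_rows: Dict[str, np.ndarray],
    n_perm: int, rng: np.random.Generator, rs_sign: str, weight: float,
) -> Dict[str, np.ndarray]:
    """Null ES per pathway from sample-permutation of the regulator vector.

    ``X``: coding genes x samples (rows with variance); ``member_rows`` maps
    pathway name to row indices of its members in ``X``. One shared set of
    ``n_perm`` permuted regulator vectors serves every pathway.
    """
    n = X.shape[1]
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Y = y[perms]                                  # (n_perm, n)
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc * Xc).sum(axis=1))
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sy = np.sqrt((Yc * Yc).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(sx, sy)        # (G, n_perm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df=n - 2), P_FLOOR)
    rs = -np.log10(p) * r
    if rs_sign == "paper":
        rs = -rs
    order = np.argsort(-rs, axis=0, kind="stable")     # (G, n_perm)
    inv = np.argsort(order, axis=0)                    # position of each row
    rs_abs = np.abs(rs) ** weight
    G = X.shape[0]
    out: Dict[str, np.ndarray] = {}
    for name, rows in member_rows.items():
        pos = inv[rows, :].T                           # (n_perm, m)
        w = rs_abs[rows, :].T
        srt = np.argsort(pos, axis=1)
        pos = np.take_along_axis(pos, srt, axis=1)
        w = np.take_along_axis(w, srt, axis=1)
        out[name] = _es_batch(pos, w, G)
    return out


# ---------------------------------------------------------------------------
# RES transform, FDR, significance
# ---------------------------------------------------------------------------

def res_transform(es: float, p_perm: float) -> float:
    """Relative enrichment score: 1-2p (ES>0), 2p-1 (ES<0), 0 at ES=0."""
    if not -1.0 <= es <= 1.0:
        raise ValidationError(f"|es| must be <= 1, got {es}")
    if not 0.0 < p_perm <= 1.0:
        raise ValidationError(f"p must be in (0, 1], got {p_perm}")
    if es > 0:
        return 1.0 - 2.0 * p_perm
    if es < 0:
        return 2.0 * p_perm - 1.0
    return 0.0


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def res_passes(res: float, regulator_class: str,
               lncres_cut: float = 0.995, tfres_cut: float = 0.990) -> bool:
    """Class-specific absolute RES threshold (strict inequality)."""
    cut = lncres_cut if regulator_class == "lncRNA" else tfres_cut
    return abs(res) > cut


def call_significant(
    results: pd.DataFrame,
    lncres_cut: float = 0.995,
    tfres_cut: float = 0.990,
    fdr_cut: float = 0.05,
    fdr_family: str = "class",
) -> pd.DataFrame:
    """Attach BH q-values and significance flags to enrichment results.

    ``results`` needs columns ``regulator``, ``regulator_class``,
    ``pathway``, ``es``, ``p_perm``, ``res``. The BH family is per regulator
    class by default (``fdr_family="class"``) or ``"global"``. A pair is
    significant iff |res| exceeds its class cut AND q < ``fdr_cut`` (strict).
    """
    if fdr_family not in ("class", "global"):
        raise ValidationError("fdr_family must be 'class' or 'global'")
    out = results.copy()
    out["q"] = np.nan
    if fdr_family == "global":
        out["q"] = bh_fdr(out["p_perm"])
    else:
        for cls in out["regulator_class"].unique():
            mask = out["regulator_class"] == cls
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p_perm"])
    out["significant"] = [
        res_passes(res, cls, lncres_cut, tfres_cut) and q < fdr_cut
        for res, cls, q in zip(out["res"], out["regulator_class"], out["q"])
    ]
    return out


# ---------------------------------------------------------------------------
# pipeline-facing orchestration
# ---------------------------------------------------------------------------

def score_regulators(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    n_perm: int = 999,
    seed: int = 0,
    rs_sign: str = "corrected",
    null_scheme: str = "gene_set",
    weight: float = 1.0,
    samples: str = "all",
) -> pd.DataFrame:
    """ES, permutation p and RES for every regulator x pathway pair.

    Returns a DataFrame with columns ``regulator``, ``regulator_class``,
    ``pathway``, ``es``, ``p_perm``, ``res``; pairs whose set has no overlap
    with the ranked list are skipped (logged). Deterministic given ``seed``.
    """
    from .ranking import build_ranked_list  # local import avoids cycle at doc build

    if null_scheme not in NULL_SCHEMES:
        raise ValidationError(f"null_scheme must be one of {NULL_SCHEMES}")
    if rs_sign not in RS_SIGNS:
        raise ValidationError(f"rs_sign must be one of {RS_SIGNS}")
    usable = sets.restrict_to(expr.coding_genes)
    dropped = set(sets.names()) - set(usable.names())
    if dropped:
        logger.warning("dropped pathway(s) with no coding members: %s",
                       sorted(dropped))
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for reg in expr.regulators:
        ranked = build_ranked_list(expr, reg, rs_sign=rs_sign, samples=samples)
        cls = expr.gene_classes[reg]
        if null_scheme == "regulator":
            gene_index = {g: i for i, g in enumerate(ranked.gene_ids)}
            # rebuild the coding matrix in ranked-row order for the null
            cols = expr.sample_ids if samples == "all" \
                else expr.samples_of_group("tumor")
            X = expr.values.loc[ranked.gene_ids, cols].to_numpy(dtype=float)
            y = expr.values.loc[reg, cols].to_numpy(dtype=float)
            member_rows = {}
            for name in usable.names():
                rows_idx = np.asarray(
                    sorted(gene_index[g] for g in usable.sets[name]
                           if g in gene_index), dtype=int)
                if rows_idx.size:
                    member_rows[name] = rows_idx
            null_es = _regulator_null_es(X, y, member_rows, n_perm, rng,
                                         rs_sign, weight)
            for name, rows_idx in member_rows.items():
                es = enrichment_score(ranked, usable.sets[name], weight=weight)
                p = _p_from_null(es, null_es[name])
                rows.append((reg, cls, name, es, p, res_transform(es, p)))
        else:
            for name in usable.names():
                try:
                    es = enrichment_score(ranked, usable.sets[name],
                                          weight=weight)
                except NoOverlapError:
                    logger.warning("skipping %s x %s: no overlap", reg, name)
                    continue
                p = permutation_pvalue(ranked, usable.sets[name],
                                       n_perm=n_perm, rng=rng, weight=weight)
                rows.append((reg, cls, name, es, p, res_transform(es, p)))
    return pd.DataFrame(
        rows, columns=["regulator", "regulator_class", "pathway",
                       "es", "p_perm", "res"],
    )


# ---------------------------------------------------------------------------
# ssGSEA per-sample pathway activity
# ---------------------------------------------------------------------------

def ssgsea_activity(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    weight: float = 1.0,
    rescale: bool = True,
) -> pd.DataFrame:
    """Per-sample pathway activity (single-sample GSEA).

    For each sample, genes are ordered by that sample's expression
    (descending, ties broken by gene id); the activity is the sum over the
    list of the difference between the weighted hit CDF (weights = average
    expression ranks raised to ``weight``) and the miss CDF. With
    ``rescale=True`` (default) scores are min-max rescaled per pathway to
    [-1, 1] across samples for reporting. Returns a tidy DataFrame with
    columns ``sample``, ``pathway``, ``activity``.

    The score is invariant to gene-row permutations of the input matrix.
    """
    usable = sets.restrict_to(expr.gene_ids)
    skipped = set(sets.names()) - set(usable.names())
    if skipped:
        logger.warning("ssGSEA: skipped set(s) with no overlap: %s",
                       sorted(skipped))
    if not usable.names():
        raise NoOverlapError("no gene set overlaps the expression matrix")
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    N = len(gene_ids)
    raw = {}
    for sample in expr.sample_ids:
        v = expr.values[sample].to_numpy(dtype=float)
        ranks = stats.rankdata(v, method="average")       # high expr -> high rank
        order = np.lexsort((gene_ids, -v))                 # descending, id tiebreak
        w_all = ranks[order] ** weight
        genes_sorted = gene_ids[order]
        idx = {g: i for i, g in enumerate(genes_sorted)}
        for name in usable.names():
            members = usable.sets[name]
            hit = np.zeros(N, dtype=bool)
            hit[[idx[g] for g in members if g in idx]] = True
            m = int(hit.sum())
            wh = np.where(hit, w_all, 0.0)
            W = wh.sum()
            hit_cdf = np.cumsum(wh) / (W if W > 0 else 1.0)
            miss_cdf = np.cumsum(~hit) / (N - m) if N > m else np.zeros(N)
            raw[(sample, name)] = float(np.sum(hit_cdf - miss_cdf))
    df = pd.DataFrame(
        [(s, p, a) for (s, p), a in raw.items()],
        columns=["sample", "pathway", "activity"],
    )
    if rescale:
        def _rescale(group: pd.Series) -> pd.Series:
            lo, hi = group.min(), group.max()
            if hi == lo:
                return pd.Series(0.0, index=group.index)
            return 2.0 * (group - lo) / (hi - lo) - 1.0
        df["activity"] = df.groupby("pathway")["activity"].transform(_rescale)
    return df
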