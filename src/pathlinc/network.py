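"""Binding-supported TF->lncRNA edges and final network assembly.

A TF binds a lncRNA when at least one of its ChIP-seq peaks overlaps the
lncRNA's regulatory window (gene body + 10 kb upstream by default; 0-based
half-open, so abutting intervals do not overlap). Binding edges are then
funnelled:

1. candidate pairs: edges whose TF and lncRNA are both pathway-significant;
2. final pairs: candidates whose members survive the differential-expression
   filter (both members by default; ``de_mode="either"`` relaxes this).

Each final pair carries the union of the two members' significant pathways
and the lncRNA's DE statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ValidationError
from .io import GeneLocus, PeakSet, TFlncRNAPair

logger = logging.getLogger(__name__)

DE_MODES = ("both", "either")


@dataclass(frozen=True)
class RegulatoryEdge:
    """One binding-supported TF->lncRNA edge."""

    tf_id: str
    lncrna_id: str
    peak_count: int

    def __post_init__(self) -> None:
        if self.peak_count < 1:
            raise ValidationError("peak_count must be >= 1")


def regulatory_window(locus: GeneLocus, upstream: int = 10_000,
                      downstream: int = 0) -> Tuple[str, int, int]:
    """Strand-aware regulatory window of a locus, clamped at 0.

    ``upstream`` extends from the transcription start (5' end), which is
    ``start`` on '+' and ``end`` on '-'; ``downstream`` extends past the
    other end.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("window extents must be non-negative")
    if locus.strand == "+":
        lo, hi = locus.start - upstream, locus.end + downstream
    else:
        lo, hi = locus.start - downstream, locus.end + upstream
    return (locus.chrom, max(0, lo), hi)


def overlap_edges(
    peaks: Sequence[PeakSet],
    loci: Sequence[GeneLocus],
    upstream: int = 10_000,
    downstream: int = 0,
) -> List[RegulatoryEdge]:
    """Edges from >=1 bp peak/window overlap (half-open semantics).

    ``loci`` should already be restricted to lncRNA-class genes. Peaks on
    chromosomes with no locus simply contribute nothing. The result is
    sorted by (tf, lncrna).
    """
    trees: Dict[str, IntervalTree] = {}
    for locus in loci:
        chrom, lo, hi = regulatory_window(locus, upstream, downstream)
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi, locus.gene_id)
    counts: Dict[Tuple[str, str], int] = {}
    for ps in peaks:
        for chrom, start, end in ps.intervals:
            tree = trees.get(chrom)
            if tree is None:
                continue
            for hit in tree.overlap(start, end):
                key = (ps.tf_id, hit.data)
                counts[key] = counts.get(key, 0) + 1
    return [RegulatoryEdge(tf, lnc, c)
            for (tf, lnc), c in sorted(counts.items())]


def _significant_pathways(enrichment: pd.DataFrame) -> Dict[str, Set[str]]:
    sig = enrichment[enrichment["significant"]]
    out: Dict[str, Set[str]] = {}
    for reg, pw in zip(sig["regulator"], sig["pathway"]):
        out.setdefault(reg, set()).add(pw)
    return out


@dataclass
class PairAssembly:
    """Candidate and final pairs plus funnel counts."""

    candidates: List[TFlncRNAPair]
    pairs: List[TFlncRNAPair]

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_final(self) -> int:
        return len(self.pairs)


def build_pairs(
    sig_tfs: pd.DataFrame,
    sig_lncs: pd.DataFrame,
    edges: Sequence[RegulatoryEdge],
    de: pd.DataFrame,
    de_mode: str = "both",
) -> PairAssembly:
    """Funnel binding edges through pathway significance and the DE filter.

    ``sig_tfs`` / ``sig_lncs`` are enrichment result frames (with ``q`` and
    ``significant`` columns) for the TF and lncRNA class respectively; ``de``
    is the DE record frame. Pair annotation (log2FC, adjusted p) uses the
    lncRNA's DE record. Candidates whose lncRNA lacks a DE record are kept
    as candidates but annotated with NaN and can never pass ``de_mode="both"``.
    """
    if de_mode not in DE_MODES:
        raise ValidationError(f"de_mode must be one of {DE_MODES}")
    tf_paths = _significant_pathways(sig_tfs)
    lnc_paths = _significant_pathways(sig_lncs)
    de_by_gene = de.set_index("gene") if len(de) else pd.DataFrame(
        columns=["log2fc", "adj_p", "passes"])

    def de_record(gene: str):
        if gene in de_by_gene.index:
            row = de_by_gene.loc[gene]
            return float(row["log2fc"]), float(row["adj_p"]), bool(row["passes"])
        return float("nan"), float("nan"), False

    candidates: List[TFlncRNAPair] = []
    finals: List[TFlncRNAPair] = []
    for edge in edges:
        if edge.tf_id not in tf_paths or edge.lncrna_id not in lnc_paths:
            continue
        pathways = frozenset(tf_paths[edge.tf_id] | lnc_paths[edge.lncrna_id])
        lfc, adj, lnc_pass = de_record(edge.lncrna_id)
        pair = TFlncRNAPair(
            tf_id=edge.tf_id, lncrna_id=edge.lncrna_id, pathways=pathways,
            lncrna_log2fc=lfc, lncrna_adj_p=adj, peak_count=edge.peak_count,
        )
        candidates.append(pair)
        _, _, tf_pass = de_record(edge.tf_id)
        keep = (tf_pass and lnc_pass) if de_mode == "both" \
            else (tf_pass or lnc_pass)
        if keep:
            finals.append(pair)
    return PairAssembly(candidates=candidates, pairs=finals)


def network_summary(pairs: Sequence[TFlncRNAPair]) -> dict:
    """Per-TF / per-lncRNA degrees, per-pathway pair counts, total."""
    tf_degree: Dict[str, int] = {}
    lnc_degree: Dict[str, int] = {}
    pathway_counts: Dict[str, int] = {}
    for p in pairs:
        tf_degree[p.tf_id] = tf_degree.get(p.tf_id, 0) + 1
        lnc_degree[p.lncrna_id] = lnc_degree.get(p.lncrna_id, 0) + 1
        for pw in p.pathways:
            pathway_counts[pw] = pathway_counts.get(pw, 0) + 1
    return {
        "n_pairs": len(pairs),
        "tf_degree": dict(sorted(tf_degree.items())),
        "lncrna_degree": dict(sorted(lnc_degree.items())),
        "pathway_pair_counts": dict(sorted(pathway_counts.items())),
    }


def to_graphml(pairs: Sequence[TFlncRNAPair], path) -> None:
    """Export the pair network as GraphML (TF and lncRNA node types)."""
    import networkx as nx

    g = nx.Graph()
    for p in pairs:
        g.add_node(p.tf_id, kind="TF")
        g.add_node(p.lncrna_id, kind="lncRNA")
        g.add_edge(p.tf_id, p.lncrna_id,
                   pathways=";".join(sorted(p.pathways)),
                   peak_count=p.peak_count,
                   lncrna_log2fc=float(p.lncrna_log2fc))
    nx.write_graphml(g, path)
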