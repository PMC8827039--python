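"""Model/Results facade over the full regulator-inference pipeline.

:class:`PathwayRegulationModel` is built from an expression matrix, pathway
gene sets and (optionally) lncRNA loci plus per-TF ChIP-seq peaks. Its
:meth:`~PathwayRegulationModel.fit` runs correlation ranking, permutation
GSEA, the RES transform and class-wise FDR, the differential-expression
test, peak-overlap edge construction and the pair funnel, and returns a
:class:`PathwayRegulationResults` carrying every stage's table, the funnel
counts and a text ``summary()``.

Example
-------
>>> from pathlinc import SimulationConfig, generate_dataset
>>> from pathlinc.model import PathwayRegulationModel
>>> expr, sets, loci, peaks, truth = generate_dataset(SimulationConfig(seed=1))
>>> res = PathwayRegulationModel(expr, sets, loci=loci, peaks=peaks).fit(seed=1)
>>> print(res.summary())                                    # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set, Tuple

import pandas as pd

from . import io as pio
from .diffexp import de_test
from .enrichment import call_significant, score_regulators, ssgsea_activity
from .exceptions import ValidationError
from .io import ExpressionMatrix, GeneLocus, GeneSetCollection, PeakSet
from .network import PairAssembly, build_pairs, network_summary, overlap_edges


@dataclass
class AnalysisSettings:
    """Every tunable threshold and scheme of the analysis, with defaults.

    ``lncres_cut``/``tfres_cut``/``fdr_cut`` gate pathway significance;
    ``de_adj_p``/``de_abs_log2fc`` gate differential expression;
    ``upstream``/``downstream`` size the lncRNA regulatory window in bp.
    """

    n_perm: int = 999
    lncres_cut: float = 0.995
    tfres_cut: float = 0.990
    fdr_cut: float = 0.05
    de_adj_p: float = 0.05
    de_abs_log2fc: float = 1.0
    upstream: int = 10_000
    downstream: int = 0
    rs_sign: str = "corrected"
    null_scheme: str = "gene_set"
    de_mode: str = "both"
    fdr_family: str = "class"
    weight: float = 1.0
    samples: str = "all"

    def __post_init__(self) -> None:
        for name in ("lncres_cut", "tfres_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("fdr_cut", "de_adj_p"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.upstream < 0 or self.downstream < 0:
            raise ValidationError("window extents must be non-negative")


class PathwayRegulationModel:
    """Pathway-regulator inference model over one expression cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Log2-scale genes x samples matrix with gene classes and groups.
    gene_sets : GeneSetCollection
        Pathway gene sets; members are restricted to coding genes.
    loci : sequence of GeneLocus, optional
        lncRNA loci. Without loci/peaks the network stage is skipped.
    peaks : sequence of PeakSet, optional
        Per-TF ChIP-seq peaks. TFs absent from the expression matrix are
        dropped (they can never be pathway-significant).
    settings : AnalysisSettings, optional
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        gene_sets: GeneSetCollection,
        loci: Optional[Sequence[GeneLocus]] = None,
        peaks: Optional[Sequence[PeakSet]] = None,
        settings: Optional[AnalysisSettings] = None,
    ):
        self.expression = expression
        self.gene_sets = gene_sets.restrict_to(expression.coding_genes)
        if not self.gene_sets.names():
            raise ValidationError(
                "no gene set overlaps the coding genes of the matrix"
            )
        lnc_ids = set(expression.genes_of_class("lncRNA"))
        self.loci = [l for l in (loci or []) if l.gene_id in lnc_ids]
        tf_ids = set(expression.genes_of_class("TF"))
        self.peaks = [p for p in (peaks or []) if p.tf_id in tf_ids]
        self.settings = settings or AnalysisSettings()

    @classmethod
    def from_files(
        cls,
        expression_path,
        groups_path,
        gmt_path,
        loci_path=None,
        peaks_dir=None,
        settings: Optional[AnalysisSettings] = None,
    ) -> "PathwayRegulationModel":
        """Build the model from the on-disk formats the CLI uses.

        ``peaks_dir`` holds one ``<TF>.bed`` per transcription factor.
        """
        from pathlib import Path

        expr = pio.read_expression(expression_path, groups_path)
        sets = pio.read_gmt(gmt_path)
        loci = pio.read_loci(loci_path) if loci_path else None
        peaks = None
        if peaks_dir:
            peaks = [pio.read_peaks(p, p.stem)
                     for p in sorted(Path(peaks_dir).glob("*.bed"))]
        return cls(expr, sets, loci=loci, peaks=peaks, settings=settings)

    def pathway_activity(self) -> pd.DataFrame:
        """Per-sample ssGSEA pathway activity (independent of fit)."""
        return ssgsea_activity(self.expression, self.gene_sets,
                               weight=self.settings.weight)

    def fit(self, seed: int = 0,
            de_table: Optional[pd.DataFrame] = None
            ) -> "PathwayRegulationResults":
        """Run every stage; deterministic given ``seed``.

        ``de_table`` optionally injects a pre-computed DE table (columns
        ``gene``, ``log2fc``, ``p``, ``adj_p``, ``passes``) in place of the
        internal Welch test.
        """
        s = self.settings
        enr = score_regulators(
            self.expression, self.gene_sets, n_perm=s.n_perm, seed=seed,
            rs_sign=s.rs_sign, null_scheme=s.null_scheme, weight=s.weight,
            samples=s.samples,
        )
        enr = call_significant(enr, lncres_cut=s.lncres_cut,
                               tfres_cut=s.tfres_cut, fdr_cut=s.fdr_cut,
                               fdr_family=s.fdr_family)
        if de_table is not None:
            de = de_table
        else:
            de = de_test(self.expression, adj_p_cut=s.de_adj_p,
                         abs_log2fc_cut=s.de_abs_log2fc)
        edges = []
        assembly = PairAssembly(candidates=[], pairs=[])
        if self.loci and self.peaks:
            edges = overlap_edges(self.peaks, self.loci,
                                  upstream=s.upstream,
                                  downstream=s.downstream)
            sig_tfs = enr[enr["regulator_class"] == "TF"]
            sig_lncs = enr[enr["regulator_class"] == "lncRNA"]
            assembly = build_pairs(sig_tfs, sig_lncs, edges, de,
                                   de_mode=s.de_mode)
        return PathwayRegulationResults(
            model=self, seed=seed, enrichment=enr, de=de,
            edges=edges, assembly=assembly,
        )


@dataclass
class PathwayRegulationResults:
    """Fitted estimates, diagnostics and the assembled network."""

    model: PathwayRegulationModel
    seed: int
    enrichment: pd.DataFrame
    de: pd.DataFrame
    edges: list
    assembly: PairAssembly

    # -- derived views ---------------------------------------------------
    @property
    def pairs(self) -> list:
        return self.assembly.pairs

    @property
    def candidate_pairs(self) -> list:
        return self.assembly.candidates

    def significant(self, regulator_class: Optional[str] = None) -> pd.DataFrame:
        df = self.enrichment[self.enrichment["significant"]]
        if regulator_class is not None:
            df = df[df["regulator_class"] == regulator_class]
        return df

    def significant_associations(self) -> Set[Tuple[str, str]]:
        sig = self.significant()
        return set(zip(sig["regulator"], sig["pathway"]))

    def called_edges(self) -> Set[Tuple[str, str]]:
        return {(p.tf_id, p.lncrna_id) for p in self.pairs}

    @property
    def funnel(self) -> Dict[str, int]:
        """Stage-wise counts along the evidence chain."""
        sig = self.significant()
        return {
            "n_regulator_pathway_pairs_scored": int(len(self.enrichment)),
            "n_significant_lncrnas":
                int(sig[sig["regulator_class"] == "lncRNA"]["regulator"].nunique()),
            "n_significant_tfs":
                int(sig[sig["regulator_class"] == "TF"]["regulator"].nunique()),
            "n_de_passing_genes": int(self.de["passes"].sum()),
            "n_binding_edges": len(self.edges),
            "n_candidate_pairs": self.assembly.n_candidates,
            "n_final_pairs": self.assembly.n_final,
        }

    def network_summary(self) -> dict:
        return network_summary(self.pairs)

    def summary(self) -> str:
        """Human-readable account of settings, funnel and top pairs."""
        s = self.model.settings
        lines = [
            "Pathway regulation analysis (pathlinc)",
            "=" * 54,
            f"genes: {self.model.expression.n_genes}  "
            f"samples: {self.model.expression.n_samples} "
            f"({len(self.model.expression.samples_of_group('tumor'))} tumor / "
            f"{len(self.model.expression.samples_of_group('control'))} control)",
            f"pathways: {len(self.model.gene_sets)}  "
            f"n_perm: {s.n_perm}  seed: {self.seed}",
            f"cuts: |lncRES|>{s.lncres_cut}  |TFRES|>{s.tfres_cut}  "
            f"FDR<{s.fdr_cut}  DE adj_p<{s.de_adj_p} & |log2FC|>{s.de_abs_log2fc}",
            f"null: {s.null_scheme} permutation  rs_sign: {s.rs_sign}  "
            f"window: +{s.upstream}/-{s.downstream} bp",
            "-" * 54,
        ]
        for k, v in self.funnel.items():
            lines.append(f"{k:<38s} {v:>6d}")
        if self.pairs:
            lines.append("-" * 54)
            lines.append("top pairs by |lncRNA log2FC|:")
            top = sorted(self.pairs,
                         key=lambda p: -abs(p.lncrna_log2fc))[:10]
            for p in top:
                lines.append(
                    f"  {p.tf_id}-{p.lncrna_id}  log2FC={p.lncrna_log2fc:+.3f}"
                    f"  adj_p={p.lncrna_adj_p:.3g}  peaks={p.peak_count}"
                )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write enrichment, DE and network tables to ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t",
                               index=False, lineterminator="\n")
        self.de.to_csv(outdir / "de.tsv", sep="\t", index=False,
                       lineterminator="\n")
        pio.write_network(self.pairs, outdir / "network.tsv")
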