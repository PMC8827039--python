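"""Synthetic expression / gene-set / locus / peak generator with planted truth.

The generator emulates the study design the pipeline was built for: a small
tumor-vs-control bulk RNA-seq cohort (12 tumor, 5 control), five
tumor-related pathway gene sets, lncRNA/TF regulators whose expression
co-varies with pathway activity, group-wise fold-change shifts, and ChIP-seq
peaks placed near a subset of lncRNA loci.

Generative model (log2 scale throughout)
----------------------------------------
Each pathway k has a latent activity vector ``z_k`` across samples: standard
normal per sample plus a tumor-group mean shift ``pathway_shift`` (the
pathways are, by premise, differentially active in tumor). Then

* pathway member gene:  ``member_loading * z_k + noise``
* planted regulator:    ``regulator_loading * z_k + noise + de_log2fc`` in
  tumor samples (planted regulators are upregulated in tumor)
* background genes and non-regulators: pure noise; ``n_de_background`` of
  the background genes additionally get a ``+/- de_log2fc`` tumor shift.

All genes receive a per-gene baseline drawn uniformly from [2, 10] so values
resemble log2 abundances. All randomness flows from a single root seed.

Genomic layout: every lncRNA gets a 1 kb gene body on one synthetic
chromosome, tiled at 21 kb spacing so that default regulatory windows
(body + 10 kb upstream) of neighbouring loci never overlap regardless of
strand. A planted (TF, lncRNA) binding edge is realised as one 200 bp peak
centred in that lncRNA's gene body, which lies inside its own regulatory
window only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionMatrix, GeneLocus, GeneSetCollection, PeakSet

_PATHWAY_NAMES = (
    "WNT_SIGNALING",
    "SHH_SIGNALING",
    "TGFB_SIGNALING",
    "ERK_MAPK_SIGNALING",
    "ERBB2_SIGNALING",
)

_BODY_BP = 1_000          # lncRNA gene body length
_SPACING_BP = 21_000      # >= body + 2 * default upstream window: no collisions
_FIRST_START = 20_000     # keeps default windows away from the chrom start
_CHROM = "chrS"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_tumor: int = 12
    n_control: int = 5
    n_pathways: int = 5
    genes_per_pathway: int = 30
    n_background_genes: int = 300
    n_lncrnas: int = 40
    n_tfs: int = 15
    n_true_regulators_per_pathway: int = 2
    regulator_loading: float = 0.6
    member_loading: float = 0.9
    pathway_shift: float = 2.0
    de_log2fc: float = 2.0
    noise_sd: float = 1.0
    n_de_background: int = 100
    frac_bound_lncrnas: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_tumor": self.n_tumor, "n_control": self.n_control,
            "n_pathways": self.n_pathways,
            "genes_per_pathway": self.genes_per_pathway,
            "n_background_genes": self.n_background_genes,
            "n_lncrnas": self.n_lncrnas, "n_tfs": self.n_tfs,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.n_true_regulators_per_pathway < 0:
            raise ValidationError("n_true_regulators_per_pathway must be >= 0")
        if self.n_true_regulators_per_pathway > self.n_lncrnas:
            raise ValidationError(
                "n_true_regulators_per_pathway cannot exceed n_lncrnas"
            )
        need = self.n_pathways * self.n_true_regulators_per_pathway
        if need > self.n_lncrnas or need > self.n_tfs:
            raise ValidationError(
                f"need {need} distinct planted regulators per class "
                f"(n_pathways * n_true_regulators_per_pathway) but have "
                f"{self.n_lncrnas} lncRNAs / {self.n_tfs} TFs"
            )
        if not 0.0 <= self.regulator_loading <= 1.0:
            raise ValidationError("regulator_loading must be in [0, 1]")
        if not 0.0 <= self.member_loading <= 1.0:
            raise ValidationError("member_loading must be in [0, 1]")
        if not 0.0 <= self.frac_bound_lncrnas <= 1.0:
            raise ValidationError("frac_bound_lncrnas must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.n_de_background < 0:
            raise ValidationError("n_de_background must be >= 0")
        if self.n_de_background > self.n_background_genes:
            raise ValidationError(
                "n_de_background cannot exceed n_background_genes"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a synthetic dataset."""

    regulator_pathway: Set[Tuple[str, str]] = field(default_factory=set)
    de_genes: Dict[str, float] = field(default_factory=dict)
    bound_edges: Set[Tuple[str, str]] = field(default_factory=set)

    def true_pairs(self) -> Set[Tuple[str, str]]:
        """Planted (TF, lncRNA) pairs sharing a pathway with a planted peak."""
        by_pathway: Dict[str, Dict[str, Set[str]]] = {}
        for reg, pw in self.regulator_pathway:
            cls = "TF" if reg.startswith("TF") else "lncRNA"
            by_pathway.setdefault(pw, {"TF": set(), "lncRNA": set()})[cls].add(reg)
        pairs = set()
        for pw, d in by_pathway.items():
            for tf in d["TF"]:
                for lnc in d["lncRNA"]:
                    if (tf, lnc) in self.bound_edges:
                        pairs.add((tf, lnc))
        return pairs

    def to_json_dict(self) -> dict:
        return {
            "regulator_pathway": sorted(map(list, self.regulator_pathway)),
            "de_genes": dict(sorted(self.de_genes.items())),
            "bound_edges": sorted(map(list, self.bound_edges)),
        }


def _pathway_names(n: int) -> List[str]:
    names = list(_PATHWAY_NAMES[:n])
    names += [f"PATHWAY_{i}" for i in range(len(names) + 1, n + 1)]
    return names


def generate_dataset(config: SimulationConfig) -> Tuple[
    ExpressionMatrix, GeneSetCollection, List[GeneLocus], List[PeakSet],
    SyntheticTruth,
]:
    """Generate a full synthetic dataset with planted ground truth.

    Returns the expression matrix, pathway gene sets, lncRNA loci, per-TF
    peak sets (only TFs that own at least one peak) and the planted truth.
    Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_tumor + cfg.n_control
    tumor = np.arange(n) < cfg.n_tumor

    sample_ids = (
        [f"T{i + 1:02d}" for i in range(cfg.n_tumor)]
        + [f"N{i + 1:02d}" for i in range(cfg.n_control)]
    )
    pathways = _pathway_names(cfg.n_pathways)
    n_members = cfg.n_pathways * cfg.genes_per_pathway
    member_ids = [f"G{i + 1:04d}" for i in range(n_members)]
    background_ids = [f"G{i + 1:04d}" for i in range(n_members,
                                                     n_members + cfg.n_background_genes)]
    lnc_ids = [f"LNC{i + 1:03d}" for i in range(cfg.n_lncrnas)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]

    truth = SyntheticTruth()

    # latent pathway activities: N(0,1) per sample + tumor shift
    z = rng.normal(0.0, 1.0, size=(cfg.n_pathways, n))
    z[:, tumor] += cfg.pathway_shift

    def noise(rows: int) -> np.ndarray:
        return rng.normal(0.0, cfg.noise_sd, size=(rows, n))

    # pathway member genes
    member_vals = np.empty((n_members, n))
    gene_sets: Dict[str, frozenset] = {}
    for k, pw in enumerate(pathways):
        sl = slice(k * cfg.genes_per_pathway, (k + 1) * cfg.genes_per_pathway)
        member_vals[sl] = cfg.member_loading * z[k]
        gene_sets[pw] = frozenset(member_ids[sl])
    member_vals += noise(n_members)

    background_vals = noise(cfg.n_background_genes)

    # planted regulators: pathway k owns a disjoint block of each class
    ntr = cfg.n_true_regulators_per_pathway
    lnc_vals = noise(cfg.n_lncrnas)
    tf_vals = noise(cfg.n_tfs)
    for k, pw in enumerate(pathways):
        for ids, vals in ((lnc_ids, lnc_vals), (tf_ids, tf_vals)):
            for j in range(k * ntr, (k + 1) * ntr):
                vals[j] += cfg.regulator_loading * z[k]
                vals[j, tumor] += cfg.de_log2fc
                truth.regulator_pathway.add((ids[j], pw))
                truth.de_genes[ids[j]] = cfg.de_log2fc

    # background DE genes with random sign
    de_idx = rng.choice(cfg.n_background_genes, size=cfg.n_de_background,
                        replace=False)
    de_signs = rng.choice([-1.0, 1.0], size=cfg.n_de_background)
    for idx, sign in zip(de_idx, de_signs):
        background_vals[idx, tumor] += sign * cfg.de_log2fc
        truth.de_genes[background_ids[idx]] = sign * cfg.de_log2fc

    values = np.vstack([member_vals, background_vals, lnc_vals, tf_vals])
    gene_ids = member_ids + background_ids + lnc_ids + tf_ids
    baselines = rng.uniform(2.0, 10.0, size=len(gene_ids))
    values = values + baselines[:, None]

    classes = (
        ["mRNA"] * (n_members + cfg.n_background_genes)
        + ["lncRNA"] * cfg.n_lncrnas
        + ["TF"] * cfg.n_tfs
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        gene_classes=pd.Series(classes, index=gene_ids),
        sample_groups=pd.Series(
            ["tumor"] * cfg.n_tumor + ["control"] * cfg.n_control,
            index=sample_ids,
        ),
    )

    # lncRNA loci on one synthetic chromosome, non-overlapping windows
    strands = rng.choice(["+", "-"], size=cfg.n_lncrnas)
    loci = [
        GeneLocus(lnc_ids[i], _CHROM,
                  _FIRST_START + i * _SPACING_BP,
                  _FIRST_START + i * _SPACING_BP + _BODY_BP,
                  strands[i])
        for i in range(cfg.n_lncrnas)
    ]
    body_start = {l.gene_id: l.start for l in loci}

    # planted binding edges: planted TF x planted lncRNA within each pathway
    planted_edges: Set[Tuple[str, str]] = set()
    for k in range(cfg.n_pathways):
        tfs_k = tf_ids[k * ntr:(k + 1) * ntr]
        lncs_k = lnc_ids[k * ntr:(k + 1) * ntr]
        for tf in tfs_k:
            for lnc in lncs_k:
                planted_edges.add((tf, lnc))

    # additional random binding: a fraction of lncRNAs gets a random TF peak
    extra = rng.random(cfg.n_lncrnas) < cfg.frac_bound_lncrnas
    extra_tfs = rng.integers(0, cfg.n_tfs, size=cfg.n_lncrnas)
    for i in range(cfg.n_lncrnas):
        if extra[i]:
            planted_edges.add((tf_ids[extra_tfs[i]], lnc_ids[i]))

    peaks_by_tf: Dict[str, List[Tuple[str, int, int]]] = {}
    for tf, lnc in sorted(planted_edges):
        s = body_start[lnc]
        peaks_by_tf.setdefault(tf, []).append((_CHROM, s + 400, s + 600))
        truth.bound_edges.add((tf, lnc))
    peak_sets = [PeakSet(tf, ivs) for tf, ivs in sorted(peaks_by_tf.items())]

    return expr, GeneSetCollection(gene_sets), loci, peak_sets, truth


def truth_recovery_report(
    truth: SyntheticTruth,
    called_associations: Set[Tuple[str, str]],
    called_edges: Set[Tuple[str, str]],
) -> Dict[str, dict]:
    """Sensitivity/precision of called results against the planted truth.

    ``called_associations`` are (regulator, pathway) pairs called significant;
    ``called_edges`` are (TF, lncRNA) pairs in the assembled network.
    Precision over an empty called set is reported as 0 and flagged.
    """
    def layer(called: Set, planted: Set) -> dict:
        called, planted = set(called), set(planted)
        inter = called & planted
        return {
            "n_called": len(called),
            "n_true": len(planted),
            "n_recovered": len(inter),
            "sensitivity": len(inter) / len(planted) if planted else 0.0,
            "precision": len(inter) / len(called) if called else 0.0,
            "precision_undefined": not called,
        }

    return {
        "association": layer(called_associations, truth.regulator_pathway),
        "edge": layer(called_edges, truth.true_pairs()),
    }
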