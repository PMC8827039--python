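"""Readers/writers for every external file the pipeline touches.

Formats
-------
* expression matrix: TSV, header ``gene_id  gene_class  <sample ...>``,
  one row per gene, log2-scale values; a companion two-column TSV maps
  sample id to group (``tumor``/``control``).
* gene sets: standard GMT (name, description, members...).
* ChIP-seq peaks: BED3+ (extra columns ignored), 0-based half-open.
* gene loci: BED6 (chrom, start, end, name, score, strand).
* network edges: TSV with a canonical (tf, lncrna) lexicographic row order.

All genomic coordinates are 0-based half-open end-exclusive throughout the
package: a length-1 feature at position ``p`` is encoded ``(p, p + 1)``.
Every writer defines a canonical form, so ``write(read(f))`` is
byte-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

GENE_CLASSES = ("mRNA", "lncRNA", "TF")
SAMPLE_GROUPS = ("tumor", "control")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 abundance with gene-class and group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id, finite floats.
    gene_classes : pandas.Series
        Per-gene label in ``{"mRNA", "lncRNA", "TF"}``, index-aligned
        with ``values.index``.
    sample_groups : pandas.Series
        Per-sample label in ``{"tumor", "control"}``, index-aligned with
        ``values.columns``.
    """

    values: pd.DataFrame
    gene_classes: pd.Series
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene id")
        _check_unique(list(self.values.columns), "sample id")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must all be finite")
        if list(self.gene_classes.index) != list(self.values.index):
            raise ValidationError("gene_classes index must match values.index")
        if list(self.sample_groups.index) != list(self.values.columns):
            raise ValidationError("sample_groups index must match values.columns")
        bad = set(self.gene_classes) - set(GENE_CLASSES)
        if bad:
            raise ValidationError(f"unknown gene class label(s): {sorted(bad)}")
        bad = set(self.sample_groups) - set(SAMPLE_GROUPS)
        if bad:
            raise ValidationError(f"unknown sample group label(s): {sorted(bad)}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes_of_class(self, gene_class: str) -> List[str]:
        if gene_class not in GENE_CLASSES:
            raise ValidationError(f"unknown gene class {gene_class!r}")
        return list(self.gene_classes.index[self.gene_classes == gene_class])

    @property
    def coding_genes(self) -> List[str]:
        return self.genes_of_class("mRNA")

    @property
    def regulators(self) -> List[str]:
        return self.genes_of_class("lncRNA") + self.genes_of_class("TF")

    def samples_of_group(self, group: str) -> List[str]:
        if group not in SAMPLE_GROUPS:
            raise ValidationError(f"unknown sample group {group!r}")
        return list(self.sample_groups.index[self.sample_groups == group])

    def expression_of(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def require_group_sizes(self, minimum: int = 3) -> None:
        """Raise unless every group has at least ``minimum`` samples."""
        for g in SAMPLE_GROUPS:
            n = len(self.samples_of_group(g))
            if n < minimum:
                raise ValidationError(
                    f"group {g!r} has {n} samples; at least {minimum} required"
                )


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (pathways)."""

    sets: Dict[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> List[str]:
        return list(self.sets)

    def restrict_to(self, gene_ids: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``gene_ids``; drops empty survivors."""
        universe = set(gene_ids)
        kept = {
            name: members & universe
            for name, members in self.sets.items()
            if members & universe
        }
        return GeneSetCollection({k: frozenset(v) for k, v in kept.items()})


@dataclass
class PeakSet:
    """ChIP-seq peak intervals for one TF, 0-based half-open, sorted."""

    tf_id: str
    intervals: List[Tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0:
                raise ValidationError(
                    f"{self.tf_id}: negative start in ({chrom}, {start}, {end})"
                )
            if start >= end:
                raise ValidationError(
                    f"{self.tf_id}: empty/inverted interval ({chrom}, {start}, {end})"
                )
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic location of one gene, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"{self.gene_id}: negative coordinate")
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class TFlncRNAPair:
    """Final network edge with pathway support and lncRNA DE annotation."""

    tf_id: str
    lncrna_id: str
    pathways: FrozenSet[str]
    lncrna_log2fc: float
    lncrna_adj_p: float
    peak_count: int

    def __post_init__(self) -> None:
        if not self.pathways:
            raise ValidationError(
                f"pair {self.tf_id}-{self.lncrna_id}: pathways must be non-empty"
            )
        if self.peak_count < 1:
            raise ValidationError(
                f"pair {self.tf_id}-{self.lncrna_id}: peak_count must be >= 1"
            )


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression(path, groups_path) -> ExpressionMatrix:
    """Read an expression TSV plus its sample-group companion TSV.

    The TSV must have header columns ``gene_id``, ``gene_class`` followed by
    one column per sample; the companion file has columns
    ``sample_id``, ``group``. Ordering of genes and samples is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read expression TSV {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise ParseError(
            f"{path}: expected gene_id, gene_class and >=1 sample column"
        )
    if list(df.columns[:2]) != ["gene_id", "gene_class"]:
        raise ParseError(
            f"{path}: first two header columns must be 'gene_id' and "
            f"'gene_class', got {list(df.columns[:2])}"
        )
    gene_ids = df["gene_id"].tolist()
    _check_unique(gene_ids, "gene id")
    sample_ids = list(df.columns[2:])
    _check_unique(sample_ids, "sample id")
    numeric = pd.DataFrame(index=gene_ids, columns=sample_ids, dtype=float)
    for col in sample_ids:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric cell at gene {gene_ids[row]!r}, "
                f"sample {col!r}: {df[col].iloc[row]!r}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(
                f"{path}: missing cell at gene {gene_ids[row]!r}, sample {col!r}"
            )
        # re-parse through numpy: correctly-rounded, so writes round-trip
        numeric[col] = df[col].to_numpy().astype(float)

    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    if list(groups.columns) != ["sample_id", "group"]:
        raise ParseError(
            f"{groups_path}: header must be 'sample_id\\tgroup', "
            f"got {list(groups.columns)}"
        )
    gmap = dict(zip(groups["sample_id"], groups["group"]))
    missing = [s for s in sample_ids if s not in gmap]
    if missing:
        raise ValidationError(
            f"{groups_path}: no group for sample(s) {missing}"
        )
    classes = pd.Series(df["gene_class"].tolist(), index=gene_ids)
    sgroups = pd.Series([gmap[s] for s in sample_ids], index=sample_ids)
    return ExpressionMatrix(values=numeric, gene_classes=classes,
                            sample_groups=sgroups)


def write_expression(matrix: ExpressionMatrix, path, groups_path) -> None:
    """Write the matrix and its group map in canonical (round-trip) form."""
    out = matrix.values.copy()
    out.insert(0, "gene_class", matrix.gene_classes.to_numpy())
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", lineterminator="\n")
    gdf = pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "group": matrix.sample_groups.to_numpy()}
    )
    gdf.to_csv(groups_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...); description dropped."""
    sets: Dict[str, FrozenSet[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member, got {len(fields)} field(s)"
                )
            name = fields[0]
            members = [m for m in fields[2:] if m]
            if not members:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write sets in name order with sorted members (canonical form)."""
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# BED peaks and loci
# ---------------------------------------------------------------------------

def read_peaks(path, tf_id: str) -> PeakSet:
    """Read a BED3+ peak file for one TF; extra columns are ignored."""
    intervals: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start must be < end ({start} >= {end})"
                )
            intervals.append((chrom, start, end))
    return PeakSet(tf_id=tf_id, intervals=intervals)


def write_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in peaks.intervals:  # already sorted
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_loci(path) -> List[GeneLocus]:
    """Read gene loci from BED6 (chrom, start, end, name, score, strand)."""
    loci: List[GeneLocus] = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom, name, strand = fields[0], fields[3], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            try:
                loci.append(GeneLocus(name, chrom, start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_loci(loci: Sequence[GeneLocus], path) -> None:
    """Write loci as BED6 sorted by (chrom, start, gene_id)."""
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.gene_id))
    with open(path, "w") as fh:
        for l in ordered:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene_id}\t0\t{l.strand}\n")


# ---------------------------------------------------------------------------
# network edge list
# ---------------------------------------------------------------------------

_NETWORK_COLUMNS = ["tf", "lncrna", "pathways", "lncrna_log2fc",
                    "lncrna_adj_p", "peak_count"]


def write_network(pairs: Sequence[TFlncRNAPair], path) -> None:
    """Write pairs as TSV, rows sorted lexicographically by (tf, lncrna)."""
    rows = []
    for p in sorted(pairs, key=lambda p: (p.tf_id, p.lncrna_id)):
        rows.append({
            "tf": p.tf_id,
            "lncrna": p.lncrna_id,
            "pathways": ";".join(sorted(p.pathways)),
            "lncrna_log2fc": repr(float(p.lncrna_log2fc)),
            "lncrna_adj_p": repr(float(p.lncrna_adj_p)),
            "peak_count": p.peak_count,
        })
    df = pd.DataFrame(rows, columns=_NETWORK_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_network(path) -> List[TFlncRNAPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _NETWORK_COLUMNS:
        raise ParseError(f"{path}: unexpected network header {list(df.columns)}")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(TFlncRNAPair(
            tf_id=row["tf"],
            lncrna_id=row["lncrna"],
            pathways=frozenset(row["pathways"].split(";")),
            lncrna_log2fc=float(row["lncrna_log2fc"]),
            lncrna_adj_p=float(row["lncrna_adj_p"]),
            peak_count=int(row["peak_count"]),
        ))
    return pairs
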