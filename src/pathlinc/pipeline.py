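"""One-command orchestration: simulate -> rank -> enrich -> de -> network.

:func:`run_pipeline` executes every stage from a :class:`RunConfig`, writes
all intermediate files to the output directory and returns (and writes) a
machine-readable run manifest with the funnel counts, a config echo, the
seed and the package version. Identical config + seed produce a
byte-identical ``manifest.json``.

Seeding: the root seed fans out to named per-stage sub-seeds through
``numpy.random.SeedSequence`` spawn keys, so adding or re-ordering stages
never shifts another stage's stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import __version__
from . import io as pio
from .diffexp import read_de_table
from .exceptions import PipelineError, ValidationError
from .model import AnalysisSettings, PathwayRegulationModel
from .simulate import SimulationConfig, generate_dataset, truth_recovery_report

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"simulate": 0, "enrich": 1}


def _stage_seed(root_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(root_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Full pipeline configuration: analysis settings, seed, inputs.

    Exactly one input mode applies: either ``simulate`` carries a
    :class:`SimulationConfig`, or the four path fields point at existing
    files. Unknown keys in a YAML config are rejected.
    """

    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    expression: Optional[str] = None
    groups: Optional[str] = None
    gmt: Optional[str] = None
    loci: Optional[str] = None
    peaks_dir: Optional[str] = None
    de_table: Optional[str] = None

    def __post_init__(self) -> None:
        if self.simulate is None and not (self.expression and self.groups
                                          and self.gmt):
            raise ValidationError(
                "config needs either a 'simulate' block or expression/"
                "groups/gmt paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "settings" in raw and raw["settings"] is not None:
            s = dict(raw["settings"])
            sknown = {f.name for f in dataclasses.fields(AnalysisSettings)}
            sunknown = set(s) - sknown
            if sunknown:
                raise ValidationError(
                    f"unknown settings key(s): {sorted(sunknown)}")
            raw["settings"] = AnalysisSettings(**s)
        if "simulate" in raw and raw["simulate"] is not None:
            c = dict(raw["simulate"])
            cknown = {f.name for f in dataclasses.fields(SimulationConfig)}
            cunknown = set(c) - cknown
            if cunknown:
                raise ValidationError(
                    f"unknown simulate key(s): {sorted(cunknown)}")
            raw["simulate"] = SimulationConfig(**c)
        return cls(**raw)


def run_pipeline(config: RunConfig, outdir) -> Dict:
    """Run every stage into ``outdir``; returns the manifest dict.

    On a stage failure the partial outputs are retained, a ``FAILED`` marker
    naming the stage is written, and :class:`PipelineError` is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        truth = None
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(
                config.simulate,
                seed=_stage_seed(config.seed, "simulate"),
            )
            expr, sets, loci, peaks, truth = generate_dataset(sim_cfg)
            pio.write_expression(expr, outdir / "expression.tsv",
                                 outdir / "groups.tsv")
            pio.write_gmt(sets, outdir / "pathways.gmt")
            pio.write_loci(loci, outdir / "lncrna_loci.bed")
            peak_dir = outdir / "peaks"
            peak_dir.mkdir(exist_ok=True)
            for ps in peaks:
                pio.write_peaks(ps, peak_dir / f"{ps.tf_id}.bed")
            with open(outdir / "truth.json", "w") as fh:
                json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
        else:
            stage = "load"
            expr = pio.read_expression(config.expression, config.groups)
            sets = pio.read_gmt(config.gmt)
            loci = pio.read_loci(config.loci) if config.loci else None
            peaks = None
            if config.peaks_dir:
                peaks = [pio.read_peaks(p, p.stem)
                         for p in sorted(Path(config.peaks_dir).glob("*.bed"))]

        stage = "fit"
        model = PathwayRegulationModel(expr, sets, loci=loci, peaks=peaks,
                                       settings=config.settings)
        de_table = read_de_table(
            config.de_table,
            adj_p_cut=config.settings.de_adj_p,
            abs_log2fc_cut=config.settings.de_abs_log2fc,
        ) if config.de_table else None
        results = model.fit(seed=_stage_seed(config.seed, "enrich"),
                            de_table=de_table)

        stage = "write"
        results.save(outdir)
        activity = model.pathway_activity()
        activity.to_csv(outdir / "activity.tsv", sep="\t", index=False,
                        lineterminator="\n")

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "settings": dataclasses.asdict(config.settings),
            "simulate": (dataclasses.asdict(config.simulate)
                         if config.simulate else None),
            "counts": results.funnel,
            "network_summary": results.network_summary(),
        }
        if truth is not None:
            manifest["truth_recovery"] = truth_recovery_report(
                truth, results.significant_associations(),
                results.called_edges(),
            )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline finished: %s", results.funnel)
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
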