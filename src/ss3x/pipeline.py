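"""End-to-end pipeline: simulate -> parse -> TSO-filter -> count -> velocity -> QC.

Driven by a single YAML config with sections `sim` (SimConfig fields),
`parse` (ParseConfig fields), `tso` (max_mm, mode, anchor), and `qc`
(QCThresholds fields). Every stage writes its outputs under the run
directory and the in-memory results come back in a PipelineResult.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .feature_count import CountResult, FeatureIndex, build_matrices, write_mtx
from .qc_cells import QCThresholds, filter_genes, profile_cells
from .sim_reads import SimConfig, SimOutput, simulate
from .tso_filter import FilterReport, filter_alignment_file
from .umi_parse import ParseConfig, parse_fastq
from .velocity_classify import summarize_cells

log = logging.getLogger("ss3x")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    parse: ParseConfig = field(default_factory=ParseConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    max_mm: int = 2
    tso_mode: str = "remove"
    anchor: str = "query_length"
    collapse: str = "cluster"
    outdir: str = "ss3x_run"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        tso = raw.get("tso", {})
        return cls(
            sim=SimConfig(**raw.get("sim", {})),
            parse=ParseConfig(**raw.get("parse", {})),
            qc=QCThresholds(**raw.get("qc", {})),
            max_mm=int(tso.get("max_mm", 2)),
            tso_mode=tso.get("mode", "remove"),
            anchor=tso.get("anchor", "query_length"),
            collapse=raw.get("collapse", "cluster"),
            outdir=raw.get("outdir", "ss3x_run"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    outdir: Path
    sim: SimOutput
    parsed: pd.DataFrame
    tso_report: FilterReport
    counts: CountResult
    velocity: pd.DataFrame
    velocity_meta: dict
    qc: pd.DataFrame
    filtered_umi_exon_intron: pd.DataFrame


def run_pipeline(config, outdir=None) -> PipelineResult:
    """Run the whole chain on simulated data from one config.

    config may be a PipelineConfig, a dict, or a path to a YAML file.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("simulating reads into %s", out / "sim")
    sim = simulate(config.sim, out / "sim")

    log.info("parsing FASTQ")
    parsed = parse_fastq(
        sim.fastq_r1, config.parse, i1_path=sim.fastq_i1,
        out_tsv=out / "parsed_reads.tsv",
    )

    log.info("TSO strand-invasion filtering (max_mm=%d)", config.max_mm)
    filtered_sam = out / "filtered.sam"
    report = filter_alignment_file(
        sim.sam, sim.fasta, out_path=filtered_sam,
        max_mm=config.max_mm, mode=config.tso_mode, anchor=config.anchor,
    )
    report.to_json(out / "tso_report.json")

    index = FeatureIndex.from_gtf(sim.gtf)
    counting_input = filtered_sam if config.tso_mode == "remove" else sim.sam
    log.info("counting features")
    counts = build_matrices(
        counting_input, index,
        cells=list(sim.cells["cell"]), collapse=config.collapse,
    )
    for name, layer in counts.layers.items():
        write_mtx(layer, out / "counts", prefix=f"{name}_")

    log.info("velocity classification")
    velocity, vmeta = summarize_cells(counting_input, index,
                                      cells=list(sim.cells["cell"]))
    velocity.to_csv(out / "velocity.tsv", sep="\t", index=False)

    log.info("per-cell QC")
    qc = profile_cells(counts.cell_stats, counts.layers["umi_exon_intron"],
                       config.qc)
    qc.to_csv(out / "qc_cells.tsv", sep="\t", index=False)

    passing = list(qc.loc[qc["pass_qc"], "cell"])
    filtered = filter_genes(
        counts.layers["umi_exon_intron"][passing] if passing
        else counts.layers["umi_exon_intron"].iloc[:, 0:0],
        min_cells=config.qc.min_cells_per_gene,
    )
    write_mtx(filtered, out / "counts", prefix="filtered_umi_exon_intron_")

    summary = {
        "n_cells": int(len(qc)),
        "n_cells_pass_qc": int(qc["pass_qc"].sum()),
        "n_genes_after_filter": int(filtered.shape[0]),
        "velocity_denominator": vmeta["denominator"],
        "tso_artifact_reads": len(report.artifact_read_names),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    return PipelineResult(
        outdir=out, sim=sim, parsed=parsed, tso_report=report, counts=counts,
        velocity=velocity, velocity_meta=vmeta, qc=qc,
        filtered_umi_exon_intron=filtered,
    )
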