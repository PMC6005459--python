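"""Pipeline configuration and end-to-end orchestration.

A :class:`PipelineConfig` binds the three analysis strands (copy-number/LOH,
bisulfite epiallele, expression subtypes) to their thresholds and a master
seed.  :func:`run_pipeline` executes the requested strands on synthetic
truth-known inputs, writes every stage output under the output directory and
a single machine-readable ``summary.json``; results are bit-reproducible
given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import baf, bisulfite, expression, io, synthetic
from .expression import MarkerGeneSet

logger = logging.getLogger(__name__)

_STRANDS = ("cnv", "bisulfite", "expression")


@dataclasses.dataclass
class PipelineConfig:
    """All tunable stage parameters plus paths and the master seed."""

    seed: int = 1
    out_dir: str = "wtprofiler_out"
    strands: tuple[str, ...] = _STRANDS
    # CNV strand
    tumour_purity: float = 0.8
    mean_depth: float = 100.0
    site_density: float = 12.0
    gq_min: float = 14
    depth_min: int = 11
    depth_max: int = 1001
    # bisulfite strand
    dense_fraction: float = 0.395
    n_reads: int = 1043
    dense_min: float = 0.9
    unmeth_max: float = 0.1
    min_called: int = 5
    # expression strand
    n_probes: int = 1000
    n_case: int = 4
    n_control: int = 12
    marker_effect: float = 3.0
    keep_fraction: float = 0.5
    fold_min: float = 2.0
    adj_p_max: float = 0.01

    def __post_init__(self) -> None:
        self.strands = tuple(self.strands)
        for s in self.strands:
            if s not in _STRANDS:
                raise ValueError(f"unknown strand {s!r}")
        if not 0 <= self.tumour_purity <= 1:
            raise ValueError("tumour_purity must lie in [0, 1]")
        if not 0 <= self.dense_fraction <= 1:
            raise ValueError("dense_fraction must lie in [0, 1]")
        if not 0 <= self.unmeth_max < self.dense_min <= 1:
            raise ValueError("require 0 <= unmeth_max < dense_min <= 1")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "strands" in data:
            data["strands"] = tuple(data["strands"])
        return cls(**data)


def default_truth_segments(purity: float) -> list[synthetic.CnvTruthSegment]:
    """Three-chromosome synthetic genome with one implanted event per type."""
    mb = 1_000_000
    return [
        synthetic.CnvTruthSegment("chr1", 1, 40 * mb, "neutral_het", purity),
        synthetic.CnvTruthSegment("chr1", 40 * mb + 1, 60 * mb, "gain", purity),
        synthetic.CnvTruthSegment("chr2", 1, 40 * mb, "neutral_het", purity),
        synthetic.CnvTruthSegment("chr2", 40 * mb + 1, 60 * mb, "loss", purity),
        synthetic.CnvTruthSegment("chr3", 1, 40 * mb, "neutral_het", purity),
        synthetic.CnvTruthSegment("chr3", 40 * mb + 1, 60 * mb, "cn_loh", purity),
    ]


def _run_cnv(cfg: PipelineConfig, out: Path) -> dict:
    truth = default_truth_segments(cfg.tumour_purity)
    table = synthetic.gen_tumour_normal_sites(
        truth, site_density=cfg.site_density, mean_depth=cfg.mean_depth,
        seed=cfg.seed)
    io.write_sites_vcf(table, out / "sites.vcf")
    table.to_csv(out / "sites_truth.tsv", sep="\t", index=False)
    sites = io.sites_from_frame(table)
    kept = baf.filter_heterozygous_sites(
        sites, gq_min=cfg.gq_min, depth_min=cfg.depth_min, depth_max=cfg.depth_max)
    track = baf.compute_baf_track(kept)
    result = baf.segment_states(track)
    baf.segments_frame(result.segments).to_csv(out / "segments.tsv", sep="\t", index=False)
    io.write_segments_bed(result.segments, out / "segments.bed")
    runs = [dataclasses.asdict(r) for r in result.loh_runs]
    if runs:
        pd.DataFrame(runs).to_csv(out / "loh_runs.tsv", sep="\t", index=False)
    return {
        "n_sites_filtered": len(kept),
        "fractional_cna_score": result.fractional_cna_score,
        "n_segments": len(result.segments),
        "n_loh_runs": len(result.loh_runs),
    }


def _run_bisulfite(cfg: PipelineConfig, out: Path) -> dict:
    amplicon = synthetic.make_amplicon()
    io.write_amplicon_fasta(amplicon, out / "amplicon.fasta")
    truth = synthetic.EpialleleTruth(
        dense_fraction=cfg.dense_fraction, n_reads=cfg.n_reads, seed=cfg.seed + 1)
    reads, truth_table = synthetic.gen_bisulfite_reads(amplicon, truth)
    io.write_fastq(reads, out / "bisulfite_reads.fastq", ids=list(truth_table["read_id"]))
    truth_table.to_csv(out / "bisulfite_truth.tsv", sep="\t", index=False)
    matrix = bisulfite.assign_and_call(reads, amplicon, read_ids=list(truth_table["read_id"]))
    bisulfite.per_cpg_proportions(matrix).to_csv(
        out / "per_cpg_proportions.tsv", sep="\t", index=False)
    (out / "lollipop.tsv").write_text(bisulfite.lollipop_matrix(matrix))
    summary = bisulfite.classify_epialleles(
        matrix, dense_min=cfg.dense_min, unmeth_max=cfg.unmeth_max,
        min_called=cfg.min_called)
    io.write_json(summary.as_dict(), out / "epialleles.json")
    return summary.as_dict()


def _run_expression(cfg: PipelineConfig, out: Path) -> dict:
    groups = ("S1",) * cfg.n_case + ("other",) * cfg.n_control
    markers = [
        MarkerGeneSet("stage_early", tuple(f"P{i:05d}" for i in range(15))),
        MarkerGeneSet("stage_late", tuple(f"P{i:05d}" for i in range(15, 30))),
    ]
    truth = synthetic.ExpressionTruth(
        group_labels=groups,
        effects={"stage_early": ("S1", cfg.marker_effect)},
        n_probes=cfg.n_probes, seed=cfg.seed + 2)
    matrix = synthetic.gen_expression_matrix(truth, markers)
    io.write_expression_tsv(matrix, out / "expression.tsv", out / "groups.tsv")
    io.write_gmt(markers, out / "marker_sets.gmt")

    filtered = expression.variance_filter(matrix, cfg.keep_fraction)
    cluster = expression.hierarchical_cluster(filtered)
    (out / "dendrogram.nwk").write_text(cluster.newick + "\n")

    de = expression.moderated_de(filtered, "S1", "other")
    de.to_csv(out / "de_table.tsv", sep="\t", index_label="probe_id")
    up, down = expression.select_by_fold_and_fdr(de, cfg.fold_min, cfg.adj_p_max)

    # independent reference cohort with the same planted biology
    ref_truth = dataclasses.replace(truth, seed=cfg.seed + 3)
    ref_matrix = synthetic.gen_expression_matrix(ref_truth, markers)
    ref_de = expression.moderated_de(
        expression.variance_filter(ref_matrix, cfg.keep_fraction), "S1", "other")
    ref_up, ref_down = expression.select_by_fold_and_fdr(ref_de, cfg.fold_min, cfg.adj_p_max)
    overlap = expression.signature_overlap(up, down, ref_up, ref_down)
    io.write_json(overlap, out / "signature_overlap.json")

    metagene_p = {}
    for ms in markers:
        score = expression.metagene_scores(matrix, ms)
        score.scores.rename("score").to_csv(
            out / f"metagene_{ms.stage_name}.tsv", sep="\t", index_label="sample_id")
        cmp = expression.compare_metagene(score, matrix.sample_groups, "S1", "other")
        metagene_p[ms.stage_name] = cmp["p_value"]
    return {
        "n_probes_filtered": len(filtered.probe_ids),
        "n_up": len(up),
        "n_down": len(down),
        "overlap": overlap,
        "metagene_p_values": metagene_p,
        "leaf_order": cluster.leaf_order,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured strands end-to-end; returns the summary dict.

    Every stage writes its artefacts under ``config.out_dir``; the summary is
    also written to ``summary.json`` there.  Any stage failure is re-raised
    with the strand named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}
    runners = {"cnv": _run_cnv, "bisulfite": _run_bisulfite, "expression": _run_expression}
    for strand in config.strands:
        try:
            summary[strand] = runners[strand](config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline strand {strand!r} failed: {exc}") from exc
    io.write_json(summary, out / "summary.json")
    return summary
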