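"""Full-protocol orchestration: validate -> metrics -> compare -> taxonomy ->
decontaminate -> consolidated report.

Every stage writes individually consumable artifacts into the output
directory; the top-level ``report.json`` references stage files and repeats
only headline numbers, never full tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import consensus_taxonomy as ct
from . import decontamination as dc
from . import io_formats as io
from . import pipeline_comparison as pc
from .errors import StageError

log = logging.getLogger("aeroscore")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run; YAML-round-trippable."""

    table_a: str
    seqs_a: str
    table_b: str
    seqs_b: str
    metadata: str
    taxonomy_primary: str
    outdir: str
    taxonomy_secondary: str | None = None
    label_a: str = "A"
    label_b: str = "B"
    alpha: float = 0.05
    match_mode: str = "exact"
    min_overlap: int = 200
    overlap_thresholds: tuple[int, ...] = (100, 500)
    low_abundance_threshold: int = 100
    weights: dict = field(default_factory=dict)
    combination_threshold: float = 0.1
    min_presence: int = 5
    high_abundance_threshold: int = 400
    control_scope: str = "all_negative"
    top_n: int = 100
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, v, lo, hi in (("alpha", self.alpha, 0, 1),
                                ("combination_threshold", self.combination_threshold, 0, 1)):
            if not lo < v < hi:
                raise ValueError(f"{name} must lie strictly in ({lo}, {hi}); got {v}")
        if self.min_overlap < 1 or self.high_abundance_threshold < 0:
            raise ValueError("thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "overlap_thresholds" in doc:
            doc["overlap_thresholds"] = tuple(doc["overlap_thresholds"])
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["overlap_thresholds"] = list(self.overlap_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def run_full_protocol(config: RunConfig) -> dict:
    """Execute all stages in order; returns the consolidated report bundle.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written by earlier stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    bundle: dict = {"stages": {}, "config": asdict(config)}
    log.info("run configuration: %s", asdict(config))

    try:
        meta = io.read_metadata(config.metadata)
        table_a = io.read_asv_table(config.table_a, sample_ids=meta.sample_ids)
        table_b = io.read_asv_table(config.table_b, sample_ids=meta.sample_ids)
        seqs_a = io.read_fasta(config.seqs_a)
        seqs_b = io.read_fasta(config.seqs_b)
        bundle["stages"]["validate"] = {
            "n_samples_a": table_a.n_samples, "n_asvs_a": table_a.n_asvs,
            "n_samples_b": table_b.n_samples, "n_asvs_b": table_b.n_asvs,
        }
        log.info("validated inputs: A %dx%d, B %dx%d", table_a.n_samples,
                 table_a.n_asvs, table_b.n_samples, table_b.n_asvs)
    except Exception as exc:
        raise StageError("validate", str(exc)) from exc

    try:
        metrics_a = pc.pipeline_metrics(config.label_a, table_a, meta, alpha=config.alpha)
        metrics_b = pc.pipeline_metrics(config.label_b, table_b, meta, alpha=config.alpha)
        for m, name in ((metrics_a, "metrics_a"), (metrics_b, "metrics_b")):
            payload = {"counts": m.count_summary.to_dict(),
                       "alpha_diversity": m.diversity.to_dict()["summary"],
                       "beta_diversity": m.beta.to_dict(),
                       "n_diff_abundant": m.n_diff_abundant}
            with open(outdir / f"{name}.json", "w") as fh:
                json.dump(payload, fh, indent=2, default=io._json_default)
        bundle["stages"]["metrics"] = {"files": ["metrics_a.json", "metrics_b.json"]}
    except Exception as exc:
        raise StageError("metrics", str(exc)) from exc

    try:
        overlap = pc.match_asvs(seqs_a, seqs_b, mode=config.match_mode,
                                min_overlap=config.min_overlap,
                                label_a=config.label_a, label_b=config.label_b)
        overlap = pc.overlap_stats(overlap, table_a, table_b,
                                   thresholds=config.overlap_thresholds)
        tests = pc.default_tests(metrics_a, metrics_b)
        scorecard = pc.build_scorecard(
            metrics_a, metrics_b, overlap, tests=tests, weights=config.weights,
            alpha=config.alpha,
            low_abundance_threshold=config.low_abundance_threshold)
        io.write_report(scorecard, outdir / "scorecard.json", "json")
        io.write_report(scorecard, outdir / "scorecard.tsv", "tsv")
        io.write_report(overlap, outdir / "overlap.json", "json")
        bundle["stages"]["compare"] = {
            "files": ["scorecard.json", "scorecard.tsv", "overlap.json"],
            "verdict": scorecard.verdict,
        }
        log.info("scorecard verdict: %s", scorecard.verdict)
    except Exception as exc:
        raise StageError("compare", str(exc)) from exc

    selected_table = table_a if scorecard.verdict == config.label_a else table_b
    try:
        tax_primary = io.read_taxonomy(config.taxonomy_primary)
        if config.taxonomy_secondary:
            tax_secondary = io.read_taxonomy(config.taxonomy_secondary)
            consensus = ct.merge_assignments(tax_primary, tax_secondary,
                                             asv_ids=selected_table.asv_ids)
            stats = ct.assignment_stats(consensus, tax_primary, tax_secondary)
            venn = ct.genus_overlap(tax_primary, tax_secondary)
            consistency = ct.consistency_at_genus(tax_primary, tax_secondary,
                                                  selected_table, top_n=config.top_n)
            consensus.to_frame().to_csv(outdir / "consensus_taxonomy.tsv", sep="\t")
            with open(outdir / "taxonomy_stats.json", "w") as fh:
                json.dump({"assignment": stats.to_dict(),
                           "genus_overlap": venn.to_frame().iloc[0].to_dict(),
                           "consistency": consistency},
                          fh, indent=2, default=io._json_default)
            bundle["stages"]["taxonomy"] = {
                "files": ["consensus_taxonomy.tsv", "taxonomy_stats.json"],
                "mode": "consensus",
                "pct_unassigned_combined": stats.pct_unassigned_combined,
            }
        else:
            log.warning("no secondary taxonomy supplied; single-database mode")
            io.write_taxonomy(tax_primary, outdir / "consensus_taxonomy.tsv")
            bundle["stages"]["taxonomy"] = {
                "files": ["consensus_taxonomy.tsv"], "mode": "single_db"}
    except Exception as exc:
        raise StageError("taxonomy", str(exc)) from exc

    try:
        contam = dc.run_decontamination(
            selected_table, meta,
            combination_threshold=config.combination_threshold,
            min_presence=config.min_presence,
            high_abundance_threshold=config.high_abundance_threshold,
            control_scope=config.control_scope)
        io.write_report(contam, outdir / "contamination.json", "json")
        io.write_asv_table(contam.subtraction.corrected,
                           outdir / "corrected_table.tsv")
        bundle["stages"]["decontam"] = {
            "files": ["contamination.json", "corrected_table.tsv"],
            "n_flagged": int(contam.scores["flagged"].sum()),
            "reads_removed": contam.subtraction.total_removed(),
        }
    except Exception as exc:
        raise StageError("decontam", str(exc)) from exc

    bundle["verdict"] = scorecard.verdict
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=io._json_default)
    log.info("bundle written to %s", outdir / "report.json")
    log.removeHandler(handler)
    handler.close()
    return bundle
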