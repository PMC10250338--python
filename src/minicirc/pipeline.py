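"""End-to-end pipeline orchestration: simulate -> classify -> concatemers ->
annotate -> quant, with a reproducibility manifest.

The config is a plain mapping (usually loaded from YAML) with per-stage
sections; it is validated before any compute so misconfigured runs fail
fast with a stage-tagged error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from ._align import Scoring
from .annotate import segment_constant_cassette, write_annotation_gff
from .classify import (
    ClassifierConfig,
    build_aligner,
    filter_hits,
    hits_to_frame,
    length_distribution,
)
from .concatemer import (
    ReadClassification,
    classify_hits,
    flag_incompatible_joins,
    summarize_concatemers,
)
from .core import AlignmentHit, MinicircleSpec, ReadRecord
from .io import read_sequences, write_fasta, write_fastq, write_tsv
from .quantstats import QPCRMeasurement, copy_ratio, fit_standard_curve
from .synthetic import (
    SimulationParams,
    build_species_model,
    cds_references,
    constant_references,
    default_config,
    generate_minicircles,
    simulate_reads,
)

import pandas as pd

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "classify", "concatemers", "annotate", "quant")


class ConfigError(ValueError):
    """Raised when the pipeline config fails validation."""


def classifier_config_from(config: Mapping[str, Any]) -> ClassifierConfig:
    section = dict(config.get("classify") or {})
    scoring_cfg = section.pop("scoring", None)
    scoring = Scoring(**scoring_cfg) if scoring_cfg else Scoring()
    allowed = {
        "min_identity_collect", "min_identity_strict", "min_cds_fraction",
        "min_hit_len_intron_rich", "min_score", "kmer_size", "max_read_overlap",
    }
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"classify: unknown keys {sorted(unknown)}")
    return ClassifierConfig(scoring=scoring, **section)


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Schema-check the config and return the resolved stage list.

    When no stages are given, all simulation/analysis stages run; quant is
    included only if qPCR tables are configured.
    """
    paths_cfg = config.get("paths") or {}
    default_stages = [s for s in ALL_STAGES if s != "quant"]
    if "qpcr_standards" in paths_cfg and "qpcr_targets" in paths_cfg:
        default_stages.append("quant")
    stages = list(config.get("stages") or default_stages)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    paths = config.get("paths") or {}
    simulate_on = "simulate" in stages
    if "classify" in stages and not simulate_on:
        for key in ("reads", "cds_refs"):
            if key not in paths:
                raise ConfigError(
                    f"classify stage without simulate requires paths.{key}"
                )
            if not Path(paths[key]).exists():
                raise ConfigError(f"paths.{key}: {paths[key]} does not exist")
    if "annotate" in stages and not simulate_on and "circles" not in paths:
        raise ConfigError("annotate stage without simulate requires paths.circles")
    if "quant" in stages:
        for key in ("qpcr_standards", "qpcr_targets"):
            if key not in paths:
                raise ConfigError(f"quant stage requires paths.{key}")
            if not Path(paths[key]).exists():
                raise ConfigError(f"paths.{key}: {paths[key]} does not exist")
    classifier_config_from(config)  # raises on bad keys
    return stages


def _config_hash(config: Mapping[str, Any], input_paths: Sequence[Path]) -> str:
    h = hashlib.sha256()
    h.update(yaml.safe_dump(dict(config), sort_keys=True).encode())
    for p in sorted(str(p) for p in input_paths):
        path = Path(p)
        if path.exists():
            h.update(path.read_bytes())
    return h.hexdigest()


def classify_read_set(
    reads: Sequence[ReadRecord],
    cds_refs: Sequence[tuple[str, str]],
    constant_refs: Sequence[tuple[str, str]],
    config: ClassifierConfig | None = None,
) -> tuple[dict[str, list[AlignmentHit]], list[ReadClassification]]:
    """Align and classify every read against CDS + constant references."""
    config = config or ClassifierConfig()
    aligner = build_aligner(list(cds_refs) + list(constant_refs), config)
    gene_map = dict(cds_refs)
    const_map = dict(constant_refs)
    hits_by_read: dict[str, list[AlignmentHit]] = {}
    classifications: list[ReadClassification] = []
    for read in reads:
        hits = aligner.align(read.sequence, read_id=read.read_id)
        hits_by_read[read.read_id] = hits
        classifications.append(
            classify_hits(read.read_id, hits, gene_map, const_map, config)
        )
    return hits_by_read, classifications


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute the requested stages; returns the machine-readable summary."""
    stages = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    paths = {k: Path(v) for k, v in (config.get("paths") or {}).items()}
    cls_config = classifier_config_from(config)
    summary: dict[str, Any] = {"stages": stages, "seed": seed}

    reads: list[ReadRecord] = []
    circles: list[MinicircleSpec] = []
    cds_refs: list[tuple[str, str]] = []
    constant_refs: list[tuple[str, str]] = []
    gene_to_group: dict[str, str] = {}

    if "simulate" in stages:
        model_cfg = config.get("model") or default_config()
        model = build_species_model(model_cfg)
        circles = generate_minicircles(model, seed)
        sim_cfg = dict(config.get("simulate") or {})
        sim_cfg.setdefault("n_reads", 200)
        params = SimulationParams(seed=seed, **sim_cfg)
        reads, truth = simulate_reads(circles, params)
        cds_refs = cds_references(circles)
        constant_refs = constant_references(circles)
        gene_to_group = model.gene_to_group()
        write_fasta(
            [ReadRecord(c.circle_id, c.sequence) for c in circles],
            outdir / "circles.fasta",
        )
        write_fasta(
            [ReadRecord(g, s) for g, s in cds_refs], outdir / "cds_refs.fasta"
        )
        write_fasta(
            [ReadRecord(g, s) for g, s in constant_refs],
            outdir / "constant_refs.fasta",
        )
        write_fastq(reads, outdir / "reads.fastq")
        write_tsv(truth, outdir / "truth.tsv")
        summary["simulate"] = {
            "n_circles": len(circles),
            "n_reads": len(reads),
            "categories": truth["category"].value_counts().to_dict(),
        }
        logger.info("simulated %d reads from %d circles", len(reads), len(circles))

    if not reads and "reads" in paths:
        reads = read_sequences(paths["reads"])
    if not cds_refs and "cds_refs" in paths:
        cds_refs = [(r.read_id, r.sequence) for r in read_sequences(paths["cds_refs"])]
    if not constant_refs and "constant_refs" in paths:
        constant_refs = [
            (r.read_id, r.sequence) for r in read_sequences(paths["constant_refs"])
        ]
    if not gene_to_group and "gene_groups" in paths:
        df = pd.read_csv(paths["gene_groups"], sep="\t")
        gene_to_group = dict(zip(df["gene"], df["group"]))

    classifications: list[ReadClassification] = []
    if "classify" in stages:
        try:
            hits_by_read, classifications = classify_read_set(
                reads, cds_refs, constant_refs, cls_config
            )
        except Exception as exc:  # stage-tagged failure
            raise RuntimeError(f"classify stage failed: {exc}") from exc
        all_hits = [h for hits in hits_by_read.values() for h in hits]
        gene_hits = [h for h in all_hits if h.ref_id in dict(cds_refs)]
        write_tsv(hits_to_frame(all_hits), outdir / "hits.tsv")
        strict = filter_hits(gene_hits, dict(cds_refs), cls_config, mode="strict")
        dists = length_distribution(reads, strict, circles or None)
        rows = [
            {
                "gene": g,
                "n_reads": int(d.lengths.size),
                "modal_length": d.modal_length,
                "circle_length": d.circle_length,
                "mode_relative_error": d.mode_relative_error,
            }
            for g, d in dists.items()
        ]
        write_tsv(pd.DataFrame(rows), outdir / "lengths.tsv")
        collected = {h.read_id for h in filter_hits(gene_hits, dict(cds_refs), cls_config, "collect")}
        summary["classify"] = {
            "n_reads": len(reads),
            "n_collected": len(collected),
            "n_hits": len(all_hits),
        }

    if "concatemers" in stages:
        if not classifications:
            raise RuntimeError("concatemers stage requires the classify stage")
        report = summarize_concatemers(classifications)
        if gene_to_group:
            report = flag_incompatible_joins(report, gene_to_group)
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "read_id": c.read_id,
                        "category": c.category,
                        "confidence": c.confidence,
                        "unit_count": c.unit_count,
                        "structure": c.structure,
                    }
                    for c in classifications
                ]
            ),
            outdir / "classification.tsv",
        )
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "count": n,
                        "flagged": report.flagged_edges.get((a, b), False),
                    }
                    for (a, b), n in sorted(report.edges.items())
                ]
            ),
            outdir / "edges.tsv",
        )
        summary["concatemers"] = {
            "counts": report.counts,
            "n_edges": len(report.edges),
            "n_flagged": sum(report.flagged_edges.values()),
        }

    if "annotate" in stages:
        if circles:
            circle_seqs = [(c.circle_id, c.sequence) for c in circles]
        else:
            circle_seqs = [
                (r.read_id, r.sequence) for r in read_sequences(paths["circles"])
            ]
        ann_cfg = dict(config.get("annotate") or {})
        try:
            result = segment_constant_cassette(circle_seqs, **ann_cfg)
        except Exception as exc:
            raise RuntimeError(f"annotate stage failed: {exc}") from exc
        write_annotation_gff(result, outdir / "annotation.gff3")
        write_fasta(
            [ReadRecord(c.circle_id, c.sequence) for c in result.circles],
            outdir / "circles_canonical.fasta",
        )
        write_tsv(
            pd.DataFrame(
                [{"circle_id": cid, "group": g} for cid, g in sorted(result.groups.items())]
            ),
            outdir / "groups.tsv",
        )
        summary["annotate"] = {
            "n_circles": len(result.circles),
            "n_groups": len(set(result.groups.values())),
            "flags": result.flags,
        }

    if "quant" in stages:
        standards = pd.read_csv(paths["qpcr_standards"], sep="\t")
        targets = pd.read_csv(paths["qpcr_targets"], sep="\t")
        curves = {}
        for gene, grp in standards.groupby("gene"):
            curves[gene] = fit_standard_curve(
                list(zip(grp["log10_copies"], grp["cq"])), gene=gene
            )
        measurements = [
            QPCRMeasurement(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                cq=float(row.cq),
                replicate=int(getattr(row, "replicate", 1)),
            )
            for row in targets.itertuples()
        ]
        reference = str(config.get("quant", {}).get("nuclear_reference", "sdhB"))
        result = copy_ratio(measurements, curves, reference)
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "gene": c.gene,
                        "slope": c.slope,
                        "intercept": c.intercept,
                        "r_squared": c.r_squared,
                        "efficiency": c.efficiency,
                    }
                    for c in curves.values()
                ]
            ),
            outdir / "curves.tsv",
        )
        write_tsv(result.per_gene, outdir / "ratios.tsv")
        summary["quant"] = {
            "mean_ratio": result.mean_ratio,
            "sd_ratio": result.sd_ratio,
            "summary": result.summary(),
        }

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config, list(paths.values())),
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
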