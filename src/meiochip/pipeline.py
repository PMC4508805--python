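"""End-to-end orchestration: simulate -> classify -> profile -> stats.

A run is driven by a YAML config that round-trips through
:class:`RunConfig`; unknown keys are rejected (with a suggestion), every
defaulted parameter is logged so a run is auditable, and a single master
seed fans out to per-module streams by stable hashing of stream names.
Outputs are plain TSV/JSON; the manifest lists every file with a content
digest so two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import profiles as prof
from .expression import (
    CLASS_LABELS,
    ClassParams,
    ClassificationResult,
    ExpressionTable,
    class_summary,
    classify_genes,
    read_expression_tsv,
    write_expression_tsv,
)
from .io_formats import (
    GeneAnnotation,
    TagCollection,
    read_annotation,
    read_tags,
    write_annotation,
    write_tags,
)
from .region_stats import (
    chisq_enrichment,
    parse_region_spec,
    region_counts,
    wilcoxon_rank_sum,
)
from .synthetic import (
    SyntheticSpec,
    make_annotation,
    simulate_expression,
    simulate_tags,
)

__all__ = ["RunConfig", "TagSetConfig", "InputPaths", "KOComparison",
           "validate_config", "run_all"]

logger = logging.getLogger("meiochip")


@dataclass
class TagSetConfig:
    mark: str
    stage: str
    path: str | None = None  # only used with explicit input paths


@dataclass
class InputPaths:
    annotation: str
    expression: str
    x_chrom_name: str = "chrX"


@dataclass
class KOComparison:
    """Wild-type vs knockout region comparison on planted escape genes."""

    mark: str = "H3K4me2"
    stage: str = "RS"
    region: str = "body:-1000"


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "meiochip_out"
    log_level: str = "INFO"
    synthetic: SyntheticSpec | None = None
    inputs: InputPaths | None = None
    tag_sets: list[TagSetConfig] = field(
        default_factory=lambda: [
            TagSetConfig("H3K4me3", "GS"),
            TagSetConfig("H3K4me3", "RS"),
            TagSetConfig("H3K4me2", "RS"),
        ]
    )
    class_params: ClassParams = field(default_factory=ClassParams)
    profile_params: prof.ProfileParams = field(default_factory=prof.ProfileParams)
    enrichment_class: str = "RS active"
    ko_comparison: KOComparison | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            self.synthetic = SyntheticSpec()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_NESTED = {
    "synthetic": SyntheticSpec,
    "inputs": InputPaths,
    "class_params": ClassParams,
    "profile_params": prof.ProfileParams,
    "ko_comparison": KOComparison,
}


def _build(cls, data: Mapping[str, Any], ctx: str):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in names:
            hint = difflib.get_close_matches(key, names, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {ctx}{key!r}{suggestion}")
        kwargs[key] = val
    return cls(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    data = dict(data or {})
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in top_names:
            hint = difflib.get_close_matches(key, top_names, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {key!r}{suggestion}")
    for key, cls in _NESTED.items():
        if data.get(key) is not None:
            data[key] = _build(cls, data[key], f"{key}.")
    if data.get("tag_sets") is not None:
        data["tag_sets"] = [
            _build(TagSetConfig, t, "tag_sets[].") for t in data["tag_sets"]
        ]
    return RunConfig(**data)


def validate_config(path: str) -> RunConfig:
    """Parse and validate a YAML run config, logging every default used."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    config = config_from_dict(raw)
    _log_parameters(config)
    return config


def _log_parameters(config: RunConfig) -> None:
    cp, pp = config.class_params, config.profile_params
    logger.info("classification: fold >= %g, adjusted p <= %g, min RPKM %g",
                cp.fold, cp.alpha_adj, cp.rpkm_min_any)
    logger.info("constitutive: active RPKM > %g (< %g-fold spread), inactive RPKM < %g",
                cp.const_active_min, cp.const_active_maxfold, cp.const_inactive_max)
    logger.info("expressed filter: RPKM > %g in at least one stage", cp.expressed_min)
    logger.info("profiles: %d bp windows, +/- %d bp span, %d bp step",
                pp.window, pp.span, pp.step)
    logger.info("metagene: %d body bins, %d flank bins", pp.body_bins, pp.flank_bins)
    if config.ko_comparison is not None:
        logger.info("WT/KO region: %s (%s %s)", config.ko_comparison.region,
                    config.ko_comparison.mark, config.ko_comparison.stage)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _gene_sets(
    classification: ClassificationResult, annotation: Sequence[GeneAnnotation]
) -> dict[str, list[str]]:
    """ATD stratifications: every non-empty class, all autosomal, all X."""
    sets: dict[str, list[str]] = {}
    for label in CLASS_LABELS:
        ids = classification.genes_in_class(label)
        if ids:
            sets[label] = ids
    sets["all_autosomal"] = [g.gene_id for g in annotation if not g.is_x]
    sets["all_X"] = [g.gene_id for g in annotation if g.is_x]
    return {k: v for k, v in sets.items() if v}


def run_all(config: RunConfig, output_dir: str | None = None) -> dict:
    """Execute the full pipeline; returns the output manifest.

    Stages: data (synthetic or from paths) -> classification -> X
    enrichment -> per mark x stage fragment-length estimation, tag
    shifting, smoothed ATDs per gene set, heatmap matrix, metagene ATDs
    -> optional WT/KO region Wilcoxon on planted escape genes.
    Any stage failure aborts with the stage name; files written so far
    are listed in the partial manifest attached to the error.
    """
    outdir = output_dir or config.output_dir
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    stage_name = "setup"

    def emit(rel: str) -> str:
        path = os.path.join(outdir, rel)
        written.append(rel)
        return path

    try:
        # ---------------- data ----------------
        stage_name = "data"
        spec = config.synthetic
        if spec is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
            annotation = make_annotation(spec)
            table, truth = simulate_expression(spec, annotation)
            write_annotation(annotation, emit("annotation.bed"))
            write_expression_tsv(table, emit("expression.tsv"))
            truth.rename_axis("gene_id").to_csv(emit("truth.tsv"), sep="\t")
            tags: dict[tuple[str, str], TagCollection] = {}
            for ts in config.tag_sets:
                tc = simulate_tags(spec, annotation, truth, ts.mark, ts.stage)
                tags[(ts.mark, ts.stage)] = tc
                write_tags(tc, emit(f"tags_{ts.mark}_{ts.stage}.bed"))
        else:
            annotation = read_annotation(
                config.inputs.annotation, x_chrom_name=config.inputs.x_chrom_name
            )
            table = read_expression_tsv(config.inputs.expression)
            truth = None
            tags = {}
            for ts in config.tag_sets:
                if ts.path is None:
                    raise ValueError(
                        f"tag set {ts.mark}/{ts.stage} needs a path when no "
                        "synthetic spec is given"
                    )
                tags[(ts.mark, ts.stage)] = read_tags(ts.path, ts.mark, ts.stage)

        # ---------------- classification ----------------
        stage_name = "classification"
        classification = classify_genes(table, annotation, config.class_params)
        cls_out = classification.table.copy()
        cls_out["all_classes"] = cls_out["all_classes"].map(
            lambda cs: ";".join(cs) if cs else "-"
        )
        cls_out.rename_axis("gene_id").to_csv(
            emit("classification.tsv"), sep="\t", float_format="%.6g"
        )
        summary = class_summary(classification, annotation)
        summary.rename_axis("class").to_csv(emit("class_summary.tsv"), sep="\t")

        # ---------------- chromosome enrichment ----------------
        stage_name = "enrichment"
        enrichment = chisq_enrichment(
            classification, annotation, config.enrichment_class
        )
        with open(emit("enrichment.json"), "w") as fh:
            json.dump(
                {
                    "target_class": config.enrichment_class,
                    "table": enrichment.table.to_dict(),
                    "x_in_class": enrichment.x_in_class,
                    "x_total": enrichment.x_total,
                    "x_percent": enrichment.x_percent,
                    "statistic": enrichment.test.statistic,
                    "p_value": enrichment.test.p_value,
                },
                fh,
                indent=1,
            )

        # ---------------- chromatin profiles ----------------
        stage_name = "profiles"
        pp = config.profile_params
        gene_sets = _gene_sets(classification, annotation)
        fraglen_rows = []
        for (mark, stg), tc in tags.items():
            est = prof.estimate_fragment_length(tc)
            fraglen_rows.append(
                {"mark": mark, "stage": stg, "fragment_length": est.length,
                 "flat": est.flat}
            )
            shifted = prof.shift_tags(tc, est.length)

            fine = prof.tss_density_matrix(shifted, annotation, pp, bin_width=pp.step)
            atd = {"offset": fine.offsets + pp.step / 2}
            for name, ids in gene_sets.items():
                profile = prof.smooth_profile(
                    prof.average_profile(fine, ids), window_bp=pp.window
                )
                atd[name] = profile.values
            pd.DataFrame(atd).to_csv(
                emit(f"atd_{mark}_{stg}.tsv"), sep="\t", index=False,
                float_format="%.6g",
            )

            tiles = prof.tss_density_matrix(shifted, annotation, pp)
            ordered = prof.heatmap_matrix(tiles)
            ordered.to_frame().to_csv(
                emit(f"heatmap_{mark}_{stg}.tsv"), sep="\t", float_format="%.6g"
            )

            meta = prof.metagene_matrix(shifted, annotation, pp)
            meta_atd = {"bin": meta.offsets + 0.5}
            for name in ("all_autosomal", "all_X"):
                ids = [g for g in gene_sets.get(name, []) if g in set(meta.gene_ids)]
                if ids:
                    meta_atd[name] = prof.average_profile(meta, ids).values
            pd.DataFrame(meta_atd).to_csv(
                emit(f"metagene_{mark}_{stg}.tsv"), sep="\t", index=False,
                float_format="%.6g",
            )
        pd.DataFrame(fraglen_rows).to_csv(
            emit("fragment_lengths.tsv"), sep="\t", index=False
        )

        # ---------------- WT vs KO region comparison ----------------
        if config.ko_comparison is not None:
            stage_name = "ko_comparison"
            ko = config.ko_comparison
            if spec is None or truth is None:
                raise ValueError("ko_comparison requires the synthetic branch")
            escape = [
                g for g in annotation
                if g.is_x and truth[g.gene_id] == "RS active"
            ]
            if not escape:
                raise ValueError("no planted escape genes for ko_comparison")
            wt = tags.get((ko.mark, ko.stage))
            if wt is None:
                wt = simulate_tags(spec, annotation, truth, ko.mark, ko.stage)
            ko_spec = dataclasses.replace(spec, seed=spec.seed + 1)
            override = {g.gene_id: 1.0 for g in escape}
            ko_tags = simulate_tags(
                ko_spec, annotation, truth, ko.mark, ko.stage,
                enrichment_override=override,
            )
            region = parse_region_spec(ko.region)
            fl = spec.fragment_length
            wt_counts = region_counts(prof.shift_tags(wt, fl), escape, region)
            ko_counts = region_counts(prof.shift_tags(ko_tags, fl), escape, region)
            test = wilcoxon_rank_sum(wt_counts.to_numpy(), ko_counts.to_numpy())
            pd.DataFrame({"WT": wt_counts, "KO": ko_counts}).rename_axis(
                "gene_id"
            ).to_csv(emit("region_counts.tsv"), sep="\t")
            with open(emit("region_wilcoxon.json"), "w") as fh:
                json.dump(
                    {
                        "mark": ko.mark, "stage": ko.stage, "region": ko.region,
                        "n_genes": len(escape), "U": test.statistic,
                        "p_value": test.p_value, "stars": test.significance_stars,
                        "method": test.method,
                    },
                    fh,
                    indent=1,
                )

        # ---------------- manifest ----------------
        stage_name = "manifest"
        manifest = {
            "seed": config.seed,
            "files": {rel: _sha256(os.path.join(outdir, rel)) for rel in written},
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        partial = {rel: _sha256(os.path.join(outdir, rel)) for rel in written
                   if os.path.exists(os.path.join(outdir, rel))}
        err = RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}")
        err.partial_manifest = {"seed": config.seed, "files": partial}
        raise err from exc
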