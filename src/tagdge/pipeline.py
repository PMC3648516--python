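"""End-to-end orchestration: index -> clean -> common -> assign -> TPM -> DE -> enrichment.

The pipeline consumes per-species transcriptome FASTAs and raw tag-count
TSVs, and produces the ortholog table, one DEG table per pairwise species
comparison, enrichment tables (when an annotation map is supplied) and a
machine-readable summary mirroring the usual library-statistics and
up/down-tally reporting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import yaml

from . import __version__
from .diff_expression import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_LFC_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    call_degs,
    deg_summary,
    write_deg_table,
)
from .enrichment import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_TERM_SIZE,
    enrich,
    load_annotation_gmt,
    write_enrichment_table,
)
from .ortholog_mapping import (
    assign_orthologs,
    common_tags,
    gene_counts,
    write_ortholog_table,
    write_tag_set,
)
from .tag_library import clean_tags, load_tag_counts, write_tag_counts
from .tag_reference import build_tag_index_from_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, priority order and thresholds for one pipeline run."""

    species: list[str]
    fasta: dict[str, str]  # species -> transcriptome FASTA path
    tags: dict[str, str]  # species -> raw tag-count TSV path
    db_order: list[str] | None = None  # defaults to `species` order
    annotation: str | None = None  # GMT-like TSV path
    outdir: str = "tagdge_out"
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    min_term_size: int = DEFAULT_MIN_TERM_SIZE
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    joint_ambiguity: bool = False
    antisense: bool = False
    strict_load: bool = True
    # annotation maps are usually keyed by gene while the ortholog table
    # carries transcript ids; the id part before this delimiter is used as
    # the annotation key (set to null/None to disable stripping)
    gene_id_delimiter: str | None = "."
    seed: int = 0

    def __post_init__(self):
        if self.db_order is None:
            self.db_order = list(self.species)
        if sorted(self.db_order) != sorted(self.species):
            raise ValueError("db_order must be a permutation of species")
        for thr in (self.fdr_threshold, self.lfc_threshold, self.alpha):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        missing = [s for s in self.species if s not in self.fasta or s not in self.tags]
        if missing:
            raise ValueError(f"species without input paths: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    ortholog_table: object
    libraries: dict
    deg_tables: dict[tuple[str, str], list]
    enrichment_tables: dict[tuple[str, str], list]
    summary: dict
    output_files: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Run every stage on the configured inputs.

    Stage failures propagate as exceptions prefixed with the stage name.
    """
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    header = f"tagdge {__version__} config={cfg.config_hash()} seed={cfg.seed}"
    summary: dict = {"libraries": {}, "comparisons": {}}
    outputs: dict[str, Path] = {}

    stage = "build-index"
    try:
        _stage(stage)
        indexes = {
            s: build_tag_index_from_fasta(cfg.fasta[s], s, antisense=cfg.antisense)
            for s in cfg.species
        }

        stage = "clean"
        _stage(stage)
        raw_libs = {
            s: load_tag_counts(cfg.tags[s], s, strict=cfg.strict_load)
            for s in cfg.species
        }
        libs = {s: clean_tags(raw_libs[s]) for s in cfg.species}
        for s in cfg.species:
            summary["libraries"][s] = {
                "raw_total": raw_libs[s].total,
                "raw_distinct": raw_libs[s].distinct,
                "clean_total": libs[s].total,
                "clean_distinct": libs[s].distinct,
            }

        stage = "common-tags"
        _stage(stage)
        common = common_tags([libs[s] for s in cfg.species])
        for s in cfg.species:
            summary["libraries"][s]["common_total"] = sum(
                libs[s].counts[t] for t in common
            )
            summary["libraries"][s]["common_distinct"] = len(common)

        stage = "map-orthologs"
        _stage(stage)
        table = assign_orthologs(
            common,
            [indexes[s] for s in cfg.db_order],
            joint_ambiguity=cfg.joint_ambiguity,
        )
        table = gene_counts(table, libs)
        summary["orthologs"] = {
            "n_genes": table.n_genes,
            "n_ambiguous_tags": len(table.ambiguous_tags),
            "n_unmatched_tags": len(table.unmatched_tags),
            "n_common_tags": len(common),
        }
        if write_outputs:
            path = outdir / "ortholog_table.tsv"
            write_ortholog_table(table, path, header=header)
            outputs["ortholog_table"] = path
            for name, tags in (
                ("ambiguous_tags", table.ambiguous_tags),
                ("unmatched_tags", table.unmatched_tags),
            ):
                p = outdir / f"{name}.txt"
                write_tag_set(tags, p)
                outputs[name] = p

        stage = "de-test"
        _stage(stage)
        annotation = (
            load_annotation_gmt(cfg.annotation) if cfg.annotation else None
        )
        deg_tables = {}
        enrichment_tables = {}

        def canonical(gene_id: str) -> str:
            if cfg.gene_id_delimiter:
                return gene_id.split(cfg.gene_id_delimiter, 1)[0]
            return gene_id

        universe = {canonical(g.gene_id) for g in table.genes}
        for a, b in combinations(cfg.species, 2):
            records = call_degs(
                table,
                libs,
                (a, b),
                fdr_threshold=cfg.fdr_threshold,
                lfc_threshold=cfg.lfc_threshold,
                pseudocount=cfg.pseudocount,
            )
            deg_tables[(a, b)] = records
            tally = deg_summary(records)
            summary["comparisons"][f"{a}_vs_{b}"] = tally
            if write_outputs:
                p = outdir / f"degs_{a}_vs_{b}.tsv"
                write_deg_table(records, p, header=header)
                outputs[f"degs_{a}_vs_{b}"] = p

            if annotation is not None:
                deg_genes = {
                    canonical(r.gene_id) for r in records if r.status != "ns"
                }
                enr = enrich(
                    deg_genes & universe,
                    annotation,
                    universe,
                    min_term_size=cfg.min_term_size,
                    alpha=cfg.alpha,
                )
                enrichment_tables[(a, b)] = enr
                summary["comparisons"][f"{a}_vs_{b}"]["n_enriched_terms"] = sum(
                    1 for r in enr if r.enriched
                )
                if write_outputs:
                    p = outdir / f"enrichment_{a}_vs_{b}.tsv"
                    write_enrichment_table(enr, p, header=header)
                    outputs[f"enrichment_{a}_vs_{b}"] = p
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if write_outputs:
        p = outdir / "summary.json"
        with open(p, "w") as fh:
            json.dump(
                {"tool": f"tagdge {__version__}", "config_hash": cfg.config_hash(),
                 "seed": cfg.seed, **summary},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        outputs["summary"] = p

    return PipelineResult(
        config=cfg,
        ortholog_table=table,
        libraries=libs,
        deg_tables=deg_tables,
        enrichment_tables=enrichment_tables,
        summary=summary,
        output_files=outputs,
    )
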