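"""End-to-end orchestration: simulate/load -> clean -> map -> quantify ->
differential expression -> enrichment -> JSON report.

A run is driven by one declarative :class:`RunConfig` (loadable from
YAML).  Inputs are either a synthetic block — in which case reference,
reads, truth and annotations are generated in-process — or paths to a
reference FASTA, per-library read files (FASTQ or one-read-per-line
text) or precomputed tag-count TSVs, and an annotation TSV.  Every
intermediate table is written to the output directory, and the final
``report.json`` contains every number the text tables do, so identical
(config, seed) pairs produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from tagdge import de as de_mod
from tagdge import synthetic as synth
from tagdge.enrichment import AnnotationTable, enrich, ontology_histogram
from tagdge.index import build_index, genome_mapping_stats, map_tags
from tagdge.quantify import library_summary, quantify
from tagdge.tags import (
    DEFAULT_ADAPTORS,
    FilterStats,
    TagCountTable,
    clean_tags,
    copy_number_distribution,
)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """One pipeline run: inputs, thresholds, comparisons, output, seed."""

    synthetic: synth.SyntheticConfig | None = None
    reference_fasta: str | None = None
    reads: dict[str, str] = field(default_factory=dict)  # library -> path
    tag_tables: dict[str, str] = field(default_factory=dict)  # library -> TSV
    annotation_tsv: str | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)  # (control, treated)
    fdr_threshold: float = 0.001
    log2_threshold: float = 1.0
    enrichment_alpha: float = 0.05
    fold_change_boundary: float = 5.0
    index_mode: str = "all_sites"
    strand_policy: str = "sense_only"
    adaptor_sequences: tuple[str, ...] = DEFAULT_ADAPTORS
    compute_genome_stats: bool = True
    output_dir: str = "tagdge_out"
    seed: int | None = None

    def __post_init__(self):
        problems = self.validate()
        if problems:
            raise ValueError("invalid run configuration:\n- " + "\n- ".join(problems))

    def validate(self) -> list[str]:
        problems = []
        if self.synthetic is None:
            if self.reference_fasta is None:
                problems.append("no reference: supply reference_fasta or a synthetic block")
            if not self.reads and not self.tag_tables:
                problems.append("no libraries: supply reads, tag_tables or a synthetic block")
            for name, path in {**self.reads, **self.tag_tables}.items():
                if not Path(path).exists():
                    problems.append(f"library {name!r}: missing file {path}")
            if self.reference_fasta and not Path(self.reference_fasta).exists():
                problems.append(f"missing reference FASTA {self.reference_fasta}")
            if self.annotation_tsv and not Path(self.annotation_tsv).exists():
                problems.append(f"missing annotation TSV {self.annotation_tsv}")
        libs = self.library_names()
        for ctrl, trt in self.comparisons:
            for lib in (ctrl, trt):
                if libs and lib not in libs:
                    problems.append(f"comparison names unknown library {lib!r}")
        for name, value in (
            ("fdr_threshold", self.fdr_threshold),
            ("log2_threshold", self.log2_threshold),
            ("enrichment_alpha", self.enrichment_alpha),
        ):
            if value <= 0:
                problems.append(f"{name} must be positive")
        return problems

    def library_names(self) -> list[str]:
        if self.synthetic is not None:
            return [f"L{i}" for i in range(self.synthetic.n_libraries)]
        return sorted({*self.reads, *self.tag_tables})

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            block = dict(raw["synthetic"])
            for key in ("transcript_length_range", "baseline_mean_log10_range",
                        "genes_per_term_range", "de_fold_changes", "adaptor_sequences"):
                if key in block and isinstance(block[key], list):
                    block[key] = tuple(block[key])
            raw["synthetic"] = synth.SyntheticConfig(**block)
        if "comparisons" in raw:
            raw["comparisons"] = [tuple(c) for c in raw["comparisons"]]
        if "adaptor_sequences" in raw and isinstance(raw["adaptor_sequences"], list):
            raw["adaptor_sequences"] = tuple(raw["adaptor_sequences"])
        return cls(**raw)

    def echo(self) -> dict:
        d: dict[str, Any] = {
            k: getattr(self, k)
            for k in (
                "reference_fasta", "reads", "tag_tables", "annotation_tsv",
                "comparisons", "fdr_threshold", "log2_threshold",
                "enrichment_alpha", "fold_change_boundary", "index_mode",
                "strand_policy", "compute_genome_stats", "output_dir", "seed",
            )
        }
        d["comparisons"] = [list(c) for c in self.comparisons]
        d["adaptor_sequences"] = list(self.adaptor_sequences)
        if self.synthetic is not None:
            s = {k: getattr(self.synthetic, k) for k in self.synthetic.__dataclass_fields__}
            for k, v in s.items():
                if isinstance(v, tuple):
                    s[k] = list(v)
            d["synthetic"] = s
        return d


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return the machine-readable report.

    Also writes, under ``config.output_dir``: the effective config, per-
    library clean tag tables, filter stats, mapping reports, expression
    tables and summaries, per-comparison DEG tables, enrichment tables,
    and ``report.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.echo(), "libraries": {}, "comparisons": {}}

    synthetic = config.synthetic
    if synthetic is not None and config.seed is not None:
        # CLI/seed override wins over the seed embedded in the block
        if synthetic.seed != config.seed:
            synthetic = synth.SyntheticConfig(
                **{**{k: getattr(synthetic, k) for k in synthetic.__dataclass_fields__},
                   "seed": config.seed}
            )

    # ---- reference and annotation ------------------------------------
    truth = None
    if synthetic is not None:
        reference = synth.generate_reference(synthetic)
        synth.write_reference_fasta(reference, out / "reference.fasta")
        annotation = synth.generate_annotation(synthetic, [g for g, _ in reference])
        annotation.to_tsv(out / "annotation.tsv")
    else:
        reference = synth.read_reference_fasta(config.reference_fasta)
        annotation = (
            AnnotationTable.from_tsv(config.annotation_tsv)
            if config.annotation_tsv
            else None
        )
    index = build_index(reference, mode=config.index_mode, strand_policy=config.strand_policy)
    index.to_tsv(out / "virtual_tag_index.tsv")
    gene_ids = index.gene_ids
    report["reference"] = {
        "n_genes": len(gene_ids),
        "n_virtual_tags": len(index),
        "n_untaggable_genes": len(index.untaggable_genes),
    }
    if synthetic is not None:
        truth = synth.generate_truth(synthetic, reference, index=index)
        truth.to_tsv(out / "truth.tsv")
        report["truth"] = {
            "n_de_genes": len(truth.de_gene_ids),
            "n_unmappable_genes": len(truth.unmappable_gene_ids),
        }

    # ---- per-library processing --------------------------------------
    expressions: dict[str, Any] = {}
    for lib_index, lib in enumerate(config.library_names()):
        if synthetic is not None:
            reads, true_counts = synth.simulate_tag_reads(
                reference, truth, synthetic, lib_index
            )
            synth.write_reads_text(reads, out / f"{lib}.reads.txt")
            clean, stats = clean_tags(reads, config.adaptor_sequences)
        elif lib in config.reads:
            reads = synth.read_reads(config.reads[lib])
            clean, stats = clean_tags(reads, config.adaptor_sequences)
        else:
            # precomputed table: already clean, so raw == clean in the stats
            clean = TagCountTable.from_tsv(config.tag_tables[lib])
            stats = FilterStats(
                raw_total=clean.total_tags,
                raw_distinct=clean.distinct_tags,
                clean_total=clean.total_tags,
                clean_distinct=clean.distinct_tags,
            )
        clean.to_tsv(out / f"{lib}.clean_tags.tsv")
        stats.to_json(out / f"{lib}.filter_stats.json")

        mapping = map_tags(clean, index)
        mapping.to_tsv(out / f"{lib}.mapping.tsv")
        expr = quantify(mapping, clean, gene_ids)
        expr.to_tsv(out / f"{lib}.expression.tsv")
        expressions[lib] = expr

        genome = (
            genome_mapping_stats(clean, [s for _, s in reference])
            if config.compute_genome_stats
            else None
        )
        summary = library_summary(stats, mapping, expr, genome_stats=genome, library_id=lib)
        summary.to_tsv(out / f"{lib}.summary.tsv")
        report["libraries"][lib] = {
            "filter_stats": stats.to_dict(),
            "summary": summary.to_dict(),
            "copy_number_distribution": copy_number_distribution(clean),
        }

    # ---- comparisons -------------------------------------------------
    comparisons = config.comparisons
    if not comparisons:
        libs = config.library_names()
        comparisons = [(libs[0], t) for t in libs[1:]]
    deg_sets: dict[str, set[str]] = {}
    for ctrl, trt in comparisons:
        name = f"{trt}_vs_{ctrl}"
        records = de_mod.call_degs(
            expressions[ctrl],
            expressions[trt],
            fdr_threshold=config.fdr_threshold,
            log2_threshold=config.log2_threshold,
        )
        records.to_csv(out / f"{name}.deg.tsv", sep="\t", index=False)
        degs = set(records.loc[records["status"] != "not_significant", "gene_id"])
        deg_sets[name] = degs
        block: dict[str, Any] = {
            "summary": de_mod.comparison_summary(records),
            "fold_change_bins": de_mod.fold_change_distribution(
                records, boundary=config.fold_change_boundary
            ),
        }
        if annotation is not None and degs:
            table = enrich(degs, annotation, alpha=config.enrichment_alpha)
            table.to_csv(out / f"{name}.enrichment.tsv", sep="\t", index=False)
            block["enrichment"] = ontology_histogram(table, annotation, degs)
        report["comparisons"][name] = block

    names = sorted(deg_sets)
    report["overlaps"] = {
        f"{a}&{b}": dict(
            zip(("a_only", "b_only", "overlap"),
                de_mod.compare_deg_sets(deg_sets[a], deg_sets[b]))
        )
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }

    with open(out / "effective_config.json", "w") as fh:
        json.dump(report["config"], fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
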