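"""Per-gene quantification and Table-1-style library summaries.

Only unambiguous tags contribute to gene expression.  Counts are
normalized to TPM = tags per million clean tags; because the tag length is
fixed there is no gene-length correction, so this TPM is a tag frequency,
not the length-corrected transcript-per-million of full-read RNA-seq.
The TPM denominator is the library's total clean tags (not its mapped
tags), so the TPMs of one library sum to less than 10^6 whenever some
clean tags do not map unambiguously; this is recorded in the table's
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from tagdge.index import MappingResult
from tagdge.tags import FilterStats, TagCountTable

__all__ = ["GeneExpressionTable", "LibrarySummary", "quantify", "library_summary"]


@dataclass
class GeneExpressionTable:
    """Per-gene unambiguous tag counts and TPM for one library."""

    table: pd.DataFrame  # index gene_id; columns raw_count, tpm
    library_clean_total: int
    reference_gene_count: int
    metadata: dict = field(default_factory=dict)

    @property
    def tag_mapped_gene_count(self) -> int:
        return int((self.table["raw_count"] > 0).sum())

    @property
    def pct_of_ref_genes(self) -> float:
        if self.reference_gene_count == 0:
            return 0.0
        return 100.0 * self.tag_mapped_gene_count / self.reference_gene_count

    def raw_counts(self) -> pd.Series:
        return self.table["raw_count"]

    def tpm(self) -> pd.Series:
        return self.table["tpm"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def quantify(
    mapping: MappingResult,
    clean: TagCountTable,
    reference_genes: Sequence[str],
) -> GeneExpressionTable:
    """Aggregate unambiguous tag counts per gene and normalize to TPM.

    Every reference gene is present in the output, with count 0 if no
    unambiguous tag mapped to it.  A tag that is unambiguous via several
    sites of one gene contributes its full copy number once.

    Raises
    ------
    ValueError
        If the library has no clean tags (TPM undefined).
    """
    clean_total = clean.total_tags
    if clean_total == 0:
        raise ValueError("empty library: clean total is 0, TPM undefined")
    counts = mapping.unambiguous_counts()
    genes = list(reference_genes)
    known = set(genes)
    stray = set(counts) - known
    if stray:
        raise ValueError(f"mapped genes absent from reference list: {sorted(stray)[:5]}")
    raw = pd.Series({g: counts.get(g, 0) for g in genes}, dtype=int, name="raw_count")
    tpm = 1e6 * raw / clean_total
    table = pd.DataFrame({"raw_count": raw, "tpm": tpm})
    table.index.name = "gene_id"
    return GeneExpressionTable(
        table=table,
        library_clean_total=clean_total,
        reference_gene_count=len(genes),
        metadata={"tpm_denominator": "total clean tags"},
    )


def _pct(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


@dataclass
class LibrarySummary:
    """One library's categorization statistics (the Table-1 replica).

    Constructible either from pipeline objects via :func:`library_summary`
    or directly from counts, in which case the percentage fields recompute
    the table's arithmetic from its printed integers.
    """

    library_id: str = ""
    raw_total: int = 0
    raw_distinct: int = 0
    clean_total: int = 0
    clean_distinct: int = 0
    all_mapped_total: int = 0
    all_mapped_distinct: int = 0
    unambiguous_total: int = 0
    unambiguous_distinct: int = 0
    genome_mapped_total: int = 0
    genome_mapped_distinct: int = 0
    unknown_total: int = 0
    unknown_distinct: int = 0
    all_tag_mapped_genes: int = 0
    unambiguous_tag_mapped_genes: int = 0
    reference_gene_count: int = 0

    # -- percentage arithmetic ------------------------------------------
    @property
    def clean_pct_of_raw(self) -> float:
        return _pct(self.clean_total, self.raw_total)

    @property
    def distinct_clean_pct_of_raw_distinct(self) -> float:
        return _pct(self.clean_distinct, self.raw_distinct)

    @property
    def all_mapped_total_pct(self) -> float:
        return _pct(self.all_mapped_total, self.clean_total)

    @property
    def all_mapped_distinct_pct(self) -> float:
        return _pct(self.all_mapped_distinct, self.clean_distinct)

    @property
    def unambiguous_total_pct(self) -> float:
        return _pct(self.unambiguous_total, self.clean_total)

    @property
    def unambiguous_distinct_pct(self) -> float:
        return _pct(self.unambiguous_distinct, self.clean_distinct)

    @property
    def genome_mapped_total_pct(self) -> float:
        return _pct(self.genome_mapped_total, self.clean_total)

    @property
    def genome_mapped_distinct_pct(self) -> float:
        return _pct(self.genome_mapped_distinct, self.clean_distinct)

    @property
    def unknown_total_pct(self) -> float:
        return _pct(self.unknown_total, self.clean_total)

    @property
    def unknown_distinct_pct(self) -> float:
        return _pct(self.unknown_distinct, self.clean_distinct)

    @property
    def all_genes_pct_of_ref(self) -> float:
        return _pct(self.all_tag_mapped_genes, self.reference_gene_count)

    @property
    def unambiguous_genes_pct_of_ref(self) -> float:
        return _pct(self.unambiguous_tag_mapped_genes, self.reference_gene_count)

    def to_dict(self) -> dict:
        """All counts plus percentages rounded to 2 decimals."""
        d = {f.name: getattr(self, f.name) for f in self.__dataclass_fields__.values()}
        for name in (
            "clean_pct_of_raw",
            "distinct_clean_pct_of_raw_distinct",
            "all_mapped_total_pct",
            "all_mapped_distinct_pct",
            "unambiguous_total_pct",
            "unambiguous_distinct_pct",
            "genome_mapped_total_pct",
            "genome_mapped_distinct_pct",
            "unknown_total_pct",
            "unknown_distinct_pct",
            "all_genes_pct_of_ref",
            "unambiguous_genes_pct_of_ref",
        ):
            d[name] = round(getattr(self, name), 2)
        return d

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("field\tvalue\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v}\n")


def library_summary(
    filter_stats: FilterStats,
    mapping: MappingResult,
    expression: GeneExpressionTable,
    genome_stats: tuple[float, float] | None = None,
    library_id: str = "",
) -> LibrarySummary:
    """Assemble the per-library statistics table from pipeline stages.

    ``genome_stats`` are the (total_pct, distinct_pct) from
    :func:`tagdge.index.genome_mapping_stats`; counts are back-computed
    from the percentages when supplied.  A zero-read library yields all
    zero percentages.
    """
    s = LibrarySummary(
        library_id=library_id,
        raw_total=filter_stats.raw_total,
        raw_distinct=filter_stats.raw_distinct,
        clean_total=filter_stats.clean_total,
        clean_distinct=filter_stats.clean_distinct,
        all_mapped_total=mapping.all_mapped_total,
        all_mapped_distinct=mapping.all_mapped_distinct,
        unambiguous_total=mapping.unambiguous_total,
        unambiguous_distinct=mapping.unambiguous_distinct,
        unknown_total=mapping.unknown_total,
        unknown_distinct=mapping.unknown_distinct,
        all_tag_mapped_genes=mapping.all_mapped_gene_count,
        unambiguous_tag_mapped_genes=mapping.unambiguous_gene_count,
        reference_gene_count=expression.reference_gene_count,
    )
    if genome_stats is not None:
        total_pct, distinct_pct = genome_stats
        s.genome_mapped_total = round(total_pct * s.clean_total / 100.0)
        s.genome_mapped_distinct = round(distinct_pct * s.clean_distinct / 100.0)
    return s
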