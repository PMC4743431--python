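"""Virtual tag library construction and clean-tag mapping.

Every NlaIII site (CATG) on a transcript with at least 17 nt downstream
defines one *virtual tag*: the 21-mer CATG+17 nt that the library prep
would produce from a cleavage at that site.  The index of all virtual tags
is the mapping target; a clean tag is looked up exactly first and, failing
that, through its 63 Hamming-distance-1 neighbors.  A tag whose hits all
fall in one gene is *unambiguous*, one hitting several genes is
*ambiguous*, and one hitting nothing is *unknown*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

ANCHOR = "CATG"
TAG_LEN = 21
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "TagSite",
    "VirtualTagIndex",
    "MappingResult",
    "build_index",
    "map_tags",
    "genome_mapping_stats",
    "hamming1_neighbors",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming1_neighbors(tag: str) -> list[str]:
    """All 63 sequences at Hamming distance exactly 1 from a 21-mer."""
    out = []
    for i, base in enumerate(tag):
        for b in _BASES:
            if b != base:
                out.append(tag[:i] + b + tag[i + 1:])
    return out


@dataclass(frozen=True)
class TagSite:
    """One CATG+17nt site: gene, 0-based offset of the CATG anchor on the
    (sense-strand) transcript, and site rank where 0 is the 3'-most site."""

    gene_id: str
    position: int
    rank: int


@dataclass
class VirtualTagIndex:
    """Map from 21-mer virtual tag to the set of sites producing it."""

    tag_to_sites: dict[str, set[TagSite]] = field(default_factory=dict)
    mode: str = "all_sites"
    strand_policy: str = "sense_only"
    untaggable_genes: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def genes_for(self, tag: str) -> set[str]:
        return {s.gene_id for s in self.tag_to_sites.get(tag, ())}

    def __contains__(self, tag: str) -> bool:
        return tag in self.tag_to_sites

    def __len__(self) -> int:
        return len(self.tag_to_sites)

    def tags_of_gene(self, gene_id: str) -> list[str]:
        """Virtual tags of one gene, ordered by rank (3'-most first)."""
        hits = [
            (s.rank, tag)
            for tag, sites in self.tag_to_sites.items()
            for s in sites
            if s.gene_id == gene_id
        ]
        return [t for _, t in sorted(hits)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#"
                + json.dumps({"mode": self.mode, "strand_policy": self.strand_policy})
                + "\n"
            )
            fh.write("tag\tgene_id\tposition\trank\n")
            for tag in sorted(self.tag_to_sites):
                for s in sorted(self.tag_to_sites[tag], key=lambda s: (s.gene_id, s.position)):
                    fh.write(f"{tag}\t{s.gene_id}\t{s.position}\t{s.rank}\n")


def _sense_sites(seq: str) -> list[tuple[int, str]]:
    """(anchor position, 21-mer) for each eligible CATG site, 5'->3' order.

    Sites whose 17-nt window contains N are skipped.
    """
    sites = []
    start = 0
    while True:
        pos = seq.find(ANCHOR, start)
        if pos == -1:
            break
        window = seq[pos: pos + TAG_LEN]
        if len(window) == TAG_LEN and "N" not in window:
            sites.append((pos, window))
        start = pos + 1
    return sites


def build_index(
    reference: Iterable[tuple[str, str]] | Mapping[str, str],
    mode: str = "all_sites",
    strand_policy: str = "sense_only",
) -> VirtualTagIndex:
    """Extract every virtual tag from a reference sequence set.

    Parameters
    ----------
    reference
        ``(gene_id, sequence)`` pairs or a mapping; sequences over
        A/C/G/T/N, uppercased internally.
    mode
        ``all_sites`` indexes every eligible CATG site; ``three_prime_most``
        keeps only the site closest to the 3' end of each strand
        (rank 0), mirroring the MmeI chemistry's preference.
    strand_policy
        ``sense_only`` or ``both_strands`` (tags are also extracted from
        the reverse complement; positions refer to the sense strand
        coordinate of the anchor on the antisense read-through).
    """
    if mode not in ("all_sites", "three_prime_most"):
        raise ValueError(f"unknown mode {mode!r}")
    if strand_policy not in ("sense_only", "both_strands"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")

    items = reference.items() if isinstance(reference, Mapping) else list(reference)
    index = VirtualTagIndex(mode=mode, strand_policy=strand_policy)
    seen: set[str] = set()
    for gene_id, seq in items:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        index.gene_ids.append(gene_id)
        seq = seq.upper()
        strands = [seq]
        if strand_policy == "both_strands":
            strands.append(reverse_complement(seq))
        any_site = False
        for strand_seq in strands:
            sites = _sense_sites(strand_seq)
            if not sites:
                continue
            any_site = True
            # rank 0 = 3'-most = last hit in 5'->3' scan order
            nsites = len(sites)
            for i, (pos, tag) in enumerate(sites):
                rank = nsites - 1 - i
                if mode == "three_prime_most" and rank != 0:
                    continue
                index.tag_to_sites.setdefault(tag, set()).add(
                    TagSite(gene_id, pos, rank)
                )
        if not any_site:
            index.untaggable_genes.append(gene_id)
    return index


@dataclass
class MappingResult:
    """Per-tag classification plus Table-1-style summary counters.

    ``per_tag`` columns: tag, count, class (unambiguous/ambiguous/unknown),
    gene_id (empty unless unambiguous), matched_via (exact/one_mismatch/none).
    """

    per_tag: pd.DataFrame
    all_mapped_total: int
    all_mapped_distinct: int
    unambiguous_total: int
    unambiguous_distinct: int
    ambiguous_total: int
    ambiguous_distinct: int
    unknown_total: int
    unknown_distinct: int
    clean_total: int
    clean_distinct: int
    all_mapped_gene_count: int
    unambiguous_gene_count: int

    def unambiguous_counts(self) -> dict[str, int]:
        """Per-gene summed copy numbers of unambiguously mapped tags."""
        sub = self.per_tag[self.per_tag["class"] == "unambiguous"]
        return sub.groupby("gene_id")["count"].sum().astype(int).to_dict()

    def to_tsv(self, path) -> None:
        self.per_tag.to_csv(path, sep="\t", index=False)


def map_tags(
    clean: "TagCountTable",
    index: VirtualTagIndex,
    max_mismatch: int = 1,
) -> MappingResult:
    """Classify every clean tag against the virtual tag index.

    An exact hit takes priority: if the tag is itself an index key, its
    gene set is that key's genes and the 1-mismatch neighborhood is not
    consulted.  Otherwise the gene sets of all Hamming-distance-1 neighbor
    keys are unioned.  Ambiguity is decided at the gene level, so a tag
    hitting two sites of the same gene is unambiguous.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")

    rows = []
    counters = {
        "unambiguous": [0, 0],
        "ambiguous": [0, 0],
        "unknown": [0, 0],
    }
    all_genes: set[str] = set()
    unambig_genes: set[str] = set()
    for tag, count in clean.items():
        if len(tag) != TAG_LEN:
            raise ValueError(
                f"clean tag {tag!r} has length {len(tag)}, expected {TAG_LEN}"
            )
        if tag in index:
            genes = index.genes_for(tag)
            via = "exact"
        elif max_mismatch == 1:
            genes = set()
            for nb in hamming1_neighbors(tag):
                genes |= index.genes_for(nb)
            via = "one_mismatch" if genes else "none"
        else:
            genes, via = set(), "none"
        if len(genes) == 1:
            cls, gene_id = "unambiguous", next(iter(genes))
            unambig_genes.add(gene_id)
        elif len(genes) > 1:
            cls, gene_id = "ambiguous", ""
        else:
            cls, gene_id = "unknown", ""
        all_genes |= genes
        counters[cls][0] += count
        counters[cls][1] += 1
        rows.append((tag, count, cls, gene_id, via))

    per_tag = pd.DataFrame(
        rows, columns=["tag", "count", "class", "gene_id", "matched_via"]
    )
    result = MappingResult(
        per_tag=per_tag,
        all_mapped_total=counters["unambiguous"][0] + counters["ambiguous"][0],
        all_mapped_distinct=counters["unambiguous"][1] + counters["ambiguous"][1],
        unambiguous_total=counters["unambiguous"][0],
        unambiguous_distinct=counters["unambiguous"][1],
        ambiguous_total=counters["ambiguous"][0],
        ambiguous_distinct=counters["ambiguous"][1],
        unknown_total=counters["unknown"][0],
        unknown_distinct=counters["unknown"][1],
        clean_total=clean.total_tags,
        clean_distinct=clean.distinct_tags,
        all_mapped_gene_count=len(all_genes),
        unambiguous_gene_count=len(unambig_genes),
    )
    # classification trichotomy, asserted on every run
    assert (
        result.unambiguous_distinct + result.ambiguous_distinct + result.unknown_distinct
        == result.clean_distinct
    )
    return result


def genome_mapping_stats(
    clean: "TagCountTable",
    genome_sequences: Iterable[str],
    max_mismatch: int = 1,
) -> tuple[float, float]:
    """Fraction of clean tags occurring anywhere in a genome sequence set.

    A membership test, not an aligner: a tag is genome-mapped iff its
    21-mer, or any 1-mismatch variant when ``max_mismatch=1``, occurs on
    either strand of any supplied sequence.  Returns
    ``(mapped_total_pct, mapped_distinct_pct)``.
    """
    kmers: set[str] = set()
    for seq in genome_sequences:
        seq = seq.upper()
        for s in (seq, reverse_complement(seq)):
            for i in range(len(s) - TAG_LEN + 1):
                k = s[i: i + TAG_LEN]
                if "N" not in k:
                    kmers.add(k)

    mapped_total = mapped_distinct = 0
    for tag, count in clean.items():
        hit = tag in kmers
        if not hit and max_mismatch == 1:
            hit = any(nb in kmers for nb in hamming1_neighbors(tag))
        if hit:
            mapped_total += count
            mapped_distinct += 1
    if clean.distinct_tags == 0:
        return 0.0, 0.0
    return (
        100.0 * mapped_total / clean.total_tags,
        100.0 * mapped_distinct / clean.distinct_tags,
    )
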