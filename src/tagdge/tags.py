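"""Raw tag-read cleaning and copy-number statistics.

A DGE library is a pile of short reads, each of which should be one 21-bp
expression tag (the NlaIII site CATG plus 17 nt).  Sequencing and library
prep also deliver artifacts: empty reads, adaptor carry-over, reads with
undetermined bases (``N``) and reads of abnormal length.  Cleaning removes
those, collapses the survivors into a table of distinct tags with copy
numbers, and finally discards single-copy tags, whose one observation
cannot be distinguished from a sequencing error.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_ADAPTORS",
    "TagCountTable",
    "FilterStats",
    "clean_tags",
    "copy_number_distribution",
]

#: Adaptor sequences screened by exact prefix match.  The library protocol
#: uses proprietary Illumina adaptors whose sequences are not public; these
#: defaults are arbitrary stand-ins and should be overridden when the true
#: adaptors are known.
DEFAULT_ADAPTORS: tuple[str, ...] = (
    "GATCGGAAGAGCTCGTATGCCGTCTTCTGCTTG",
    "ACACTCTTTCCCTACACGACGCTCTTCCGATCT",
)


@dataclass
class TagCountTable:
    """Distinct tag sequences with integer copy numbers.

    After cleaning, every key is a 21-mer over A/C/G/T with copy number >= 2.
    """

    entries: dict[str, int] = field(default_factory=dict)

    @property
    def total_tags(self) -> int:
        return sum(self.entries.values())

    @property
    def distinct_tags(self) -> int:
        return len(self.entries)

    def __getitem__(self, tag: str) -> int:
        return self.entries[tag]

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def items(self):
        return self.entries.items()

    def to_tsv(self, path) -> None:
        """Write (tag, count) rows sorted by descending count, then tag."""
        rows = sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        with open(path, "w") as fh:
            fh.write("tag\tcount\n")
            for tag, count in rows:
                fh.write(f"{tag}\t{count}\n")

    @classmethod
    def from_tsv(cls, path) -> "TagCountTable":
        entries: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tag"):
                raise ValueError(f"{path}: expected a 'tag\\tcount' header")
            for line in fh:
                if not line.strip():
                    continue
                tag, count = line.rstrip("\n").split("\t")
                entries[tag] = int(count)
        return cls(entries)


@dataclass
class FilterStats:
    """Audit trail of the cleaning filters, Table-1 style.

    Copy conservation holds for any input:
    ``clean_total + all removed categories == raw_total``.
    """

    raw_total: int = 0
    raw_distinct: int = 0
    removed_empty: int = 0
    removed_adaptor: int = 0
    removed_low_quality: int = 0
    removed_abnormal_length: int = 0
    removed_singletons: int = 0
    clean_total: int = 0
    clean_distinct: int = 0

    @property
    def clean_pct_of_raw(self) -> float:
        if self.raw_total == 0:
            return 0.0
        return 100.0 * self.clean_total / self.raw_total

    @property
    def distinct_clean_pct_of_raw_distinct(self) -> float:
        if self.raw_distinct == 0:
            return 0.0
        return 100.0 * self.clean_distinct / self.raw_distinct

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clean_pct_of_raw"] = round(self.clean_pct_of_raw, 1)
        d["distinct_clean_pct_of_raw_distinct"] = round(
            self.distinct_clean_pct_of_raw_distinct, 1
        )
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def clean_tags(
    raw_reads: Iterable[str],
    adaptor_sequences: Sequence[str] = DEFAULT_ADAPTORS,
    tag_length: int = 21,
) -> tuple[TagCountTable, FilterStats]:
    """Filter raw reads and collapse them into a clean tag-count table.

    Filters are applied in a fixed order so that each read is counted in
    exactly one removal category: empty -> adaptor (exact prefix match) ->
    contains ``N`` -> abnormal length -> (after collapsing) single-copy.

    Parameters
    ----------
    raw_reads
        Read sequences, one string per read.
    adaptor_sequences
        Adaptor sequences; a read starting with any of them is an adaptor
        artifact.
    tag_length
        Expected tag length in nt; reads of any other length are abnormal.
        Must be >= 5 (CATG plus at least one transcript base).

    Returns
    -------
    (TagCountTable, FilterStats)
    """
    if tag_length < 5:
        raise ValueError(f"tag_length must be >= 5, got {tag_length}")
    adaptors = tuple(adaptor_sequences)

    stats = FilterStats()
    survivors: Counter[str] = Counter()
    raw_seen: set[str] = set()
    for read in raw_reads:
        stats.raw_total += 1
        raw_seen.add(read)
        if read == "":
            stats.removed_empty += 1
        elif any(read.startswith(a) for a in adaptors):
            stats.removed_adaptor += 1
        elif "N" in read:
            stats.removed_low_quality += 1
        elif len(read) != tag_length:
            stats.removed_abnormal_length += 1
        else:
            survivors[read] += 1
    stats.raw_distinct = len(raw_seen)

    clean = {tag: n for tag, n in survivors.items() if n >= 2}
    stats.removed_singletons = sum(n for n in survivors.values() if n < 2)
    stats.clean_total = sum(clean.values())
    stats.clean_distinct = len(clean)
    return TagCountTable(clean), stats


def copy_number_distribution(
    table: TagCountTable,
    bins: Sequence[tuple[int, int | None]] = ((2, 10), (11, 100), (101, None)),
) -> list[dict]:
    """Per-bin shares of total and of distinct clean tags.

    ``bins`` is a list of inclusive copy-number ranges ``(lo, hi)`` with
    ``hi=None`` meaning unbounded; together they must partition [2, inf).
    Returns one dict per bin with keys ``lo``, ``hi``, ``distinct_count``,
    ``total_count``, ``distinct_pct``, ``total_pct``.
    """
    ordered = sorted(bins, key=lambda b: b[0])
    if not ordered or ordered[0][0] != 2 or ordered[-1][1] is not None:
        raise ValueError("bins must partition [2, inf)")
    for (lo, hi), (nlo, _) in zip(ordered, ordered[1:]):
        if hi is None or nlo != hi + 1:
            raise ValueError(f"bins must be contiguous and non-overlapping: ({lo},{hi}) then {nlo}")

    distinct_total = table.distinct_tags
    copies_total = table.total_tags
    out = []
    for lo, hi in ordered:
        d = sum(1 for n in table.entries.values() if n >= lo and (hi is None or n <= hi))
        t = sum(n for n in table.entries.values() if n >= lo and (hi is None or n <= hi))
        out.append(
            {
                "lo": lo,
                "hi": hi,
                "distinct_count": d,
                "total_count": t,
                "distinct_pct": 100.0 * d / distinct_total if distinct_total else 0.0,
                "total_pct": 100.0 * t / copies_total if copies_total else 0.0,
            }
        )
    return out
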