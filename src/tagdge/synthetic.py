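"""Synthetic references, expression truth and artifact-bearing tag reads.

Emulates an NlaIII/MmeI DGE library: every genuine read is one of a
gene's virtual tags (CATG + 17 nt), drawn with probability proportional
to the gene's expression level, with a bias toward the 3'-most site
reflecting the library chemistry; sequencing errors are i.i.d. per-base
substitutions, and artifact reads (adaptor-only, N-containing,
abnormal-length, empty) are injected at configurable rates.  Single-copy
tags are not injected: singletons arise naturally from sampling.

Per-gene genuine counts follow a negative-binomial law (gamma-distributed
rates, variance mu + dispersion*mu^2) conditioned on the library total,
so each library conserves its read depth exactly; dispersion 0 gives the
Poisson special case.  Defaults describe a scaled-down three-library
experiment: a few thousand genes, 10^5 raw tags per library against the
millions of a production run, expression spanning ~3.5 decades, 5% of
genes spiked with 2- to 8-fold changes in the treated libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagdge.enrichment import ONTOLOGIES, AnnotationTable
from tagdge.index import VirtualTagIndex, build_index
from tagdge.tags import DEFAULT_ADAPTORS

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_reference",
    "generate_truth",
    "simulate_gene_counts",
    "simulate_tag_reads",
    "generate_annotation",
    "write_reference_fasta",
    "read_reference_fasta",
    "write_reads_fastq",
    "write_reads_text",
    "read_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: artifact classes, in the order the cleaning filters see them
ARTIFACT_CLASSES = ("empty", "adaptor_only", "contains_N", "abnormal_length")


@dataclass
class SyntheticConfig:
    """Study-design knobs for the simulator.

    ``artifact_rates`` are per-read probabilities; genuine reads make up
    the remainder.  ``dispersion`` is the negative-binomial overdispersion
    (variance = mu + dispersion*mu^2); 0 means Poisson.  ``de_fraction``
    of genes receive a fold change drawn from ``de_fold_changes`` in every
    treated library (library 0 is the untreated control); all other genes
    have fold change exactly 1.
    """

    n_genes: int = 2000
    transcript_length_range: tuple[int, int] = (300, 2000)
    n_libraries: int = 3
    library_depth: int = 100_000
    baseline_mean_log10_range: tuple[float, float] = (-1.0, 2.5)
    dispersion: float = 0.1
    de_fraction: float = 0.05
    de_fold_changes: tuple[float, ...] = (0.125, 0.25, 0.5, 2.0, 4.0, 8.0)
    error_rate: float = 0.005
    artifact_rates: dict[str, float] = field(
        default_factory=lambda: {
            "adaptor_only": 0.02,
            "contains_N": 0.02,
            "abnormal_length": 0.01,
            "empty": 0.005,
        }
    )
    n_terms: int = 40
    genes_per_term_range: tuple[int, int] = (10, 80)
    taggable_fraction: float = 0.98
    three_prime_weight: float = 0.8
    adaptor_sequences: tuple[str, ...] = DEFAULT_ADAPTORS
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_libraries < 1 or self.library_depth < 1:
            raise ValueError("n_genes, n_libraries and library_depth must be positive")
        lo, hi = self.transcript_length_range
        if lo < 25 or hi < lo:
            raise ValueError(
                "transcript lengths must be >= 25 nt (room for CATG + 17 nt)"
            )
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if any(fc <= 0 for fc in self.de_fold_changes):
            raise ValueError("fold changes must be positive")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must lie in [0, 1]")
        unknown = set(self.artifact_rates) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ValueError(f"unknown artifact classes: {sorted(unknown)}")
        rates = [self.artifact_rates.get(c, 0.0) for c in ARTIFACT_CLASSES]
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("artifact rates must lie in [0,1] and sum to < 1")
        if not 0 < self.three_prime_weight <= 1:
            raise ValueError("three_prime_weight must lie in (0, 1]")

    def library_rng(self, library_index: int) -> np.random.Generator:
        """Deterministic child generator for one library."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(library_index,))
        )


@dataclass
class GroundTruth:
    """What the simulator knows and the pipeline must recover."""

    gene_ids: list[str]
    baseline_mean: pd.Series  # positive reals, index = gene_ids
    fold_change: pd.DataFrame  # genes x libraries, control column is all 1
    tags: dict[str, tuple[str, ...]]  # per gene, 3'-most first
    de_gene_ids: set[str]
    unmappable_gene_ids: set[str]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            libs = list(self.fold_change.columns)
            fh.write(
                "gene_id\tbaseline_mean\t"
                + "\t".join(f"fold_change_lib{l}" for l in libs)
                + "\tis_de\ttags\n"
            )
            for g in self.gene_ids:
                fcs = "\t".join(f"{self.fold_change.at[g, l]:g}" for l in libs)
                fh.write(
                    f"{g}\t{self.baseline_mean[g]:.6g}\t{fcs}\t"
                    f"{int(g in self.de_gene_ids)}\t{','.join(self.tags.get(g, ()))}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _has_eligible_site(seq: str) -> bool:
    pos = seq.find("CATG")
    while pos != -1:
        if len(seq) - pos >= 21:
            return True
        pos = seq.find("CATG", pos + 1)
    return False


def generate_reference(config: SyntheticConfig) -> list[tuple[str, str]]:
    """Random transcript sequences with NlaIII (CATG) tag sites.

    Each transcript is uniform-random A/C/G/T; for ``taggable_fraction``
    of transcripts a CATG is planted at a random eligible position if the
    random sequence happens to contain none, so that by construction at
    least that fraction carries a virtual tag site.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1_000_000,))
    )
    lo, hi = config.transcript_length_range
    width = max(4, len(str(config.n_genes)))
    reference = []
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        arr = _random_seq(rng, length)
        ensure = rng.random() < config.taggable_fraction
        seq = arr.tobytes().decode()
        if ensure and not _has_eligible_site(seq):
            pos = int(rng.integers(0, length - 20))
            arr[pos: pos + 4] = _BASES[[1, 0, 3, 2]]  # C A T G
            seq = arr.tobytes().decode()
        reference.append((gene_id, seq))
    return reference


def generate_truth(
    config: SyntheticConfig,
    reference: Sequence[tuple[str, str]],
    index: VirtualTagIndex | None = None,
) -> GroundTruth:
    """Assign baseline expression and spiked fold changes to the reference.

    Baseline means are log-uniform over ``baseline_mean_log10_range``.
    ``round(de_fraction * n_genes)`` genes are flagged DE, restricted to
    genes with at least one virtual tag (a warning is issued if that
    restriction bites), and given a fold change drawn from
    ``de_fold_changes`` in every treated library.
    """
    if not reference:
        raise ValueError("reference is empty")
    if index is None:
        index = build_index(reference)
    gene_ids = [g for g, _ in reference]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2_000_000,))
    )
    lo, hi = config.baseline_mean_log10_range
    baseline = pd.Series(
        10.0 ** rng.uniform(lo, hi, size=len(gene_ids)), index=gene_ids
    )

    tags = {g: tuple(index.tags_of_gene(g)) for g in gene_ids}
    unmappable = {g for g in gene_ids if not tags[g]}
    mappable = [g for g in gene_ids if tags[g]]

    n_de = round(config.de_fraction * len(gene_ids))
    if n_de > len(mappable):
        warnings.warn(
            f"requested {n_de} DE genes but only {len(mappable)} have virtual "
            "tags; assigning DE only to mappable genes"
        )
        n_de = len(mappable)
    de_genes = set(
        rng.choice(mappable, size=n_de, replace=False) if n_de else []
    )

    fold = pd.DataFrame(
        1.0, index=gene_ids, columns=list(range(config.n_libraries))
    )
    fcs = rng.choice(config.de_fold_changes, size=len(de_genes))
    for g, fc in zip(sorted(de_genes), fcs):
        for lib in range(1, config.n_libraries):
            fold.at[g, lib] = fc
    return GroundTruth(
        gene_ids=gene_ids,
        baseline_mean=baseline,
        fold_change=fold,
        tags=tags,
        de_gene_ids=de_genes,
        unmappable_gene_ids=unmappable,
    )


def simulate_gene_counts(
    truth: GroundTruth,
    config: SyntheticConfig,
    library_index: int,
    n_reads: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Genuine read counts per gene, summing to ``n_reads`` exactly.

    Gamma-distributed per-gene rates (mean mu, variance dispersion*mu^2)
    conditioned on the total by multinomial sampling give negative-
    binomial-dispersed counts that conserve the library depth.  Genes
    without a virtual tag emit no reads.
    """
    weights = truth.baseline_mean * truth.fold_change[library_index]
    mappable = [g for g in truth.gene_ids if g not in truth.unmappable_gene_ids]
    w = weights[mappable].to_numpy()
    mu = n_reads * w / w.sum()
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        rates = mu * rng.gamma(shape, 1.0, size=len(mu)) / shape
    else:
        rates = mu
    total = rates.sum()
    if total <= 0:
        raise ValueError("all sampling rates are zero")
    counts = rng.multinomial(n_reads, rates / total)
    out = pd.Series(0, index=truth.gene_ids, dtype=int)
    out[mappable] = counts
    return out


def _apply_errors(
    reads: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """i.i.d. per-base substitutions on an (n, 21) uint8 base array."""
    if error_rate == 0 or reads.size == 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lookup[b] = i
    idx = lookup[reads[mask]]
    new_idx = (idx + rng.integers(1, 4, size=n_err)) % 4
    reads[mask] = _BASES[new_idx]
    return reads


def simulate_tag_reads(
    reference: Sequence[tuple[str, str]],
    truth: GroundTruth,
    config: SyntheticConfig,
    library_index: int,
) -> tuple[list[str], pd.Series]:
    """One library of raw reads plus the per-gene true tag-origin counts.

    Genuine reads are exact virtual tags of their gene — the 3'-most site
    receives ``three_prime_weight`` of a gene's reads, the remainder is
    spread uniformly over its other sites — then corrupted by per-base
    substitution at ``error_rate``.  Artifact reads are injected at
    ``artifact_rates``; the returned read list has length
    ``library_depth`` exactly and is deterministically shuffled.
    """
    rng = config.library_rng(library_index)
    depth = config.library_depth
    probs = [config.artifact_rates.get(c, 0.0) for c in ARTIFACT_CLASSES]
    probs.append(1.0 - sum(probs))
    n_by_class = rng.multinomial(depth, probs)
    n_genuine = int(n_by_class[-1])

    counts = simulate_gene_counts(truth, config, library_index, n_genuine, rng)

    genuine: list[str] = []
    for gene, count in counts.items():
        if count == 0:
            continue
        sites = truth.tags[gene]
        if len(sites) == 1:
            per_site = [count]
        else:
            w = np.full(len(sites), (1.0 - config.three_prime_weight) / (len(sites) - 1))
            w[0] = config.three_prime_weight
            per_site = rng.multinomial(count, w)
        for tag, k in zip(sites, per_site):
            genuine.extend([tag] * int(k))

    arr = np.frombuffer("".join(genuine).encode(), dtype=np.uint8).reshape(-1, 21).copy()
    arr = _apply_errors(arr, config.error_rate, rng)
    genuine = [row.tobytes().decode() for row in arr]

    reads: list[str] = []
    reads.extend([""] * int(n_by_class[0]))
    adaptors = list(config.adaptor_sequences)
    reads.extend(
        adaptors[i] for i in rng.integers(0, len(adaptors), size=int(n_by_class[1]))
    )
    for _ in range(int(n_by_class[2])):  # N-containing 21-mers
        bases = _random_seq(rng, 21)
        bases[int(rng.integers(0, 21))] = ord("N")
        reads.append(bases.tobytes().decode())
    for _ in range(int(n_by_class[3])):  # abnormal lengths
        length = int(rng.choice([15, 16, 17, 18, 19, 20, 22, 23, 24, 25, 26, 27]))
        reads.append(_random_seq(rng, length).tobytes().decode())
    reads.extend(genuine)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    assert len(reads) == depth
    return reads, counts


def generate_annotation(
    config: SyntheticConfig, gene_ids: Sequence[str]
) -> AnnotationTable:
    """Random flat gene-to-term annotations cycling over CC/MF/BP/PATHWAY."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(3_000_000,))
    )
    lo, hi = config.genes_per_term_range
    table = AnnotationTable()
    width = max(4, len(str(config.n_terms)))
    for t in range(config.n_terms):
        ontology = ONTOLOGIES[t % len(ONTOLOGIES)]
        size = min(int(rng.integers(lo, hi + 1)), len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        term_id = f"TERM{t + 1:0{width}d}"
        for g in members:
            table.add(str(g), term_id, ontology, name=f"synthetic term {t + 1}")
    return table


# ---------------------------------------------------------------------------
# I/O helpers

def write_reference_fasta(reference: Sequence[tuple[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in reference
    ]
    SeqIO.write(records, path, "fasta")


def read_reference_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_reads_fastq(reads: Sequence[str], path) -> None:
    """FASTQ with uniform quality 'I' (Phred 40)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")


def write_reads_text(reads: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read + "\n")


def read_reads(path) -> list[str]:
    """Read FASTQ (by extension .fastq/.fq) or one-read-per-line text."""
    p = str(path)
    if p.endswith((".fastq", ".fq")):
        return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh]
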