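"""Hypergeometric term enrichment of DEG sets.

For one annotation term, with N annotated genes in the universe, n of
them differentially expressed, M annotated to the term and m of those
differentially expressed, the enrichment p-value is the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N,n) = Pr[X >= m]

for X hypergeometric.  Terms are treated as flat, independent labels (no
GO-DAG ancestor propagation); the universe is the set of genes carrying
at least one annotation in the ontology under test, and correction is
Benjamini-Hochberg within each ontology (Bonferroni available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Iterable

import pandas as pd

from tagdge.de import bh_fdr

ONTOLOGIES = ("CC", "MF", "BP", "PATHWAY")

__all__ = ["AnnotationTable", "hypergeom_upper_tail", "enrich", "ontology_histogram"]


@dataclass
class AnnotationTable:
    """Gene-to-term annotations with per-term ontology labels."""

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    term_ontology: dict[str, str] = field(default_factory=dict)
    term_name: dict[str, str] = field(default_factory=dict)

    def add(self, gene_id: str, term_id: str, ontology: str, name: str = "") -> None:
        if ontology not in ONTOLOGIES:
            raise ValueError(f"unknown ontology {ontology!r}; expected one of {ONTOLOGIES}")
        prev = self.term_ontology.get(term_id)
        if prev is not None and prev != ontology:
            raise ValueError(f"term {term_id!r} annotated to two ontologies")
        self.gene_to_terms.setdefault(gene_id, set()).add(term_id)
        self.term_to_genes.setdefault(term_id, set()).add(gene_id)
        self.term_ontology[term_id] = ontology
        if name:
            self.term_name[term_id] = name

    def universe(self, ontology: str) -> set[str]:
        """Genes with at least one annotation in this ontology."""
        return {
            g
            for term, genes in self.term_to_genes.items()
            if self.term_ontology[term] == ontology
            for g in genes
        }

    def terms(self, ontology: str) -> list[str]:
        return sorted(t for t, o in self.term_ontology.items() if o == ontology)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        """Read TSV with columns gene_id, term_id, ontology[, term_name]."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        table = cls()
        has_name = "term_name" in df.columns
        for row in df.itertuples(index=False):
            table.add(
                row.gene_id,
                row.term_id,
                row.ontology,
                getattr(row, "term_name", "") if has_name else "",
            )
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tterm_id\tontology\tterm_name\n")
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(
                        f"{gene}\t{term}\t{self.term_ontology[term]}\t"
                        f"{self.term_name.get(term, '')}\n"
                    )


def hypergeom_upper_tail(m: int, n: int, M: int, N: int) -> float:
    """Pr[X >= m] for X ~ hypergeometric(N population, M marked, n drawn).

    Evaluated with exact integer binomial coefficients (no normal
    approximation); the empty sum at m = 0 gives exactly 1.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(
            f"invalid hypergeometric arguments m={m}, n={n}, M={M}, N={N}"
        )
    denom = comb(N, n)
    lower = sum(comb(M, i) * comb(N - M, n - i) for i in range(m))
    # exact rational arithmetic until the final division
    return 1.0 - lower / denom


def enrich(
    deg_genes: Iterable[str],
    annotation: AnnotationTable,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    correction: str = "bh",
) -> pd.DataFrame:
    """Test every annotated term for DEG over-representation.

    The universe defaults, per ontology, to the genes annotated in that
    ontology; an explicit ``universe`` is intersected with it.  Returns a
    DataFrame with columns term_id, ontology, term_name, N, n, M, m, P, Q,
    significant, sorted by (ontology, Q, term_id).
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    degs = set(deg_genes)
    restrict = set(universe) if universe is not None else None

    frames = []
    for ontology in ONTOLOGIES:
        uni = annotation.universe(ontology)
        if restrict is not None:
            uni &= restrict
        if not uni:
            continue
        N = len(uni)
        deg_in = degs & uni
        n = len(deg_in)
        if n == 0:
            warnings.warn(
                f"DEG set is disjoint from the {ontology} universe; all P = 1"
            )
        rows = []
        for term in annotation.terms(ontology):
            genes = annotation.term_to_genes[term] & uni
            M = len(genes)
            if M == 0:
                continue
            m = len(genes & deg_in)
            rows.append(
                (
                    term,
                    ontology,
                    annotation.term_name.get(term, ""),
                    N,
                    n,
                    M,
                    m,
                    hypergeom_upper_tail(m, n, M, N),
                )
            )
        df = pd.DataFrame(
            rows, columns=["term_id", "ontology", "term_name", "N", "n", "M", "m", "P"]
        )
        if correction == "bh":
            df["Q"] = bh_fdr(df["P"])
        else:
            df["Q"] = (df["P"] * len(df)).clip(upper=1.0)
        df["significant"] = df["Q"] <= alpha
        frames.append(df)
    if not frames:
        raise ValueError("empty universe: no annotated genes to test against")
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["ontology", "Q", "term_id"]).reset_index(drop=True)


def ontology_histogram(
    records: pd.DataFrame, annotation: AnnotationTable, deg_genes: Iterable[str]
) -> dict[str, dict[str, int]]:
    """Per-ontology count of significant terms ("functional groups") and
    of distinct DEGs annotated to at least one of them."""
    degs = set(deg_genes)
    out: dict[str, dict[str, int]] = {}
    for ontology in ONTOLOGIES:
        sub = records[(records["ontology"] == ontology) & records["significant"]]
        genes: set[str] = set()
        for term in sub["term_id"]:
            genes |= annotation.term_to_genes[term] & degs
        out[ontology] = {"n_significant_terms": int(len(sub)), "n_genes": len(genes)}
    return out
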