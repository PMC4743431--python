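# Methods

## The tag model

A DGE library reduces each transcript to fixed-length sequence tags: the
restriction enzyme NlaIII cuts cDNA at CATG sites, and MmeI cuts 17 bp
downstream of the adaptor/CATG junction, so every potential tag is the
21-mer `CATG + 17 nt` anchored at a CATG site with at least 17 nt
downstream. The *virtual tag library* of a reference sequence set is the
exhaustive collection of these 21-mers (all sites by default, sense
strand only; `three_prime_most` and `both_strands` are options). A site
whose 17-nt window contains `N` is skipped. Site rank counts from the 3′
end (rank 0 = 3′-most) because the library chemistry sequences the
3′-most cleavage product preferentially.

## Cleaning

Reads are filtered in a fixed order — empty → adaptor (exact prefix
match) → contains-`N` → abnormal length → (after collapsing to copy
numbers) single-copy — so each removed read is counted in exactly one
category and the audit statistics are reproducible; the order among the
read-level filters is a convention, chosen because the categories are
disjoint for the artifact classes the simulator produces. Abnormal
length is judged on the read as delivered. Adaptor sequences are a
required input with arbitrary documented defaults (the real platform
adaptors are proprietary). Quality scores are ignored beyond the `N`
rule; single-copy tags are removed because one observation cannot be
distinguished from a sequencing error.

## Mapping

Clean tags are looked up in the virtual tag index exactly first; only if
no exact key exists is the union of gene sets over all 63
Hamming-distance-1 neighbours used (exact-over-mismatch priority prevents
a perfectly matching tag from being declared ambiguous by a
near-neighbour; this mirrors standard DGE practice). Mismatches are
allowed at any of the 21 positions, including the CATG anchor. Ambiguity
is decided at the gene level: a tag hitting several sites of one gene is
unambiguous. Every tag therefore lands in exactly one of
unambiguous/ambiguous/unknown, an invariant asserted on every run.
Genome-level mapping is a pure membership test (either strand, ≤1
mismatch), not an aligner.

## Quantification

Only unambiguous tags contribute; a tag unambiguous via several sites of
one gene contributes its full copy number once. TPM is tag copies per
million **clean** tags — the denominator is the library clean total, not
the mapped total, so per-library TPMs sum below 10⁶ whenever tags remain
unmapped; the choice is recorded in the table metadata. There is no
gene-length correction: tags are fixed-length, so this TPM is a tag
frequency.

## Differential expression

For counts x, y in libraries of N1, N2 clean tags, the null conditional
distribution of y given x is

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

equivalently negative binomial with x+1 successes and success probability
N1/(N1+N2) — a fact used as an independent cross-check in the tests, not
as the implementation, which evaluates log-space gamma functions and sums
tails directly. When the complement form `1 − lower_tail` of the upper
tail would cancel (tail < 1e-10), the tail is re-summed forward from y in
log space; the term ratio tends to N2/(N1+N2) < 1 so the series converges
geometrically. The two-sided p doubles the smaller tail, capped at 1; a
minimum-likelihood alternative (`method="minlike"`) sums all outcomes no
more probable than the observed one. Note the conditional test is not
exactly symmetric under exchanging the libraries: the log2 ratio flips
sign exactly, but the two directions' p-values can differ up to the
tail-doubling factor (e.g. x=0, y=5, N1=N2 gives 1/16 vs 1/32).

Genes absent from both libraries are excluded before testing so they do
not dilute the Benjamini–Hochberg correction (delegated to statsmodels;
the tests check it against the hand-applied step-up definition). The
log2 ratio is computed on TPM with a pseudo-TPM floor of 0.001 applied
only on the zero side, keeping ratios finite for genes detected in one
library while leaving all non-zero genes exact. Calls use FDR ≤ 0.001
and |log2 ratio| ≥ 1 by default. Fold-change binning places the boundary
value in the extreme bins (FC = 5 counts as ≥5-fold).

## Enrichment

P = Pr[X ≥ m] = 1 − Σ_{i<m} C(M,i)·C(N−M, n−i)/C(N,n), evaluated with
exact integer binomial coefficients (the formula is sometimes typeset
with the middle factor as a fraction; the binomial-coefficient reading is
the only one that yields a probability). The universe N is, per
ontology, the set of genes carrying at least one annotation in that
ontology; terms are flat independent labels with no GO-DAG propagation
(pre-propagated annotations are accepted as input). Correction is BH
within each ontology (Bonferroni behind a flag); significance is
Q ≤ 0.05 by default.

## qPCR

2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_reference)_treated − (… )_control.
Replicate Ct values are averaged before building records; efficiency
correction (Pfaffl) and variance propagation are out of scope.
Concordance against DGE is sign agreement of log2 levels plus Spearman
rank correlation over shared genes.

## The simulator

What it emulates: genuine reads are exact virtual tags of their gene —
the 3′-most site receives weight 0.8 by default, the remainder uniform
over other sites (a configurable choice; real positional bias is not
known, so it is flagged rather than fixed) — corrupted by i.i.d.
per-base substitutions (default 0.005, an Illumina-like error rate).
Artifact reads (adaptor-only, N-containing, abnormal-length, empty) are
injected at per-read rates; singletons are never injected — they arise
naturally from sampling. Per-gene expression weights are baseline mean ×
fold change; baseline means are log-uniform over 10^[−1, 2.5] (about
3.5 decades, so most genes sit at low copy number, as in real tag
libraries), and `round(de_fraction · n_genes)` genes receive a fold
change from {8×, 4×, 2× up and down} in every treated library, the rest
exactly 1. Defaults describe a scaled-down three-library experiment:
2 000 genes and 10⁵ raw tags per library stand in for the tens of
thousands of genes and ~4.5 million clean tags of a production run; the
tests and the acceptance script state the sizes they use.

Count noise: per-gene rates are gamma-distributed with mean μ and
variance `dispersion·μ²` and the library total is allocated
multinomially across genes, giving negative-binomial-dispersed counts
*conditioned on an exactly conserved depth* (exact NB marginals and an
exact total are mutually exclusive; conservation was chosen because the
cleaning audit depends on it). `dispersion=0` is the Poisson special
case. One master seed yields per-library child generators derived from
the library index, so identical (config, seed) produce byte-identical
outputs.

What it does not emulate: PCR amplification and GC bias, base-quality
distributions, paired ends, biological replicate structure, or real
annotation topology (terms are random gene sets). Passing tests on
synthetic data therefore demonstrate the pipeline's arithmetic and its
operating characteristics under the test's own sampling model — not
robustness to the full noise structure of real libraries.

## Operating characteristics and their conditions

Type-I error and power are measured under Poisson sampling
(`dispersion=0`): the Audic–Claverie test models technical sampling of
one library pair, and that is the regime in which its error rates are
defined. This is a real limitation, not a convenience: with biological
overdispersion between libraries the exact test is anticonservative, one
reason single-library exact tests were later superseded by
dispersion-aware models (deliberately out of scope here — the package
reproduces the classic methodology). On null data (2 000 genes, 10⁵
tags/library, 10 replicates) the fraction of genes with FDR ≤ 0.05 and
|log2 ratio| ≥ 1 stays within 0.05 + 2·SE (in practice ≈ 0), and at
FDR ≤ 0.001 false calls average < 1 per run; 4-fold spikes with baseline
count ≥ 100 at 10⁶ depth are recovered with sensitivity ≥ 0.9 and
correct signs. All of these are recomputed, never quoted, by the test
suite and `scripts/acceptance.py`.

## Numerical and degenerate-input conventions

Tail sums are exact log-space summations (no normal approximations);
the hypergeometric tail uses exact integer arithmetic until the final
division. BH ties follow the step-up definition with no randomisation.
Empty read lists yield all-zero statistics (not an error); an empty
clean library makes TPM undefined and raises; copy-number bins must
partition [2, ∞) and empty tables report zero percentages. Zero-read
libraries report zero percentages throughout. Tags of the wrong length
reaching the mapper indicate an upstream bug and raise immediately
rather than being filtered.
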