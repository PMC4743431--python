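"""Audic-Claverie exact test for two-library tag counts, FDR and DEG calls.

For a gene observed ``x`` times in a library of ``N1`` clean tags, the
probability of observing it ``y`` times in a second library of ``N2``
clean tags, under the null of equal underlying frequency with a flat prior
on that frequency, is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is a proper distribution over y (it is negative binomial with x+1
successes and success probability N1/(N1+N2)).  All evaluation is in log
space; tail sums are direct, never normal-approximated.

A gene is called differentially expressed when its Benjamini-Hochberg
adjusted p (FDR) is at most 0.001 and its |log2 TPM ratio| is at least 1,
i.e. at least a two-fold change.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from tagdge.quantify import GeneExpressionTable

__all__ = [
    "ac_probability",
    "ac_two_sided_p",
    "bh_fdr",
    "call_degs",
    "comparison_summary",
    "fold_change_distribution",
    "compare_deg_sets",
]


def _check_counts(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative, got x={x}, y={y}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive, got N1={n1}, N2={n2}")


def _log_pmf(y, x: int, n1: float, n2: float):
    """log p(y|x) for scalar or array y."""
    y = np.asarray(y, dtype=float)
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    return (
        y * log_r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log_1pr
    )


def ac_probability(y: int, x: int, n1: float, n2: float) -> float:
    """p(y|x): probability of count ``y`` in library 2 given ``x`` in
    library 1, with clean-tag totals ``n1`` and ``n2``."""
    _check_counts(x, y, n1, n2)
    return float(np.exp(_log_pmf(y, x, n1, n2)))


def _upper_tail_direct(y: int, x: int, n1: float, n2: float) -> float:
    """Pr[Y >= y] by forward summation from y, in log space.

    Used when 1 - lower_tail would cancel; the term ratio tends to
    N2/(N1+N2) < 1, so the series converges geometrically.
    """
    log_term = float(_log_pmf(y, x, n1, n2))
    log_r_over_1pr = math.log(n2) - math.log(n1 + n2)
    total = log_term
    k = y
    while True:
        log_term += log_r_over_1pr + math.log((x + k + 1) / (k + 1))
        new_total = np.logaddexp(total, log_term)
        if new_total - total < 1e-17 and log_term < total - 40:
            total = new_total
            break
        total = new_total
        k += 1
        if k > y + 10_000_000:  # pragma: no cover - geometric decay guard
            break
    return float(np.exp(total))


def _tails(x: int, y: int, n1: float, n2: float) -> tuple[float, float]:
    """(Pr[Y <= y], Pr[Y >= y]) by direct log-space summation."""
    ks = np.arange(0, y + 1)
    log_pmf = _log_pmf(ks, x, n1, n2)
    lower = float(np.exp(logsumexp(log_pmf)))
    if y == 0:
        upper = 1.0
    else:
        upper = 1.0 - float(np.exp(logsumexp(log_pmf[:-1])))
        if upper < 1e-10:  # recompute without cancellation
            upper = _upper_tail_direct(y, x, n1, n2)
    return min(lower, 1.0), min(upper, 1.0)


def ac_two_sided_p(
    x: int, y: int, n1: float, n2: float, method: str = "doubled"
) -> float:
    """Two-sided p-value for observing counts ``(x, y)``.

    ``method="doubled"`` (default): twice the smaller of the two tails of
    p(.|x), capped at 1.  ``method="minlike"``: the sum of p(k|x) over all
    k whose probability does not exceed p(y|x) (the minimum-likelihood
    convention).
    """
    _check_counts(x, y, n1, n2)
    if method == "doubled":
        lower, upper = _tails(x, y, n1, n2)
        return min(1.0, 2.0 * min(lower, upper))
    if method == "minlike":
        mode = int((x + 1) * n2 / n1) + 2
        hi = max(y + 10, 4 * mode + 40)
        ks = np.arange(0, hi + 1)
        pmf = np.exp(_log_pmf(ks, x, n1, n2))
        obs = pmf[y]
        p = float(pmf[pmf <= obs * (1 + 1e-12)].sum())
        # tail beyond hi is below pmf[y] whenever included; add it
        p += max(0.0, 1.0 - float(pmf.sum()))
        return min(1.0, p)
    raise ValueError(f"unknown method {method!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    expr1: GeneExpressionTable,
    expr2: GeneExpressionTable,
    fdr_threshold: float = 0.001,
    log2_threshold: float = 1.0,
    pseudo_tpm: float = 0.001,
    method: str = "doubled",
) -> pd.DataFrame:
    """Test every gene of two libraries for differential expression.

    Genes absent from both libraries (x = y = 0) are excluded before
    testing so they do not dilute the FDR correction.  The log2 ratio is
    log2(tpm2/tpm1) computed on TPM, with ``pseudo_tpm`` substituted only
    on the zero side for genes detected in exactly one library.

    Returns a DataFrame with one row per tested gene: gene_id, x, y, n1,
    n2, tpm1, tpm2, log2_ratio, p_value, fdr, status (up / down /
    not_significant, library 2 relative to library 1).
    """
    g1 = set(expr1.table.index)
    g2 = set(expr2.table.index)
    if g1 != g2:
        raise ValueError("expression tables cover different gene universes")
    genes = list(expr1.table.index)
    n1 = expr1.library_clean_total
    n2 = expr2.library_clean_total

    x = expr1.table["raw_count"].to_numpy()
    y = expr2.table.loc[genes, "raw_count"].to_numpy()
    tested = (x > 0) | (y > 0)

    rows = []
    for gi in np.nonzero(tested)[0]:
        xi, yi = int(x[gi]), int(y[gi])
        tpm1 = 1e6 * xi / n1
        tpm2 = 1e6 * yi / n2
        r1 = tpm1 if tpm1 > 0 else pseudo_tpm
        r2 = tpm2 if tpm2 > 0 else pseudo_tpm
        rows.append(
            (
                genes[gi],
                xi,
                yi,
                tpm1,
                tpm2,
                math.log2(r2 / r1),
                ac_two_sided_p(xi, yi, n1, n2, method=method),
            )
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "x", "y", "tpm1", "tpm2", "log2_ratio", "p_value"]
    )
    df["n1"] = n1
    df["n2"] = n2
    df["fdr"] = bh_fdr(df["p_value"]) if len(df) else np.array([])
    sig = df["fdr"] <= fdr_threshold
    df["status"] = "not_significant"
    df.loc[sig & (df["log2_ratio"] >= log2_threshold), "status"] = "up"
    df.loc[sig & (df["log2_ratio"] <= -log2_threshold), "status"] = "down"
    return df[
        ["gene_id", "x", "y", "n1", "n2", "tpm1", "tpm2", "log2_ratio", "p_value", "fdr", "status"]
    ]


def comparison_summary(records: pd.DataFrame) -> dict:
    """Up/down/total DEG bookkeeping for one two-library comparison."""
    n_up = int((records["status"] == "up").sum())
    n_down = int((records["status"] == "down").sum())
    return {
        "n_tested": int(len(records)),
        "n_up": n_up,
        "n_down": n_down,
        "n_deg": n_up + n_down,
    }


def fold_change_distribution(records: pd.DataFrame, boundary: float = 5.0) -> dict:
    """Three-bin fold-change distribution over all tested items.

    Bins: |FC| < boundary; FC >= boundary (up); FC <= 1/boundary (down);
    the boundary itself belongs to the extreme bins.  Percentages are over
    all tested records and sum to 100.
    """
    if boundary <= 1:
        raise ValueError(f"boundary must exceed 1, got {boundary}")
    log_b = math.log2(boundary)
    l2 = records["log2_ratio"].to_numpy()
    n = len(l2)
    up = int((l2 >= log_b).sum())
    down = int((l2 <= -log_b).sum())
    within = n - up - down
    pct = lambda k: 100.0 * k / n if n else 0.0
    return {
        "boundary": boundary,
        "n": n,
        "within_count": within,
        "up_count": up,
        "down_count": down,
        "within_pct": pct(within),
        "up_pct": pct(up),
        "down_pct": pct(down),
    }


def compare_deg_sets(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int]:
    """(|A only|, |B only|, |A and B|) for two DEG gene-id sets."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(b - a), len(a & b)
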