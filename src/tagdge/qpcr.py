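"""Relative qPCR quantification (2^-ddCt) and DGE concordance.

Each Ct record pairs a target gene's threshold cycle with that of an
internal control (e.g. 18S rRNA) in the same sample.  The relative level
of the target in a treated sample versus a control sample is 2^-ddCt with
ddCt = dCt_treated - dCt_control and dCt = Ct_target - Ct_reference; the
control sample's own level is exactly 1.  Replicate Ct values should be
averaged before building records; amplification-efficiency correction is
out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import spearmanr

__all__ = ["CtRecord", "relative_level", "concordance", "read_ct_tsv"]


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    gene_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"Ct values must be positive and finite, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_level(treated: CtRecord, control: CtRecord) -> float:
    """2^-ddCt relative expression of ``treated`` versus ``control``."""
    if treated.gene_id != control.gene_id:
        raise ValueError(
            f"gene mismatch: {treated.gene_id!r} vs {control.gene_id!r}"
        )
    ddct = treated.delta_ct - control.delta_ct
    return 2.0 ** (-ddct)


def concordance(
    dge_log2fc: Mapping[str, float], qpcr_levels: Mapping[str, float]
) -> tuple[float, float]:
    """Agreement between DGE fold changes and qPCR relative levels.

    Over the genes shared by both inputs, returns the fraction whose
    log2 DGE ratio and log2 qPCR level share a sign (zeros agree only
    with zeros), and the Spearman rank correlation.
    """
    shared = sorted(set(dge_log2fc) & set(qpcr_levels))
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared genes, got {len(shared)}")
    dge = [dge_log2fc[g] for g in shared]
    qpcr = [math.log2(qpcr_levels[g]) for g in shared]
    sign = lambda v: (v > 0) - (v < 0)
    agree = sum(sign(a) == sign(b) for a, b in zip(dge, qpcr)) / len(shared)
    rho = float(spearmanr(dge, qpcr).statistic)
    return agree, rho


def read_ct_tsv(path) -> list[CtRecord]:
    """Read records from TSV: sample_id, gene_id, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    return [
        CtRecord(str(r.sample_id), str(r.gene_id), float(r.ct_target), float(r.ct_reference))
        for r in df.itertuples(index=False)
    ]
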