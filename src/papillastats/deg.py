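"""Transcript selection filter for trafficking / actin-remodelling genes.

Applies the study's screening criteria to a precomputed expression table
(the differential-expression fit itself is upstream): a transcript is
kept when it is expressed (RPKM > 1 at 3 h or 12 h of culture) and
either shows a log2 fold change > 1 on 0->3 h or 3->12 h with FDR < 5%,
or is up-regulated on both intervals with both FDRs < 5% (sustained
up-regulation).  For known Ca2+-sensitive candidates the magnitude gate
can be relaxed (direction, expression and FDR gates are kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["TranscriptRecord", "select_degs", "passes_criteria"]

RPKM_MIN = 1.0
LOG2FC_MIN = 1.0
FDR_MAX = 0.05


@dataclass(frozen=True)
class TranscriptRecord:
    gene_id: str
    rpkm_0h: float
    rpkm_3h: float
    rpkm_12h: float
    log2fc_0_3: float
    log2fc_3_12: float
    fdr_0_3: float
    fdr_3_12: float
    ca_sensitive: bool = False

    def __post_init__(self) -> None:
        for name in ("rpkm_0h", "rpkm_3h", "rpkm_12h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene_id}: {name} must be >= 0")
        for name in ("fdr_0_3", "fdr_3_12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.gene_id}: {name} must lie in [0, 1]")


def passes_criteria(
    rec: TranscriptRecord, relax_ca_sensitive: bool = False
) -> bool:
    """Apply the selection predicate to one transcript."""
    expressed = rec.rpkm_3h > RPKM_MIN or rec.rpkm_12h > RPKM_MIN
    if not expressed:
        return False
    fc_early = rec.log2fc_0_3 > LOG2FC_MIN and rec.fdr_0_3 < FDR_MAX
    fc_late = rec.log2fc_3_12 > LOG2FC_MIN and rec.fdr_3_12 < FDR_MAX
    sustained = (
        rec.log2fc_0_3 > 0.0
        and rec.log2fc_3_12 > 0.0
        and rec.fdr_0_3 < FDR_MAX
        and rec.fdr_3_12 < FDR_MAX
    )
    if fc_early or fc_late or sustained:
        return True
    if relax_ca_sensitive and rec.ca_sensitive:
        # drop the magnitude gate only: still up-regulated and significant
        return (rec.log2fc_0_3 > 0.0 and rec.fdr_0_3 < FDR_MAX) or (
            rec.log2fc_3_12 > 0.0 and rec.fdr_3_12 < FDR_MAX
        )
    return False


def select_degs(
    records: Iterable[TranscriptRecord], relax_ca_sensitive: bool = False
) -> list[TranscriptRecord]:
    """Filter a transcript table down to the selected genes."""
    return [
        rec for rec in records if passes_criteria(rec, relax_ca_sensitive)
    ]
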