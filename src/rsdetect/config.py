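"""Pipeline configuration: every threshold the pipelines use, in one place.

Defaults are the published pipeline parameters where the source analysis
printed one (1 kb / 50 kb intron minima, 10-read up-junction cutoff,
2-read down-junction cutoff, >2-fold / >1-fold RPM enrichment, 350 nt
down-junction window) and simulator-calibrated values for the automated
saw-tooth / exon-likeness classification, which replaces manual visual
inspection of coverage profiles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Literal

Strandedness = Literal["forward", "reverse", "unstranded"]


@dataclass(frozen=True)
class PipelineThresholds:
    """All tunable pipeline parameters.

    Attributes
    ----------
    min_intron : minimum host-intron length (nt) for the RS pipeline.
    min_count : minimum replicate-merged up-junction read count for an
        RS candidate.
    min_fold : total-RNA pooled RPM must exceed ``min_fold`` times the
        mRNA-control pooled RPM (strict inequality).
    window : down-junction scan window (nt) 3' of the RS acceptor.
    flank_w : half-window W (nt) for the saw-tooth step statistic.
    epsilon : pseudocount (reads/base) in coverage log-ratios.
    tau_saw : saw-tooth score (log2) at or above which a candidate is
        classified RS.
    tau_exon : exon-likeness score (log2) at or above which a non-RS
        candidate is classified as an unannotated exon.
    tau_bg : mean intron coverage (reads/base) at or above which a
        candidate with neither pattern is classified nascent.
    bin_size : bin width (nt) for coverage trend tests.
    rho_max : maximum Spearman rho for a flank to count as declining.
    cryptic_min_intron, cryptic_min_up, cryptic_min_down,
    cryptic_min_fold : the cryptic-exon pipeline variants of the filters.
    motif : acceptor motif pattern (must start with AG; N is a wildcard).
    strandedness : library strandedness of the alignments.
    """

    min_intron: int = 1000
    min_count: int = 10
    min_fold: float = 2.0
    window: int = 350
    flank_w: int = 5000
    epsilon: float = 0.1
    tau_saw: float = 1.0
    tau_exon: float = 1.0
    tau_bg: float = 0.05
    bin_size: int = 200
    rho_max: float = -0.3
    cryptic_min_intron: int = 50000
    cryptic_min_up: int = 10
    cryptic_min_down: int = 2
    cryptic_min_fold: float = 1.0
    motif: str = "AGGT"
    strandedness: Strandedness = "forward"

    def replace(self, **kwargs) -> "PipelineThresholds":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
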