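"""Co-occurrence of region catalogs with a TF occupancy cistrome.

Colocalization is declared at >= 1 bp overlap by default.  The odds-ratio /
Fisher contrast is an artifact addition on top of raw percentages and is
flagged as such in its output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .intervals import IntervalSet, filter_overlapping

__all__ = ["ColocalizationResult", "colocalize", "colocalization_contrast"]


@dataclass(frozen=True)
class ColocalizationResult:
    category: str
    n_regions: int
    n_colocalized: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_colocalized <= self.n_regions:
            raise ValidationError("n_colocalized must be within [0, n_regions]")

    @property
    def percent(self) -> float:
        """100 x n_colocalized / n_regions, reported to one decimal."""
        return round(100.0 * self.n_colocalized / self.n_regions, 1)


@dataclass(frozen=True)
class ColocalizationContrast:
    percent_difference: float
    odds_ratio: float | None
    p_value: float
    odds_ratio_defined: bool
    note: str = "statistical contrast is an addition beyond raw percentages"


def colocalize(regions: IntervalSet, occupancy: IntervalSet,
               min_overlap_bp: int = 1,
               category: str = "custom") -> ColocalizationResult:
    """Fraction of regions sharing >= ``min_overlap_bp`` bases with occupancy."""
    if len(regions) == 0:
        raise ValidationError("regions set is empty")
    hits = filter_overlapping(regions, occupancy, min_overlap_bp)
    return ColocalizationResult(category=category, n_regions=len(regions),
                                n_colocalized=len(hits))


def colocalization_contrast(a: ColocalizationResult,
                            b: ColocalizationResult) -> ColocalizationContrast:
    """2x2 Fisher exact contrast of two colocalization results."""
    table = [
        [a.n_colocalized, a.n_regions - a.n_colocalized],
        [b.n_colocalized, b.n_regions - b.n_colocalized],
    ]
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    num = table[0][0] * table[1][1]
    den = table[0][1] * table[1][0]
    defined = den > 0
    odds_ratio = num / den if defined else None
    return ColocalizationContrast(
        percent_difference=a.percent - b.percent,
        odds_ratio=odds_ratio,
        p_value=float(p_value),
        odds_ratio_defined=defined,
    )
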