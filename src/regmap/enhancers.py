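"""Putative-enhancer calling and super-enhancer stitching.

A putative enhancer is a region positive for both H3K27ac and H3K4me1 in
the same specimen.  Two call modes are provided because the double-positive
definition can be read two ways:

``double_positive_union`` (default)
    Merge the two mark tracks together (gap 0) and keep union intervals
    that contain at least one peak of *each* mark.
``intersection``
    Exact base-pair AND of the two tracks.

Super enhancers are stitched from H3K27ac peaks alone: peaks within
``stitch_gap`` (default 12,500 bp) are merged and the stitched span must be
strictly larger than ``size_threshold`` (default 15,000 bp).  This is a
purely geometric rule — deliberately not ROSE-style signal ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .intervals import (
    GenomicInterval,
    IntervalSet,
    consensus,
    filter_overlapping,
    intersect_regions,
    merge,
)

__all__ = [
    "SuperEnhancer",
    "EnhancerCatalog",
    "call_putative_enhancers",
    "build_catalog",
    "call_super_enhancers",
    "common_super_enhancers",
]

DEFAULT_STITCH_GAP = 12_500
DEFAULT_SIZE_THRESHOLD = 15_000


@dataclass(frozen=True)
class SuperEnhancer:
    """A stitched H3K27ac cluster exceeding the size threshold."""

    region: GenomicInterval
    n_constituents: int
    constituent_bp: int

    def __post_init__(self) -> None:
        if self.n_constituents < 1:
            raise ValidationError("a super enhancer needs >= 1 constituent peak")
        if self.constituent_bp > len(self.region):
            raise ValidationError("constituent bases cannot exceed the stitched span")


@dataclass
class EnhancerCatalog:
    """Per-sample putative enhancers plus the all-sample common set."""

    per_sample: dict[str, IntervalSet]
    common: IntervalSet
    counts: dict[str, int] = field(default_factory=dict)
    fraction_common: dict[str, float] = field(default_factory=dict)
    mode: str = "double_positive_union"

    @property
    def n_common(self) -> int:
        return len(self.common)


def call_putative_enhancers(h3k27ac: IntervalSet, h3k4me1: IntervalSet,
                            mode: str = "double_positive_union") -> IntervalSet:
    """Call double-positive putative enhancers for one specimen."""
    if len(h3k27ac) == 0 or len(h3k4me1) == 0:
        raise ValidationError("both mark tracks must be non-empty")
    if mode == "intersection":
        return intersect_regions(h3k27ac, h3k4me1)
    if mode != "double_positive_union":
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = IntervalSet(list(h3k27ac) + list(h3k4me1))
    union = merge(pooled, max_gap=0)
    with_k27 = {(iv.chrom, iv.start, iv.end)
                for iv in filter_overlapping(union, h3k27ac)}
    with_k4 = {(iv.chrom, iv.start, iv.end)
               for iv in filter_overlapping(union, h3k4me1)}
    both = [iv for iv in union if (iv.chrom, iv.start, iv.end) in (with_k27 & with_k4)]
    return IntervalSet(both, sample_id=h3k27ac.sample_id,
                       track_label="putative_enhancer", canonical=True)


def build_catalog(per_sample_enhancers: Mapping[str, IntervalSet],
                  mode: str = "double_positive_union") -> EnhancerCatalog:
    """Derive the common enhancer set (present in every sample) and
    per-sample accounting."""
    sample_ids = list(per_sample_enhancers)
    if len(sample_ids) != len(set(sample_ids)):
        raise ValidationError("duplicate sample ids")
    if len(sample_ids) < 2:
        raise ValidationError("catalog requires >= 2 samples")
    sets = [per_sample_enhancers[s] for s in sample_ids]
    common = consensus(sets, min_samples=len(sets))
    counts = {s: len(per_sample_enhancers[s]) for s in sample_ids}
    fraction_common: dict[str, float] = {}
    for s in sample_ids:
        own = per_sample_enhancers[s]
        if len(own) == 0:
            fraction_common[s] = 0.0
        else:
            hits = filter_overlapping(own, common)
            fraction_common[s] = len(hits) / len(own)
    return EnhancerCatalog(per_sample=dict(per_sample_enhancers), common=common,
                           counts=counts, fraction_common=fraction_common, mode=mode)


def call_super_enhancers(h3k27ac_peaks: IntervalSet,
                         stitch_gap: int = DEFAULT_STITCH_GAP,
                         size_threshold: int = DEFAULT_SIZE_THRESHOLD,
                         ) -> list[SuperEnhancer]:
    """Stitch H3K27ac peaks (gap <= ``stitch_gap``) and keep spans strictly
    larger than ``size_threshold``."""
    if stitch_gap <= 0 or size_threshold <= 0:
        raise ValidationError("stitch_gap and size_threshold must be positive")
    if not h3k27ac_peaks.is_canonical():
        h3k27ac_peaks = h3k27ac_peaks.canonicalize()
    stitched = merge(h3k27ac_peaks, max_gap=stitch_gap)
    out: list[SuperEnhancer] = []
    for region in stitched:
        if len(region) <= size_threshold:
            continue
        members = [iv for iv in h3k27ac_peaks
                   if iv.chrom == region.chrom
                   and iv.start >= region.start and iv.end <= region.end]
        out.append(SuperEnhancer(region=region, n_constituents=len(members),
                                 constituent_bp=sum(len(iv) for iv in members)))
    out.sort(key=lambda se: (se.region.chrom, se.region.start))
    return out


def common_super_enhancers(per_sample: Mapping[str, Sequence[SuperEnhancer]],
                           ) -> IntervalSet:
    """Consensus (all samples) over per-sample stitched super-enhancer spans."""
    if len(per_sample) < 2:
        raise ValidationError("requires >= 2 samples")
    sets = []
    for sample_id, ses in per_sample.items():
        if not ses:
            raise ValidationError(f"sample {sample_id!r} has no super enhancers")
        sets.append(IntervalSet([se.region for se in ses], sample_id=sample_id,
                                canonical=True))
    return consensus(sets, min_samples=len(sets))
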