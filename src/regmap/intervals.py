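"""Genomic interval data model and exact set operations.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Strand is ignored for peak math (histone marks are
unstranded); chromosome names are compared by exact string equality.

The merge-gap semantics mirror ``bedtools merge -d``: two intervals are
joined when ``later.start - earlier.end <= max_gap``, so book-ended
intervals merge at ``max_gap = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .errors import ParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "OverlapReport",
    "read_bed",
    "write_bed",
    "merge",
    "intersect_regions",
    "filter_overlapping",
    "consensus",
    "overlap_report",
    "normalize_chrom",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open region ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(
                f"start must be non-negative, got {self.start}"
            )
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalSet:
    """An ordered collection of intervals from one sample and track.

    A *canonical* set is sorted by ``(chrom, start, end)`` and contains no
    overlapping or book-ended intervals on the same chromosome.  Readers
    return *raw* sets preserving file order; most set operations require
    canonical inputs and produce canonical outputs.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    sample_id: str | None = None
    track_label: str | None = None
    canonical: bool = False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def sorted(self) -> "IntervalSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return replace(self, intervals=ivs)

    def canonicalize(self) -> "IntervalSet":
        """Sort and merge overlapping/book-ended intervals (gap 0)."""
        out = merge(self, max_gap=0)
        out.sample_id = self.sample_id
        out.track_label = self.track_label
        return out

    def is_canonical(self) -> bool:
        prev: GenomicInterval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start <= prev.end or (iv.chrom, iv.start, iv.end) < (
                    prev.chrom,
                    prev.start,
                    prev.end,
                ):
                    return False
            elif prev is not None and iv.chrom < prev.chrom:
                return False
            prev = iv
        return True


@dataclass(frozen=True)
class OverlapReport:
    """Counts of query intervals overlapped by a subject set."""

    n_query: int
    n_overlapping: int

    def __post_init__(self) -> None:
        if self.n_overlapping > self.n_query:
            raise ValidationError("n_overlapping cannot exceed n_query")

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_query


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("bed3", "bed6", "narrowPeak")


def read_bed(path, dialect: str = "bed6", sample_id: str | None = None,
             track_label: str | None = None) -> IntervalSet:
    """Read a BED3/BED6/narrowPeak file into a raw :class:`IntervalSet`.

    Row order is preserved and no merging is performed.  narrowPeak's
    ``signalValue`` (column 7) is mapped onto ``score``.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >=3 tab-separated fields", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path, lineno) from None
            name = None
            score = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ParseError("narrowPeak requires 10 fields", path, lineno)
                name = fields[3] if fields[3] != "." else None
                score = float(fields[6])
            elif dialect == "bed6" and len(fields) >= 4:
                name = fields[3] if fields[3] != "." else None
                if len(fields) >= 5 and fields[4] not in (".", ""):
                    score = float(fields[4])
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name, score))
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno) from None
    return IntervalSet(intervals, sample_id=sample_id, track_label=track_label)


def write_bed(iset: IntervalSet, path) -> None:
    """Write a set as BED (bed6 when any interval carries a name, else bed3)."""
    use_bed6 = any(iv.name is not None or iv.score is not None for iv in iset)
    with open(path, "w") as fh:
        for iv in iset:
            if use_bed6:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------

def merge(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is ``<= max_gap`` (bedtools ``-d`` semantics).

    Accepts raw input; the result is canonical for ``max_gap == 0`` and is
    always sorted and non-overlapping.  Idempotent for any fixed gap.
    """
    if max_gap < 0:
        raise ValidationError(f"max_gap must be non-negative, got {max_gap}")
    ivs = sorted(iset.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in ivs:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= max_gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                out.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(cur)
    return IntervalSet(out, sample_id=iset.sample_id,
                       track_label=iset.track_label, canonical=True)


def _require_canonical(iset: IntervalSet, role: str) -> None:
    if not iset.is_canonical():
        raise ValidationError(f"{role} set must be canonical (sorted, non-overlapping)")


def intersect_regions(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact base-pair intersection of two canonical sets."""
    _require_canonical(a, "first")
    _require_canonical(b, "second")
    out: list[GenomicInterval] = []
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    by_chrom_a: dict[str, list[GenomicInterval]] = {}
    for iv in a:
        by_chrom_a.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
        xs, ys = by_chrom_a[chrom], by_chrom_b[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out, canonical=True)


def filter_overlapping(query: IntervalSet, subject: IntervalSet,
                       min_overlap_bp: int = 1) -> IntervalSet:
    """Return query intervals (whole) sharing >= ``min_overlap_bp`` bases
    with at least one subject interval."""
    if min_overlap_bp < 1:
        raise ValidationError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    _require_canonical(query, "query")
    _require_canonical(subject, "subject")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in subject:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept: list[GenomicInterval] = []
    for q in query:
        subs = by_chrom.get(q.chrom, ())
        for s in subs:
            if s.start >= q.end:
                break
            if min(q.end, s.end) - max(q.start, s.start) >= min_overlap_bp:
                kept.append(q)
                break
    return IntervalSet(kept, sample_id=query.sample_id,
                       track_label=query.track_label, canonical=True)


def consensus(sets: Sequence[IntervalSet], min_samples: int) -> IntervalSet:
    """Intervals of the pooled merged union supported by >= ``min_samples``
    distinct input sets (>= 1 bp overlap each)."""
    if not sets:
        raise ValidationError("consensus requires at least one set")
    if not 1 <= min_samples <= len(sets):
        raise ValidationError(
            f"min_samples must be in [1, {len(sets)}], got {min_samples}"
        )
    pooled = IntervalSet([iv for s in sets for iv in s])
    union = merge(pooled, max_gap=0)
    kept: list[GenomicInterval] = []
    for u in union:
        support = 0
        for s in sets:
            if any(u.overlap_bp(iv) > 0 for iv in s):
                support += 1
                if support >= min_samples:
                    break
        if support >= min_samples:
            kept.append(u)
    return IntervalSet(kept, canonical=True)


def overlap_report(query: IntervalSet, subject: IntervalSet,
                   min_overlap_bp: int = 1) -> OverlapReport:
    """Fraction of query intervals overlapped by the subject set."""
    if len(query) == 0:
        raise ValidationError("overlap_report requires a non-empty query set")
    hits = filter_overlapping(query, subject, min_overlap_bp)
    return OverlapReport(n_query=len(query), n_overlapping=len(hits))


def normalize_chrom(name: str) -> str:
    """Optional helper mapping e.g. ``1`` -> ``chr1``; off by default everywhere."""
    return name if name.startswith("chr") else f"chr{name}"
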