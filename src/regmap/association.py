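"""Enhancer-gene association by TSS window and by chromatin-loop anchors,
plus FPKM expression binning and per-bin association fractions.

Bins partition [0, inf): inactive FPKM < 1; low 1 <= FPKM < 5;
mid 5 <= FPKM < 15; high FPKM >= 15.  Boundary values land in the upper
bin.  Association fractions are computed over enhancers (an enhancer with
>= 1 link to a gene of a bin counts toward that bin; bins need not sum
to 1).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "GeneModel",
    "ExpressionTable",
    "ChromatinLoop",
    "EnhancerGeneLink",
    "BIN_LABELS",
    "DEFAULT_BIN_EDGES",
    "bin_expression",
    "associate_by_window",
    "associate_by_loop",
    "association_fractions",
    "read_genes",
    "read_loops",
]

BIN_LABELS = ("inactive", "low", "mid", "high")
DEFAULT_BIN_EDGES = (1.0, 5.0, 15.0)
DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError("tss must be non-negative")

    @classmethod
    def from_span(cls, gene_id: str, chrom: str, strand: str,
                  start: int, end: int) -> "GeneModel":
        """TSS from a stranded span: plus strand -> start; minus -> end - 1."""
        tss = start if strand == "+" else end - 1
        return cls(gene_id, chrom, strand, tss)


@dataclass
class ExpressionTable:
    """Gene x sample non-negative expression matrix (FPKM or counts)."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    assay_note: str = "FPKM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, assay_note: str = "FPKM"):
        return cls(genes=list(frame.index), samples=list(frame.columns),
                   values=frame.to_numpy(dtype=float), assay_note=assay_note)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @classmethod
    def read_tsv(cls, path, assay_note: str = "FPKM"):
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame, assay_note=assay_note)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class ChromatinLoop:
    """A pair of interacting Hi-C anchors on one chromosome."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValidationError("loop anchors must share a chromosome")
        if self.anchor_a.overlap_bp(self.anchor_b) > 0:
            raise ValidationError("loop anchors must not overlap")


@dataclass(frozen=True)
class EnhancerGeneLink:
    enhancer: GenomicInterval
    gene_id: str
    distance: int
    evidence: str  # window | loop | both
    gene_bin: str | None = None


# ---------------------------------------------------------------------------
# Expression binning
# ---------------------------------------------------------------------------

def bin_expression(table: ExpressionTable,
                   sample_summary: str = "mean",
                   edges: Sequence[float] = DEFAULT_BIN_EDGES,
                   ) -> dict[str, str] | dict[str, dict[str, str]]:
    """Assign each gene one bin from its mean FPKM (default) or per sample."""
    if len(table.genes) == 0:
        raise ValidationError("expression table is empty")
    lo, mid, hi = edges

    def classify(v: float) -> str:
        if v >= hi:
            return "high"
        if v >= mid:
            return "mid"
        if v >= lo:
            return "low"
        return "inactive"

    if sample_summary == "mean":
        means = table.values.mean(axis=1)
        return {g: classify(v) for g, v in zip(table.genes, means)}
    if sample_summary == "per_sample":
        return {
            s: {g: classify(table.values[i, j]) for i, g in enumerate(table.genes)}
            for j, s in enumerate(table.samples)
        }
    raise ValidationError(f"unknown sample_summary {sample_summary!r}")


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def _enh_distance(enh: GenomicInterval, tss: int, anchor: str) -> int:
    if anchor == "midpoint":
        return abs((enh.start + enh.end) // 2 - tss)
    if anchor == "edge":
        if enh.start <= tss < enh.end:
            return 0
        return min(abs(enh.start - tss), abs(enh.end - 1 - tss))
    raise ValidationError(f"unknown anchor mode {anchor!r}")


def associate_by_window(enhancers: IntervalSet, genes: Sequence[GeneModel],
                        window: int = DEFAULT_WINDOW,
                        anchor: str = "midpoint") -> list[EnhancerGeneLink]:
    """Link every (enhancer, gene) pair whose distance is <= ``window``.

    Uses a sorted-TSS bisect per chromosome; equivalent to the all-pairs
    scan.
    """
    if window <= 0:
        raise ValidationError(f"window must be positive, got {window}")
    by_chrom: dict[str, list[tuple[int, GeneModel]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t[0])
    links: list[EnhancerGeneLink] = []
    for enh in enhancers:
        cands = by_chrom.get(enh.chrom)
        if not cands:
            continue
        tss_list = [t for t, _ in cands]
        # any distance-qualifying TSS lies within [start - window, end + window)
        lo = bisect.bisect_left(tss_list, enh.start - window)
        hi = bisect.bisect_right(tss_list, enh.end + window)
        for tss, gene in cands[lo:hi]:
            d = _enh_distance(enh, tss, anchor)
            if d <= window:
                links.append(EnhancerGeneLink(enh, gene.gene_id, d, "window"))
    return links


def associate_by_loop(enhancers: IntervalSet, genes: Sequence[GeneModel],
                      loops: Sequence[ChromatinLoop],
                      window_links: Sequence[EnhancerGeneLink] = (),
                      anchor: str = "midpoint") -> list[EnhancerGeneLink]:
    """Link an enhancer to a gene when the enhancer overlaps one loop anchor
    and the gene TSS lies inside the other.

    Pre-computed window links may be supplied; pairs supported by both
    routes are returned once with ``evidence='both'``.
    """
    loop_pairs: dict[tuple, int] = {}
    for loop in loops:
        for enh_anchor, tss_anchor in ((loop.anchor_a, loop.anchor_b),
                                       (loop.anchor_b, loop.anchor_a)):
            for enh in enhancers:
                if enh.overlap_bp(enh_anchor) == 0:
                    continue
                for g in genes:
                    if g.chrom != tss_anchor.chrom:
                        continue
                    if tss_anchor.start <= g.tss < tss_anchor.end:
                        key = (enh.chrom, enh.start, enh.end, g.gene_id)
                        d = _enh_distance(enh, g.tss, anchor)
                        loop_pairs.setdefault(key, d)
    window_keys = {
        (lk.enhancer.chrom, lk.enhancer.start, lk.enhancer.end, lk.gene_id): lk
        for lk in window_links
    }
    out: list[EnhancerGeneLink] = []
    for key, d in loop_pairs.items():
        chrom, start, end, gene_id = key
        evidence = "both" if key in window_keys else "loop"
        out.append(EnhancerGeneLink(GenomicInterval(chrom, start, end),
                                    gene_id, d, evidence))
    for key, lk in window_keys.items():
        if key not in loop_pairs:
            out.append(lk)
    return out


def association_fractions(links: Sequence[EnhancerGeneLink],
                          enhancers: IntervalSet,
                          bins: Mapping[str, str]) -> dict[str, float]:
    """Per-bin fraction of enhancers with >= 1 link to a gene of that bin."""
    if len(enhancers) == 0:
        raise ValidationError("enhancer set is empty")
    linked: dict[str, set[tuple]] = {label: set() for label in BIN_LABELS}
    for lk in links:
        label = bins.get(lk.gene_id)
        if label is None:
            continue
        key = (lk.enhancer.chrom, lk.enhancer.start, lk.enhancer.end)
        linked[label].add(key)
    n = len(enhancers)
    return {label: len(keys) / n for label, keys in linked.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genes(path) -> list[GeneModel]:
    """Read gene models from 4-column TSV (gene_id, chrom, strand, tss) or
    6-column BED (TSS derived from the stranded span)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) >= 6 and fields[5] in ("+", "-"):
                    genes.append(GeneModel.from_span(
                        fields[3], fields[0], fields[5],
                        int(fields[1]), int(fields[2])))
                elif len(fields) >= 4:
                    if lineno == 1 and fields[0] == "gene_id":
                        continue
                    genes.append(GeneModel(fields[0], fields[1], fields[2],
                                           int(fields[3])))
                else:
                    raise ParseError("expected 4-column TSV or 6-column BED",
                                     path, lineno)
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path, lineno) from None
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def read_loops(path, sample_id: str | None = None) -> list[ChromatinLoop]:
    """Read chromatin loops from BEDPE (chrom1 start1 end1 chrom2 start2 end2)."""
    loops: list[ChromatinLoop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("BEDPE needs >= 6 fields", path, lineno)
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                loops.append(ChromatinLoop(a, b, sample_id=sample_id))
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path, lineno) from None
    return loops


def write_loops(loops: Iterable[ChromatinLoop], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor_a, lp.anchor_b
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def write_links(links: Iterable[EnhancerGeneLink], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\tdistance\tevidence\tgene_bin\n")
        for lk in links:
            e = lk.enhancer
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{lk.gene_id}\t"
                     f"{lk.distance}\t{lk.evidence}\t{lk.gene_bin or '.'}\n")
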