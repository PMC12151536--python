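"""Independent brute-force oracles used to verify the implementations.

These deliberately avoid the package's sweep-line/bisect code paths: they
enumerate per-base boolean masks or all pairs, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

from regmap.intervals import GenomicInterval, IntervalSet


def mask_of(intervals, chrom: str, chrom_len: int) -> np.ndarray:
    """Per-base boolean coverage mask of one chromosome."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start:min(iv.end, chrom_len)] = True
    return mask


def mask_to_intervals(mask: np.ndarray, chrom: str) -> list[GenomicInterval]:
    """Maximal runs of True as intervals (the canonical form of a mask)."""
    out = []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def merge_oracle(intervals, max_gap: int, chrom: str,
                 chrom_len: int) -> list[GenomicInterval]:
    """Definition-based gap merge: dilate the mask by max_gap, take runs,
    then trim each run back to covered bases at its flanks."""
    mask = mask_of(intervals, chrom, chrom_len + max_gap + 1)
    covered = np.flatnonzero(mask)
    if covered.size == 0:
        return []
    out = []
    run_start = covered[0]
    prev = covered[0]
    for pos in covered[1:]:
        if pos - prev - 1 > max_gap:  # gap of uncovered bases exceeds max_gap
            out.append(GenomicInterval(chrom, int(run_start), int(prev) + 1))
            run_start = pos
        prev = pos
    out.append(GenomicInterval(chrom, int(run_start), int(prev) + 1))
    return out


def intersect_oracle(a, b, chrom: str, chrom_len: int) -> list[GenomicInterval]:
    return mask_to_intervals(
        mask_of(a, chrom, chrom_len) & mask_of(b, chrom, chrom_len), chrom)


def filter_overlap_oracle(query, subject, min_overlap_bp: int = 1):
    """All-pairs overlap scan."""
    kept = []
    for q in query:
        if any(q.overlap_bp(s) >= min_overlap_bp for s in subject):
            kept.append(q)
    return kept


def consensus_oracle(sets, min_samples: int, chrom: str, chrom_len: int):
    """Union runs supported by >= min_samples sets (per-interval check)."""
    pooled = [iv for s in sets for iv in s]
    union = mask_to_intervals(mask_of(pooled, chrom, chrom_len), chrom)
    kept = []
    for u in union:
        support = sum(1 for s in sets if any(u.overlap_bp(iv) > 0 for iv in s))
        if support >= min_samples:
            kept.append(u)
    return kept


def window_links_oracle(enhancers, genes, window: int, anchor: str):
    """All-pairs enhancer-gene scan; returns {(chrom,start,end,gene_id): dist}."""
    out = {}
    for enh in enhancers:
        for g in genes:
            if g.chrom != enh.chrom:
                continue
            if anchor == "midpoint":
                d = abs((enh.start + enh.end) // 2 - g.tss)
            else:
                if enh.start <= g.tss < enh.end:
                    d = 0
                else:
                    d = min(abs(enh.start - g.tss), abs(enh.end - 1 - g.tss))
            if d <= window:
                out[(enh.chrom, enh.start, enh.end, g.gene_id)] = d
    return out


def random_interval_set(rng, chrom: str = "chrT", chrom_len: int = 100_000,
                        n_max: int = 20, max_len: int = 5_000,
                        canonical: bool = False) -> IntervalSet:
    n = int(rng.integers(1, n_max + 1))
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, min(start + length, chrom_len)))
    iset = IntervalSet(ivs)
    return iset.canonicalize() if canonical else iset


def fisher_oracle_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration (n <= ~50)."""
    from math import comb

    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> float:
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)
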