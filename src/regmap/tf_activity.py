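"""Signature-based TF activity scoring and correlation with a target gene.

The per-specimen activity score (T-score) is a Welch two-sample
t-statistic comparing that specimen's per-gene z-scores of the signature's
up genes against its down genes (or against all non-signature genes when
the down list is empty).  The exact upstream formula is not public, so
this standard signature-scoring construction is used as a documented,
pluggable stand-in.

Also provides the bulk count normalization (scale each sample by
``target / total_mapped_pairs``, target 56.5 million pairs) and the strict
mean-normalized-count > 1 expressed-gene filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import ExpressionTable
from .errors import ValidationError

__all__ = [
    "GeneSignature",
    "ActivityScores",
    "CorrelationResult",
    "TARGET_MAPPED_PAIRS",
    "scale_counts",
    "filter_expressed",
    "compute_tscores",
    "correlate_activity",
    "read_signature",
]

TARGET_MAPPED_PAIRS = 56.5e6


@dataclass
class GeneSignature:
    """Up/down gene lists defining a TF activity signature."""

    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)
    source_note: str = ""

    def __post_init__(self) -> None:
        up = {g.upper() for g in self.up_genes}
        down = {g.upper() for g in self.down_genes}
        if up & down:
            raise ValidationError(
                f"up and down lists overlap: {sorted(up & down)[:5]}"
            )
        if not self.up_genes:
            raise ValidationError("up gene list must be non-empty")


@dataclass
class ActivityScores:
    samples: list[str]
    t_score: np.ndarray
    n_up_used: int = 0
    n_down_used: int = 0
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_score = np.asarray(self.t_score, dtype=float)
        if len(self.samples) != self.t_score.shape[0]:
            raise ValidationError("score length must match sample list")
        if not np.all(np.isfinite(self.t_score)):
            raise ValidationError("T-scores must be finite")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError("|r| must be <= 1")
        if self.n < 3:
            raise ValidationError("correlation needs n >= 3")


def scale_counts(counts: pd.DataFrame, total_mapped_pairs: Sequence[float],
                 target: float = TARGET_MAPPED_PAIRS) -> pd.DataFrame:
    """Multiply each sample column by ``target / total_mapped_pairs``."""
    totals = np.asarray(total_mapped_pairs, dtype=float)
    if totals.shape[0] != counts.shape[1]:
        raise ValidationError("one total per sample column required")
    if np.any(totals <= 0):
        raise ValidationError("total mapped pairs must be positive")
    return counts * (target / totals)


def filter_expressed(normalized: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Keep genes whose mean normalized count across samples is strictly
    greater than ``min_mean``."""
    keep = normalized.mean(axis=1) > min_mean
    return normalized.loc[keep]


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-scores across samples; returns (z, usable_row_mask)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    usable = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    return z, usable


def compute_tscores(expression: ExpressionTable, signature: GeneSignature,
                    ) -> ActivityScores:
    """Per-sample Welch t-statistic of up-gene vs down-gene z-scores.

    Signature gene symbols are matched case-insensitively (mouse symbols
    match their human orthologs by symbol).  Constant genes are dropped
    with a warning; swapping up and down negates every score exactly.
    """
    if len(expression.samples) < 3:
        raise ValidationError("need >= 3 samples")
    index = {g.upper(): i for i, g in enumerate(expression.genes)}
    z, usable = _zscore_rows(expression.values)

    def resolve(symbols: Sequence[str]) -> tuple[list[int], list[str]]:
        rows, missing = [], []
        for s in symbols:
            i = index.get(s.upper())
            if i is None:
                missing.append(s)
            elif usable[i]:
                rows.append(i)
            else:
                missing.append(s)
                warnings.warn(f"signature gene {s!r} has zero variance; dropped",
                              stacklevel=2)
        return rows, missing

    up_rows, up_missing = resolve(signature.up_genes)
    if signature.down_genes:
        down_rows, down_missing = resolve(signature.down_genes)
    else:
        sig_upper = {g.upper() for g in signature.up_genes}
        down_rows = [i for g, i in index.items() if g not in sig_upper and usable[i]]
        down_missing = []
    if len(up_rows) < 2 or len(down_rows) < 2:
        raise ValidationError(
            "need >= 2 usable genes on each side; "
            f"missing/dropped: up={up_missing}, down={down_missing}"
        )
    t = stats.ttest_ind(z[up_rows, :], z[down_rows, :], axis=0,
                        equal_var=False).statistic
    return ActivityScores(samples=list(expression.samples), t_score=t,
                          n_up_used=len(up_rows), n_down_used=len(down_rows),
                          missing_genes=up_missing + down_missing)


def correlate_activity(scores: ActivityScores,
                       target_expression: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of activity scores with target-gene expression."""
    y = np.asarray(target_expression, dtype=float)
    x = scores.t_score
    if y.shape[0] != x.shape[0]:
        raise ValidationError("sample count mismatch")
    if x.shape[0] < 3:
        raise ValidationError("need >= 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=x.shape[0],
                             p_value=float(res.pvalue))


def read_signature(path, source_note: str = "") -> GeneSignature:
    """Two-column TSV: gene_id <tab> direction in {up, down}."""
    up, down = [], []
    frame = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "direction"],
                        comment="#")
    if len(frame) and tuple(frame.iloc[0]) == ("gene_id", "direction"):
        frame = frame.iloc[1:]
    for _, row in frame.iterrows():
        if row.direction == "up":
            up.append(str(row.gene_id))
        elif row.direction == "down":
            down.append(str(row.gene_id))
        else:
            raise ValidationError(f"direction must be up/down, got {row.direction!r}")
    return GeneSignature(up_genes=up, down_genes=down, source_note=source_note)
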