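"""CRISPRa Perturb-seq analysis: gRNA-to-cell assignment, singlet
filtering, depth normalization, activation calling and differential
expression versus non-targeting control cells.

Rules: a gRNA is detected in a cell at count >= ``min_count`` (default 1);
cells with more than one detected gRNA species are excluded from
comparisons; activation requires fold change strictly greater than 1.5;
differential-expression hits additionally require Benjamini-Hochberg
adjusted p < 0.05 from a two-sided Wilcoxon rank-sum test.

Depth normalization is a documented stand-in (median library size then
log1p) for the variance-stabilizing transform used upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "PerturbDataset",
    "CellAssignment",
    "ActivationCall",
    "assign_grnas",
    "filter_singlets",
    "normalize_cells",
    "call_activation",
    "differential_expression",
    "benjamini_hochberg",
]

FC_EPS = 1e-9
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_ALPHA = 0.05


@dataclass
class PerturbDataset:
    """Paired gRNA x cell and gene x cell count matrices."""

    grna_counts: pd.DataFrame
    expression: pd.DataFrame
    grna_targets: dict[str, str]
    control_label: str

    def __post_init__(self) -> None:
        if list(self.grna_counts.columns) != list(self.expression.columns):
            raise ValidationError("matrices must share identical cell columns")
        if (self.grna_counts.to_numpy() < 0).any() or (
                self.expression.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.control_label not in self.grna_targets:
            raise ValidationError(
                f"control label {self.control_label!r} absent from grna_targets")
        unknown = set(self.grna_counts.index) - set(self.grna_targets)
        if unknown:
            raise ValidationError(f"gRNAs without target annotation: {sorted(unknown)}")

    @property
    def cells(self) -> list[str]:
        return list(self.expression.columns)


@dataclass(frozen=True)
class CellAssignment:
    cell_id: str
    detected_grnas: frozenset[str]
    multiplicity_class: str  # none | singlet | multiplet

    def __post_init__(self) -> None:
        n = len(self.detected_grnas)
        expected = "none" if n == 0 else ("singlet" if n == 1 else "multiplet")
        if self.multiplicity_class != expected:
            raise ValidationError("multiplicity class inconsistent with gRNA set")


@dataclass(frozen=True)
class ActivationCall:
    grna_id: str
    gene_id: str
    fold_change: float
    adjusted_p: float | None
    activated: bool
    n_perturbed: int = 0
    n_control: int = 0
    p_value: float | None = None
    all_tied: bool = False


def assign_grnas(grna_counts: pd.DataFrame, min_count: int = 1,
                 ) -> list[CellAssignment]:
    """Detect gRNAs per cell at ``count >= min_count`` and classify
    multiplicity (none / singlet / multiplet)."""
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    values = grna_counts.to_numpy()
    if (values < 0).any():
        raise ValidationError("gRNA counts must be non-negative")
    grnas = np.asarray(grna_counts.index)
    out: list[CellAssignment] = []
    detected = values >= min_count
    for j, cell in enumerate(grna_counts.columns):
        hits = frozenset(grnas[detected[:, j]])
        n = len(hits)
        cls = "none" if n == 0 else ("singlet" if n == 1 else "multiplet")
        out.append(CellAssignment(cell_id=str(cell), detected_grnas=hits,
                                  multiplicity_class=cls))
    return out


def multiplicity_fractions(assignments: Sequence[CellAssignment]) -> dict[str, float]:
    n = len(assignments)
    counts = {"none": 0, "singlet": 0, "multiplet": 0}
    for a in assignments:
        counts[a.multiplicity_class] += 1
    return {k: v / n for k, v in counts.items()}


def filter_singlets(assignments: Sequence[CellAssignment],
                    dataset: PerturbDataset) -> tuple[PerturbDataset, dict[str, int]]:
    """Keep singlet cells only; returns the subset and per-gRNA cell counts."""
    by_cell = {a.cell_id: a for a in assignments}
    missing = [c for c in dataset.cells if c not in by_cell]
    if missing:
        raise ValidationError(f"assignments missing for cells: {missing[:5]}")
    keep = [c for c in dataset.cells
            if by_cell[c].multiplicity_class == "singlet"]
    grna_of = {c: next(iter(by_cell[c].detected_grnas)) for c in keep}
    counts: dict[str, int] = {g: 0 for g in dataset.grna_counts.index}
    for c in keep:
        counts[grna_of[c]] += 1
    for g, n in counts.items():
        if n == 0:
            warnings.warn(f"gRNA {g!r} has zero singlet cells; excluded from calls",
                          stacklevel=2)
    if not keep:
        warnings.warn("no singlet cells remain after filtering", stacklevel=2)
    subset = PerturbDataset(
        grna_counts=dataset.grna_counts[keep],
        expression=dataset.expression[keep],
        grna_targets=dict(dataset.grna_targets),
        control_label=dataset.control_label,
    )
    return subset, counts


def normalize_cells(expression: pd.DataFrame) -> pd.DataFrame:
    """Scale every cell to the median library size, then log1p.

    Zero-depth cells are dropped with a warning.
    """
    depth = expression.sum(axis=0)
    zero = depth[depth == 0].index
    if len(zero):
        warnings.warn(f"dropping {len(zero)} zero-depth cells", stacklevel=2)
        expression = expression.drop(columns=zero)
        depth = depth.drop(zero)
    if expression.shape[1] == 0:
        return expression.astype(float)
    median_depth = float(np.median(depth.to_numpy()))
    scaled = expression * (median_depth / depth)
    return np.log1p(scaled)


def _split_cells(dataset: PerturbDataset, assignments: Sequence[CellAssignment],
                 grna_id: str) -> tuple[list[str], list[str]]:
    by_cell = {a.cell_id: a for a in assignments}
    pert, ctrl = [], []
    for c in dataset.cells:
        a = by_cell.get(c)
        if a is None or a.multiplicity_class != "singlet":
            continue
        g = next(iter(a.detected_grnas))
        if g == grna_id:
            pert.append(c)
        elif g == dataset.control_label:
            ctrl.append(c)
    return pert, ctrl


def _fold_change(norm: pd.DataFrame, gene_id: str, pert: list[str],
                 ctrl: list[str]) -> float:
    # back to linear scale so a planted fold change is recovered directly
    pert_mean = float(np.expm1(norm.loc[gene_id, pert]).mean())
    ctrl_mean = float(np.expm1(norm.loc[gene_id, ctrl]).mean())
    return (pert_mean + FC_EPS) / (ctrl_mean + FC_EPS)


def call_activation(dataset: PerturbDataset,
                    assignments: Sequence[CellAssignment],
                    grna_id: str, known_target: str,
                    fc_threshold: float = DEFAULT_FC_THRESHOLD,
                    normalized: pd.DataFrame | None = None) -> ActivationCall:
    """Fold-change activation call for one gRNA's known target gene.

    ``activated`` requires fold change strictly greater than
    ``fc_threshold``.
    """
    if known_target not in dataset.expression.index:
        raise ValidationError(f"target gene {known_target!r} not in expression matrix")
    pert, ctrl = _split_cells(dataset, assignments, grna_id)
    if len(pert) < 3 or len(ctrl) < 3:
        raise ValidationError(
            f"need >= 3 cells per arm, got perturbed={len(pert)}, control={len(ctrl)}")
    if normalized is None:
        normalized = normalize_cells(dataset.expression)
    pert = [c for c in pert if c in normalized.columns]
    ctrl = [c for c in ctrl if c in normalized.columns]
    fc = _fold_change(normalized, known_target, pert, ctrl)
    return ActivationCall(grna_id=grna_id, gene_id=known_target, fold_change=fc,
                          adjusted_p=None, activated=fc > fc_threshold,
                          n_perturbed=len(pert), n_control=len(ctrl))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.shape[0]
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_expression(dataset: PerturbDataset,
                            assignments: Sequence[CellAssignment],
                            grna_id: str,
                            fc_threshold: float = DEFAULT_FC_THRESHOLD,
                            alpha: float = DEFAULT_ALPHA,
                            normalized: pd.DataFrame | None = None,
                            ) -> list[ActivationCall]:
    """Per-gene Wilcoxon rank-sum (gRNA singlets vs control singlets) with
    BH adjustment; hits need FC > ``fc_threshold`` and adjusted p < ``alpha``.

    Returns calls ranked by adjusted p then descending \\|log FC\\|.
    """
    if dataset.expression.shape[0] < 2:
        raise ValidationError("need >= 2 genes")
    pert, ctrl = _split_cells(dataset, assignments, grna_id)
    if len(pert) < 3 or len(ctrl) < 3:
        raise ValidationError(
            f"need >= 3 cells per arm, got perturbed={len(pert)}, control={len(ctrl)}")
    if normalized is None:
        normalized = normalize_cells(dataset.expression)
    pert = [c for c in pert if c in normalized.columns]
    ctrl = [c for c in ctrl if c in normalized.columns]
    x = normalized[pert].to_numpy()
    y = normalized[ctrl].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    tied = np.array([np.all(row == row[0])
                     for row in np.concatenate([x, y], axis=1)])
    p = np.where(tied | ~np.isfinite(p), 1.0, p)
    padj = benjamini_hochberg(p)
    calls: list[ActivationCall] = []
    lin = np.expm1(normalized)
    pert_means = lin[pert].mean(axis=1).to_numpy()
    ctrl_means = lin[ctrl].mean(axis=1).to_numpy()
    fcs = (pert_means + FC_EPS) / (ctrl_means + FC_EPS)
    for i, gene in enumerate(normalized.index):
        calls.append(ActivationCall(
            grna_id=grna_id, gene_id=str(gene), fold_change=float(fcs[i]),
            adjusted_p=float(padj[i]), p_value=float(p[i]),
            activated=bool(fcs[i] > fc_threshold and padj[i] < alpha),
            n_perturbed=len(pert), n_control=len(ctrl), all_tied=bool(tied[i])))
    calls.sort(key=lambda c: (c.adjusted_p, -abs(np.log(max(c.fold_change, FC_EPS)))))
    return calls
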