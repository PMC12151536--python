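"""End-to-end orchestration: config validation, stage execution, run report.

The run report mirrors the per-sample accounting of the source datasets:
interval counts per track, enhancer and super-enhancer counts (per sample
and common), per-bin association fractions, colocalization percentages,
the activity correlation and the perturbation call table.  Every number in
the report is recomputable from the inputs plus the config, and a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .association import (
    ExpressionTable,
    associate_by_loop,
    associate_by_window,
    association_fractions,
    bin_expression,
    read_genes,
    read_loops,
    write_links,
)
from .colocalization import colocalization_contrast, colocalize
from .enhancers import (
    build_catalog,
    call_putative_enhancers,
    call_super_enhancers,
    common_super_enhancers,
)
from .errors import ValidationError
from .intervals import IntervalSet, read_bed, write_bed
from .perturb import (
    PerturbDataset,
    assign_grnas,
    differential_expression,
    filter_singlets,
    multiplicity_fractions,
    normalize_cells,
)
from .tf_activity import compute_tscores, correlate_activity, read_signature

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

DEFAULT_THRESHOLDS = {
    "stitch_gap": 12_500,
    "size_threshold": 15_000,
    "window": 100_000,
    "fpkm_bins": [1.0, 5.0, 15.0],
    "fc_threshold": 1.5,
    "alpha": 0.05,
    "target_depth": 56.5e6,
    "min_overlap": 1,
    "grna_min_count": 1,
}
DEFAULT_MODES = {"enhancer_mode": "double_positive_union", "anchor": "midpoint"}
_KNOWN_KEYS = {"samples", "genes", "expression_fpkm", "occupancy", "loops",
               "signature", "activity_expression", "target_gene", "perturb",
               "thresholds", "modes", "seed", "output_dir"}


@dataclass
class RunConfig:
    samples: list[dict[str, str]]
    genes: str | None = None
    expression_fpkm: str | None = None
    occupancy: str | None = None
    loops: list[str] = field(default_factory=list)
    signature: str | None = None
    activity_expression: str | None = None
    target_gene: str | None = None
    perturb: dict[str, str] | None = None
    thresholds: dict[str, Any] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    modes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MODES))
    seed: int = 0
    output_dir: str = "regmap_out"

    def content_hash(self) -> str:
        """Hash of the analytic settings (thresholds, modes, seed) only —
        deliberately excludes file paths so reports are location-independent."""
        payload = json.dumps({"thresholds": self.thresholds, "modes": self.modes,
                              "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def validate_config(path) -> RunConfig:
    """Parse, default and validate a YAML run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(raw.get("thresholds") or {})
    unknown_thr = set(thresholds) - set(DEFAULT_THRESHOLDS)
    if unknown_thr:
        problems.append(f"unknown thresholds: {sorted(unknown_thr)}")
    for key in ("stitch_gap", "size_threshold", "window", "fc_threshold",
                "alpha", "target_depth", "min_overlap", "grna_min_count"):
        if key in thresholds and not (
                isinstance(thresholds[key], (int, float)) and thresholds[key] > 0):
            problems.append(f"threshold {key} must be a positive number")
    bins = thresholds.get("fpkm_bins", [])
    if (not isinstance(bins, (list, tuple)) or len(bins) != 3
            or list(bins) != sorted(bins)):
        problems.append("fpkm_bins must be three ascending numbers")
    modes = dict(DEFAULT_MODES)
    modes.update(raw.get("modes") or {})
    if modes["enhancer_mode"] not in ("double_positive_union", "intersection"):
        problems.append(f"bad enhancer_mode {modes['enhancer_mode']!r}")
    if modes["anchor"] not in ("midpoint", "edge"):
        problems.append(f"bad anchor {modes['anchor']!r}")
    samples = raw.get("samples") or []
    if not samples:
        problems.append("at least one sample required")
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    for i, sample in enumerate(samples):
        for key in ("id", "h3k27ac", "h3k4me1"):
            if key not in sample:
                problems.append(f"sample #{i}: missing {key!r}")
        for key in ("h3k27ac", "h3k4me1"):
            if key in sample:
                sample[key] = resolve(sample[key])
                if not os.path.exists(sample[key]):
                    problems.append(f"missing file: {sample[key]}")
    file_keys = ("genes", "expression_fpkm", "occupancy", "signature",
                 "activity_expression")
    resolved: dict[str, Any] = {}
    for key in file_keys:
        value = raw.get(key)
        if value is not None:
            value = resolve(value)
            if not os.path.exists(value):
                problems.append(f"missing file: {value}")
        resolved[key] = value
    loops = [resolve(p) for p in (raw.get("loops") or [])]
    for p in loops:
        if not os.path.exists(p):
            problems.append(f"missing file: {p}")
    perturb_cfg = raw.get("perturb")
    if perturb_cfg is not None:
        for key in ("grna_counts", "expression", "targets", "control"):
            if key not in perturb_cfg:
                problems.append(f"perturb: missing {key!r}")
        for key in ("grna_counts", "expression", "targets"):
            if key in perturb_cfg:
                perturb_cfg[key] = resolve(perturb_cfg[key])
                if not os.path.exists(perturb_cfg[key]):
                    problems.append(f"missing file: {perturb_cfg[key]}")
    if problems:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(problems))
    return RunConfig(
        samples=samples, genes=resolved["genes"],
        expression_fpkm=resolved["expression_fpkm"],
        occupancy=resolved["occupancy"], loops=loops,
        signature=resolved["signature"],
        activity_expression=resolved["activity_expression"],
        target_gene=raw.get("target_gene"),
        perturb=perturb_cfg, thresholds=thresholds, modes=modes,
        seed=int(raw.get("seed", 0)),
        output_dir=resolve(raw.get("output_dir", "regmap_out")))


def _round(x: float, nd: int = 10) -> float:
    return round(float(x), nd)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and return the run report dict.

    Per-stage BED/TSV outputs and ``report.json`` are written under
    ``config.output_dir``.
    """
    thr = config.thresholds
    modes = config.modes
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {"tool": "regmap", "version": __version__,
                       "config_hash": config.content_hash(),
                       "seed": config.seed},
        "samples": {},
    }

    def stage(name):
        def wrap(exc):
            return ValidationError(f"stage {name!r}: {exc}")
        return wrap

    # --- intervals + enhancers ------------------------------------------
    per_sample_enh: dict[str, IntervalSet] = {}
    per_sample_k27: dict[str, IntervalSet] = {}
    per_sample_se: dict[str, list] = {}
    for sample in config.samples:
        sid = sample["id"]
        try:
            k27 = read_bed(sample["h3k27ac"],
                           dialect=sample.get("dialect", "bed6"),
                           sample_id=sid, track_label="H3K27ac").canonicalize()
            k4 = read_bed(sample["h3k4me1"],
                          dialect=sample.get("dialect", "bed6"),
                          sample_id=sid, track_label="H3K4me1").canonicalize()
            enh = call_putative_enhancers(k27, k4, mode=modes["enhancer_mode"])
            ses = call_super_enhancers(k27, stitch_gap=int(thr["stitch_gap"]),
                                       size_threshold=int(thr["size_threshold"]))
        except ValidationError as exc:
            raise stage(f"enhancers[{sid}]")(exc) from exc
        per_sample_k27[sid] = k27
        per_sample_enh[sid] = enh
        per_sample_se[sid] = ses
        report["samples"][sid] = {
            "n_h3k27ac": len(k27), "n_h3k4me1": len(k4),
            "n_putative_enhancers": len(enh), "n_super_enhancers": len(ses),
        }
        write_bed(enh, os.path.join(out, f"{sid}.enhancers.bed"))
        write_bed(IntervalSet([se.region for se in ses], canonical=True),
                  os.path.join(out, f"{sid}.superenhancers.bed"))

    common_enh = None
    common_se = None
    if len(per_sample_enh) >= 2:
        catalog = build_catalog(per_sample_enh, mode=modes["enhancer_mode"])
        report["enhancers"] = {
            "mode": modes["enhancer_mode"],
            "n_common": catalog.n_common,
            "fraction_common": {s: _round(f)
                                for s, f in catalog.fraction_common.items()},
        }
        common_enh = catalog.common
        write_bed(common_enh, os.path.join(out, "common.enhancers.bed"))
        if all(per_sample_se.values()):
            common_se = common_super_enhancers(per_sample_se)
            report["super_enhancers"] = {"n_common": len(common_se)}
            write_bed(common_se, os.path.join(out, "common.superenhancers.bed"))

    # --- expression bins + association ----------------------------------
    genes = read_genes(config.genes) if config.genes else None
    bins = None
    if config.expression_fpkm:
        table = ExpressionTable.read_tsv(config.expression_fpkm)
        bins = bin_expression(table, edges=tuple(thr["fpkm_bins"]))
        n_active = sum(1 for b in bins.values() if b != "inactive")
        report["expression"] = {
            "n_genes": len(table.genes), "n_active": n_active,
            "bin_counts": {label: sum(1 for b in bins.values() if b == label)
                           for label in ("inactive", "low", "mid", "high")},
        }
    if genes is not None and bins is not None and common_enh is not None:
        window = int(thr["window"])
        anchor = modes["anchor"]
        loops = [lp for p in config.loops for lp in read_loops(p)]
        report["association"] = {}
        for label, regions in (("enhancers", common_enh),
                               ("super_enhancers", common_se)):
            if regions is None or len(regions) == 0:
                continue
            links = associate_by_window(regions, genes, window=window,
                                        anchor=anchor)
            if loops:
                links = associate_by_loop(regions, genes, loops,
                                          window_links=links, anchor=anchor)
            fractions = association_fractions(links, regions, bins)
            report["association"][label] = {
                "n_links": len(links),
                "n_loop_supported": sum(1 for lk in links
                                        if lk.evidence in ("loop", "both")),
                "fractions": {b: _round(f) for b, f in fractions.items()},
            }
            write_links(links, os.path.join(out, f"{label}.links.tsv"))

    # --- colocalization --------------------------------------------------
    if config.occupancy and common_enh is not None and len(common_enh) > 0:
        occupancy = read_bed(config.occupancy).canonicalize()
        min_ov = int(thr["min_overlap"])
        res_enh = colocalize(common_enh, occupancy, min_ov, category="enhancer")
        report["colocalization"] = {
            "enhancer": {"n": res_enh.n_regions, "n_coloc": res_enh.n_colocalized,
                         "percent": res_enh.percent},
        }
        if common_se is not None and len(common_se) > 0:
            res_se = colocalize(common_se, occupancy, min_ov,
                                category="super_enhancer")
            contrast = colocalization_contrast(res_se, res_enh)
            report["colocalization"]["super_enhancer"] = {
                "n": res_se.n_regions, "n_coloc": res_se.n_colocalized,
                "percent": res_se.percent,
            }
            report["colocalization"]["contrast"] = {
                "percent_difference": _round(contrast.percent_difference),
                "odds_ratio": (None if contrast.odds_ratio is None
                               else _round(contrast.odds_ratio)),
                "fisher_p": _round(contrast.p_value),
                "note": contrast.note,
            }

    # --- TF activity ------------------------------------------------------
    activity_path = config.activity_expression or config.expression_fpkm
    if config.signature and activity_path and config.target_gene:
        signature = read_signature(config.signature)
        table = ExpressionTable.read_tsv(activity_path)
        try:
            scores = compute_tscores(table, signature)
            target_row = [g.upper() for g in table.genes].index(
                config.target_gene.upper())
            corr = correlate_activity(scores, table.values[target_row, :])
        except ValidationError as exc:
            raise stage("tf_activity")(exc) from exc
        report["tf_activity"] = {
            "target_gene": config.target_gene,
            "n_samples": corr.n,
            "r": _round(corr.r), "p_value": _round(corr.p_value),
            "n_up_used": scores.n_up_used, "n_down_used": scores.n_down_used,
        }
        pd.DataFrame({"sample_id": scores.samples,
                      "t_score": scores.t_score}).to_csv(
            os.path.join(out, "tscores.tsv"), sep="\t", index=False)

    # --- perturb ----------------------------------------------------------
    if config.perturb:
        pcfg = config.perturb
        grna_counts = pd.read_csv(pcfg["grna_counts"], sep="\t", index_col=0)
        expression = pd.read_csv(pcfg["expression"], sep="\t", index_col=0)
        targets_frame = pd.read_csv(pcfg["targets"], sep="\t")
        grna_targets = dict(zip(targets_frame.iloc[:, 0].astype(str),
                                targets_frame.iloc[:, 1].astype(str)))
        dataset = PerturbDataset(grna_counts=grna_counts, expression=expression,
                                 grna_targets=grna_targets,
                                 control_label=pcfg["control"])
        assignments = assign_grnas(dataset.grna_counts,
                                   min_count=int(thr["grna_min_count"]))
        fractions = multiplicity_fractions(assignments)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            subset, per_grna = filter_singlets(assignments, dataset)
            normalized = normalize_cells(subset.expression)
        calls = []
        for grna, target in sorted(dataset.grna_targets.items()):
            if grna == dataset.control_label or target not in expression.index:
                continue
            if per_grna.get(grna, 0) < 3:
                continue
            de = differential_expression(
                subset, assignments, grna,
                fc_threshold=float(thr["fc_threshold"]),
                alpha=float(thr["alpha"]), normalized=normalized)
            for call in de:
                if call.gene_id == target:
                    calls.append({
                        "grna": grna, "gene": call.gene_id,
                        "fold_change": _round(call.fold_change),
                        "adjusted_p": _round(call.adjusted_p),
                        "activated": call.activated,
                        "rank": de.index(call) + 1,
                    })
        report["perturb"] = {
            "n_cells": len(dataset.cells),
            "multiplicity_fractions": {k: _round(v)
                                       for k, v in fractions.items()},
            "per_grna_singlets": per_grna,
            "target_calls": calls,
        }
        pd.DataFrame(calls).to_csv(os.path.join(out, "perturb.calls.tsv"),
                                   sep="\t", index=False)

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
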