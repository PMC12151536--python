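"""Seeded generators for every input the pipeline consumes.

Each generator returns its data plus a manifest recording the planted
ground truth (shared peak identities, super-enhancer spans, per-bin link
counts, planted activity and correlation, per-gRNA fold changes, cell
multiplicity proportions), so every downstream stage has an exact expected
answer without any external data.  Regeneration from ``(seed, parameters)``
is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import ExpressionTable, GeneModel
from .errors import ValidationError
from .intervals import GenomicInterval, IntervalSet
from .perturb import PerturbDataset
from .tf_activity import GeneSignature

__all__ = [
    "SimulationManifest",
    "simulate_peaksets",
    "simulate_super_enhancer_landscape",
    "simulate_expression_and_links",
    "simulate_activity_correlation",
    "simulate_perturb",
]


@dataclass
class SimulationManifest:
    """Seed, parameters and planted truth for one generator run."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)
    planted_truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed,
             "parameters": self.parameters, "planted_truth": self.planted_truth},
            indent=2, sort_keys=True)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")


# ---------------------------------------------------------------------------
# Peak sets for two histone marks across samples
# ---------------------------------------------------------------------------

def simulate_peaksets(n_samples: int = 3,
                      genome: Mapping[str, int] | None = None,
                      n_shared: int = 50,
                      n_private_per_sample: int = 20,
                      jitter_bp: int = 0,
                      peak_len: int = 800,
                      min_gap: int = 13_000,
                      seed: int = 0,
                      ) -> tuple[dict[str, dict[str, IntervalSet]], SimulationManifest]:
    """Per-sample H3K27ac/H3K4me1 peak sets with a controlled shared fraction.

    Peaks occupy well-separated slots so that boundary jitter can never
    create accidental cross-slot overlap: shared slots carry a peak of both
    marks in every sample, private slots in exactly one sample.  Thus the
    all-sample consensus recovers exactly ``n_shared`` regions and each
    slot is double-positive by construction.
    """
    if genome is None:
        genome = {"chr1": 250_000_000}
    if jitter_bp < 0 or peak_len <= 2 * jitter_bp:
        raise ValidationError("need 0 <= 2*jitter_bp < peak_len")
    rng = np.random.default_rng(seed)
    if min_gap < 1:
        raise ValidationError("min_gap must be positive")
    n_slots = n_shared + n_samples * n_private_per_sample
    # default slot separation exceeds the super-enhancer stitch gap so
    # jittered slots can neither overlap nor stitch across slots
    pitch = peak_len + 2 * jitter_bp + min_gap
    chroms = list(genome)
    per_chrom_capacity = {c: genome[c] // pitch for c in chroms}
    if n_slots > sum(per_chrom_capacity.values()):
        raise ValidationError("genome too small for requested slot count")
    # deterministic slot layout: fill chromosomes in order
    slots: list[tuple[str, int]] = []
    for c in chroms:
        for i in range(per_chrom_capacity[c]):
            slots.append((c, jitter_bp + i * pitch))
            if len(slots) == n_slots:
                break
        if len(slots) == n_slots:
            break
    order = rng.permutation(n_slots)
    shared_ids = [int(i) for i in order[:n_shared]]
    private_ids: dict[str, list[int]] = {}
    cursor = n_shared
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    for s in sample_ids:
        private_ids[s] = [int(i) for i in order[cursor:cursor + n_private_per_sample]]
        cursor += n_private_per_sample

    def jittered(chrom: str, pos: int) -> GenomicInterval:
        ds = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
        de = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
        return GenomicInterval(chrom, pos + ds, pos + peak_len + de)

    tracks: dict[str, dict[str, IntervalSet]] = {}
    for s in sample_ids:
        own = sorted(shared_ids + private_ids[s])
        per_mark: dict[str, IntervalSet] = {}
        for mark, widen in (("H3K27ac", 0), ("H3K4me1", 200)):
            ivs = []
            for slot_id in own:
                chrom, pos = slots[slot_id]
                iv = jittered(chrom, pos)
                ivs.append(GenomicInterval(iv.chrom, iv.start,
                                           iv.end + widen))
            ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            per_mark[mark] = IntervalSet(ivs, sample_id=s, track_label=mark,
                                         canonical=True)
        tracks[s] = per_mark
    manifest = SimulationManifest(
        generator="simulate_peaksets", seed=seed,
        parameters={"n_samples": n_samples, "n_shared": n_shared,
                    "n_private_per_sample": n_private_per_sample,
                    "jitter_bp": jitter_bp, "peak_len": peak_len,
                    "min_gap": min_gap},
        planted_truth={
            "n_shared": n_shared,
            "shared_slots": [list(slots[i]) for i in sorted(shared_ids)],
            "private_slots": {s: [list(slots[i]) for i in sorted(ids)]
                              for s, ids in private_ids.items()},
            "per_sample_peak_count": n_shared + n_private_per_sample,
        })
    return tracks, manifest


# ---------------------------------------------------------------------------
# Super-enhancer landscape
# ---------------------------------------------------------------------------

def simulate_super_enhancer_landscape(k_clusters: int,
                                      n_noise: int = 10,
                                      min_span: int = 15_001,
                                      max_span: int = 40_000,
                                      intra_gap: int = 12_500,
                                      inter_gap: int = 12_501,
                                      chrom: str = "chr1",
                                      seed: int = 0,
                                      ) -> tuple[IntervalSet, SimulationManifest]:
    """Plant exactly ``k_clusters`` stitchable peak clusters.

    Each cluster has >= 2 peaks with intra-cluster gaps <= ``intra_gap``
    and total span drawn from ``[min_span, max_span]``; clusters and noise
    peaks are separated by > ``inter_gap``.  Noise peaks are single short
    peaks whose span can never pass a 15 kb size threshold.
    """
    if k_clusters < 0 or n_noise < 0:
        raise ValidationError("counts must be non-negative")
    if min_span > max_span or intra_gap < 1 or inter_gap <= intra_gap:
        raise ValidationError("infeasible geometric constraints")
    rng = np.random.default_rng(seed)
    items = ["cluster"] * k_clusters + ["noise"] * n_noise
    rng.shuffle(items)
    cursor = 1_000
    peaks: list[GenomicInterval] = []
    spans: list[list[int]] = []
    for kind in items:
        if kind == "noise":
            length = int(rng.integers(200, 2_000))
            peaks.append(GenomicInterval(chrom, cursor, cursor + length))
            cursor += length + inter_gap + int(rng.integers(1, 5_000))
        else:
            span = int(rng.integers(min_span, max_span + 1))
            start = cursor
            n_peaks = int(rng.integers(2, 7))
            # gaps first (each <= intra_gap and jointly < span/2), then split
            # the remaining bases into n_peaks positive lengths
            max_gap_here = max(1, min(intra_gap, span // (2 * (n_peaks - 1))))
            gaps = [int(rng.integers(1, max_gap_here + 1))
                    for _ in range(n_peaks - 1)]
            total_len = span - sum(gaps)
            cuts = np.sort(rng.choice(np.arange(1, total_len),
                                      size=n_peaks - 1, replace=False))
            lengths = np.diff(np.concatenate([[0], cuts, [total_len]]))
            pos = start
            for i, length in enumerate(lengths):
                peaks.append(GenomicInterval(chrom, pos, pos + int(length)))
                if i < n_peaks - 1:
                    pos += int(length) + gaps[i]
            spans.append([start, start + span])
            cursor = start + span + inter_gap + int(rng.integers(1, 5_000))
    peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    spans.sort()
    iset = IntervalSet(peaks, track_label="H3K27ac", canonical=True)
    manifest = SimulationManifest(
        generator="simulate_super_enhancer_landscape", seed=seed,
        parameters={"k_clusters": k_clusters, "n_noise": n_noise,
                    "min_span": min_span, "max_span": max_span,
                    "intra_gap": intra_gap, "inter_gap": inter_gap},
        planted_truth={"k": k_clusters,
                       "spans": [[chrom, s, e] for s, e in spans]})
    return iset, manifest


# ---------------------------------------------------------------------------
# Expression + enhancer-gene links
# ---------------------------------------------------------------------------

_BIN_BOUNDS = {"inactive": (0.0, 1.0), "low": (1.0, 5.0),
               "mid": (5.0, 15.0), "high": (15.0, 500.0)}


def simulate_expression_and_links(n_enhancers: int = 50,
                                  bin_targets: Mapping[str, float] | None = None,
                                  n_unlinked_genes_per_bin: int = 3,
                                  n_samples: int = 3,
                                  window: int = 100_000,
                                  chrom: str = "chr1",
                                  seed: int = 0,
                                  ) -> tuple[IntervalSet, list[GeneModel],
                                             ExpressionTable, SimulationManifest]:
    """Enhancers, genes and an FPKM table hitting per-bin link fractions
    exactly.

    For each bin, ``round(target * n_enhancers)`` enhancers receive one
    gene of that bin with its TSS inside the window; enhancers are spaced
    more than two windows apart so no gene can link to a second enhancer.
    Extra unlinked genes per bin are placed beyond any window.
    """
    if bin_targets is None:
        bin_targets = {"high": 0.4, "low": 0.2}
    for label, f in bin_targets.items():
        if label not in _BIN_BOUNDS:
            raise ValidationError(f"unknown bin {label!r}")
        if not 0 <= f <= 1:
            raise ValidationError("bin target fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = 2_000
    pitch = 2 * window + 60_000
    enhancers = IntervalSet(
        [GenomicInterval(chrom, 10_000 + i * pitch, 10_000 + i * pitch + width)
         for i in range(n_enhancers)],
        track_label="enhancer", canonical=True)
    genes: list[GeneModel] = []
    values: list[float] = []
    planted_counts: dict[str, int] = {}
    planted_enhancers: dict[str, list[int]] = {}
    gid = 0
    for label in sorted(bin_targets):
        k = round(bin_targets[label] * n_enhancers)
        planted_counts[label] = k
        chosen = sorted(int(i) for i in rng.choice(n_enhancers, size=k, replace=False))
        planted_enhancers[label] = chosen
        lo, hi = _BIN_BOUNDS[label]
        for i in chosen:
            enh = enhancers[i]
            mid = (enh.start + enh.end) // 2
            offset = int(rng.integers(-window, window + 1))
            tss = max(0, mid + offset)
            genes.append(GeneModel(f"G{gid:05d}", chrom, "+", tss))
            values.append(float(rng.uniform(lo, min(hi, lo + (hi - lo) * 0.98))))
            gid += 1
    far_start = 10_000 + n_enhancers * pitch + 2 * window + 100_000
    for label, (lo, hi) in _BIN_BOUNDS.items():
        for j in range(n_unlinked_genes_per_bin):
            genes.append(GeneModel(f"G{gid:05d}", chrom, "+",
                                   far_start + gid * 10_000))
            values.append(float(rng.uniform(lo, min(hi, lo + (hi - lo) * 0.98))))
            gid += 1
    table = ExpressionTable(
        genes=[g.gene_id for g in genes],
        samples=[f"S{i + 1}" for i in range(n_samples)],
        values=np.tile(np.asarray(values)[:, None], (1, n_samples)),
        assay_note="FPKM (synthetic, constant across samples)")
    manifest = SimulationManifest(
        generator="simulate_expression_and_links", seed=seed,
        parameters={"n_enhancers": n_enhancers, "bin_targets": dict(bin_targets),
                    "window": window, "n_samples": n_samples},
        planted_truth={
            "linked_counts": planted_counts,
            "linked_fractions": {b: c / n_enhancers
                                 for b, c in planted_counts.items()},
            "linked_enhancer_indices": planted_enhancers,
        })
    return enhancers, genes, table, manifest


# ---------------------------------------------------------------------------
# Activity-correlation regime
# ---------------------------------------------------------------------------

def simulate_activity_correlation(n_samples: int = 43,
                                  n_up: int = 60, n_down: int = 60,
                                  n_background: int = 100,
                                  delta_scale: float = 1.0,
                                  noise_sd: float = 0.5,
                                  rho: float = 0.47,
                                  target_gene: str = "TARGET",
                                  seed: int = 0,
                                  ) -> tuple[ExpressionTable, GeneSignature,
                                             str, SimulationManifest]:
    """Expression table with a planted per-sample activity and a target gene
    correlated with it at ``rho`` in expectation.

    Up-signature genes are shifted by ``+delta_s``, down genes by
    ``-delta_s`` (``delta_s`` standard normal times ``delta_scale``), all
    genes carry independent noise.  The target gene equals
    ``rho * z(delta) + sqrt(1 - rho^2) * eps`` plus an offset keeping the
    table non-negative.
    """
    if not -1 <= rho <= 1:
        raise ValidationError("|rho| must be <= 1")
    if n_up < 2 or n_down < 2 or n_samples < 3:
        raise ValidationError("degenerate simulation sizes")
    rng = np.random.default_rng(seed)
    offset = 100.0
    delta = rng.standard_normal(n_samples) * delta_scale
    up_names = [f"UP{i:04d}" for i in range(n_up)]
    down_names = [f"DN{i:04d}" for i in range(n_down)]
    bg_names = [f"BG{i:04d}" for i in range(n_background)]
    rows = []
    for _ in up_names:
        rows.append(offset + delta + rng.standard_normal(n_samples) * noise_sd)
    for _ in down_names:
        rows.append(offset - delta + rng.standard_normal(n_samples) * noise_sd)
    for _ in bg_names:
        rows.append(offset + rng.standard_normal(n_samples) * noise_sd)
    dz = (delta - delta.mean()) / delta.std(ddof=0) if delta.std() > 0 else delta
    eps = rng.standard_normal(n_samples)
    eps = (eps - eps.mean()) / eps.std(ddof=0)
    target = offset + rho * dz + np.sqrt(max(0.0, 1 - rho ** 2)) * eps
    rows.append(target)
    values = np.clip(np.vstack(rows), 0.0, None)
    table = ExpressionTable(
        genes=up_names + down_names + bg_names + [target_gene],
        samples=[f"M{i + 1:02d}" for i in range(n_samples)],
        values=values, assay_note="normalized counts (synthetic)")
    signature = GeneSignature(up_genes=up_names, down_genes=down_names,
                              source_note="synthetic planted signature")
    manifest = SimulationManifest(
        generator="simulate_activity_correlation", seed=seed,
        parameters={"n_samples": n_samples, "n_up": n_up, "n_down": n_down,
                    "n_background": n_background, "delta_scale": delta_scale,
                    "noise_sd": noise_sd, "rho": rho},
        planted_truth={"rho": rho, "delta": [float(d) for d in delta],
                       "target_gene": target_gene})
    return table, signature, target_gene, manifest


# ---------------------------------------------------------------------------
# Perturb-seq dataset
# ---------------------------------------------------------------------------

def simulate_perturb(n_cells: int = 1_000,
                     grna_targets: Mapping[str, str | None] | None = None,
                     fold_changes: Mapping[str, float] | None = None,
                     multiplicity_probs: Sequence[float] = (0.163, 0.567, 0.270),
                     n_background_genes: int = 50,
                     base_mean: float = 5.0,
                     nb_dispersion: float = 2.0,
                     control_label: str = "NonTargeting",
                     seed: int = 0,
                     ) -> tuple[PerturbDataset, SimulationManifest]:
    """Paired gRNA x cell and gene x cell count matrices with planted
    per-gRNA activation fold changes.

    ``multiplicity_probs`` are (none, singlet, multiplet) proportions; the
    defaults echo the realistic regime of a published screen.  Gene counts
    are negative binomial; a gRNA's planted fold change multiplies its
    target gene's mean in that gRNA's singlet cells.
    """
    probs = np.asarray(multiplicity_probs, dtype=float)
    if probs.shape != (3,) or abs(probs.sum() - 1) > 1e-9 or np.any(probs < 0):
        raise ValidationError("multiplicity_probs must be 3 non-negative "
                              "values summing to 1")
    if grna_targets is None:
        grna_targets = {control_label: None,
                        **{f"g{i}": f"TGT{i}" for i in range(1, 5)}}
    if control_label not in grna_targets:
        raise ValidationError("control label missing from panel")
    fold_changes = dict(fold_changes or {})
    for g in grna_targets:
        fold_changes.setdefault(g, 1.0)
    rng = np.random.default_rng(seed)
    grnas = list(grna_targets)
    targets = sorted({t for t in grna_targets.values() if t})
    gene_names = targets + [f"BG{i:04d}" for i in range(n_background_genes)]
    cells = [f"C{i:05d}" for i in range(n_cells)]

    classes = rng.choice(3, size=n_cells, p=probs)  # 0 none, 1 singlet, 2 multiplet
    grna_mat = np.zeros((len(grnas), n_cells), dtype=int)
    singlet_grna: dict[str, str] = {}
    for j in range(n_cells):
        if classes[j] == 0:
            continue
        k = 1 if classes[j] == 1 else int(rng.integers(2, min(3, len(grnas)) + 1))
        picked = rng.choice(len(grnas), size=k, replace=False)
        for gi in picked:
            grna_mat[gi, j] = 1 + int(rng.poisson(5))
        if k == 1:
            singlet_grna[cells[j]] = grnas[int(picked[0])]

    base_mu = np.full(len(gene_names), base_mean, dtype=float)
    size = nb_dispersion  # NB "size"; variance = mu + mu^2 / size
    expr = np.empty((len(gene_names), n_cells), dtype=int)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for j in range(n_cells):
        mu = base_mu.copy()
        g = singlet_grna.get(cells[j])
        if g is not None and grna_targets[g]:
            mu[gene_index[grna_targets[g]]] *= fold_changes[g]
        p = size / (size + mu)
        expr[:, j] = rng.negative_binomial(size, p)

    dataset = PerturbDataset(
        grna_counts=pd.DataFrame(grna_mat, index=grnas, columns=cells),
        expression=pd.DataFrame(expr, index=gene_names, columns=cells),
        grna_targets={g: (t if t else "non-targeting")
                      for g, t in grna_targets.items()},
        control_label=control_label)
    n_by_class = {"none": int((classes == 0).sum()),
                  "singlet": int((classes == 1).sum()),
                  "multiplet": int((classes == 2).sum())}
    manifest = SimulationManifest(
        generator="simulate_perturb", seed=seed,
        parameters={"n_cells": n_cells, "multiplicity_probs": list(probs),
                    "n_background_genes": n_background_genes,
                    "base_mean": base_mean, "nb_dispersion": nb_dispersion},
        planted_truth={"fold_changes": dict(fold_changes),
                       "multiplicity_probs": list(map(float, probs)),
                       "class_counts": n_by_class,
                       "grna_targets": {g: t for g, t in grna_targets.items()}})
    return dataset, manifest


# ---------------------------------------------------------------------------
# Full on-disk scenario for the end-to-end pipeline
# ---------------------------------------------------------------------------

def write_scenario(outdir, seed: int = 0, n_shared: int = 40,
                   n_private_per_sample: int = 15, k_superenhancers: int = 6,
                   se_occupancy_fraction: float = 0.75,
                   enh_occupancy_fraction: float = 0.2,
                   n_perturb_cells: int = 600) -> str:
    """Write every pipeline input (BED, TSV, BEDPE, YAML config) for a
    self-contained synthetic run; returns the config path.

    The layout is deterministic in ``seed``: chr1 carries the jittered
    three-sample peak slots plus genes binned round-robin near the shared
    slots, chr2 carries identical super-enhancer clusters in all samples,
    and the occupancy track covers planted fractions of each catalog.
    """
    import os

    import yaml

    from .association import write_genes, write_loops, ChromatinLoop
    from .intervals import write_bed, merge

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tracks, peaks_manifest = simulate_peaksets(
        n_samples=3, n_shared=n_shared,
        n_private_per_sample=n_private_per_sample,
        jitter_bp=100, seed=int(rng.integers(2**31)))
    se_peaks, se_manifest = simulate_super_enhancer_landscape(
        k_clusters=k_superenhancers, chrom="chr2",
        seed=int(rng.integers(2**31)))

    sample_entries = []
    for sid, marks in tracks.items():
        k27 = IntervalSet(list(marks["H3K27ac"]) + list(se_peaks),
                          sample_id=sid, track_label="H3K27ac").sorted()
        k4_extra = merge(se_peaks, max_gap=20_000)  # chr2 clusters K4-covered
        k4 = IntervalSet(list(marks["H3K4me1"]) + list(k4_extra),
                         sample_id=sid, track_label="H3K4me1").sorted()
        p27 = os.path.join(outdir, f"{sid}.h3k27ac.bed")
        p4 = os.path.join(outdir, f"{sid}.h3k4me1.bed")
        write_bed(k27, p27)
        write_bed(k4, p4)
        sample_entries.append({"id": sid, "h3k27ac": os.path.basename(p27),
                               "h3k4me1": os.path.basename(p4),
                               "dialect": "bed3"})

    # genes near the shared chr1 slots, binned round-robin
    shared_slots = peaks_manifest.planted_truth["shared_slots"]
    peak_len = peaks_manifest.parameters["peak_len"]
    labels = ["high", "mid", "low", "inactive"]
    genes, fpkm = [], []
    for i, (chrom, pos) in enumerate(shared_slots):
        label = labels[i % 4]
        lo, hi = _BIN_BOUNDS[label]
        tss = pos + peak_len // 2 + int(rng.integers(-50_000, 50_001))
        genes.append(GeneModel(f"G{i:04d}", chrom, "+", max(0, tss)))
        fpkm.append(float(rng.uniform(lo, min(hi, lo + (hi - lo) * 0.98))))
    genes_path = os.path.join(outdir, "genes.tsv")
    write_genes(genes, genes_path)
    fpkm_table = ExpressionTable(
        genes=[g.gene_id for g in genes], samples=["S1", "S2", "S3"],
        values=np.tile(np.asarray(fpkm)[:, None], (1, 3)))
    fpkm_path = os.path.join(outdir, "fpkm.tsv")
    fpkm_table.write_tsv(fpkm_path)

    # loops: one anchor at a gene TSS, the other over that gene's slot peak
    # (gene i was planted relative to shared slot i), so loop-supported
    # links are guaranteed whenever the TSS sits clear of the slot
    loops = []
    for g, (chrom, pos) in list(zip(genes, shared_slots))[:8]:
        tss_anchor = GenomicInterval(chrom, max(0, g.tss - 2_500), g.tss + 2_500)
        slot_anchor = GenomicInterval(chrom, max(0, pos - 2_000),
                                      pos + peak_len + 2_000)
        if slot_anchor.overlap_bp(tss_anchor) == 0:
            loops.append(ChromatinLoop(tss_anchor, slot_anchor))
    loops_path = os.path.join(outdir, "loops.bedpe")
    write_loops(loops, loops_path)

    # occupancy: cover a planted fraction of SE spans and of shared slots
    occ = []
    spans = se_manifest.planted_truth["spans"]
    n_se_occ = round(se_occupancy_fraction * len(spans))
    for chrom, s, e in spans[:n_se_occ]:
        occ.append(GenomicInterval(chrom, s, min(e, s + 1_000)))
    n_slot_occ = round(enh_occupancy_fraction * len(shared_slots))
    for chrom, pos in shared_slots[:n_slot_occ]:
        occ.append(GenomicInterval(chrom, pos, pos + 200))
    occ_path = os.path.join(outdir, "occupancy.bed")
    write_bed(IntervalSet(sorted(occ, key=lambda iv: (iv.chrom, iv.start))),
              occ_path)

    # activity cohort + signature
    act_table, signature, target, _ = simulate_activity_correlation(
        seed=int(rng.integers(2**31)))
    act_path = os.path.join(outdir, "activity_fpkm.tsv")
    act_table.write_tsv(act_path)
    sig_path = os.path.join(outdir, "signature.tsv")
    with open(sig_path, "w") as fh:
        for g in signature.up_genes:
            fh.write(f"{g}\tup\n")
        for g in signature.down_genes:
            fh.write(f"{g}\tdown\n")

    # perturb matrices
    dataset, perturb_manifest = simulate_perturb(
        n_cells=n_perturb_cells,
        fold_changes={"g1": 3.0, "g2": 1.0},
        seed=int(rng.integers(2**31)))
    grna_path = os.path.join(outdir, "grna_counts.tsv")
    expr_path = os.path.join(outdir, "perturb_expr.tsv")
    targets_path = os.path.join(outdir, "grna_targets.tsv")
    dataset.grna_counts.to_csv(grna_path, sep="\t", index_label="grna")
    dataset.expression.to_csv(expr_path, sep="\t", index_label="gene")
    with open(targets_path, "w") as fh:
        fh.write("grna\ttarget\n")
        for g, t in dataset.grna_targets.items():
            fh.write(f"{g}\t{t}\n")

    config = {
        "samples": sample_entries,
        "genes": os.path.basename(genes_path),
        "expression_fpkm": os.path.basename(fpkm_path),
        "occupancy": os.path.basename(occ_path),
        "loops": [os.path.basename(loops_path)],
        "signature": os.path.basename(sig_path),
        "activity_expression": os.path.basename(act_path),
        "target_gene": target,
        "perturb": {"grna_counts": os.path.basename(grna_path),
                    "expression": os.path.basename(expr_path),
                    "targets": os.path.basename(targets_path),
                    "control": dataset.control_label},
        "seed": seed,
        "output_dir": "out",
    }
    config_path = os.path.join(outdir, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    manifest = SimulationManifest(
        generator="write_scenario", seed=seed,
        parameters={"n_shared": n_shared,
                    "n_private_per_sample": n_private_per_sample,
                    "k_superenhancers": k_superenhancers},
        planted_truth={
            "n_common_enhancer_slots": n_shared,
            "k_superenhancers": k_superenhancers,
            "se_spans": spans,
            "perturb_fold_changes":
                perturb_manifest.planted_truth["fold_changes"],
        })
    manifest.write(os.path.join(outdir, "manifest.json"))
    return config_path
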