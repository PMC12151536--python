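import numpy as np
import pytest

from oracles import window_links_oracle
from regmap.association import (
    ChromatinLoop,
    ExpressionTable,
    GeneModel,
    associate_by_loop,
    associate_by_window,
    association_fractions,
    bin_expression,
    read_genes,
    read_loops,
    write_genes,
    write_loops,
)
from regmap.errors import ValidationError
from regmap.intervals import GenomicInterval, IntervalSet
from regmap.synthetic import simulate_expression_and_links


def enh_set(*triples):
    return IntervalSet([GenomicInterval(*t) for t in triples]).canonicalize()


def link_keys(links):
    return {(lk.enhancer.chrom, lk.enhancer.start, lk.enhancer.end, lk.gene_id)
            for lk in links}


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------

def test_tss_from_stranded_span():
    plus = GeneModel.from_span("g+", "chr1", "+", 100, 500)
    minus = GeneModel.from_span("g-", "chr1", "-", 100, 500)
    assert plus.tss == 100
    assert minus.tss == 499


def test_gene_strand_validated():
    with pytest.raises(ValidationError):
        GeneModel("g", "chr1", ".", 100)


def test_gene_io_roundtrip(tmp_path):
    genes = [GeneModel("g1", "chr1", "+", 100), GeneModel("g2", "chr2", "-", 999)]
    p = tmp_path / "genes.tsv"
    write_genes(genes, p)
    assert read_genes(p) == genes


def test_gene_bed6_input(tmp_path):
    p = tmp_path / "genes.bed"
    p.write_text("chr1\t100\t500\tgA\t0\t+\nchr1\t100\t500\tgB\t0\t-\n")
    genes = read_genes(p)
    assert genes[0].tss == 100 and genes[1].tss == 499


# ---------------------------------------------------------------------------
# bin_expression
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fpkm,label", [
    (15.0, "high"), (14.99, "mid"), (5.0, "mid"), (4.99, "low"),
    (1.0, "low"), (0.99, "inactive"), (0.0, "inactive"),
])
def test_bin_boundaries(fpkm, label):
    table = ExpressionTable(genes=["g"], samples=["s1"],
                            values=np.array([[fpkm]]))
    assert bin_expression(table)["g"] == label


def test_bin_uses_mean_across_samples():
    table = ExpressionTable(genes=["g"], samples=["a", "b"],
                            values=np.array([[10.0, 20.0]]))
    assert bin_expression(table)["g"] == "high"  # mean 15


def test_bin_partition_and_counts(rng):
    values = rng.uniform(0, 30, size=(200, 3))
    table = ExpressionTable(genes=[f"g{i}" for i in range(200)],
                            samples=["a", "b", "c"], values=values)
    bins = bin_expression(table)
    assert len(bins) == 200  # every gene in exactly one bin
    means = values.mean(axis=1)
    expected = {"inactive": int((means < 1).sum()),
                "low": int(((means >= 1) & (means < 5)).sum()),
                "mid": int(((means >= 5) & (means < 15)).sum()),
                "high": int((means >= 15).sum())}
    got = {lab: sum(1 for b in bins.values() if b == lab) for lab in expected}
    assert got == expected
    assert sum(got.values()) == 200


def test_negative_fpkm_rejected():
    with pytest.raises(ValidationError):
        ExpressionTable(genes=["g"], samples=["s"], values=np.array([[-1.0]]))


def test_empty_table_rejected():
    table = ExpressionTable(genes=[], samples=["s"], values=np.zeros((0, 1)))
    with pytest.raises(ValidationError):
        bin_expression(table)


# ---------------------------------------------------------------------------
# associate_by_window
# ---------------------------------------------------------------------------

def test_window_boundary_midpoint():
    enh = enh_set(("chr1", 49_000, 51_000))  # midpoint 50000
    near = GeneModel("near", "chr1", "+", 149_999)   # distance 99999
    far = GeneModel("far", "chr1", "+", 150_001)     # distance 100001
    at = GeneModel("at", "chr1", "+", 150_000)       # distance 100000
    links = associate_by_window(enh, [near, far, at], window=100_000)
    assert {lk.gene_id for lk in links} == {"near", "at"}
    assert {lk.distance for lk in links} == {99_999, 100_000}


def test_tss_inside_enhancer_edge_mode():
    enh = enh_set(("chr1", 100, 200))
    g = GeneModel("g", "chr1", "+", 150)
    links = associate_by_window(enh, [g], window=10, anchor="edge")
    assert links[0].distance == 0


def test_window_nonpositive_rejected():
    with pytest.raises(ValidationError):
        associate_by_window(enh_set(("chr1", 0, 10)), [], window=0)


def test_many_to_many_links():
    enh = enh_set(("chr1", 0, 1_000), ("chr1", 5_000, 6_000))
    genes = [GeneModel("g1", "chr1", "+", 2_000),
             GeneModel("g2", "chr1", "+", 3_000)]
    links = associate_by_window(enh, genes, window=100_000)
    assert len(links) == 4


@pytest.mark.parametrize("anchor", ["midpoint", "edge"])
def test_window_matches_all_pairs_oracle(rng, anchor):
    for _ in range(60):
        n_enh = int(rng.integers(1, 30))
        n_gene = int(rng.integers(1, 30))
        enh = IntervalSet(sorted(
            [GenomicInterval("chr1", int(s), int(s) + int(l))
             for s, l in zip(rng.integers(0, 500_000, n_enh),
                             rng.integers(1, 5_000, n_enh))],
            key=lambda iv: (iv.start, iv.end)))
        enh = enh.canonicalize()
        genes = [GeneModel(f"g{i}", "chr1", "+", int(t))
                 for i, t in enumerate(rng.integers(0, 600_000, n_gene))]
        window = int(rng.integers(1_000, 150_000))
        links = associate_by_window(enh, genes, window=window, anchor=anchor)
        oracle = window_links_oracle(enh, genes, window, anchor)
        assert link_keys(links) == set(oracle)
        for lk in links:
            key = (lk.enhancer.chrom, lk.enhancer.start, lk.enhancer.end,
                   lk.gene_id)
            assert lk.distance == oracle[key]


def test_window_monotonicity(rng):
    enh = enh_set(*[("chr1", int(s), int(s) + 500)
                    for s in sorted(rng.integers(0, 300_000, 10) * 7 // 7)])
    genes = [GeneModel(f"g{i}", "chr1", "+", int(t))
             for i, t in enumerate(rng.integers(0, 300_000, 20))]
    small = link_keys(associate_by_window(enh, genes, window=20_000))
    large = link_keys(associate_by_window(enh, genes, window=80_000))
    assert small <= large


# ---------------------------------------------------------------------------
# associate_by_loop
# ---------------------------------------------------------------------------

def _loop(a, b):
    return ChromatinLoop(GenomicInterval(*a), GenomicInterval(*b))


def test_loop_links_enhancer_to_tss():
    enh = enh_set(("chr1", 10_000, 11_000))
    genes = [GeneModel("g", "chr1", "+", 200_500)]
    loop = _loop(("chr1", 9_000, 12_000), ("chr1", 200_000, 201_000))
    links = associate_by_loop(enh, genes, [loop])
    assert len(links) == 1
    assert links[0].evidence == "loop"


def test_same_anchor_not_linked():
    enh = enh_set(("chr1", 10_000, 11_000))
    genes = [GeneModel("g", "chr1", "+", 10_500)]  # TSS in the same anchor
    loop = _loop(("chr1", 9_000, 12_000), ("chr1", 200_000, 201_000))
    assert associate_by_loop(enh, genes, [loop]) == []


def test_loop_anchor_swap_invariance():
    enh = enh_set(("chr1", 10_000, 11_000))
    genes = [GeneModel("g", "chr1", "+", 200_500)]
    fwd = _loop(("chr1", 9_000, 12_000), ("chr1", 200_000, 201_000))
    rev = _loop(("chr1", 200_000, 201_000), ("chr1", 9_000, 12_000))
    assert link_keys(associate_by_loop(enh, genes, [fwd])) == \
        link_keys(associate_by_loop(enh, genes, [rev]))


def test_loop_plus_window_evidence_both():
    # TSS-anchored loop whose other end sits ~90 kb upstream over an enhancer
    tss = 500_000
    genes = [GeneModel("target", "chr1", "+", tss)]
    enh = enh_set(("chr1", tss - 91_000, tss - 89_500))
    loop = _loop(("chr1", tss - 2_500, tss + 2_500),
                 ("chr1", tss - 92_500, tss - 87_500))
    window_links = associate_by_window(enh, genes, window=100_000)
    merged = associate_by_loop(enh, genes, [loop], window_links=window_links)
    assert len(merged) == 1
    assert merged[0].evidence == "both"


def test_loop_cross_chromosome_rejected_at_load():
    with pytest.raises(ValidationError):
        ChromatinLoop(GenomicInterval("chr1", 0, 100),
                      GenomicInterval("chr2", 0, 100))


def test_overlapping_anchors_rejected():
    with pytest.raises(ValidationError):
        _loop(("chr1", 0, 100), ("chr1", 50, 200))


def test_loop_io_roundtrip(tmp_path):
    loops = [_loop(("chr1", 0, 100), ("chr1", 500, 600))]
    p = tmp_path / "loops.bedpe"
    write_loops(loops, p)
    back = read_loops(p)
    assert back[0].anchor_a == loops[0].anchor_a
    assert back[0].anchor_b == loops[0].anchor_b


# ---------------------------------------------------------------------------
# association_fractions
# ---------------------------------------------------------------------------

def test_fraction_half_high():
    enh = enh_set(("chr1", 0, 10), ("chr1", 100, 110),
                  ("chr1", 200, 210), ("chr1", 300, 310))
    genes = [GeneModel("h", "chr1", "+", 5)]
    bins = {"h": "high"}
    from regmap.association import EnhancerGeneLink
    links = [EnhancerGeneLink(enh[0], "h", 0, "window"),
             EnhancerGeneLink(enh[1], "h", 0, "window")]
    fractions = association_fractions(links, enh, bins)
    assert fractions["high"] == 0.5
    assert fractions["low"] == 0.0


def test_fraction_no_links_all_zero():
    enh = enh_set(("chr1", 0, 10))
    fractions = association_fractions([], enh, {})
    assert set(fractions.values()) == {0.0}


def test_fraction_empty_enhancers_rejected():
    with pytest.raises(ValidationError):
        association_fractions([], IntervalSet([], canonical=True), {})


def test_planted_fractions_exact():
    enh, genes, table, manifest = simulate_expression_and_links(
        n_enhancers=40, bin_targets={"high": 0.4, "low": 0.2, "mid": 0.1},
        seed=5)
    bins = bin_expression(table)
    links = associate_by_window(enh, genes, window=100_000)
    fractions = association_fractions(links, enh, bins)
    for label, planted in manifest.planted_truth["linked_fractions"].items():
        assert fractions[label] == pytest.approx(planted, abs=0)


def test_planted_fractions_540_regime():
    # 216 of 540 enhancers linked to a high-bin gene -> exactly 0.4
    enh, genes, table, manifest = simulate_expression_and_links(
        n_enhancers=540, bin_targets={"high": 0.4}, seed=1)
    bins = bin_expression(table)
    links = associate_by_window(enh, genes, window=100_000)
    fractions = association_fractions(links, enh, bins)
    assert manifest.planted_truth["linked_counts"]["high"] == 216
    assert fractions["high"] == 216 / 540
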