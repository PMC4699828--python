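from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from apaseq.cluster import PolyASite
from apaseq.expression import (
    GeneBoundary,
    call_degs,
    de_test,
    gene_boundaries,
    gene_expression,
    sample_correlation,
)
from apaseq.io_formats import GeneModel

from oracles import bh_ladder, fisher_two_sided


def _gene(gid, start, end, strand="+", chrom="chr1"):
    mid = (start + end) // 2
    return GeneModel(gid, chrom, strand, [(start, end)], cds_start=start + 10,
                     cds_end=mid, annotated_utr_ends=[end - 1])


class TestGeneBoundaries:
    def test_extension_capped_by_available_gap(self):
        genes = [_gene("a", 5_000, 10_000), _gene("b", 15_000, 20_000)]
        bounds = {b.gene_id: b for b in gene_boundaries(genes)}
        assert bounds["a"].end == 13_000  # min(3000, 5000 gap)
        assert bounds["b"].start == 15_000  # b is + strand: no left extension

    def test_convergent_extensions_split_gap_at_midpoint(self):
        genes = [_gene("a", 5_000, 10_000, "+"), _gene("b", 12_000, 20_000, "-")]
        bounds = {b.gene_id: b for b in gene_boundaries(genes)}
        assert bounds["a"].end == 11_000
        assert bounds["b"].start == 11_000

    def test_zero_gap_means_no_extension(self):
        genes = [_gene("a", 5_000, 10_000, "+"), _gene("b", 10_000, 20_000, "-")]
        bounds = {b.gene_id: b for b in gene_boundaries(genes)}
        assert bounds["a"].end == 10_000 and bounds["b"].start == 10_000

    def test_overlapping_annotation_raises_with_pair(self):
        genes = [_gene("a", 5_000, 10_000), _gene("b", 9_000, 20_000)]
        with pytest.raises(ValueError, match="'a', 'b'"):
            gene_boundaries(genes)

    def test_boundaries_never_overlap_on_synthetic_genome(self, study):
        bounds = gene_boundaries(study["genes"])
        by_chrom: dict[str, list[GeneBoundary]] = {}
        for b in bounds:
            by_chrom.setdefault(b.chrom, []).append(b)
        for bs in by_chrom.values():
            bs.sort(key=lambda b: b.start)
            for x, y in zip(bs, bs[1:]):
                assert x.end <= y.start


class TestGeneExpression:
    BOUNDS = [GeneBoundary("g1", "chr1", "+", 100, 1000)]

    def _site(self, pos, rpm, count=10, strand="+"):
        return PolyASite("s", "chr1", strand, pos, {"a": count}, {"a": rpm},
                         rpm)

    def test_rpm_sums_over_contained_sites(self):
        sites = [self._site(200, 3.0), self._site(800, 4.5)]
        expr = gene_expression(sites, self.BOUNDS, ["a"])
        assert expr.loc["g1", "rpm_a"] == pytest.approx(7.5)

    def test_half_open_boundary_excludes_end(self):
        expr = gene_expression([self._site(1000, 5.0)], self.BOUNDS, ["a"])
        assert expr.loc["g1", "rpm_a"] == 0.0

    def test_wrong_strand_not_counted(self):
        expr = gene_expression([self._site(500, 5.0, strand="-")], self.BOUNDS, ["a"])
        assert expr.loc["g1", "rpm_a"] == 0.0

    def test_no_sites_gives_zero(self):
        expr = gene_expression([], self.BOUNDS, ["a"])
        assert expr.loc["g1", "count_a"] == 0


class TestFisher:
    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 200, size=4))
            p = de_test(a, a + b, c, c + d)
            worst = max(worst, abs(p - fisher_two_sided(a, b, c, d)))
        assert worst < 1e-9

    def test_worked_example(self):
        p = de_test(30, 1000, 5, 1000)
        assert p == pytest.approx(fisher_two_sided(30, 970, 5, 995), abs=1e-12)
        assert p < 1e-4

    def test_no_association_gives_p_one(self):
        assert de_test(10, 100, 10, 100) == 1.0
        assert de_test(0, 50, 0, 80) == 1.0

    def test_symmetry(self):
        assert de_test(30, 1000, 5, 1000) == pytest.approx(de_test(5, 1000, 30, 1000))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            de_test(-1, 10, 0, 10)


class TestCallDegs:
    def _expr(self, counts_a, counts_b, lib=100_000):
        df = pd.DataFrame({
            "count_a": counts_a,
            "count_b": counts_b,
            "rpm_a": [c / lib * 1e6 for c in counts_a],
            "rpm_b": [c / lib * 1e6 for c in counts_b],
        }, index=[f"g{i}" for i in range(len(counts_a))])
        df.index.name = "gene_id"
        return df

    def test_bh_ladder_hand_example(self):
        # statsmodels BH against the hand-computed ladder for {0.001, 0.01, 0.04}
        got = multipletests([0.001, 0.01, 0.04], method="fdr_bh")[1]
        assert got == pytest.approx([0.003, 0.015, 0.04])
        assert bh_ladder([0.001, 0.01, 0.04]) == pytest.approx([0.003, 0.015, 0.04])

    def test_fold_change_exactly_two_is_not_deg(self):
        # equal pseudocounted RPM ratio of exactly 2 must fail the strict cut
        df = self._expr([4000], [2000])
        df["rpm_a"], df["rpm_b"] = 3.9, 1.9  # (3.9+0.1)/(1.9+0.1) = 2.0
        out = call_degs(df, [("a", "b")], {"a": 100_000, "b": 100_000})
        assert not out["deg_a_vs_b"].iloc[0]
        assert out["fdr_a_vs_b"].iloc[0] < 0.01  # significant but FC-filtered

    def test_direction_flips_under_sample_swap(self):
        df = self._expr([400, 30], [100, 30])
        fwd = call_degs(df, [("a", "b")], {"a": 100_000, "b": 100_000})
        rev = call_degs(df, [("b", "a")], {"a": 100_000, "b": 100_000})
        assert fwd["direction_a_vs_b"].iloc[0] == "up"
        assert rev["direction_b_vs_a"].iloc[0] == "down"
        assert fwd["p_a_vs_b"].iloc[0] == pytest.approx(rev["p_b_vs_a"].iloc[0])

    def test_min_count_filter_skips_low_genes(self):
        df = self._expr([4, 400], [4, 100])
        out = call_degs(df, [("a", "b")], {"a": 100_000, "b": 100_000},
                        min_total_count=10)
        assert np.isnan(out["p_a_vs_b"].iloc[0])
        assert not np.isnan(out["p_a_vs_b"].iloc[1])

    def test_planted_fold_changes_recovered(self, study):
        from apaseq.expression import gene_boundaries as gb

        sites = study["sites"]
        expr = gene_expression(sites, gb(study["genes"]), list(study["config"].conditions))
        out = call_degs(expr, [("GSC", "ESC")], study["library_sizes"])
        planted = {gid: d for gid, _, d in study["truth"].de_genes}
        for gid, direction in planted.items():
            assert out.loc[gid, "deg_GSC_vs_ESC"]
            assert out.loc[gid, "direction_GSC_vs_ESC"] == direction
        false_flags = out["deg_GSC_vs_ESC"] & ~out.index.isin(planted)
        assert false_flags.sum() == 0


def test_sample_correlation_matrix():
    # genes spanning a wide dynamic range with small multiplicative noise:
    # samples must correlate strongly on log2(RPM + 1)
    rng = np.random.default_rng(9)
    base = rng.lognormal(mean=3.0, sigma=2.0, size=300)
    df = pd.DataFrame({
        "rpm_a": base * rng.lognormal(0, 0.2, 300),
        "rpm_b": base * rng.lognormal(0, 0.2, 300),
        "rpm_c": rng.permutation(base),  # unrelated sample
    }, index=[f"g{i}" for i in range(300)])
    corr = sample_correlation(df, ["a", "b", "c"])
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr.values, corr.values.T)
    assert corr.loc["a", "b"] > 0.9
    assert corr.loc["a", "b"] > abs(corr.loc["a", "c"])
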