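from __future__ import annotations

import numpy as np
import pytest

from apaseq.apa import (
    UTRGroup,
    UTRIsoform,
    group_utrs,
    normalized_utr_length,
    summarize_switches,
    switch_test,
    run_switch_tests,
    top_two_isoforms,
    weighted_utr_length,
)
from apaseq.cluster import PolyASite
from apaseq.io_formats import GeneModel

from oracles import fisher_two_sided


def _iso(distance, counts, position=None):
    position = position if position is not None else 1000 + distance
    rpm = {k: float(v) for k, v in counts.items()}
    return UTRIsoform(position, distance, dict(counts), rpm)


def _group(members, strand="+", mode="mRNA_3UTR"):
    return UTRGroup("g1:1000", "g1", "chr1", strand, 1000, (1000, 4000),
                    list(members), mode)


class TestGrouping:
    def _gene(self, gid, start, end, strand="+", utr_ends=None):
        mid = (start + end) // 2
        return GeneModel(gid, "chr1", strand, [(start, end)], cds_start=start + 10,
                         cds_end=mid, annotated_utr_ends=utr_ends or [end - 1])

    def _site(self, pos, counts, strand="+"):
        rpm = {k: float(v) for k, v in counts.items()}
        return PolyASite(f"s{pos}", "chr1", strand, pos, dict(counts), rpm,
                         sum(rpm.values()))

    def test_sites_attach_with_distances_from_stop(self):
        g = self._gene("g1", 1000, 3000)  # stop boundary at 2000
        sites = [self._site(2300, {"a": 5}), self._site(2900, {"a": 3})]
        (grp,), discards = group_utrs([g], sites)
        assert discards == []
        assert [m.distance for m in grp.members] == [300, 900]

    def test_minus_strand_distances(self):
        g = self._gene("g1", 1000, 3000, strand="-")  # stop boundary at 2000
        sites = [self._site(1700, {"a": 5}, "-"), self._site(1100, {"a": 3}, "-")]
        (grp,), _ = group_utrs([g], sites)
        assert [m.distance for m in grp.members] == [299, 899]

    def test_overlapping_utr_discards_group(self):
        a = self._gene("a", 1000, 3000, utr_ends=[4500])  # annotated UTR runs into b
        b = self._gene("b", 4000, 6000)
        groups, discards = group_utrs([a, b], [])
        dropped = {gid for gid, _ in discards}
        assert any(g.startswith("a:") for g in dropped)

    def test_lncRNA_forms_genewide_group(self):
        g = GeneModel("l1", "chr1", "+", [(1000, 3000)], biotype="lncRNA")
        sites = [self._site(1500, {"a": 2}), self._site(2500, {"a": 2})]
        (grp,), _ = group_utrs([g], sites)
        assert grp.mode == "lncRNA_genewide"
        assert [m.distance for m in grp.members] == [500, 1500]


class TestTopTwo:
    def test_two_most_abundant_selected(self):
        grp = _group([_iso(100, {"a": 120}), _iso(500, {"a": 80}), _iso(900, {"a": 5})])
        prox, dist = top_two_isoforms(grp)
        assert (prox.distance, dist.distance) == (100, 500)

    def test_abundance_tie_prefers_closer_to_stop(self):
        grp = _group([_iso(100, {"a": 50}), _iso(500, {"a": 80}), _iso(900, {"a": 50})])
        prox, dist = top_two_isoforms(grp)
        assert (prox.distance, dist.distance) == (100, 500)

    def test_single_member_returns_none(self):
        assert top_two_isoforms(_group([_iso(100, {"a": 50})])) is None


class TestSwitchTest:
    def test_strong_switch_detected_with_direction(self):
        pair = (_iso(100, {"a": 80, "b": 20}), _iso(900, {"a": 20, "b": 80}))
        res = switch_test(pair, "a", "b", n_tests=1)
        assert res.delta_usage == pytest.approx(0.60)
        assert res.p_raw == pytest.approx(fisher_two_sided(80, 20, 20, 80), abs=1e-12)
        assert res.significant and res.direction == "distal_to_proximal"

    def test_identical_usage_not_significant(self):
        pair = (_iso(100, {"a": 50, "b": 50}), _iso(900, {"a": 50, "b": 50}))
        res = switch_test(pair, "a", "b")
        assert res.p_raw == 1.0 and res.direction == "none"

    def test_delta_of_exactly_five_points_not_significant(self):
        # usage 1.00 vs 0.95 -> |delta| = 0.05 exactly; the > rule is strict
        pair = (_iso(100, {"a": 2000, "b": 1900}), _iso(900, {"a": 0, "b": 100}))
        res = switch_test(pair, "a", "b", n_tests=1)
        assert res.delta_usage == pytest.approx(0.05)
        assert not res.significant

    def test_antisymmetry_under_sample_swap(self):
        pair = (_iso(100, {"a": 70, "b": 30}), _iso(900, {"a": 30, "b": 70}))
        fwd = switch_test(pair, "a", "b", n_tests=1)
        rev = switch_test(pair, "b", "a", n_tests=1)
        assert fwd.delta_usage == pytest.approx(-rev.delta_usage)
        assert fwd.p_raw == pytest.approx(rev.p_raw)
        assert {fwd.direction, rev.direction} == {"distal_to_proximal", "proximal_to_distal"}

    def test_all_zero_sample_skipped(self):
        pair = (_iso(100, {"a": 10, "b": 0}), _iso(900, {"a": 10, "b": 0}))
        assert switch_test(pair, "a", "b") is None

    def test_bonferroni_scales_with_family_size(self):
        pair = (_iso(100, {"a": 60, "b": 40}), _iso(900, {"a": 40, "b": 60}))
        r1 = switch_test(pair, "a", "b", n_tests=1)
        r100 = switch_test(pair, "a", "b", n_tests=100)
        assert r100.p_bonferroni == pytest.approx(min(1.0, r1.p_raw * 100))


class TestLengthMetrics:
    def test_weighted_length_worked_example(self):
        grp = _group([_iso(200, {"a": 3}), _iso(1000, {"a": 1})])
        assert weighted_utr_length(grp, "a") == pytest.approx(400.0)

    def test_single_isoform_identity(self):
        grp = _group([_iso(700, {"a": 9})])
        assert weighted_utr_length(grp, "a") == pytest.approx(700.0)

    def test_equal_rpm_gives_arithmetic_mean(self):
        grp = _group([_iso(200, {"a": 4}), _iso(600, {"a": 4}), _iso(1000, {"a": 4})])
        assert weighted_utr_length(grp, "a") == pytest.approx(600.0)

    def test_unexpressed_sample_is_missing(self):
        grp = _group([_iso(200, {"a": 3})])
        assert weighted_utr_length(grp, "b") is None

    def test_normalized_length_examples(self):
        grp = _group([_iso(200, {"a": 3}), _iso(1000, {"a": 1})])
        assert normalized_utr_length(grp, "a") == pytest.approx(0.4)
        all_distal = _group([_iso(200, {"a": 0}), _iso(1000, {"a": 8})])
        assert normalized_utr_length(all_distal, "a") == pytest.approx(1.0)
        half = _group([_iso(500, {"a": 8}), _iso(1000, {"a": 0})])
        assert normalized_utr_length(half, "a") == pytest.approx(0.5)

    def test_bounded_by_member_distances_and_scale_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            members = [
                _iso(int(d), {"a": float(w)})
                for d, w in zip(rng.integers(1, 2000, n), rng.uniform(0.1, 50, n))
            ]
            grp = _group(members)
            w = weighted_utr_length(grp, "a")
            assert min(m.distance for m in members) <= w <= max(m.distance for m in members)
            scaled = _group([
                UTRIsoform(m.position, m.distance, m.counts,
                           {"a": m.rpm["a"] * 7.5}) for m in members
            ])
            assert weighted_utr_length(scaled, "a") == pytest.approx(w)


class TestSummary:
    def test_counts_by_direction(self):
        def res(direction):
            sig = direction != "none"
            from apaseq.apa import SwitchResult

            return SwitchResult("g", 1, 2, 1, 1, 1, 1, 0.5, 0.5, 0.0, 1.0, 1.0,
                                direction, sig)

        results = [res("distal_to_proximal")] * 3 + [res("proximal_to_distal")] + [res("none")] * 2
        summary = summarize_switches(results)
        assert summary == {"shortened": 3, "lengthened": 1, "unchanged": 2, "tested": 6}
        assert summary["tested"] == sum(
            v for k, v in summary.items() if k != "tested"
        )

    def test_empty_input(self):
        assert summarize_switches([]) == {
            "shortened": 0, "lengthened": 0, "unchanged": 0, "tested": 0
        }


class TestOnSyntheticStudy:
    def test_planted_switches_recovered_with_direction(self, study):
        groups, _ = group_utrs(study["genes"], study["sites"])
        results = {r.group_id.split(":")[0]: r
                   for r in run_switch_tests(groups, "GSC", "ESC")}
        for gid, direction in study["truth"].switch_genes:
            assert gid in results
            assert results[gid].significant
            assert results[gid].direction == direction

    def test_global_length_ordering_follows_usage_gradient(self, study):
        # proximal usage GSC 0.7 > ESC 0.5 > MEF 0.3 => mean normalized
        # 3'UTR length strictly ordered GSC < ESC < MEF
        groups, _ = group_utrs(study["genes"], study["sites"])
        means = {}
        for cond in study["config"].conditions:
            vals = [normalized_utr_length(g, cond) for g in groups
                    if len(g.members) >= 2]
            vals = [v for v in vals if v is not None]
            means[cond] = float(np.mean(vals))
        assert means["GSC"] < means["ESC"] < means["MEF"]
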