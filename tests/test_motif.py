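from __future__ import annotations

import numpy as np
import pytest

from apaseq.cluster import PolyASite
from apaseq.motif import (
    FlankSequence,
    background_expectation,
    extract_flanks,
    iterative_hexamer_discovery,
    kmer_code,
    pas_presence,
    subregion_partition,
)
from apaseq.sequence import revcomp


def _site(pos, strand="+", chrom="chr1", sid="s1"):
    return PolyASite(sid, chrom, strand, pos, {}, {}, 1.0)


def _random_flanks(rng, n, length=200, offset=100):
    bases = np.array(list("ACGT"))
    return [
        FlankSequence(f"f{i}", "".join(rng.choice(bases, size=length)), offset)
        for i in range(n)
    ]


def _plant(flank: FlankSequence, motif: str, rel_start: int) -> FlankSequence:
    i = flank.offset + rel_start
    seq = flank.sequence[:i] + motif + flank.sequence[i + len(motif):]
    return FlankSequence(flank.site_id, seq, flank.offset)


class TestExtractFlanks:
    GENOME = {"chr1": "".join(
        np.random.default_rng(0).choice(np.array(list("ACGT")), size=10_000)
    )}

    def test_plus_strand_window(self):
        (f,) = extract_flanks([_site(5000)], self.GENOME)
        assert f.sequence == self.GENOME["chr1"][4900:5100]
        assert f.offset == 100
        assert f.sequence[f.offset] == self.GENOME["chr1"][5000]

    def test_minus_strand_reverse_complement(self):
        (f,) = extract_flanks([_site(5000, strand="-")], self.GENOME)
        assert f.sequence == revcomp(self.GENOME["chr1"][4901:5101])
        # cleavage base at relative position 0 in transcript sense
        assert f.sequence[f.offset] == revcomp(self.GENOME["chr1"][5000])

    def test_truncation_recorded_near_contig_start(self):
        (f,) = extract_flanks([_site(30)], self.GENOME)
        assert f.trunc_left == 70
        assert len(f.sequence) == 130
        assert f.offset == 30

    def test_missing_chromosome_raises(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_flanks([_site(10, chrom="chrX")], self.GENOME)


class TestBackground:
    def test_uniform_composition_gives_quarter_powers(self):
        rng = np.random.default_rng(1)
        flanks = _random_flanks(rng, 400)
        expected, p_contain = background_expectation(flanks)
        per_window = (1 / 4) ** 6
        w = 200 - 5
        ref = 1 - (1 - per_window) ** w
        # composition is only approximately uniform; probabilities cluster
        assert np.all(np.abs(p_contain.mean() - ref) < 0.2 * ref)

    def test_degenerate_composition(self):
        flanks = [FlankSequence("f", "A" * 50, 25)]
        expected, p_contain = background_expectation(flanks)
        assert p_contain[kmer_code("AAAAAA")] == pytest.approx(1.0)
        assert p_contain[kmer_code("AAAAAC")] == pytest.approx(0.0)

    def test_monte_carlo_agreement(self):
        """Expected containment count matches empirical frequency on random
        sequences drawn from the estimated composition."""
        rng = np.random.default_rng(2)
        flanks = _random_flanks(rng, 2000, length=100, offset=50)
        expected, _ = background_expectation(flanks)
        probe = kmer_code("ACGTAC")
        hits = sum("ACGTAC" in f.sequence for f in flanks)
        se = np.sqrt(expected[probe] * (1 - expected[probe] / len(flanks)))
        assert abs(hits - expected[probe]) < 4 * max(se, 1.0)

    def test_empty_flanks_rejected(self):
        with pytest.raises(ValueError):
            background_expectation([])


class TestDiscovery:
    def test_planted_motif_is_rank_one_and_removed(self):
        rng = np.random.default_rng(3)
        flanks = _random_flanks(rng, 2000)
        planted = [
            _plant(f, "AATAAA", -25) if i < 1600 else f
            for i, f in enumerate(flanks)
        ]
        results = iterative_hexamer_discovery(planted)
        assert results[0].hexamer == "AATAAA"
        assert results[0].rna == "AAUAAA"
        assert results[0].observed >= 1600
        # removal rule: no remaining flank contains an emitted hexamer, so
        # observed counts never refer to removed flanks
        if len(results) > 1:
            assert results[1].hexamer != "AATAAA"

    def test_two_planted_motifs_ranked_in_order(self):
        rng = np.random.default_rng(4)
        flanks = _random_flanks(rng, 2000)
        planted = []
        for i, f in enumerate(flanks):
            if i < 1200:
                planted.append(_plant(f, "AATAAA", -25))
            elif i < 1600:
                planted.append(_plant(f, "ATTAAA", -30))
            else:
                planted.append(f)
        results = iterative_hexamer_discovery(planted)
        assert [r.hexamer for r in results[:2]] == ["AATAAA", "ATTAAA"]
        assert [r.iteration for r in results] == list(range(1, len(results) + 1))

    def test_null_flanks_stop_early(self):
        rng = np.random.default_rng(5)
        flanks = _random_flanks(rng, 1000)
        results = iterative_hexamer_discovery(flanks)
        assert len(results) < 10

    def test_strand_mirror_gives_identical_ranking(self):
        """A minus-strand dataset mirrors its plus-strand counterpart."""
        rng = np.random.default_rng(6)
        n = 500
        chrom_len = 300_000
        seq = list(rng.choice(np.array(list("ACGT")), size=chrom_len))
        positions = sorted(rng.choice(np.arange(1000, chrom_len - 1000), size=n,
                                      replace=False).tolist())
        for p in positions[: int(0.8 * n)]:
            seq[p - 25 : p - 19] = list("AATAAA")
        fwd_genome = {"chr1": "".join(seq)}
        rev_genome = {"chr1": revcomp(fwd_genome["chr1"])}
        fwd_sites = [_site(p, "+", sid=f"s{p}") for p in positions]
        rev_sites = [_site(chrom_len - 1 - p, "-", sid=f"s{p}") for p in positions]
        fwd = iterative_hexamer_discovery(extract_flanks(fwd_sites, fwd_genome))
        rev = iterative_hexamer_discovery(extract_flanks(rev_sites, rev_genome))
        assert [r.hexamer for r in fwd] == [r.hexamer for r in rev]
        assert [r.observed for r in fwd] == [r.observed for r in rev]


class TestPasPresence:
    def test_match_start_window_boundaries(self):
        base = FlankSequence("f", "C" * 200, 100)
        inside = _plant(base, "AATAAA", -25)
        at_edge_low = _plant(base, "AATAAA", -40)
        at_edge_high = _plant(base, "AATAAA", -10)
        outside = _plant(base, "AATAAA", -5)
        assert pas_presence([inside], ["AATAAA"]) == 1.0
        assert pas_presence([at_edge_low], ["AATAAA"]) == 1.0
        assert pas_presence([at_edge_high], ["AATAAA"]) == 1.0
        assert pas_presence([outside], ["AATAAA"]) == 0.0

    def test_fraction_over_sites(self):
        base = FlankSequence("f", "C" * 200, 100)
        flanks = [_plant(base, "ATTAAA", -30), base, base, base]
        assert pas_presence(flanks, ["AATAAA", "ATTAAA"]) == pytest.approx(0.25)

    def test_forced_presence_on_synthetic_truth(self):
        from apaseq.synthio import SimConfig, make_genome

        cfg = SimConfig(seed=21, n_genes=30, pas_rate=1.0)
        genome, _, truth = make_genome(cfg)
        sites = [
            PolyASite(f"t{i}", s.chrom, s.strand, s.position, {}, {}, 1.0)
            for i, s in enumerate(truth.true_sites)
        ]
        flanks = extract_flanks(sites, genome)
        assert pas_presence(flanks, ["AATAAA", "ATTAAA"]) == 1.0


class TestSubregions:
    def test_five_equal_subregions_written(self, tmp_path):
        genome = {"chr1": "".join(
            np.random.default_rng(7).choice(np.array(list("ACGT")), size=5000)
        )}
        sites = [_site(2500, sid="a"), _site(100, sid="b")]  # b is truncated
        paths, n_excluded = subregion_partition(sites, genome, tmp_path / "region_")
        assert len(paths) == 5 and n_excluded == 1
        for i, p in enumerate(paths):
            lines = p.read_text().strip().splitlines()
            assert len(lines) == 2  # one surviving site
            assert len(lines[1]) == 200
        # middle subregion covers genomic [p-100, p+100)
        middle = paths[2].read_text().strip().splitlines()[1]
        assert middle == genome["chr1"][2400:2600]

    def test_no_sites_gives_empty_fastas(self, tmp_path):
        genome = {"chr1": "ACGT" * 500}
        paths, n_excluded = subregion_partition([], genome, tmp_path / "r_")
        assert n_excluded == 0
        assert all(p.read_text() == "" for p in paths)
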