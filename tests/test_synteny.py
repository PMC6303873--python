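"""Chain mapper and SC/SU/UN classification: oracle-checked semantics."""

import numpy as np
import pytest

from crosstf.formats import ChainAlignment, GenomicInterval, Peak
from crosstf import synteny
from crosstf.synteny import (
    ChainIndex,
    MapperConfig,
    MappingFailure,
    background_conservation,
    classify_peaks,
    conservation_by_strength_quartile,
    map_interval,
    summit_distance_spectrum,
    syntenic_rate,
)

from helpers import brute_force_map, per_base_image_map, random_chain


def simple_chain(blocks=((200, 0, 0),), q_strand="+", score=100.0, cid=1):
    sizes = sum(b[0] for b in blocks)
    dts = sum(b[1] for b in blocks)
    dqs = sum(b[2] for b in blocks)
    return ChainAlignment(
        score=score,
        t_name="chrM",
        t_size=1000,
        t_strand="+",
        t_start=100,
        t_end=100 + sizes + dts,
        q_name="chrH",
        q_size=2000,
        q_strand=q_strand,
        q_start=500,
        q_end=500 + sizes + dqs,
        blocks=blocks,
        chain_id=cid,
    )


def peak(chrom, start, end, name="p", q=0.0, summit=-1):
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        name=name,
        neglog10_q=q,
        summit_offset=summit,
    )


class TestMapInterval:
    def test_fully_inside_block(self):
        index = ChainIndex([simple_chain()])
        m = map_interval(GenomicInterval("chrM", 150, 250), index)
        assert m.target == GenomicInterval("chrH", 550, 650)
        assert m.mapped_fraction == 1.0

    def test_half_covered_boundary_succeeds_at_exactly_half(self):
        index = ChainIndex([simple_chain()])
        m = map_interval(GenomicInterval("chrM", 50, 150), index)
        assert m.mapped_fraction == 0.5
        assert m.target == GenomicInterval("chrH", 500, 550)

    def test_uncovered_interval_fails(self):
        index = ChainIndex([simple_chain()])
        m = map_interval(GenomicInterval("chrM", 0, 90), index)
        assert isinstance(m, MappingFailure)
        assert m.reason == "below_min_match"

    def test_unknown_chromosome(self):
        index = ChainIndex([simple_chain()])
        m = map_interval(GenomicInterval("chrZ", 0, 100), index)
        assert isinstance(m, MappingFailure) and m.reason == "no_chain"

    def test_minus_strand_images(self):
        # q file coords are on the reversed strand: image of t position p
        # is q_size - q_file - 1
        chain = simple_chain(q_strand="-")
        index = ChainIndex([chain])
        m = map_interval(GenomicInterval("chrM", 150, 250), index)
        imap = per_base_image_map(chain)
        images = [imap[p] for p in range(150, 250)]
        assert m.target.start == min(images)
        assert m.target.end == max(images) + 1
        assert m.target_strand == "-"

    def test_best_coverage_chain_wins_tie_by_score(self):
        c1 = simple_chain(score=10, cid=1)
        c2 = ChainAlignment(
            score=99,
            t_name="chrM",
            t_size=1000,
            t_strand="+",
            t_start=100,
            t_end=300,
            q_name="chrH",
            q_size=2000,
            q_strand="+",
            q_start=1200,
            q_end=1400,
            blocks=((200, 0, 0),),
            chain_id=2,
        )
        index = ChainIndex([c1, c2])
        m = map_interval(GenomicInterval("chrM", 150, 250), index)
        assert m.chain_id == 2  # equal coverage, higher score

    def test_identity_chain_is_identity(self):
        chain = ChainAlignment(
            score=1,
            t_name="c",
            t_size=5000,
            t_strand="+",
            t_start=0,
            t_end=5000,
            q_name="c2",
            q_size=5000,
            q_strand="+",
            q_start=0,
            q_end=5000,
            blocks=((5000, 0, 0),),
            chain_id=1,
        )
        index = ChainIndex([chain])
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = int(rng.integers(0, 4900))
            e = s + int(rng.integers(1, 100))
            m = map_interval(GenomicInterval("c", s, e), index)
            assert (m.target.start, m.target.end) == (s, e)
            assert m.mapped_fraction == 1.0

    def test_oracle_equivalence_random_chains(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            chains = [
                random_chain(rng, chain_id=i + 1) for i in range(3)
            ]
            index = ChainIndex(chains)
            t_max = max(c.t_end for c in chains)
            for _ in range(200):
                s = int(rng.integers(0, t_max))
                e = s + int(rng.integers(1, 300))
                iv = GenomicInterval("chrM", s, e)
                got = map_interval(iv, index)
                want = brute_force_map(iv, chains)
                if want is None:
                    assert isinstance(got, MappingFailure)
                else:
                    assert not isinstance(got, MappingFailure)
                    assert (
                        got.target.chrom,
                        got.target.start,
                        got.target.end,
                        got.chain_id,
                    ) == (want[0], want[1], want[2], want[4])
                    assert got.mapped_fraction == pytest.approx(want[3])

    def test_lowering_min_match_never_breaks_success(self):
        rng = np.random.default_rng(3)
        chains = [random_chain(rng, chain_id=1)]
        index = ChainIndex(chains)
        for _ in range(200):
            s = int(rng.integers(0, chains[0].t_end))
            iv = GenomicInterval("chrM", s, s + int(rng.integers(1, 200)))
            strict = map_interval(iv, index, MapperConfig(min_match=0.8))
            loose = map_interval(iv, index, MapperConfig(min_match=0.2))
            if not isinstance(strict, MappingFailure):
                assert not isinstance(loose, MappingFailure)


class TestClassify:
    def make_index(self):
        return ChainIndex([simple_chain()])

    def test_overlap_makes_sc_with_max_overlap_partner(self):
        index = self.make_index()
        src = [peak("chrM", 150, 250, "a")]
        dst = [
            peak("chrH", 600, 800, "big"),
            peak("chrH", 640, 660, "small"),
        ]
        (call,) = classify_peaks(src, dst, index)
        assert call.klass == "SC"
        assert call.partner_peak == "big"  # overlap 50 vs 20... big wins

    def test_adjacent_half_open_is_su(self):
        index = self.make_index()
        src = [peak("chrM", 150, 250, "a")]  # maps to chrH:[550,650)
        dst = [peak("chrH", 650, 800, "next")]
        (call,) = classify_peaks(src, dst, index)
        assert call.klass == "SU"

    def test_unmapped_is_un(self):
        index = self.make_index()
        (call,) = classify_peaks([peak("chrM", 0, 90, "a")], [], index)
        assert call.klass == "UN" and call.mapped is None

    def test_partition_invariant(self, small_dataset):
        ds = small_dataset
        index = ChainIndex(ds.scaffold.chains)
        for f in ds.cfg.factors:
            calls = classify_peaks(
                ds.peaks.source[f], ds.peaks.target[f], index
            )
            counts = {k: sum(c.klass == k for c in calls) for k in ("SC", "SU", "UN")}
            assert sum(counts.values()) == len(ds.peaks.source[f])

    def test_planted_truth_recovered_exactly(self, small_dataset):
        ds = small_dataset
        index = ChainIndex(ds.scaffold.chains)
        truth = ds.truth.set_index("name").klass.to_dict()
        for f in ds.cfg.factors:
            calls = classify_peaks(
                ds.peaks.source[f], ds.peaks.target[f], index
            )
            assert all(truth[c.name] == c.klass for c in calls)


class TestBackground:
    def test_dst_covering_genome_gives_rate_one(self):
        index = ChainIndex([simple_chain()])
        src = [peak("chrM", 150, 250, "a"), peak("chrM", 120, 220, "b")]
        dst = [peak("chrH", 0, 2000, "all")]
        res = background_conservation(
            src, dst, index, {"chrM": 1000}, {"chrH": 2000},
            n_shuffles=20, seed=0,
        )
        # src peaks may fail to map after shuffling, but every mapped peak
        # hits the whole-genome dst peak, so the SC rate equals the mapping
        # rate and never exceeds 1
        assert np.all(res.samples <= 1.0)

    def test_identity_chain_point_peaks_match_density(self):
        # With an identity chain and 1 bp source peaks, the chance that a
        # shuffled source peak lands inside a shuffled dst peak equals the
        # dst peak density d; mean SC rate -> d.
        L = 10_000
        chain = ChainAlignment(
            score=1, t_name="c", t_size=L, t_strand="+", t_start=0, t_end=L,
            q_name="q", q_size=L, q_strand="+", q_start=0, q_end=L,
            blocks=((L, 0, 0),), chain_id=1,
        )
        index = ChainIndex([chain])
        src = [peak("c", 0, 1, f"s{i}") for i in range(40)]
        dst = [peak("q", 0, 500, "d1"), peak("q", 1000, 1500, "d2")]
        d = 1000 / L
        res = background_conservation(
            src, dst, index, {"c": L}, {"q": L}, n_shuffles=300, seed=1
        )
        # per-peak hit prob is ~d (edge effects O(len/L)); 3 s.e. window
        se = np.sqrt(d * (1 - d) / (40 * 300))
        assert abs(res.mean - d) < 3 * se + 0.05 * d

    def test_peak_longer_than_chromosome_errors(self):
        index = ChainIndex([simple_chain()])
        with pytest.raises(ValueError, match="longer than"):
            background_conservation(
                [peak("chrM", 0, 900, "a")], [], index,
                {"chrM": 500}, {"chrH": 2000}, n_shuffles=1,
            )


class TestStrengthQuartiles:
    def _calls(self, classes):
        calls = []
        for i, k in enumerate(classes):
            mapped = None
            partner = None
            if k != "UN":
                mapped = synteny.MappedInterval(
                    GenomicInterval("a", 0, 1),
                    GenomicInterval("b", 0, 1),
                    1.0,
                    1,
                    "+",
                )
            if k == "SC":
                partner = f"x{i}"
            calls.append(synteny.ConservationCall(f"p{i}", k, mapped, partner))
        return calls

    def test_all_sc(self):
        classes = ["SC"] * 8
        peaks = [peak("c", i * 10, i * 10 + 5, f"p{i}", q=i) for i in range(8)]
        assert conservation_by_strength_quartile(
            self._calls(classes), peaks
        ) == (100, 100, 100, 100)

    def test_top_half_sc(self):
        # peaks p0..p7 with q descending 8..1; top 4 are SC
        peaks = [
            peak("c", i * 10, i * 10 + 5, f"p{i}", q=8 - i) for i in range(8)
        ]
        classes = ["SC"] * 4 + ["SU"] * 4
        assert conservation_by_strength_quartile(
            self._calls(classes), peaks
        ) == (100, 100, 0, 0)

    def test_remainder_goes_to_strong_groups(self):
        peaks = [
            peak("c", i * 10, i * 10 + 5, f"p{i}", q=9 - i) for i in range(9)
        ]
        classes = ["SC"] * 9
        # 9 syntenic peaks -> groups of 3,2,2,2
        assert conservation_by_strength_quartile(
            self._calls(classes), peaks
        ) == (100, 100, 100, 100)


class TestSummitSpectrum:
    def test_dst_at_images_concentrates_first_bin(self):
        index = ChainIndex([simple_chain()])
        src = [peak("chrM", 150, 250, "a", summit=50)]  # summit 200 -> 600
        dst = [peak("chrH", 550, 650, "b", summit=50)]  # summit 600
        res = summit_distance_spectrum(
            src, dst, index, {"chrH": 2000}, n_shuffles=50, seed=0
        )
        assert res.observed[0] == 1
        assert res.log2_ratio[0] > 0

    def test_independent_dst_within_null_band(self):
        # destination peaks placed uniformly -> observed histogram behaves
        # like one more shuffle; every bin inside the 99% shuffle envelope
        rng = np.random.default_rng(5)
        L = 200_000
        chain = ChainAlignment(
            score=1, t_name="c", t_size=L, t_strand="+", t_start=0, t_end=L,
            q_name="q", q_size=L, q_strand="+", q_start=0, q_end=L,
            blocks=((L, 0, 0),), chain_id=1,
        )
        index = ChainIndex([chain])
        src = [
            peak("c", int(s), int(s) + 100, f"s{i}", summit=50)
            for i, s in enumerate(rng.integers(0, L - 100, 150))
        ]
        dst = [
            peak("q", int(s), int(s) + 100, f"d{i}", summit=50)
            for i, s in enumerate(rng.integers(0, L - 100, 150))
        ]
        res = summit_distance_spectrum(
            src, dst, index, {"q": L}, n_shuffles=200, seed=1
        )
        lo = np.percentile(res.expected_samples, 0.5, axis=0)
        hi = np.percentile(res.expected_samples, 99.5, axis=0)
        assert np.all(res.observed >= lo - 1)
        assert np.all(res.observed <= hi + 1)


def test_syntenic_rate_simple():
    calls = [
        synteny.ConservationCall("a", "UN"),
        synteny.ConservationCall(
            "b",
            "SU",
            synteny.MappedInterval(
                GenomicInterval("x", 0, 1), GenomicInterval("y", 0, 1), 1.0, 1, "+"
            ),
        ),
    ]
    assert syntenic_rate(calls) == 0.5
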