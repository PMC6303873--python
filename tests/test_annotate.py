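"""TSS distances, target genes, hypergeometric overlap, repeats, persistence."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from crosstf import annotate
from crosstf.annotate import (
    TssRecord,
    assign_target_genes,
    hypergeom_sf,
    persistence_fraction,
    repeat_association,
    target_overlap_test,
    tss_distance_distribution,
)
from crosstf.formats import GenomicInterval, Peak
from crosstf.synteny import ConservationCall, MappedInterval

from helpers import brute_force_hypergeom_sf


def peak(chrom, start, end, name="p", summit=-1):
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        name=name,
        summit_offset=summit,
    )


class TestTssDistance:
    def test_binning(self):
        tss = [TssRecord("g1", "c", 1000)]
        peaks = [
            peak("c", 2950, 3050, "near"),  # summit 3000 -> distance 2000
            peak("c", 990, 1010, "exact", summit=10),  # summit 1000 -> 0
            peak("c", 200_000, 200_100, "far"),  # 199 kb -> third bin
        ]
        frac = tss_distance_distribution(peaks, tss)
        assert frac == pytest.approx([2 / 3, 0, 1 / 3, 0])

    def test_missing_chromosome_lands_in_last_bin(self):
        tss = [TssRecord("g1", "c", 1000)]
        frac = tss_distance_distribution([peak("other", 0, 10, "x")], tss)
        assert frac[-1] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        tss = [TssRecord(f"g{i}", "c", int(p)) for i, p in
               enumerate(rng.integers(0, 10**6, 50))]
        peaks = [
            peak("c", int(s), int(s) + 100, f"p{i}")
            for i, s in enumerate(rng.integers(0, 10**6 - 100, 500))
        ]
        assert tss_distance_distribution(peaks, tss).sum() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_uniform_summits_grid_tss_analytic(self):
        # TSS every 100 kb; uniform summits: |d| <= 5 kb has probability
        # 10/100, 5-50 kb probability 90/100 (50-500 kb impossible).
        spacing = 100_000
        L = 10_000_000
        tss = [
            TssRecord(f"g{i}", "c", i * spacing + spacing // 2)
            for i in range(L // spacing)
        ]
        rng = np.random.default_rng(1)
        n = 4000
        peaks = [
            peak("c", int(s), int(s) + 1, f"p{i}")
            for i, s in enumerate(rng.integers(0, L - 1, n))
        ]
        frac = tss_distance_distribution(peaks, tss)
        p0 = 10_000 / spacing
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(frac[0] - p0) < 3 * se
        assert frac[2] == 0 and frac[3] == 0


class TestTargets:
    def test_tie_goes_to_lexicographically_smaller(self):
        tss = [TssRecord("gB", "c", 900), TssRecord("gA", "c", 1100)]
        genes, per_peak = assign_target_genes(
            [peak("c", 950, 1050, "p", summit=50)], tss
        )
        assert per_peak["p"] == "gA"

    def test_distance_irrelevant(self):
        tss = [TssRecord("g", "c", 0)]
        genes, _ = assign_target_genes(
            [peak("c", 9_999_900, 10_000_000, "p")], tss
        )
        assert genes == {"g"}

    def test_union(self):
        tss = [TssRecord("g", "c", 100)]
        peaks = [peak("c", i * 10, i * 10 + 5, f"p{i}") for i in range(5)]
        genes, _ = assign_target_genes(peaks, tss)
        assert genes == {"g"}


class TestHypergeom:
    def test_exact_small_cases(self):
        assert hypergeom_sf(2, 4, 2, 2) == pytest.approx(1 / 6, rel=1e-12)
        assert hypergeom_sf(1, 4, 2, 2) == pytest.approx(5 / 6, rel=1e-12)
        assert hypergeom_sf(5, 10, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_sf(0, 100, 40, 30) == 1.0

    def test_above_support_raises(self):
        with pytest.raises(ValueError):
            hypergeom_sf(3, 4, 2, 2)
        with pytest.raises(ValueError):
            hypergeom_sf(1, 4, 5, 2)

    def test_enumeration_oracle_sample(self):
        # spot grid here; the exhaustive N <= 60 sweep runs in acceptance
        rng = np.random.default_rng(2)
        for _ in range(200):
            N = int(rng.integers(1, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, K + n - N)
            k = int(rng.integers(lo, min(K, n) + 1))
            want = brute_force_hypergeom_sf(k, N, K, n)
            assert hypergeom_sf(k, N, K, n) == pytest.approx(want, rel=1e-12)

    def test_large_population_matches_scipy(self):
        # the published-scale test: overlap 3919 of universe 15789
        p = hypergeom_sf(3919, 15789, 8433, 6867)
        assert p == pytest.approx(hypergeom.sf(3918, 15789, 8433, 6867), rel=1e-6)
        assert 1e-17 < p < 1e-14


class TestOverlapTest:
    ORTH = [(f"a{i}", f"b{i}") for i in range(10)]

    def test_exact_value(self):
        a = {f"a{i}" for i in range(5)}
        b = {f"b{i}" for i in range(5)}
        res = target_overlap_test(a, b, self.ORTH)
        assert res["overlap"] == 5
        assert res["p_value"] == pytest.approx(1 / 252, rel=1e-12)

    def test_symmetric(self):
        a = {f"a{i}" for i in (0, 1, 2, 5)}
        b = {f"b{i}" for i in (1, 2, 8)}
        r1 = target_overlap_test(a, b, self.ORTH)
        r2 = target_overlap_test(
            {f"a{i}" for i in (1, 2, 8)},
            {f"b{i}" for i in (0, 1, 2, 5)},
            self.ORTH,
        )
        assert r1["p_value"] == pytest.approx(r2["p_value"], rel=1e-12)

    def test_non_orthologs_dropped(self):
        res = target_overlap_test({"a0", "zzz"}, {"b0"}, self.ORTH)
        assert res["size_a"] == 1 and res["overlap"] == 1


class TestRepeats:
    def test_containment_rule(self):
        peaks = [peak("c", 100, 600, "p")]
        inside = [(GenomicInterval("c", 120, 180), "LINE")]
        straddle = [(GenomicInterval("c", 50, 150), "LINE")]
        assert repeat_association(peaks, inside)[0] == 1.0
        assert repeat_association(peaks, straddle)[0] == 0.0

    def test_multiple_families_per_peak(self):
        peaks = [peak("c", 0, 1000, "p")]
        reps = [
            (GenomicInterval("c", 10, 60), "SINE"),
            (GenomicInterval("c", 100, 160), "LTR"),
        ]
        overall, fams = repeat_association(peaks, reps)
        assert overall == 1.0
        assert fams["SINE"] == 1.0 and fams["LTR"] == 1.0

    def test_no_repeats(self):
        overall, fams = repeat_association([peak("c", 0, 100, "p")], [])
        assert overall == 0.0


class TestPersistence:
    def _call(self, name, klass):
        mapped = None
        partner = None
        if klass != "UN":
            mapped = MappedInterval(
                GenomicInterval("a", 0, 1), GenomicInterval("b", 0, 1), 1.0, 1, "+"
            )
        if klass == "SC":
            partner = "x"
        return ConservationCall(name, klass, mapped, partner)

    def test_identical_sets_100_percent(self):
        peaks = [peak("c", 0, 100, "p1"), peak("c", 500, 600, "p2")]
        calls = [self._call("p1", "SC"), self._call("p2", "UN")]
        pct = persistence_fraction(peaks, peaks, calls)
        assert pct == {"SC": 100.0, "SU": None, "UN": 100.0}

    def test_empty_pluripotent_set(self):
        peaks = [peak("c", 0, 100, "p1")]
        pct = persistence_fraction(peaks, [], [self._call("p1", "SU")])
        assert pct["SU"] == 0.0

    def test_planted_rates_recovered(self, default_dataset):
        # per factor (the function's contract is same-factor overlap),
        # pooled over the four factors for stable counts
        ds = default_dataset
        truth = ds.truth
        num = {"SC": 0.0, "SU": 0.0, "UN": 0.0}
        den = {"SC": 0, "SU": 0, "UN": 0}
        for f in ds.cfg.factors:
            sub = truth[truth.factor == f]
            calls = [
                self._call(r.name, r.klass) for r in sub.itertuples(index=False)
            ]
            pct = persistence_fraction(
                ds.peaks.source[f], ds.peaks.esc[f], calls
            )
            counts = sub.klass.value_counts()
            for cls in ("SC", "SU", "UN"):
                if pct[cls] is not None:
                    num[cls] += pct[cls] / 100 * counts.get(cls, 0)
                    den[cls] += counts.get(cls, 0)
        for cls, planted in zip(("SC", "SU", "UN"), ds.cfg.esc_persistence):
            assert abs(num[cls] / den[cls] - planted) < 0.05
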