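"""Binarization, Bernoulli-emission HMM training and state assignment."""

import numpy as np
import pytest
from scipy.stats import poisson

from crosstf import chromstate
from crosstf.chromstate import (
    BinnedMarks,
    ChromatinHMM,
    StateSegmentation,
    assign_peak_state,
    binarize_counts,
    concat_corpus,
    decode_states,
    fit_hmm,
    posterior_marginals,
    sample_hmm,
    segment_log_likelihood,
    state_enrichment,
)
from crosstf.formats import GenomicInterval, Peak

from helpers import brute_force_hmm_loglik


def binned(counts, marks=("m1",), species="sp", bin_size=200):
    return BinnedMarks(
        species, bin_size, tuple(marks), {"chr1": np.asarray(counts)}
    )


class TestBinarize:
    def test_poisson_cutoff_lambda_one(self):
        # mean 1 per construction; smallest c with P[X >= c] <= 1e-4 is 7
        counts = np.ones((1000, 1), dtype=int)
        b = binarize_counts(binned(counts))
        assert b.thresholds == (7,)
        assert poisson.sf(5, 1.0) > 1e-4 >= poisson.sf(6, 1.0)

    def test_all_zero_mark_warns_and_zeroes(self):
        counts = np.zeros((100, 1), dtype=int)
        with pytest.warns(UserWarning, match="all-zero"):
            b = binarize_counts(binned(counts))
        assert b.segments["chr1"].sum() == 0

    def test_threshold_one_gives_all_ones(self):
        counts = np.zeros((100, 1), dtype=int)
        b = binarize_counts(binned(counts + 1), p_threshold=1.0)
        assert b.segments["chr1"].all()


class TestCorpus:
    def test_pooling_counts_segments(self):
        a = binarize_counts(
            BinnedMarks("a", 200, ("m",), {"c1": np.ones((10, 1)), "c2": np.ones((10, 1))})
        )
        b = binarize_counts(
            BinnedMarks(
                "b",
                200,
                ("m",),
                {"c3": np.ones((10, 1)), "c4": np.ones((10, 1)), "c5": np.ones((10, 1))},
            )
        )
        corpus = concat_corpus(a, b)
        assert len(corpus.segments) == 5

    def test_mark_mismatch_raises(self):
        a = binarize_counts(
            BinnedMarks("a", 200, ("m1", "m2"), {"c": np.ones((10, 2))})
        )
        b = binarize_counts(
            BinnedMarks("b", 200, ("m2", "m1"), {"c": np.ones((10, 2))})
        )
        with pytest.raises(ValueError, match="mark mismatch"):
            concat_corpus(a, b)

    def test_single_species(self):
        a = binarize_counts(BinnedMarks("a", 200, ("m",), {"c": np.ones((10, 1))}))
        assert len(concat_corpus(a, None).segments) == 1


def random_corpus(rng, n_bins=200, n_marks=3, n_segments=2):
    segs = [
        ("sp", f"c{i}", (rng.random((n_bins, n_marks)) < 0.3).astype(np.uint8))
        for i in range(n_segments)
    ]
    return chromstate.Corpus(200, tuple(f"m{j}" for j in range(n_marks)), segs)


class TestFitHMM:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(0)
        corpus = random_corpus(rng)
        hmm = fit_hmm(corpus, n_states=1)
        allX = np.concatenate([s for _, _, s in corpus.segments])
        f = allX.mean(axis=0)
        assert hmm.emissions[0] == pytest.approx(f)
        # closed-form Bernoulli log-likelihood
        n = len(allX)
        expected = float(
            sum(
                n * (fi * np.log(fi) + (1 - fi) * np.log(1 - fi))
                for fi in f
                if 0 < fi < 1
            )
        )
        assert hmm.log_likelihoods[-1] == pytest.approx(expected, rel=1e-9)

    def test_forward_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        for K in (2, 3):
            init = rng.dirichlet(np.ones(K))
            trans = rng.dirichlet(np.ones(K), size=K)
            emis = rng.uniform(0.1, 0.9, (K, 2))
            hmm = ChromatinHMM(init, trans, emis, ("m1", "m2"))
            for T in (1, 4, 8):
                X = (rng.random((T, 2)) < 0.5).astype(np.uint8)
                want = brute_force_hmm_loglik(X, init, trans, emis)
                got = segment_log_likelihood(hmm, X)
                assert got == pytest.approx(want, rel=1e-10)

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        corpus = random_corpus(rng, n_bins=300)
        hmm = fit_hmm(corpus, n_states=3, seed=5, max_iter=40)
        lls = np.array(hmm.log_likelihoods)
        assert np.all(np.diff(lls) >= -1e-6)

    def test_segment_order_invariance(self):
        rng = np.random.default_rng(3)
        corpus = random_corpus(rng, n_segments=3)
        reversed_corpus = chromstate.Corpus(
            corpus.bin_size, corpus.mark_names, corpus.segments[::-1]
        )
        h1 = fit_hmm(corpus, n_states=2, seed=1, max_iter=10)
        h2 = fit_hmm(reversed_corpus, n_states=2, seed=1, max_iter=10)
        assert h1.emissions == pytest.approx(h2.emissions)
        assert h1.transitions == pytest.approx(h2.transitions)

    def test_too_few_bins(self):
        rng = np.random.default_rng(4)
        corpus = random_corpus(rng, n_bins=5, n_segments=1)
        with pytest.raises(ValueError):
            fit_hmm(corpus, n_states=4)

    def test_two_state_recovery(self):
        # planted 2-state chain: emissions recovered up to permutation
        truth = ChromatinHMM(
            initial=np.array([0.5, 0.5]),
            transitions=np.array([[0.95, 0.05], [0.05, 0.95]]),
            emissions=np.array([[0.9, 0.9, 0.1], [0.1, 0.1, 0.9]]),
            mark_names=("a", "b", "c"),
        )
        states, obs = sample_hmm(truth, [4000], seed=9)
        corpus = chromstate.Corpus(200, truth.mark_names, [("s", "c", obs[0])])
        hmm = fit_hmm(corpus, n_states=2, seed=0)
        perm = (
            (0, 1)
            if abs(hmm.emissions[0, 0] - 0.9) < abs(hmm.emissions[1, 0] - 0.9)
            else (1, 0)
        )
        assert np.abs(
            hmm.emissions[list(perm)] - truth.emissions
        ).max() < 0.05


class TestDecode:
    def test_k1_all_state_one(self):
        rng = np.random.default_rng(0)
        corpus = random_corpus(rng)
        hmm = fit_hmm(corpus, n_states=1)
        segs = decode_states(hmm, corpus)
        assert all(
            (s == 1).all() for s in segs["sp"].states.values()
        )

    def test_noiseless_emissions_recover_exactly(self):
        hmm = ChromatinHMM(
            initial=np.array([0.5, 0.5]),
            transitions=np.array([[0.9, 0.1], [0.1, 0.9]]),
            emissions=np.array([[1.0, 0.0], [0.0, 1.0]]),
            mark_names=("a", "b"),
        )
        states, obs = sample_hmm(hmm, [500], seed=3)
        corpus = chromstate.Corpus(200, hmm.mark_names, [("s", "c", obs[0])])
        segs = decode_states(hmm, corpus)
        assert np.array_equal(segs["s"].states["c"] - 1, states[0])

    def test_posterior_rows_normalized(self):
        rng = np.random.default_rng(5)
        corpus = random_corpus(rng)
        hmm = fit_hmm(corpus, n_states=3, seed=2, max_iter=5)
        gamma = posterior_marginals(hmm, corpus.segments[0][2])
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestPeakStates:
    def seg(self, states, bin_size=200):
        return StateSegmentation(
            "sp", bin_size, int(max(states)), {"c": np.asarray(states)}
        )

    def test_max_overlap(self):
        # peak [100,600) over bins with states 2,2,7 -> overlaps 100+200 vs 200
        seg = self.seg([2, 2, 7])
        p = Peak(interval=GenomicInterval("c", 100, 600), name="p")
        assert assign_peak_state([p], seg)[0] == 2

    def test_single_bin(self):
        seg = self.seg([4, 5])
        p = Peak(interval=GenomicInterval("c", 210, 280), name="p")
        assert assign_peak_state([p], seg)[0] == 5

    def test_tie_broken_by_summit_bin(self):
        seg = self.seg([3, 9])
        p = Peak(
            interval=GenomicInterval("c", 100, 300),
            name="p",
            summit_offset=150,  # summit 250 -> bin 1 -> state 9
        )
        assert assign_peak_state([p], seg)[0] == 9

    def test_unsegmented_chromosome_raises(self):
        seg = self.seg([1])
        p = Peak(interval=GenomicInterval("zzz", 0, 10), name="p")
        with pytest.raises(ValueError, match="not segmented"):
            assign_peak_state([p], seg)


class TestStateEnrichment:
    def test_proportional_peaks_flat(self):
        seg = StateSegmentation(
            "sp", 200, 2, {"c": np.array([1] * 90 + [2] * 10)}
        )
        peak_states = np.array([1] * 90 + [2] * 10)
        enr = state_enrichment(peak_states, seg)
        assert np.abs(enr["log2_enrichment"]).max() < 1e-3

    def test_concentration_arithmetic(self):
        seg = StateSegmentation(
            "sp", 200, 3, {"c": np.array([1] * 80 + [2] * 10 + [3] * 10)}
        )
        peak_states = np.array([3] * 50)
        enr = state_enrichment(peak_states, seg)
        assert enr["log2_enrichment"][2] == pytest.approx(np.log2(1.0 / 0.1), abs=1e-3)
        assert enr["genome_fraction"].sum() == pytest.approx(1.0)
        assert enr["peak_fraction"].sum() == pytest.approx(1.0)
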