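"""Chromatin-state modelling on a concatenated two-species genome.

The model is a K-state hidden Markov model over fixed-width genomic bins
(default 200 bp) with independent Bernoulli emissions per histone mark —
the ChromHMM model family, trained here by Baum–Welch EM on the pooled
binarized bins of both species so that a *single* set of emission
probabilities describes both genomes.  Each chromosome is an independent
chain; no transitions cross chromosome (or species) boundaries.

Binarization follows the ChromHMM convention: per mark, a global Poisson
rate equal to the mean bin count, a bin being "on" when its count clears the
upper-tail threshold (default p <= 1e-4).

Decoding is per-bin posterior argmax (forward–backward), ChromHMM's
behaviour, with Viterbi available as an alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .formats import GenomicInterval, Peak

__all__ = [
    "BinnedMarks",
    "BinarizedTracks",
    "Corpus",
    "ChromatinHMM",
    "StateSegmentation",
    "binarize_counts",
    "concat_corpus",
    "fit_hmm",
    "decode_states",
    "sample_hmm",
    "assign_peak_state",
    "state_enrichment",
]

_EMIT_EPS = 1e-6


@dataclass
class BinnedMarks:
    """Per-chromosome histone-mark count matrices for one species.

    ``segments`` maps chromosome name -> (n_bins x n_marks) integer counts;
    the final bin of a chromosome may cover a short tail.
    """

    species: str
    bin_size: int
    mark_names: tuple[str, ...]
    segments: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, mat in self.segments.items():
            if mat.ndim != 2 or mat.shape[1] != len(self.mark_names):
                raise ValueError(f"{chrom}: bad count matrix shape {mat.shape}")
            if (mat < 0).any():
                raise ValueError(f"{chrom}: negative counts")


@dataclass
class BinarizedTracks:
    species: str
    bin_size: int
    mark_names: tuple[str, ...]
    segments: dict[str, np.ndarray]  # uint8 matrices
    thresholds: tuple[int, ...] = ()


@dataclass
class Corpus:
    """Training corpus: binarized segments pooled across species."""

    bin_size: int
    mark_names: tuple[str, ...]
    segments: list[tuple[str, str, np.ndarray]]  # (species, chrom, binary)


def binarize_counts(
    binned: BinnedMarks, p_threshold: float = 1e-4
) -> BinarizedTracks:
    """Binarize counts against a global per-mark Poisson background.

    For each mark the rate lambda is the mean count over all bins; a bin is
    1 iff the Poisson upper tail P[X >= count] <= ``p_threshold``, i.e.
    count >= the smallest c with sf(c - 1) <= threshold.  An all-zero mark
    yields an all-zero column (with a warning).
    """
    mats = list(binned.segments.values())
    all_counts = np.concatenate(mats, axis=0)
    thresholds = []
    for m, mark in enumerate(binned.mark_names):
        lam = float(all_counts[:, m].mean())
        if lam == 0:
            warnings.warn(f"mark {mark}: all-zero counts")
            thresholds.append(np.iinfo(np.int64).max)
            continue
        if p_threshold >= 1.0:
            thresholds.append(0)
            continue
        # smallest c with P[X >= c] <= p_threshold
        c = int(poisson.isf(p_threshold, lam)) + 1
        while c > 0 and poisson.sf(c - 2, lam) <= p_threshold:
            c -= 1
        thresholds.append(c)
    thr = np.array(thresholds)
    segments = {
        chrom: (mat >= thr[None, :]).astype(np.uint8)
        for chrom, mat in binned.segments.items()
    }
    return BinarizedTracks(
        binned.species,
        binned.bin_size,
        binned.mark_names,
        segments,
        tuple(int(t) for t in thresholds),
    )


def concat_corpus(a: BinarizedTracks, b: BinarizedTracks | None) -> Corpus:
    """Pool both species' binarized segments into one training corpus.

    Mark names and order must match exactly; each chromosome remains an
    independent chain (the concatenation is of the corpus, not of the
    coordinate systems).
    """
    if b is not None and a.mark_names != b.mark_names:
        sym = set(a.mark_names) ^ set(b.mark_names)
        raise ValueError(
            f"mark mismatch between species: order/sets differ ({sorted(sym) or 'order'})"
        )
    if b is not None and a.bin_size != b.bin_size:
        raise ValueError("bin sizes differ between species")
    segments = [(a.species, c, m) for c, m in a.segments.items()]
    if b is not None:
        segments += [(b.species, c, m) for c, m in b.segments.items()]
    return Corpus(a.bin_size, a.mark_names, segments)


@dataclass
class ChromatinHMM:
    """Bernoulli-emission HMM: initial (K), transitions (K x K, rows sum to
    1), emissions (K x M Bernoulli probabilities per mark)."""

    initial: np.ndarray
    transitions: np.ndarray
    emissions: np.ndarray
    mark_names: tuple[str, ...]
    log_likelihoods: list[float] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_states(self) -> int:
        return len(self.initial)

    def __post_init__(self) -> None:
        K = self.n_states
        if self.transitions.shape != (K, K):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        for arr in (self.initial, self.transitions, self.emissions):
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError("probabilities outside [0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_states": self.n_states,
            "mark_names": list(self.mark_names),
            "initial": self.initial.tolist(),
            "transitions": self.transitions.tolist(),
            "emissions": self.emissions.tolist(),
            "log_likelihoods": self.log_likelihoods,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromatinHMM":
        d = json.loads(Path(path).read_text())
        return cls(
            initial=np.array(d["initial"]),
            transitions=np.array(d["transitions"]),
            emissions=np.array(d["emissions"]),
            mark_names=tuple(d["mark_names"]),
            log_likelihoods=list(d.get("log_likelihoods", [])),
            seed=d.get("seed"),
        )


def _log_emission(X: np.ndarray, emissions: np.ndarray) -> np.ndarray:
    """(T x K) log P[x_t | state k] for binary X (T x M)."""
    e = np.clip(emissions, _EMIT_EPS, 1 - _EMIT_EPS)
    return X @ np.log(e).T + (1 - X) @ np.log(1 - e).T


def _forward_backward(
    logB: np.ndarray, initial: np.ndarray, trans: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Scaled forward-backward.

    Returns (gamma, xi_sum, alpha_hat, loglik) where gamma is the posterior
    (T x K), xi_sum the summed transition responsibilities (K x K).
    """
    T, K = logB.shape
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = initial * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    loglik = float(np.log(scale).sum() + logB.max(axis=1).sum())

    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = (trans @ bb) / scale[t + 1]
        xi_sum += np.outer(alpha[t], bb / scale[t + 1]) * trans
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi_sum, alpha, loglik


def segment_log_likelihood(
    hmm: ChromatinHMM, X: np.ndarray
) -> float:
    """Forward log-likelihood of one binary segment under the model."""
    logB = _log_emission(X.astype(float), hmm.emissions)
    _, _, _, ll = _forward_backward(logB, hmm.initial, hmm.transitions)
    return ll


def fit_hmm(
    corpus: Corpus,
    n_states: int = 15,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    self_transition_prior: float = 0.9,
) -> ChromatinHMM:
    """Baum–Welch EM for the Bernoulli-emission chromatin-state HMM.

    Initialization: emissions from a seeded random-responsibility split of
    the bins; transitions uniform with ``self_transition_prior`` mass on the
    diagonal.  The log-likelihood is asserted non-decreasing each iteration;
    training stops at relative improvement below ``tol`` or ``max_iter``.
    A state that loses all responsibility triggers one re-seed, then an
    error.
    """
    K = n_states
    if K < 1:
        raise ValueError("n_states must be >= 1")
    data = [seg.astype(float) for _, _, seg in corpus.segments]
    total_bins = sum(len(x) for x in data)
    if K > total_bins:
        raise ValueError("more states than bins")
    if K >= 2 and total_bins < 10 * K:
        raise ValueError(f"need >= {10 * K} bins to fit {K} states")
    M = len(corpus.mark_names)

    if K == 1:
        # closed form: emissions are the empirical mark frequencies
        allX = np.concatenate(data, axis=0)
        emis = allX.mean(axis=0, keepdims=True)
        hmm = ChromatinHMM(
            initial=np.ones(1),
            transitions=np.ones((1, 1)),
            emissions=emis,
            mark_names=corpus.mark_names,
            seed=seed,
        )
        ll = sum(segment_log_likelihood(hmm, x.astype(np.uint8)) for x in data)
        hmm.log_likelihoods.append(ll)
        return hmm

    for attempt in range(2):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        allX = np.concatenate(data, axis=0)
        # k-means-style seeding: emissions around the K most frequent
        # distinct mark patterns (random rows fill in when the data shows
        # fewer), shrunk toward 1/2 so no state starts deterministic
        uniq, counts = np.unique(allX, axis=0, return_counts=True)
        order = np.argsort(-counts)
        # greedy diversity pass: a pattern one bit away from an already
        # chosen (more frequent) seed is usually its noise shadow
        chosen: list[np.ndarray] = []
        skipped: list[np.ndarray] = []
        for i in order:
            row = uniq[i]
            if any(np.abs(row - c).sum() <= 1 for c in chosen):
                skipped.append(row)
            else:
                chosen.append(row)
            if len(chosen) == K:
                break
        for row in skipped:
            if len(chosen) == K:
                break
            chosen.append(row)
        exemplars = np.array(chosen, dtype=float)
        if len(exemplars) < K:
            extra = allX[rng.choice(total_bins, size=K - len(exemplars))]
            exemplars = np.vstack([exemplars, extra])
        emis = 0.7 * exemplars + 0.15 + rng.uniform(-0.02, 0.02, (K, M))
        trans = np.full((K, K), (1 - self_transition_prior) / (K - 1))
        np.fill_diagonal(trans, self_transition_prior)
        initial = np.full(K, 1.0 / K)

        prev_ll = -np.inf
        lls: list[float] = []
        degenerate = False
        for _ in range(max_iter):
            gamma_sum = np.zeros(K)
            emit_num = np.zeros((K, M))
            xi_total = np.zeros((K, K))
            init_sum = np.zeros(K)
            ll = 0.0
            for X in data:
                logB = _log_emission(X, emis)
                gamma, xi, _, seg_ll = _forward_backward(logB, initial, trans)
                ll += seg_ll
                gamma_sum += gamma.sum(axis=0)
                emit_num += gamma.T @ X
                xi_total += xi
                init_sum += gamma[0]
            if ll + 1e-6 < prev_ll:
                raise AssertionError(
                    f"EM log-likelihood decreased: {prev_ll} -> {ll}"
                )
            lls.append(ll)
            if gamma_sum.min() < 1e-8:
                degenerate = True
                break
            converged = (
                np.isfinite(prev_ll)
                and abs(ll - prev_ll) <= tol * abs(prev_ll)
            )
            prev_ll = ll
            # M-step
            initial = init_sum / init_sum.sum()
            row = xi_total.sum(axis=1, keepdims=True)
            trans = np.where(row > 0, xi_total / np.where(row == 0, 1, row), trans)
            trans /= trans.sum(axis=1, keepdims=True)
            emis = np.clip(
                emit_num / gamma_sum[:, None], _EMIT_EPS, 1 - _EMIT_EPS
            )
            if converged:
                break
        if degenerate and attempt == 0:
            continue
        if degenerate:
            raise RuntimeError("degenerate state after re-seeding")
        return ChromatinHMM(
            initial=initial,
            transitions=trans,
            emissions=emis,
            mark_names=corpus.mark_names,
            log_likelihoods=lls,
            seed=seed,
        )
    raise RuntimeError("unreachable")


@dataclass
class StateSegmentation:
    """Per-bin state assignment (states numbered 1..K) for one species."""

    species: str
    bin_size: int
    n_states: int
    states: dict[str, np.ndarray]  # chrom -> int array of state ids (1-based)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.states:
                s = self.states[chrom]
                if len(s) == 0:
                    continue
                # merge runs
                change = np.nonzero(np.diff(s))[0]
                starts = np.concatenate(([0], change + 1))
                ends = np.concatenate((change + 1, [len(s)]))
                for a, b in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{a * self.bin_size}\t{b * self.bin_size}"
                        f"\tE{s[a]}\n"
                    )

    def genome_state_fractions(self) -> np.ndarray:
        counts = np.zeros(self.n_states)
        for s in self.states.values():
            counts += np.bincount(s - 1, minlength=self.n_states)
        return counts / counts.sum()


def decode_states(
    hmm: ChromatinHMM,
    corpus: Corpus,
    method: Literal["posterior", "viterbi"] = "posterior",
) -> dict[str, StateSegmentation]:
    """Decode every corpus segment; returns one segmentation per species.

    Posterior decoding takes the per-bin forward–backward argmax (ties to
    the lower state id, guaranteed by argmax order).
    """
    per_species: dict[str, dict[str, np.ndarray]] = {}
    for species, chrom, X in corpus.segments:
        logB = _log_emission(X.astype(float), hmm.emissions)
        if method == "posterior":
            gamma, _, _, _ = _forward_backward(
                logB, hmm.initial, hmm.transitions
            )
            states = gamma.argmax(axis=1) + 1
        else:
            states = _viterbi(logB, hmm.initial, hmm.transitions) + 1
        per_species.setdefault(species, {})[chrom] = states.astype(np.int64)
    return {
        sp: StateSegmentation(sp, corpus.bin_size, hmm.n_states, segs)
        for sp, segs in per_species.items()
    }


def posterior_marginals(hmm: ChromatinHMM, X: np.ndarray) -> np.ndarray:
    """(T x K) posterior state probabilities for one binary segment."""
    logB = _log_emission(X.astype(float), hmm.emissions)
    gamma, _, _, _ = _forward_backward(logB, hmm.initial, hmm.transitions)
    return gamma


def _viterbi(
    logB: np.ndarray, initial: np.ndarray, trans: np.ndarray
) -> np.ndarray:
    T, K = logB.shape
    logT = np.log(np.clip(trans, 1e-300, None))
    delta = np.log(np.clip(initial, 1e-300, None)) + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logT
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def sample_hmm(
    hmm: ChromatinHMM, lengths: Sequence[int], seed: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Sample (states, binary observations) for segments of given lengths.

    Used to build planted-truth corpora for model-recovery checks.
    """
    rng = np.random.default_rng(seed)
    K = hmm.n_states
    states_out, obs_out = [], []
    for T in lengths:
        states = np.empty(T, dtype=np.int64)
        states[0] = rng.choice(K, p=hmm.initial)
        for t in range(1, T):
            states[t] = rng.choice(K, p=hmm.transitions[states[t - 1]])
        probs = hmm.emissions[states]
        obs = (rng.random(probs.shape) < probs).astype(np.uint8)
        states_out.append(states)
        obs_out.append(obs)
    return states_out, obs_out


def assign_peak_state(
    peaks: Sequence[Peak], seg: StateSegmentation
) -> np.ndarray:
    """State id (1..K) per peak: the state with maximal bp overlap with the
    peak; tie -> state of the summit bin; still tied -> lower id."""
    out = np.empty(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        states = seg.states.get(p.interval.chrom)
        if states is None:
            raise ValueError(f"chromosome {p.interval.chrom} not segmented")
        bs = seg.bin_size
        b0 = p.interval.start // bs
        b1 = (p.interval.end - 1) // bs
        b1 = min(b1, len(states) - 1)
        if b0 >= len(states):
            raise ValueError(f"peak {p.name} beyond segmented region")
        overlap: dict[int, int] = {}
        for b in range(b0, b1 + 1):
            lo = max(p.interval.start, b * bs)
            hi = min(p.interval.end, (b + 1) * bs)
            s = int(states[b])
            overlap[s] = overlap.get(s, 0) + (hi - lo)
        best = max(overlap.values())
        tied = sorted(s for s, v in overlap.items() if v == best)
        if len(tied) == 1:
            out[i] = tied[0]
        else:
            summit_bin = min(p.summit // bs, len(states) - 1)
            summit_state = int(states[summit_bin])
            out[i] = summit_state if summit_state in tied else tied[0]
    return out


def state_enrichment(
    peak_states: np.ndarray, seg: StateSegmentation, eps: float = 1e-6
) -> dict[str, np.ndarray]:
    """Per state: fraction of peaks, fraction of genome, log2 enrichment."""
    if len(peak_states) == 0:
        raise ValueError("need at least one peak")
    K = seg.n_states
    peak_frac = np.bincount(peak_states - 1, minlength=K) / len(peak_states)
    genome_frac = seg.genome_state_fractions()
    log2 = np.log2((peak_frac + eps) / (genome_frac + eps))
    return {
        "peak_fraction": peak_frac,
        "genome_fraction": genome_frac,
        "log2_enrichment": log2,
    }
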