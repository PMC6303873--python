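"""PWM scanning with an exact score->p-value map.

A position frequency matrix is turned into a log2 likelihood-ratio PWM over
a background base composition, and the *exact* distribution of the
(discretized) score of a random background k-mer is computed by dynamic
programming over columns — the standard lattice construction used by
FIMO/MOODS/TFM-Pvalue.  A window is a hit when its score's upper-tail
probability is at or below the p-value cutoff (default 0.001).  Both
strands are scanned; windows containing N are skipped; a peak "has the
motif" when any window inside it is a hit (per-window p-values, no
multiple-testing correction — the per-peak presence/absence usage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .formats import PFM, GenomicInterval, Peak

__all__ = [
    "PWM",
    "ScoreDistribution",
    "MotifHit",
    "pfm_to_pwm",
    "score_distribution",
    "scan_interval",
    "motif_occurrence_flags",
    "top_summit_sequences",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PWM:
    """Log2 likelihood-ratio scores, ``scores[pos][base]``, plus background."""

    name: str
    scores: tuple[tuple[float, float, float, float], ...]
    background: tuple[float, float, float, float] = UNIFORM_BG

    @property
    def width(self) -> int:
        return len(self.scores)

    def matrix(self) -> np.ndarray:
        return np.array(self.scores, dtype=float)

    def max_score(self) -> float:
        return float(self.matrix().max(axis=1).sum())


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] = UNIFORM_BG,
    pseudocount: float = 0.01,
    score_floor: float = -30.0,
) -> PWM:
    """Column-normalize the PFM and convert to log2 odds against background.

    score(i, b) = log2((p_ib + pseudocount * bg_b) / ((1 + pseudocount) * bg_b)),
    with zero-probability cells clamped at ``score_floor`` when
    ``pseudocount`` is 0.
    """
    bg = np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background probabilities must be positive")
    bg = bg / bg.sum()
    rows = []
    for col in pfm.counts:
        total = sum(col)
        if total <= 0:
            raise ValueError(f"PFM {pfm.name}: zero-sum column")
        p = np.array(col, dtype=float) / total
        with np.errstate(divide="ignore"):
            s = np.log2((p + pseudocount * bg) / ((1 + pseudocount) * bg))
        s = np.maximum(s, score_floor)
        rows.append(tuple(float(x) for x in s))
    return PWM(pfm.name, tuple(rows), tuple(float(x) for x in bg))


@dataclass
class ScoreDistribution:
    """Exact upper-tail probabilities of the discretized PWM score.

    Scores are held on an integer lattice: ``int_score = round(score/step)``.
    ``tail[i]`` is P[discretized score >= offset + i] under the background
    model; the tail is 1 at -inf and non-increasing in the score.
    """

    step: float
    offset: int  # lattice index of tail[0]
    tail: np.ndarray
    int_matrix: np.ndarray  # width x 4 integer lattice scores

    def pvalue(self, score: float) -> float:
        """Upper-tail probability of a raw (undiscretized) score."""
        return self.pvalue_int(int(round(score / self.step)))

    def pvalue_int(self, int_score: int) -> float:
        i = int_score - self.offset
        if i < 0:
            return 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])

    def int_threshold(self, p_threshold: float) -> int:
        """Smallest lattice score whose tail probability is <= threshold
        (one past the lattice top when no score qualifies)."""
        idx = int(np.searchsorted(-self.tail, -p_threshold, side="left"))
        return self.offset + idx


def score_distribution(pwm: PWM, step: float = 0.01) -> ScoreDistribution:
    """Exact background distribution of the discretized score by positional
    convolution (dynamic programming over PWM columns)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if pwm.width > 30:
        raise ValueError("width > 30 not supported by the exact DP")
    mat = pwm.matrix()
    int_mat = np.round(mat / step).astype(np.int64)
    bg = np.asarray(pwm.background)

    lo = int(int_mat.min(axis=1).sum())
    hi = int(int_mat.max(axis=1).sum())
    size = hi - lo + 1
    dist = np.zeros(size)
    # start with the first column
    first_lo = int(int_mat[0].min())
    for b in range(4):
        dist[int_mat[0, b] - first_lo] += bg[b]
    cur_lo = first_lo
    cur_len = int(int_mat[0].max()) - first_lo + 1
    for i in range(1, pwm.width):
        col = int_mat[i]
        col_lo, col_hi = int(col.min()), int(col.max())
        new_lo = cur_lo + col_lo
        new_len = cur_len + (col_hi - col_lo)
        new = np.zeros(new_len)
        for b in range(4):
            off = int(col[b]) - col_lo
            new[off : off + cur_len] += bg[b] * dist[:cur_len]
        dist = new
        cur_lo, cur_len = new_lo, new_len
    tail = np.cumsum(dist[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(step, cur_lo, tail, int_mat)


@dataclass(frozen=True)
class MotifHit:
    offset: int  # window start within the scanned sequence
    strand: str
    score: float
    p_value: float


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        code[arr == ord(base)] = idx
    return code


def _window_int_scores(
    code: np.ndarray, int_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Integer lattice scores for every window plus validity mask."""
    w = len(int_mat)
    n = len(code) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    padded = np.vstack([int_mat.T, np.zeros(w, dtype=np.int64)])  # N row
    for j in range(w):
        col = code[j : j + n]
        scores += padded[col, j]
        valid &= col != 4
    return scores, valid


def scan_interval(
    sequence: str,
    pwm: PWM,
    dist: ScoreDistribution,
    p_threshold: float = 0.001,
) -> list[MotifHit]:
    """Scan one sequence on both strands; a window is a hit when its exact
    upper-tail probability is <= ``p_threshold``."""
    code = _encode(sequence)
    w = pwm.width
    if len(code) < w:
        return []
    hits: list[MotifHit] = []
    rc = _COMPLEMENT[np.clip(code[::-1], 0, 3)]
    rc[code[::-1] == 4] = 4
    thr = dist.int_threshold(p_threshold)
    for strand, arr in (("+", code), ("-", rc)):
        scores, valid = _window_int_scores(arr, dist.int_matrix)
        for i in np.nonzero(valid & (scores >= thr))[0]:
            p = dist.pvalue_int(int(scores[i]))
            offset = int(i) if strand == "+" else len(code) - w - int(i)
            hits.append(
                MotifHit(offset, strand, float(scores[i]) * dist.step, p)
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def motif_occurrence_flags(
    intervals: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    pwm: PWM,
    dist: ScoreDistribution,
    p_threshold: float = 0.001,
) -> np.ndarray:
    """Boolean per interval: does it contain >= 1 motif hit?

    Works on any intervals — peak intervals in the peaks' own genome, or
    mapped orthologous intervals in the other genome.
    """
    flags = np.zeros(len(intervals), dtype=bool)
    for i, iv in enumerate(intervals):
        seq = genome.get(iv.chrom)
        if seq is None or iv.end > len(seq):
            raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} outside genome")
        hits = scan_interval(seq[iv.start : iv.end], pwm, dist, p_threshold)
        flags[i] = len(hits) > 0
    return flags


def peak_flags(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwm: PWM,
    dist: ScoreDistribution,
    p_threshold: float = 0.001,
) -> np.ndarray:
    return motif_occurrence_flags(
        [p.interval for p in peaks], genome, pwm, dist, p_threshold
    )


def top_summit_sequences(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    n: int = 10000,
    flank: int = 100,
) -> dict[str, str]:
    """Summit-centred sequences of the strongest peaks (utility for external
    de novo motif discovery): top ``n`` by -log10(q), each summit with
    ``flank`` bp on either side, clipped at chromosome ends."""
    ranked = sorted(peaks, key=lambda p: (-p.neglog10_q, p.name))[:n]
    out: dict[str, str] = {}
    for p in ranked:
        seq = genome[p.interval.chrom]
        lo = max(0, p.summit - flank)
        hi = min(len(seq), p.summit + flank)
        out[f"{p.name}|{p.interval.chrom}:{lo}-{hi}"] = seq[lo:hi]
    return out
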