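"""Peak annotation: TSS distances, nearest-TSS target genes, cross-species
target overlap, repeat association and binding persistence.

Peak positions are represented by their summit throughout (midpoint when the
summit is unknown), consistent with the summit-based co-binding and distance
rules elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .formats import GenomicInterval, Peak
from .synteny import ConservationCall

__all__ = [
    "TssRecord",
    "tss_distance_distribution",
    "assign_target_genes",
    "hypergeom_sf",
    "target_overlap_test",
    "repeat_association",
    "persistence_fraction",
    "REPEAT_FAMILIES",
]

REPEAT_FAMILIES = (
    "DNA",
    "LINE",
    "LTR",
    "Retroposon",
    "Satellite",
    "Simple",
    "SINE",
)

DEFAULT_TSS_BINS = (0.0, 5e3, 5e4, 5e5, np.inf)


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: one strand-aware genomic position."""

    gene: str
    chrom: str
    pos: int
    strand: str = "+"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1, self.strand)


def _tss_arrays(
    tss_set: Sequence[TssRecord],
) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Per chromosome: sorted positions and gene ids ordered to break
    equal-distance ties toward the lexicographically smaller gene."""
    by: dict[str, list[tuple[int, str]]] = {}
    for t in tss_set:
        by.setdefault(t.chrom, []).append((t.pos, t.gene))
    out = {}
    for chrom, entries in by.items():
        entries.sort()
        out[chrom] = (
            np.array([p for p, _ in entries]),
            [g for _, g in entries],
        )
    return out


def _nearest_tss(
    summit: int, positions: np.ndarray, genes: list[str]
) -> tuple[float, str]:
    j = int(np.searchsorted(positions, summit))
    best_d, best_g = np.inf, ""
    for k in range(max(0, j - 1), min(len(positions), j + 1)):
        d = abs(int(positions[k]) - summit)
        g = genes[k]
        if d < best_d or (d == best_d and g < best_g):
            best_d, best_g = d, g
    # ties among equidistant TSS of the same position: scan neighbours
    for k in range(max(0, j - 2), min(len(positions), j + 2)):
        d = abs(int(positions[k]) - summit)
        if d == best_d and genes[k] < best_g:
            best_g = genes[k]
    return best_d, best_g


def tss_distance_distribution(
    peaks: Sequence[Peak],
    tss_set: Sequence[TssRecord],
    bin_edges_bp: Sequence[float] = DEFAULT_TSS_BINS,
) -> np.ndarray:
    """Fraction of peaks whose |summit - nearest TSS| falls in each bin.

    Bins are half-open ``[edge_i, edge_{i+1})``; the last edge is normally
    ``inf`` so peaks on chromosomes without any TSS land in the final bin.
    Fractions sum to 1.
    """
    if not tss_set:
        raise ValueError("need at least one TSS")
    if not peaks:
        raise ValueError("need at least one peak")
    arrays = _tss_arrays(tss_set)
    edges = np.asarray(bin_edges_bp, dtype=float)
    counts = np.zeros(len(edges) - 1)
    for p in peaks:
        entry = arrays.get(p.interval.chrom)
        d = np.inf if entry is None else _nearest_tss(p.summit, *entry)[0]
        k = int(np.searchsorted(edges, d, side="right")) - 1
        counts[min(max(k, 0), len(counts) - 1)] += 1
    return counts / counts.sum()


def assign_target_genes(
    peaks: Sequence[Peak], tss_set: Sequence[TssRecord]
) -> tuple[set[str], dict[str, str]]:
    """Nearest-TSS target gene per peak, irrespective of binding distance.

    Equidistant TSS tie toward the lexicographically smaller gene id.  Peaks
    on chromosomes with no TSS fall back to the globally nearest gene on any
    chromosome being undefined, so they are assigned no gene (skipped).
    Returns (union of target genes, per-peak assignment).
    """
    if not tss_set:
        raise ValueError("need at least one TSS")
    arrays = _tss_arrays(tss_set)
    per_peak: dict[str, str] = {}
    for p in peaks:
        entry = arrays.get(p.interval.chrom)
        if entry is None:
            continue
        _, gene = _nearest_tss(p.summit, *entry)
        per_peak[p.name] = gene
    return set(per_peak.values()), per_peak


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    Exact tail sum computed in log space (gammaln + logsumexp), stable for
    population sizes up to ~10^6.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    hi = min(K, n)
    lo_support = max(0, K + n - N)
    if k <= lo_support:
        return 1.0
    if k > hi:
        raise ValueError(f"k={k} above support max {hi}")

    j = np.arange(k, hi + 1)
    logpmf = (
        gammaln(K + 1)
        - gammaln(j + 1)
        - gammaln(K - j + 1)
        + gammaln(N - K + 1)
        - gammaln(n - j + 1)
        - gammaln(N - K - n + j + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def target_overlap_test(
    targets_a: set[str],
    targets_b: set[str],
    orthologs: Sequence[tuple[str, str]],
) -> dict:
    """Hypergeometric overlap of two target-gene sets through an ortholog map.

    Both sets are projected into the ortholog-pair namespace (pair index);
    the universe N is the number of ortholog pairs.  Returns the overlap k,
    N, the projected set sizes K and n, and the exact upper-tail p-value —
    symmetric in (a, b).
    """
    a_idx = {g: i for i, (g, _) in enumerate(orthologs)}
    b_idx = {g: i for i, (_, g) in enumerate(orthologs)}
    set_a = {a_idx[g] for g in targets_a if g in a_idx}
    set_b = {b_idx[g] for g in targets_b if g in b_idx}
    N = len(orthologs)
    K, n = len(set_a), len(set_b)
    k = len(set_a & set_b)
    return {
        "overlap": k,
        "universe": N,
        "size_a": K,
        "size_b": n,
        "p_value": hypergeom_sf(k, N, K, n) if min(K, n) > 0 else 1.0,
    }


def repeat_association(
    peaks: Sequence[Peak],
    repeats: Sequence[tuple[GenomicInterval, str]],
) -> tuple[float, dict[str, float]]:
    """Fraction of peaks containing >= 1 repeat, overall and per family.

    A peak is associated with a repeat only when the repeat interval is
    *fully contained* in the peak interval.  A peak can count toward several
    families; families beyond the seven canonical ones pass through.
    """
    if not peaks:
        return float("nan"), {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for iv, fam in repeats:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, fam))
    starts = {}
    for chrom, lst in by_chrom.items():
        lst.sort()
        starts[chrom] = np.array([s for s, _, _ in lst])

    families = set(REPEAT_FAMILIES) | {fam for _, fam in repeats}
    fam_counts = {f: 0 for f in sorted(families)}
    any_count = 0
    for p in peaks:
        lst = by_chrom.get(p.interval.chrom, [])
        if not lst:
            continue
        st = starts[p.interval.chrom]
        lo = int(np.searchsorted(st, p.interval.start, side="left"))
        hi = int(np.searchsorted(st, p.interval.end, side="left"))
        hit_fams = {
            fam
            for s, e, fam in lst[lo:hi]
            if s >= p.interval.start and e <= p.interval.end
        }
        if hit_fams:
            any_count += 1
            for f in hit_fams:
                fam_counts[f] += 1
    n = len(peaks)
    return any_count / n, {f: c / n for f, c in fam_counts.items()}


def persistence_fraction(
    peaks_48h: Sequence[Peak],
    peaks_pluripotent: Sequence[Peak],
    calls: Sequence[ConservationCall],
) -> dict[str, float | None]:
    """Percentage of 48 h peaks per conservation class that persist.

    A 48 h peak is persistent when it overlaps (>= 1 bp) any pluripotent
    peak of the same factor.  Classes with no peaks report ``None`` rather
    than 0 (the percentage is undefined, not zero).
    """
    klass = {c.name: c.klass for c in calls}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks_pluripotent:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    starts, maxlen = {}, {}
    for chrom, lst in by_chrom.items():
        lst.sort()
        starts[chrom] = np.array([s for s, _ in lst])
        maxlen[chrom] = max(e - s for s, e in lst)

    totals = {"SC": 0, "SU": 0, "UN": 0}
    persistent = {"SC": 0, "SU": 0, "UN": 0}
    for p in peaks_48h:
        c = klass.get(p.name)
        if c is None:
            raise ValueError(f"no conservation call for peak {p.name}")
        totals[c] += 1
        lst = by_chrom.get(p.interval.chrom, [])
        if not lst:
            continue
        st = starts[p.interval.chrom]
        lo = int(
            np.searchsorted(
                st, p.interval.start - maxlen[p.interval.chrom], side="left"
            )
        )
        hi = int(np.searchsorted(st, p.interval.end, side="left"))
        for s, e in lst[lo:hi]:
            if e > p.interval.start and s < p.interval.end:
                persistent[c] += 1
                break
    return {
        c: (100.0 * persistent[c] / totals[c]) if totals[c] else None
        for c in ("SC", "SU", "UN")
    }
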