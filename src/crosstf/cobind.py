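"""Combinatorial ("co-") and solo binding of multiple transcription factors.

Peak summits from different factors lying within 100 bp of each other
(single linkage) form a co-binding cluster; a peak is *solo* when its summit
is at least 500 bp from every summit of every other factor.  Peaks between
the two cutoffs are neither.  Enrichment of each factor combination is
measured against a null that uniformly re-places every peak on its own
chromosome (lengths preserved), the ``bedtools shuffle`` convention.

Boundary semantics: "within 100 bp" means ``<= 100``, "at least 500 bp"
means ``>= 500`` (both inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .formats import Peak

__all__ = [
    "SummitCluster",
    "CobindResult",
    "cluster_summits",
    "combination_counts",
    "solo_calls",
    "shuffle_null",
    "cobind_enrichment",
]


@dataclass(frozen=True)
class SummitCluster:
    chrom: str
    members: tuple[tuple[str, int, str], ...]  # (factor, position, peak name)

    @property
    def combination(self) -> frozenset[str]:
        return frozenset(f for f, _, _ in self.members)


def cluster_summits(
    peaks_by_factor: Mapping[str, Sequence[Peak]], radius: int = 100
) -> list[SummitCluster]:
    """Single-linkage clustering of pooled summits per chromosome.

    Adjacent summits are chained into one cluster while consecutive gaps stay
    ``<= radius``; the cluster's combination is the set of distinct factors
    present.  Output order: by chromosome, then leftmost summit.
    """
    pooled: dict[str, list[tuple[int, str, str]]] = {}
    for factor, peaks in peaks_by_factor.items():
        for p in peaks:
            pooled.setdefault(p.interval.chrom, []).append(
                (p.summit, factor, p.name)
            )
    clusters: list[SummitCluster] = []
    for chrom in sorted(pooled):
        entries = sorted(pooled[chrom])
        current: list[tuple[str, int, str]] = []
        last_pos: int | None = None
        for pos, factor, name in entries:
            if last_pos is not None and pos - last_pos > radius:
                clusters.append(SummitCluster(chrom, tuple(current)))
                current = []
            current.append((factor, pos, name))
            last_pos = pos
        if current:
            clusters.append(SummitCluster(chrom, tuple(current)))
    return clusters


def combination_counts(
    clusters: Sequence[SummitCluster],
) -> dict[frozenset[str], int]:
    counts: dict[frozenset[str], int] = {}
    for c in clusters:
        counts[c.combination] = counts.get(c.combination, 0) + 1
    return counts


def solo_calls(
    peaks_by_factor: Mapping[str, Sequence[Peak]], min_dist: int = 500
) -> dict[str, list[Peak]]:
    """Per factor, the peaks whose summit is >= ``min_dist`` from every
    other factor's summits (same-factor neighbours are ignored; a single
    factor in the input makes all of its peaks solo)."""
    summits_by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for factor, peaks in peaks_by_factor.items():
        by: dict[str, list[int]] = {}
        for p in peaks:
            by.setdefault(p.interval.chrom, []).append(p.summit)
        summits_by_chrom[factor] = {
            c: np.sort(np.array(v)) for c, v in by.items()
        }
    out: dict[str, list[Peak]] = {}
    for factor, peaks in peaks_by_factor.items():
        solo: list[Peak] = []
        for p in peaks:
            s = p.summit
            ok = True
            for other, by in summits_by_chrom.items():
                if other == factor:
                    continue
                arr = by.get(p.interval.chrom)
                if arr is None or len(arr) == 0:
                    continue
                j = np.searchsorted(arr, s)
                for cand in arr[max(0, j - 1) : j + 1]:
                    if abs(int(cand) - s) < min_dist:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                solo.append(p)
        out[factor] = solo
    return out


@dataclass
class CobindResult:
    """Observed vs expected counts per key and their log2 enrichment.

    Keys are frozensets of factor names for co-binding combinations and
    single-factor tuples ``("solo", factor)`` for solo counts.
    """

    observed: dict
    expected: dict
    samples: dict  # key -> np.ndarray of per-shuffle counts
    log2_ratio: dict


def _all_count_keys(factors: Sequence[str]) -> list:
    keys: list = []
    factors = list(factors)
    for mask in range(1, 1 << len(factors)):
        keys.append(
            frozenset(f for i, f in enumerate(factors) if mask >> i & 1)
        )
    keys += [("solo", f) for f in factors]
    return keys


def _counts_once(
    peaks_by_factor: Mapping[str, Sequence[Peak]], radius: int, min_dist: int
) -> dict:
    counts = {
        k: 0 for k in _all_count_keys(list(peaks_by_factor))
    }
    for combo, n in combination_counts(
        cluster_summits(peaks_by_factor, radius)
    ).items():
        counts[combo] = n
    for factor, solos in solo_calls(peaks_by_factor, min_dist).items():
        counts[("solo", factor)] = len(solos)
    return counts


def shuffle_null(
    peaks_by_factor: Mapping[str, Sequence[Peak]],
    chrom_sizes: Mapping[str, int],
    n_shuffles: int = 100,
    seed: int = 0,
    radius: int = 100,
    min_dist: int = 500,
) -> tuple[dict, dict]:
    """Expected combination/solo counts under uniform re-placement.

    Returns ``(expected_means, samples)`` over ``n_shuffles`` independent
    shuffles of every factor's peaks.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    keys = _all_count_keys(list(peaks_by_factor))
    samples = {k: np.zeros(n_shuffles) for k in keys}
    for i in range(n_shuffles):
        shuffled = {}
        for factor, peaks in peaks_by_factor.items():
            placed = []
            for p in peaks:
                limit = chrom_sizes[p.interval.chrom] - len(p.interval)
                if limit < 0:
                    raise ValueError(
                        f"peak {p.name} longer than its chromosome"
                    )
                placed.append(p.moved_to(int(rng.integers(0, limit + 1))))
            shuffled[factor] = placed
        for k, v in _counts_once(shuffled, radius, min_dist).items():
            samples[k][i] = v
    expected = {k: float(v.mean()) for k, v in samples.items()}
    return expected, samples


def cobind_enrichment(
    peaks_by_factor: Mapping[str, Sequence[Peak]],
    chrom_sizes: Mapping[str, int],
    n_shuffles: int = 100,
    seed: int = 0,
    radius: int = 100,
    min_dist: int = 500,
) -> CobindResult:
    """log2((observed + 0.5) / (expected + 0.5)) for every combination and
    per-factor solo count (Haldane–Anscombe pseudocount)."""
    observed = _counts_once(peaks_by_factor, radius, min_dist)
    expected, samples = shuffle_null(
        peaks_by_factor, chrom_sizes, n_shuffles, seed, radius, min_dist
    )
    log2 = {
        k: float(np.log2((observed[k] + 0.5) / (expected[k] + 0.5)))
        for k in observed
    }
    return CobindResult(observed, expected, samples, log2)
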