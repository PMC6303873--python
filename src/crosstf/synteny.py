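"""Chain-based interval mapping and the SC/SU/UN conservation analysis.

The mapper is a minimal re-implementation of the UCSC liftOver interval
semantics: a source interval maps through the single chain that covers the
largest number of its bases (ties broken by chain score), succeeds when that
coverage is at least ``min_match`` (default 0.5, the cutoff used for
cross-species TF-binding comparisons), and returns the ``[min, max+1)`` span
of the per-base images on the other genome.

Chains are oriented with the FROM species on the chain *target* (t) side,
the UCSC ``over.chain`` convention.  ``min_match`` is interpreted as
aligned-base coverage of the source interval (``liftOver -minMatch``
semantics); sequence identity inside blocks is not re-checked.

Conservation classes of a source peak:

* **SC** (syntenic conserved)   — maps, and the mapped interval overlaps a
  same-factor peak in the other species;
* **SU** (syntenic unconserved) — maps, but no such partner peak;
* **UN** (unsyntenic)           — does not map (no chain, or coverage below
  the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .formats import ChainAlignment, GenomicInterval, Peak

__all__ = [
    "MapperConfig",
    "MappedInterval",
    "MappingFailure",
    "ConservationCall",
    "ChainIndex",
    "map_interval",
    "classify_peaks",
    "syntenic_rate",
    "background_conservation",
    "conservation_by_strength_quartile",
    "summit_distance_spectrum",
    "BackgroundResult",
    "SpectrumResult",
]

SC, SU, UN = "SC", "SU", "UN"


@dataclass(frozen=True)
class MapperConfig:
    """Interval-mapping parameters (defaults match the 0.5 liftOver cutoff)."""

    min_match: float = 0.5
    multi_chain_policy: Literal["best_coverage"] = "best_coverage"
    summit_policy: Literal["nearest_mapped_base"] = "nearest_mapped_base"
    # SC partner criterion: ">=1 bp overlap" (default) or "summit inside"
    partner_criterion: Literal["overlap", "summit_inside"] = "overlap"

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")


@dataclass(frozen=True)
class MappedInterval:
    source: GenomicInterval
    target: GenomicInterval
    mapped_fraction: float
    chain_id: int
    target_strand: str


@dataclass(frozen=True)
class MappingFailure:
    source: GenomicInterval
    reason: Literal["no_chain", "below_min_match"]


@dataclass(frozen=True)
class ConservationCall:
    name: str
    klass: str  # SC | SU | UN
    mapped: MappedInterval | None = None
    partner_peak: str | None = None

    def __post_init__(self) -> None:
        if (self.klass == UN) != (self.mapped is None):
            raise ValueError("mapped must be absent iff class is UN")
        if (self.klass == SC) != (self.partner_peak is not None):
            raise ValueError("partner_peak must be present iff class is SC")


class ChainIndex:
    """Per-chromosome arrays of aligned blocks for fast coverage queries."""

    def __init__(self, chains: Sequence[ChainAlignment]):
        self.chains = list(chains)
        by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
        for ci, chain in enumerate(self.chains):
            for t0, t1, q0 in chain.aligned_blocks():
                by_chrom.setdefault(chain.t_name, []).append((t0, t1, q0, ci))
        self._blocks: dict[str, dict[str, np.ndarray]] = {}
        for chrom, blocks in by_chrom.items():
            blocks.sort()
            arr = np.array(blocks, dtype=np.int64)
            self._blocks[chrom] = {
                "t0": arr[:, 0],
                "t1": arr[:, 1],
                "q0": arr[:, 2],
                "chain": arr[:, 3],
            }

    def overlapping_blocks(self, iv: GenomicInterval) -> np.ndarray | None:
        """Indices (into per-chrom arrays) of blocks overlapping ``iv``."""
        b = self._blocks.get(iv.chrom)
        if b is None:
            return None
        hi = np.searchsorted(b["t0"], iv.end, side="left")
        cand = np.nonzero(b["t1"][:hi] > iv.start)[0]
        return cand

    def blocks_for(self, chrom: str) -> dict[str, np.ndarray] | None:
        return self._blocks.get(chrom)


def _block_image_span(
    chain: ChainAlignment, t_lo: int, t_hi: int, q0: int
) -> tuple[int, int]:
    """Plus-strand image span of contiguous target bases [t_lo, t_hi)
    lying inside one aligned block whose query start (file coords) is q0
    offset-adjusted already, i.e. q0 corresponds to t position t_lo."""
    if chain.q_strand == "+":
        return q0, q0 + (t_hi - t_lo)
    # reversed query: image of position p is q_size - p_rev - 1
    hi_rev = q0 + (t_hi - t_lo) - 1  # last base, reversed coords
    return chain.q_size - hi_rev - 1, chain.q_size - q0


def map_interval(
    iv: GenomicInterval, index: ChainIndex, cfg: MapperConfig = MapperConfig()
) -> MappedInterval | MappingFailure:
    """Map one interval through the best-covering chain.

    Returns a :class:`MappedInterval` on success, otherwise a
    :class:`MappingFailure` with reason ``no_chain`` (chromosome absent from
    every chain) or ``below_min_match``.
    """
    blocks = index.blocks_for(iv.chrom)
    if blocks is None:
        return MappingFailure(iv, "no_chain")
    cand = index.overlapping_blocks(iv)
    if cand is None or len(cand) == 0:
        return MappingFailure(iv, "below_min_match")

    lo = np.maximum(blocks["t0"][cand], iv.start)
    hi = np.minimum(blocks["t1"][cand], iv.end)
    cover = hi - lo
    chain_ids = blocks["chain"][cand]

    # coverage per chain
    best_ci, best_cover, best_score = -1, -1, -np.inf
    for ci in np.unique(chain_ids):
        c = int(cover[chain_ids == ci].sum())
        score = index.chains[ci].score
        if c > best_cover or (c == best_cover and score > best_score):
            best_ci, best_cover, best_score = int(ci), c, score

    fraction = best_cover / len(iv)
    if fraction < cfg.min_match:
        return MappingFailure(iv, "below_min_match")

    chain = index.chains[best_ci]
    sel = chain_ids == best_ci
    spans = []
    for j in np.nonzero(sel)[0]:
        b = cand[j]
        q0_file = int(blocks["q0"][b]) + (int(lo[j]) - int(blocks["t0"][b]))
        spans.append(_block_image_span(chain, int(lo[j]), int(hi[j]), q0_file))
    t_start = min(s for s, _ in spans)
    t_end = max(e for _, e in spans)
    return MappedInterval(
        source=iv,
        target=GenomicInterval(chain.q_name, t_start, t_end),
        mapped_fraction=fraction,
        chain_id=chain.chain_id,
        target_strand=chain.q_strand,
    )


def map_position(
    chrom: str,
    pos: int,
    index: ChainIndex,
    chain_id: int | None = None,
) -> tuple[str, int] | None:
    """Image of a single base; nearest aligned base within the chain when
    the position itself falls in a gap.  Restricted to ``chain_id`` when
    given, otherwise the first chain whose span contains the position."""
    blocks = index.blocks_for(chrom)
    if blocks is None:
        return None
    if chain_id is not None:
        cidx = [
            i for i, c in enumerate(index.chains) if c.chain_id == chain_id
        ]
        if not cidx:
            return None
        sel = blocks["chain"] == cidx[0]
    else:
        sel = np.ones(len(blocks["t0"]), dtype=bool)
    t0, t1, q0 = blocks["t0"][sel], blocks["t1"][sel], blocks["q0"][sel]
    chains_sel = blocks["chain"][sel]
    if len(t0) == 0:
        return None
    # nearest covered base
    clamped = np.clip(pos, t0, t1 - 1)
    dist = np.abs(clamped - pos)
    j = int(np.argmin(dist))
    chain = index.chains[int(chains_sel[j])]
    q_file = int(q0[j]) + int(clamped[j]) - int(t0[j])
    if chain.q_strand == "-":
        return chain.q_name, chain.q_size - q_file - 1
    return chain.q_name, q_file


# ---------------------------------------------------------------------------
# conservation classes


def _peaks_by_chrom(peaks: Sequence[Peak]) -> dict[str, list[Peak]]:
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        out.setdefault(p.interval.chrom, []).append(p)
    for lst in out.values():
        lst.sort(key=lambda p: (p.interval.start, p.interval.end, p.name))
    return out


def classify_peaks(
    src_peaks: Sequence[Peak],
    dst_peaks: Sequence[Peak],
    index: ChainIndex,
    cfg: MapperConfig = MapperConfig(),
) -> list[ConservationCall]:
    """Classify each source peak as SC, SU or UN against same-factor peaks.

    SC requires >=1 bp overlap between the mapped interval and a destination
    peak; the partner is the peak of maximal overlap (tie -> leftmost).
    """
    dst_by_chrom = _peaks_by_chrom(dst_peaks)
    starts = {
        c: np.array([p.interval.start for p in lst])
        for c, lst in dst_by_chrom.items()
    }
    max_len = {
        c: max(len(p.interval) for p in lst) for c, lst in dst_by_chrom.items()
    }
    calls: list[ConservationCall] = []
    for peak in src_peaks:
        mapped = map_interval(peak.interval, index, cfg)
        if isinstance(mapped, MappingFailure):
            calls.append(ConservationCall(peak.name, UN))
            continue
        tgt = mapped.target
        partner: Peak | None = None
        best_ov = 0
        lst = dst_by_chrom.get(tgt.chrom, [])
        if lst:
            st = starts[tgt.chrom]
            hi = int(np.searchsorted(st, tgt.end, side="left"))
            lo = int(
                np.searchsorted(st, tgt.start - max_len[tgt.chrom], side="left")
            )
            for q in lst[lo:hi]:
                if q.interval.end <= tgt.start:
                    continue
                if cfg.partner_criterion == "summit_inside":
                    ok = tgt.start <= q.summit < tgt.end
                    ov = 1 if ok else 0
                else:
                    ov = tgt.overlap(q.interval)
                if ov > best_ov:
                    best_ov, partner = ov, q
        if partner is not None:
            calls.append(ConservationCall(peak.name, SC, mapped, partner.name))
        else:
            calls.append(ConservationCall(peak.name, SU, mapped))
    return calls


def syntenic_rate(calls: Sequence[ConservationCall]) -> float:
    """Fraction of peaks in syntenic regions: (SC + SU) / all."""
    if not calls:
        return float("nan")
    return sum(c.klass != UN for c in calls) / len(calls)


def sc_rate(calls: Sequence[ConservationCall]) -> float:
    if not calls:
        return float("nan")
    return sum(c.klass == SC for c in calls) / len(calls)


@dataclass
class BackgroundResult:
    samples: np.ndarray  # per-shuffle SC rates
    mean: float
    ci_low: float
    ci_high: float


def _shuffle_peaks(
    peaks: Sequence[Peak], sizes: dict[str, int], rng: np.random.Generator
) -> list[Peak]:
    out = []
    for p in peaks:
        length = len(p.interval)
        limit = sizes[p.interval.chrom] - length
        if limit < 0:
            raise ValueError(
                f"peak {p.name} longer than chromosome {p.interval.chrom}"
            )
        out.append(p.moved_to(int(rng.integers(0, limit + 1))))
    return out


def background_conservation(
    src_peaks: Sequence[Peak],
    dst_peaks: Sequence[Peak],
    index: ChainIndex,
    src_sizes: dict[str, int],
    dst_sizes: dict[str, int],
    n_shuffles: int = 1000,
    seed: int = 0,
    cfg: MapperConfig = MapperConfig(),
) -> BackgroundResult:
    """Chance level of the SC rate.

    Each iteration independently re-places *both* peak sets uniformly at
    random (lengths and chromosome assignment preserved, peaks fully inside
    bounds, overlaps allowed — ``bedtools shuffle`` defaults), re-runs the
    classification and records the SC fraction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    rates = np.empty(n_shuffles)
    for i in range(n_shuffles):
        src = _shuffle_peaks(src_peaks, src_sizes, rng)
        dst = _shuffle_peaks(dst_peaks, dst_sizes, rng)
        rates[i] = sc_rate(classify_peaks(src, dst, index, cfg))
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return BackgroundResult(rates, float(rates.mean()), float(lo), float(hi))


def conservation_by_strength_quartile(
    calls: Sequence[ConservationCall], peaks: Sequence[Peak]
) -> tuple[float, float, float, float]:
    """SC percentage within strength quartiles of syntenic peaks.

    Syntenic (SC + SU) peaks are sorted by -log10(q) descending (ties broken
    by peak name) and split into four equal groups, remainder going to the
    earlier (stronger) groups; returns the %SC of each group, strongest
    first.
    """
    by_name = {p.name: p for p in peaks}
    syntenic = [c for c in calls if c.klass != UN]
    if len(syntenic) < 4:
        raise ValueError("need at least 4 syntenic peaks")
    syntenic.sort(key=lambda c: (-by_name[c.name].neglog10_q, c.name))
    n = len(syntenic)
    base, rem = divmod(n, 4)
    out = []
    pos = 0
    for g in range(4):
        size = base + (1 if g < rem else 0)
        grp = syntenic[pos : pos + size]
        pos += size
        out.append(100.0 * sum(c.klass == SC for c in grp) / size)
    return tuple(out)  # type: ignore[return-value]


@dataclass
class SpectrumResult:
    bin_edges: np.ndarray  # len n_bins+1, last edge = inf
    observed: np.ndarray
    expected_mean: np.ndarray
    expected_samples: np.ndarray  # n_shuffles x n_bins
    log2_ratio: np.ndarray


def _summit_histogram(
    mapped_summits: list[tuple[str, int]],
    dst_peaks_by_chrom: dict[str, np.ndarray],
    edges: np.ndarray,
) -> np.ndarray:
    counts = np.zeros(len(edges) - 1)
    for chrom, pos in mapped_summits:
        summits = dst_peaks_by_chrom.get(chrom)
        if summits is None or len(summits) == 0:
            d = np.inf
        else:
            j = np.searchsorted(summits, pos)
            cands = summits[max(0, j - 1) : j + 1]
            d = float(np.min(np.abs(cands - pos)))
        k = int(np.searchsorted(edges, d, side="right")) - 1
        counts[min(k, len(counts) - 1)] += 1
    return counts


def summit_distance_spectrum(
    src_syntenic_peaks: Sequence[Peak],
    dst_peaks: Sequence[Peak],
    index: ChainIndex,
    dst_sizes: dict[str, int],
    bin_bp: int = 200,
    max_bp: int = 2000,
    n_shuffles: int = 100,
    seed: int = 0,
    cfg: MapperConfig = MapperConfig(),
) -> SpectrumResult:
    """Distance spectrum between mapped source summits and the nearest
    destination summit, as log2(observed / shuffled expectation) per bin.

    Distances are binned as [0, bin_bp), [bin_bp, 2*bin_bp), ... up to
    ``max_bp``; larger (or infinite) distances land in a final overflow bin.
    The expectation re-places the destination peaks uniformly (sources kept
    fixed); 0.5 pseudocounts guard the ratio.
    """
    edges = np.append(np.arange(0, max_bp + bin_bp, bin_bp), np.inf)
    mapped_summits: list[tuple[str, int]] = []
    for p in src_syntenic_peaks:
        m = map_interval(p.interval, index, cfg)
        if isinstance(m, MappingFailure):
            continue
        img = map_position(p.interval.chrom, p.summit, index, m.chain_id)
        if img is not None:
            mapped_summits.append(img)

    def summit_arrays(peaks: Sequence[Peak]) -> dict[str, np.ndarray]:
        by: dict[str, list[int]] = {}
        for p in peaks:
            by.setdefault(p.interval.chrom, []).append(p.summit)
        return {c: np.sort(np.array(v)) for c, v in by.items()}

    observed = _summit_histogram(mapped_summits, summit_arrays(dst_peaks), edges)

    rng = np.random.default_rng(seed)
    samples = np.empty((n_shuffles, len(observed)))
    for i in range(n_shuffles):
        shuffled = _shuffle_peaks(dst_peaks, dst_sizes, rng)
        samples[i] = _summit_histogram(
            mapped_summits, summit_arrays(shuffled), edges
        )
    expected = samples.mean(axis=0)
    log2 = np.log2((observed + 0.5) / (expected + 0.5))
    return SpectrumResult(edges, observed, expected, samples, log2)
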