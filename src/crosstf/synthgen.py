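"""Synthetic paired-species ChIP-seq dataset generator with known ground truth.

The generator emulates the study design of a cross-species reprogramming
factor comparison: two genomes related by a chain alignment covering a
configurable syntenic fraction (default 40%, the genome-wide background
rate), per-factor peak sets with planted conservation classes (SC/SU/UN,
default SC fractions 4/4.5/10.9/34.4% for the four factors and syntenic
fractions 74/80/73/89%), peak strengths positively shifted for conserved
peaks, co-binding sites shared by several factors within 100 bp,
motif instances planted at summits at different rates for conserved
(53%) and unconserved (35%) peaks, chromatin-state tracks with concentrated
cross-species state transitions at conserved peaks, repeat annotations
biased toward unsyntenic peaks, and pluripotent-state ("ESC") peak sets
with class-dependent persistence (56/17/23% for SC/SU/UN).

Everything is a pure function of :class:`SynthConfig` (including the seed):
each stage draws from its own PRNG stream derived from ``(seed, stage
name)``, so adding a stage never perturbs the output of earlier ones.

Layout conventions: peaks are planted on a lattice of ``peak_length`` sites
aligned to chromatin bins, fully inside aligned chain blocks (SC/SU) or
fully outside chain spans (UN); sites are spaced ``site_stride`` bins apart
so that peaks at different sites are unambiguously "solo" under the 500 bp
rule, while factors sharing a site are unambiguously "co" under the 100 bp
rule.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import formats
from .annotate import REPEAT_FAMILIES, TssRecord
from .chromstate import BinnedMarks
from .formats import ChainAlignment, GenomicInterval, PFM, Peak

__all__ = [
    "SynthConfig",
    "SyntenyScaffold",
    "SyntheticDataset",
    "build_synteny",
    "plant_peaks",
    "plant_chromatin",
    "plant_motifs",
    "plant_annotations",
    "generate",
    "emit_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac", "H3K36me3")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset (all sizes in bp)."""

    seed: int = 0
    source_species: str = "mouse"
    target_species: str = "human"
    source_chroms: tuple[tuple[str, int], ...] = (
        ("mchr1", 10_000_000),
        ("mchr2", 10_000_000),
    )
    target_chroms: tuple[tuple[str, int], ...] = (
        ("hchr1", 10_000_000),
        ("hchr2", 10_000_000),
    )
    syntenic_fraction: float = 0.40
    n_blocks: int = 40
    min_block_bins: int = 20

    factors: tuple[str, ...] = ("Oct4", "Sox2", "Klf4", "cMyc")
    peaks_per_factor: int = 1000
    peak_length: int = 200
    sc_fraction: tuple[float, ...] = (0.04, 0.045, 0.109, 0.344)
    syntenic_peak_fraction: tuple[float, ...] = (0.74, 0.80, 0.73, 0.89)
    cobind_fraction: float = 0.30
    combo_size_weights: tuple[float, ...] = (0.4, 0.3, 0.3)  # sizes 2,3,4
    site_stride: int = 3  # sites every stride bins: keeps non-co peaks solo
    summit_jitter: int = 40
    straddle_fraction: float = 0.0
    dst_only_peaks_per_factor: int = 500

    strength_base_shape: float = 2.0
    strength_base_scale: float = 10.0
    strength_conservation_effect: float = 15.0

    n_marks: int = 5
    mark_names: tuple[str, ...] = DEFAULT_MARKS
    n_states: int = 15
    bin_size: int = 200
    lambda_high: float = 40.0
    lambda_low: float = 0.05
    emission_high: float = 0.95
    emission_low: float = 0.02
    self_transition: float = 0.9
    quiescent_weight: float = 25.0
    n_active_states: int = 4
    state_concentration: float = 0.8

    motif_width: int = 10
    motif_rate_sc: float = 0.53
    motif_rate_unc: float = 0.35
    motif_rate_target_unbound: float = 0.20
    motif_correlated: bool = True

    n_genes: int = 2000
    repeats_per_mb: float = 50.0
    repeat_family_weights: tuple[float, ...] = (
        0.10,  # DNA
        0.25,  # LINE
        0.20,  # LTR
        0.025,  # Retroposon
        0.025,  # Satellite
        0.10,  # Simple
        0.30,  # SINE
    )
    repeat_assoc_rate: tuple[float, float, float] = (0.05, 0.10, 0.25)  # SC,SU,UN
    esc_persistence: tuple[float, float, float] = (0.56, 0.17, 0.23)  # SC,SU,UN
    esc_only_peaks_per_factor: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.syntenic_fraction <= 1):
            raise ValueError("syntenic_fraction must be in (0, 1]")
        for name in (
            "sc_fraction",
            "syntenic_peak_fraction",
            "repeat_assoc_rate",
            "esc_persistence",
        ):
            if any(not (0 <= x <= 1) for x in getattr(self, name)):
                raise ValueError(f"{name} entries must be in [0, 1]")
        if len(self.sc_fraction) != len(self.factors):
            raise ValueError("one sc_fraction per factor required")
        if len(self.syntenic_peak_fraction) != len(self.factors):
            raise ValueError("one syntenic_peak_fraction per factor required")
        if self.peaks_per_factor < 1:
            raise ValueError("peaks_per_factor must be >= 1")
        if self.peak_length != self.bin_size:
            raise ValueError(
                "peak_length must equal bin_size (site lattice = bin lattice)"
            )
        for _, size in self.source_chroms + self.target_chroms:
            if size % self.bin_size:
                raise ValueError("chromosome sizes must be bin_size multiples")
        if len(self.mark_names) != self.n_marks:
            raise ValueError("mark_names length must equal n_marks")
        if self.n_states < 2:
            raise ValueError("need at least 2 chromatin states")
        if self.n_active_states >= self.n_states:
            raise ValueError("n_active_states must be < n_states")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        def tup(x):
            if isinstance(x, list):
                return tuple(tup(v) for v in x)
            return x

        return cls(**{k: tup(v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# stage 1: genomes + chain


@dataclass
class SyntenyScaffold:
    cfg: SynthConfig
    source_seqs: dict[str, np.ndarray]  # uint8 base codes, mutable
    target_seqs: dict[str, np.ndarray]
    chains: list[ChainAlignment]
    # flattened aligned blocks: (src_chrom, src_start, size, dst_chrom, dst_start)
    aligned_blocks: list[tuple[str, int, int, str, int]]

    def source_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.source_seqs.items()}

    def target_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.target_seqs.items()}

    def copy_blocks_to_target(self) -> None:
        for sc, ss, size, dc, ds in self.aligned_blocks:
            self.target_seqs[dc][ds : ds + size] = self.source_seqs[sc][
                ss : ss + size
            ]

    def sequences(self, side: Literal["source", "target"]) -> dict[str, str]:
        seqs = self.source_seqs if side == "source" else self.target_seqs
        return {c: _BASES[a].tobytes().decode() for c, a in seqs.items()}


def _split_sizes(
    total: int, n: int, minimum: int, rng: np.random.Generator
) -> list[int]:
    """Random partition of ``total`` into ``n`` parts each >= ``minimum``."""
    if total < n * minimum:
        raise ValueError(
            f"cannot split {total} into {n} parts of >= {minimum}"
        )
    extra = total - n * minimum
    props = rng.dirichlet(np.ones(n))
    sizes = (props * extra).astype(int)
    sizes[0] += extra - sizes.sum()
    return [minimum + int(s) for s in sizes]


def build_synteny(cfg: SynthConfig) -> SyntenyScaffold:
    """Generate both genomes and the chain alignment relating them.

    The union of aligned chain blocks covers ``syntenic_fraction`` (within
    rounding) of the source genome; aligned block sequence is copied
    verbatim to the target genome, everything else is independent random
    sequence.  Chains may contain small internal dt/dq gaps (unaligned on
    either side); all block boundaries fall on the chromatin bin lattice.
    """
    rng = _stage_rng(cfg.seed, "synteny")
    bs = cfg.bin_size
    src_bins = {c: n // bs for c, n in cfg.source_chroms}
    dst_bins = {c: n // bs for c, n in cfg.target_chroms}
    total_src_bins = sum(src_bins.values())
    syn_bins = int(round(cfg.syntenic_fraction * total_src_bins))

    aligned_sizes = _split_sizes(
        syn_bins, cfg.n_blocks, cfg.min_block_bins, rng
    )

    # internal structure: 1-3 sub-blocks with small dt/dq gaps (in bins);
    # internal gaps come out of the non-syntenic budget, so skip them when
    # the genome is nearly fully syntenic
    slack = total_src_bins - syn_bins
    allow_gaps = slack >= cfg.n_blocks * 12
    segments = []  # per chain: list of (sub_size, dt, dq) in bins
    for a in aligned_sizes:
        n_sub = (
            int(rng.integers(1, 4))
            if (allow_gaps and a >= 3 * cfg.min_block_bins)
            else 1
        )
        subs = (
            _split_sizes(a, n_sub, max(1, a // (2 * n_sub)), rng)
            if n_sub > 1
            else [a]
        )
        blocks = []
        for i, s in enumerate(subs):
            if i < len(subs) - 1:
                blocks.append((s, int(rng.integers(1, 6)), int(rng.integers(1, 6))))
            else:
                blocks.append((s, 0, 0))
        segments.append(blocks)

    def _layout(
        chrom_bins: dict[str, int], spans: list[int], order: list[int]
    ) -> dict[int, tuple[str, int]]:
        """Place chains (by index) across chromosomes; returns chain index
        -> (chrom, start bin).  Gaps >= 1 bin everywhere."""
        chroms = list(chrom_bins)
        per_chrom: dict[str, list[int]] = {c: [] for c in chroms}
        for j, ci in enumerate(order):
            per_chrom[chroms[j % len(chroms)]].append(ci)
        out: dict[int, tuple[str, int]] = {}
        for chrom, members in per_chrom.items():
            used = sum(spans[ci] for ci in members)
            free = chrom_bins[chrom] - used
            n_gaps = len(members) + 1
            if free < 0:
                raise ValueError(
                    f"syntenic blocks do not fit on {chrom}; reduce "
                    "syntenic_fraction or n_blocks"
                )
            gaps = _split_sizes(free, n_gaps, 1 if free >= n_gaps else 0, rng)
            pos = 0
            for g, ci in zip(gaps, members):
                pos += g
                out[ci] = (chrom, pos)
                pos += spans[ci]
        return out

    src_spans = [sum(s for s, dt, _ in seg) + sum(dt for _, dt, _ in seg)
                 for seg in segments]
    dst_spans = [sum(s for s, _, _ in seg) + sum(dq for _, _, dq in seg)
                 for seg in segments]
    src_layout = _layout(src_bins, src_spans, list(range(len(segments))))
    dst_order = [int(i) for i in rng.permutation(len(segments))]
    dst_layout = _layout(dst_bins, dst_spans, dst_order)

    chains: list[ChainAlignment] = []
    aligned_blocks: list[tuple[str, int, int, str, int]] = []
    dst_size_bp = dict(cfg.target_chroms)
    src_size_bp = dict(cfg.source_chroms)
    for ci, seg in enumerate(segments):
        s_chrom, s_bin = src_layout[ci]
        d_chrom, d_bin = dst_layout[ci]
        t_start, q_start = s_bin * bs, d_bin * bs
        blocks_bp = tuple((s * bs, dt * bs, dq * bs) for s, dt, dq in seg)
        t_end = t_start + sum(b[0] + b[1] for b in blocks_bp)
        q_end = q_start + sum(b[0] + b[2] for b in blocks_bp)
        chains.append(
            ChainAlignment(
                score=float(1000 + ci),
                t_name=s_chrom,
                t_size=src_size_bp[s_chrom],
                t_strand="+",
                t_start=t_start,
                t_end=t_end,
                q_name=d_chrom,
                q_size=dst_size_bp[d_chrom],
                q_strand="+",
                q_start=q_start,
                q_end=q_end,
                blocks=blocks_bp,
                chain_id=ci + 1,
            )
        )
        t, q = t_start, q_start
        for size, dt, dq in blocks_bp:
            aligned_blocks.append((s_chrom, t, size, d_chrom, q))
            t += size + dt
            q += size + dq

    source_seqs = {
        c: rng.integers(0, 4, size, dtype=np.uint8)
        for c, size in cfg.source_chroms
    }
    target_seqs = {
        c: rng.integers(0, 4, size, dtype=np.uint8)
        for c, size in cfg.target_chroms
    }
    scaffold = SyntenyScaffold(
        cfg, source_seqs, target_seqs, chains, aligned_blocks
    )
    scaffold.copy_blocks_to_target()
    return scaffold


# ---------------------------------------------------------------------------
# stage 2: peaks


_CLASSES = ("SC", "SU", "UN")


@dataclass
class PeakSets:
    source: dict[str, list[Peak]]  # factor -> peaks (48 h, source species)
    target: dict[str, list[Peak]]  # factor -> peaks (target species)
    esc: dict[str, list[Peak]]  # factor -> pluripotent-state source peaks


def _chain_spans_by_chrom(
    chains: Sequence[ChainAlignment],
) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    for c in chains:
        spans.setdefault(c.t_name, []).append((c.t_start, c.t_end))
    for lst in spans.values():
        lst.sort()
    return spans


def plant_peaks(
    cfg: SynthConfig, scaffold: SyntenyScaffold
) -> tuple[PeakSets, pd.DataFrame]:
    """Plant per-factor peak sets with exact per-class counts.

    Per factor: ``round(syntenic_peak_fraction * n)`` peaks inside aligned
    blocks, of which ``round(sc_fraction * n)`` get a matching target-side
    partner peak at the mapped location (SC) and the rest do not (SU); the
    remaining peaks lie fully outside chain spans (UN).  A ``cobind_fraction``
    of each factor's peaks is placed at sites shared with other factors
    (summits within 100 bp); all remaining sites are >= 500 bp apart.
    Conserved peaks draw their -log10(q) strength with an additive positive
    shift of ``strength_conservation_effect``.
    """
    rng = _stage_rng(cfg.seed, "peaks")
    bs = cfg.bin_size
    stride = cfg.site_stride

    # --- site lattices -----------------------------------------------------
    syn_sites: list[tuple[str, int, str, int]] = []
    straddle_candidates: list[tuple[str, int, str, int]] = []
    for sc_, ss, size, dc, ds in scaffold.aligned_blocks:
        n_bins = size // bs
        start_bin = 1 if cfg.straddle_fraction > 0 else 0
        for b in range(start_bin, n_bins, stride):
            syn_sites.append((sc_, ss + b * bs, dc, ds + b * bs))
        if cfg.straddle_fraction > 0 and size >= bs:
            straddle_candidates.append((sc_, ss - bs // 2, dc, ds))

    spans = _chain_spans_by_chrom(scaffold.chains)
    un_sites: list[tuple[str, int]] = []
    for chrom, length in cfg.source_chroms:
        pos = 0
        for s, e in spans.get(chrom, []) + [(length, length)]:
            b0 = pos // bs
            b1 = s // bs
            for b in range(b0, b1, stride):
                un_sites.append((chrom, b * bs))
            pos = e
    # target-side free sites (outside chain q-spans) for target-only peaks
    q_spans: dict[str, list[tuple[int, int]]] = {}
    for c in scaffold.chains:
        q_spans.setdefault(c.q_name, []).append((c.q_start, c.q_end))
    for lst in q_spans.values():
        lst.sort()
    dst_free: list[tuple[str, int]] = []
    for chrom, length in cfg.target_chroms:
        pos = 0
        for s, e in q_spans.get(chrom, []) + [(length, length)]:
            for b in range(pos // bs, s // bs, stride):
                dst_free.append((chrom, b * bs))
            pos = e

    rng.shuffle(syn_sites)
    rng.shuffle(un_sites)
    rng.shuffle(dst_free)
    syn_sites_iter = iter(syn_sites)
    un_sites_iter = iter(un_sites)
    dst_free_iter = iter(dst_free)

    def pop_site(kind: str):
        try:
            if kind == "syn":
                return next(syn_sites_iter)
            if kind == "un":
                return next(un_sites_iter)
            return next(dst_free_iter)
        except StopIteration:
            raise RuntimeError(
                "site lattice exhausted: genome too small for requested "
                "peak counts"
            ) from None

    # --- per-factor class quotas -------------------------------------------
    n = cfg.peaks_per_factor
    remaining: dict[str, dict[str, int]] = {}
    for f, scf, synf in zip(
        cfg.factors, cfg.sc_fraction, cfg.syntenic_peak_fraction
    ):
        n_syn = int(round(synf * n))
        n_sc = int(round(scf * n))
        if n_sc > n_syn:
            raise ValueError(f"{f}: sc_fraction exceeds syntenic fraction")
        remaining[f] = {"SC": n_sc, "SU": n_syn - n_sc, "UN": n - n_syn}
    co_quota = {f: int(round(cfg.cobind_fraction * n)) for f in cfg.factors}

    # placement records: (factor, class, src_chrom, src_start, dst_chrom,
    #                     dst_start or None, straddle)
    placements: list[tuple] = []

    def take_class(f: str, kind: str) -> str:
        if kind == "un":
            remaining[f]["UN"] -= 1
            return "UN"
        tot = remaining[f]["SC"] + remaining[f]["SU"]
        if rng.random() < remaining[f]["SC"] / tot:
            remaining[f]["SC"] -= 1
            return "SC"
        remaining[f]["SU"] -= 1
        return "SU"

    # co-binding sites: subsets of >= 2 factors share one site
    sizes = np.arange(2, 2 + len(cfg.combo_size_weights))
    size_w = np.array(cfg.combo_size_weights, dtype=float)
    size_w /= size_w.sum()
    while True:
        eligible = [f for f in cfg.factors if co_quota[f] > 0]
        if len(eligible) < 2:
            break
        size = int(rng.choice(sizes, p=size_w))
        size = min(size, len(eligible))
        members = [
            eligible[i]
            for i in rng.choice(len(eligible), size=size, replace=False)
        ]
        syn_ok = all(
            remaining[f]["SC"] + remaining[f]["SU"] > 0 for f in members
        )
        un_ok = all(remaining[f]["UN"] > 0 for f in members)
        if not syn_ok and not un_ok:
            break
        if syn_ok and un_ok:
            syn_left = sum(
                remaining[f]["SC"] + remaining[f]["SU"] for f in members
            )
            un_left = sum(remaining[f]["UN"] for f in members)
            kind = "syn" if rng.random() < syn_left / (syn_left + un_left) else "un"
        else:
            kind = "syn" if syn_ok else "un"
        site = pop_site(kind)
        for f in members:
            klass = take_class(f, kind)
            if kind == "syn":
                placements.append((f, klass, site[0], site[1], site[2], site[3], False))
            else:
                placements.append((f, klass, site[0], site[1], None, None, False))
            co_quota[f] -= 1

    # straddle placements: SU peaks centred on a block start (coverage 0.5)
    if cfg.straddle_fraction > 0:
        rng.shuffle(straddle_candidates)
        cand = iter(straddle_candidates)
        for f in cfg.factors:
            n_str = min(
                int(round(cfg.straddle_fraction * n)), remaining[f]["SU"]
            )
            for _ in range(n_str):
                try:
                    site = next(cand)
                except StopIteration:
                    break
                remaining[f]["SU"] -= 1
                placements.append(
                    (f, "SU", site[0], site[1], site[2], site[3], True)
                )

    # fresh (non-shared) sites for all remaining quota
    for f in cfg.factors:
        for klass in _CLASSES:
            for _ in range(remaining[f][klass]):
                if klass == "UN":
                    chrom, pos = pop_site("un")
                    placements.append((f, klass, chrom, pos, None, None, False))
                else:
                    site = pop_site("syn")
                    placements.append(
                        (f, klass, site[0], site[1], site[2], site[3], False)
                    )
            remaining[f][klass] = 0

    # --- materialize Peak objects ------------------------------------------
    L = cfg.peak_length
    shape, scale = cfg.strength_base_shape, cfg.strength_base_scale
    effect = cfg.strength_conservation_effect
    src_peaks: dict[str, list[Peak]] = {f: [] for f in cfg.factors}
    dst_peaks: dict[str, list[Peak]] = {f: [] for f in cfg.factors}
    esc_peaks: dict[str, list[Peak]] = {f: [] for f in cfg.factors}
    rows = []
    counters = {f: 0 for f in cfg.factors}
    p_persist = dict(zip(_CLASSES, cfg.esc_persistence))

    def make_peak(name, chrom, start, q, summit_off, strand=".") -> Peak:
        return Peak(
            interval=GenomicInterval(chrom, start, start + L, strand),
            name=name,
            score=int(min(1000, round(q * 10))),
            signal_value=round(q / 2, 3),
            neglog10_p=round(q + 2, 3),
            neglog10_q=q,
            summit_offset=summit_off,
        )

    for f, klass, s_chrom, s_start, d_chrom, d_start, straddle in placements:
        i = counters[f]
        counters[f] += 1
        name = f"{f}_m{i:05d}"
        jitter = int(rng.integers(-cfg.summit_jitter, cfg.summit_jitter + 1))
        q = round(float(rng.gamma(shape, scale)) + (effect if klass == "SC" else 0.0), 3)
        summit_off = L // 2 + jitter
        peak = make_peak(name, s_chrom, s_start, q, summit_off)
        src_peaks[f].append(peak)

        partner_name = ""
        if klass == "SC":
            partner_name = f"{f}_h{i:05d}"
            jq = round(
                float(rng.gamma(shape, scale)) + effect, 3
            )
            pj = int(rng.integers(-cfg.summit_jitter, cfg.summit_jitter + 1))
            dst_peaks[f].append(
                make_peak(partner_name, d_chrom, d_start, jq, L // 2 + pj)
            )
        persistent = bool(rng.random() < p_persist[klass])
        if persistent:
            esc_peaks[f].append(
                make_peak(f"{f}_esc{i:05d}", s_chrom, s_start, q, L // 2)
            )
        rows.append(
            {
                "name": name,
                "factor": f,
                "klass": klass,
                "chrom": s_chrom,
                "start": s_start,
                "end": s_start + L,
                "summit": s_start + summit_off,
                "dst_chrom": d_chrom or "",
                "dst_start": -1 if d_start is None else d_start,
                "partner": partner_name,
                "straddle": straddle,
                "persistent": persistent,
                "motif_src": False,
                "motif_dst": False,
                "state_src": 0,
                "state_dst": 0,
            }
        )

    # pluripotent-only peaks (bound in ESC but not at 48 h)
    for f in cfg.factors:
        for j in range(cfg.esc_only_peaks_per_factor):
            kind = "syn" if rng.random() < cfg.syntenic_fraction else "un"
            site = pop_site(kind)
            q = round(float(rng.gamma(shape, scale)), 3)
            esc_peaks[f].append(
                make_peak(f"{f}_esconly{j:05d}", site[0], site[1], q, L // 2)
            )
    # target-only background peaks.  Half of them reuse the target images
    # of syntenic sites bound by *other* factors in the source species
    # (shared open chromatin; never the same factor, so SU truth labels are
    # untouched); the rest go to free sites — unsyntenic bins plus images
    # of unused syntenic sites.
    used_by: dict[tuple[str, int], set[str]] = {}
    for f, klass, _, _, d_chrom, d_start, _ in placements:
        if d_chrom is not None:
            used_by.setdefault((d_chrom, d_start), set()).add(f)
    free_pool = [(dc, dp) for _, _, dc, dp in syn_sites_iter] + list(
        dst_free_iter
    )
    rng.shuffle(free_pool)
    free_iter = iter(free_pool)
    for f in cfg.factors:
        others = [site for site, users in used_by.items() if f not in users]
        others = [others[i] for i in rng.permutation(len(others))]
        others_iter = iter(others)
        for j in range(cfg.dst_only_peaks_per_factor):
            chrom = pos = None
            if rng.random() < 0.5:
                chrom, pos = next(others_iter, (None, None))
            if chrom is None:
                try:
                    chrom, pos = next(free_iter)
                except StopIteration:
                    raise RuntimeError(
                        "site lattice exhausted: genome too small for "
                        "requested peak counts"
                    ) from None
            q = round(float(rng.gamma(shape, scale)), 3)
            pj = int(rng.integers(-cfg.summit_jitter, cfg.summit_jitter + 1))
            dst_peaks[f].append(
                make_peak(f"{f}_hbg{j:05d}", chrom, pos, q, L // 2 + pj)
            )

    for d in (src_peaks, dst_peaks, esc_peaks):
        for f in d:
            d[f].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.name))
    truth = pd.DataFrame(rows)
    return PeakSets(src_peaks, dst_peaks, esc_peaks), truth


# ---------------------------------------------------------------------------
# stage 3: chromatin


@dataclass
class ChromatinTracks:
    source: BinnedMarks
    target: BinnedMarks
    emission_table: np.ndarray  # K x M Bernoulli probabilities
    true_states: dict[str, dict[str, np.ndarray]]  # species -> chrom -> 0-based


def _even_parity_patterns(m: int) -> np.ndarray:
    words = np.arange(2 ** m)
    bits = ((words[:, None] >> np.arange(m)) & 1).astype(np.uint8)
    return bits[bits.sum(axis=1) % 2 == 0]


def _make_emission_table(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """K x M Bernoulli table from distinct mark patterns.

    State 1 is the quiescent all-zero pattern; other states take distinct
    even-parity patterns (pairwise Hamming distance >= 2) when enough exist,
    arbitrary distinct non-zero patterns otherwise.  Pairwise L1 separation
    is asserted >= 0.5.
    """
    m, K = cfg.n_marks, cfg.n_states
    even = _even_parity_patterns(m)
    nonzero_even = even[even.sum(axis=1) > 0]
    if K - 1 <= len(nonzero_even):
        pool = nonzero_even
    else:
        words = np.arange(1, 2 ** m)
        pool = ((words[:, None] >> np.arange(m)) & 1).astype(np.uint8)
        if K - 1 > len(pool):
            raise ValueError("too many states for the number of marks")
    idx = rng.choice(len(pool), size=K - 1, replace=False)
    patterns = np.vstack([np.zeros(m, dtype=np.uint8), pool[idx]])
    table = np.where(patterns == 1, cfg.emission_high, cfg.emission_low)
    for i in range(K):
        for j in range(i + 1, K):
            if np.abs(table[i] - table[j]).sum() < 0.5:
                raise AssertionError("emission rows not separated")
    return table


def _sample_state_chain(
    K: int,
    length: int,
    weights: np.ndarray,
    self_p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sticky Markov chain: stay with prob ``self_p``, otherwise jump to a
    state drawn from ``weights`` excluding the current one."""
    w = weights / weights.sum()
    states = np.empty(length, dtype=np.int64)
    pos = 0
    current = int(rng.choice(K, p=w))
    while pos < length:
        run = int(rng.geometric(1 - self_p))
        states[pos : pos + run] = current
        pos += run
        nxt = current
        while nxt == current:
            nxt = int(rng.choice(K, p=w))
        current = nxt
    return states


def plant_chromatin(
    cfg: SynthConfig, scaffold: SyntenyScaffold, truth: pd.DataFrame
) -> ChromatinTracks:
    """Simulate per-bin histone-mark counts for both species.

    Background state sequences follow a sticky Markov chain dominated by the
    quiescent state.  At planted SC peaks the (source, target) state pair is
    drawn from a concentrated distribution — the same "active" state on both
    sides with probability ``state_concentration`` — while SU peaks draw the
    two states independently (diffuse).  Counts are Poisson(lambda_high)
    where the state emits the mark in that bin (Bernoulli of the emission
    table) and Poisson(lambda_low) otherwise.  ``truth`` gains the 1-based
    true state ids.
    """
    rng = _stage_rng(cfg.seed, "chromatin")
    K, bs = cfg.n_states, cfg.bin_size
    if K < 2:
        raise ValueError("need K >= 2")
    table = _make_emission_table(cfg, rng)
    weights = np.ones(K)
    weights[0] = cfg.quiescent_weight

    true_states: dict[str, dict[str, np.ndarray]] = {"source": {}, "target": {}}
    for side, chroms in (
        ("source", cfg.source_chroms),
        ("target", cfg.target_chroms),
    ):
        for chrom, size in chroms:
            true_states[side][chrom] = _sample_state_chain(
                K, size // bs, weights, cfg.self_transition, rng
            )

    # peak-bin overrides
    active = np.arange(1, cfg.n_active_states + 1)
    pi = weights / weights.sum()
    state_src = np.zeros(len(truth), dtype=np.int64)
    state_dst = np.zeros(len(truth), dtype=np.int64)
    for i, row in enumerate(truth.itertuples(index=False)):
        b_src = row.summit // bs
        if row.klass == "SC" and rng.random() < cfg.state_concentration:
            s = int(rng.choice(active))
            s_src = s_dst = s
        else:
            s_src = int(rng.choice(K, p=pi))
            s_dst = int(rng.choice(K, p=pi))
        true_states["source"][row.chrom][b_src] = s_src
        state_src[i] = s_src + 1
        if row.klass != "UN":
            b_dst = row.dst_start // bs
            true_states["target"][row.dst_chrom][b_dst] = s_dst
            state_dst[i] = s_dst + 1
    truth["state_src"] = state_src
    truth["state_dst"] = state_dst

    def _counts(states_by_chrom: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for chrom, states in states_by_chrom.items():
            probs = table[states]
            emits = rng.random(probs.shape) < probs
            lam = np.where(emits, cfg.lambda_high, cfg.lambda_low)
            out[chrom] = rng.poisson(lam).astype(np.int64)
        return out

    src = BinnedMarks(
        cfg.source_species, bs, cfg.mark_names, _counts(true_states["source"])
    )
    dst = BinnedMarks(
        cfg.target_species, bs, cfg.mark_names, _counts(true_states["target"])
    )
    return ChromatinTracks(src, dst, table, true_states)


# ---------------------------------------------------------------------------
# stage 4: motifs


def _make_pfms(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, PFM]:
    pfms = {}
    for f in cfg.factors:
        consensus = rng.integers(0, 4, cfg.motif_width)
        counts = []
        for b in consensus:
            col = [5.0, 5.0, 5.0, 5.0]
            col[int(b)] = 85.0
            counts.append(tuple(col))
        pfms[f] = PFM(name=f, counts=tuple(counts))
    return pfms


def plant_motifs(
    cfg: SynthConfig,
    scaffold: SyntenyScaffold,
    truth: pd.DataFrame,
) -> dict[str, PFM]:
    """Write motif consensus instances into peak sequences at summits.

    SC peaks receive a *shared* instance in both genomes with probability
    ``motif_rate_sc`` (equivalent to planting before the block copy); SU/UN
    peaks receive an instance in their own genome with probability
    ``motif_rate_unc``, and SU orthologous regions independently with
    ``motif_rate_target_unbound``.  With ``motif_correlated=False`` the SC
    source/target draws are made independent (for state-signal-only
    datasets).  Instances never overlap each other; a blocked plant is
    skipped and flagged False.  ``truth`` gains the realized flags.
    """
    rng = _stage_rng(cfg.seed, "motifs")
    pfms = _make_pfms(cfg, rng)
    w = cfg.motif_width
    consensus_codes = {
        f: np.array(
            ["ACGT".index(c) for c in pfm.consensus()], dtype=np.uint8
        )
        for f, pfm in pfms.items()
    }
    occupied: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def _free(side: str, chrom: str, start: int) -> bool:
        seqs = (
            scaffold.source_seqs if side == "source" else scaffold.target_seqs
        )
        if start < 0 or start + w > len(seqs[chrom]):
            return False
        for s, e in occupied.get((side, chrom), []):
            if s < start + w and start < e:
                return False
        return True

    def _write(side: str, chrom: str, start: int, codes: np.ndarray) -> None:
        seqs = (
            scaffold.source_seqs if side == "source" else scaffold.target_seqs
        )
        seqs[chrom][start : start + w] = codes
        occupied.setdefault((side, chrom), []).append((start, start + w))

    # a blocked position (another factor's instance at a shared site) may
    # shift by up to two motif widths while staying inside the peak
    _SHIFTS = (0, w, -w, 2 * w, -2 * w)

    def try_plant(
        side: str,
        chrom: str,
        start: int,
        codes: np.ndarray,
        lo: int,
        hi: int,
    ) -> bool:
        for k in _SHIFTS:
            s = start + k
            if s < lo or s + w > hi:
                continue
            if _free(side, chrom, s):
                _write(side, chrom, s, codes)
                return True
        return False

    def try_plant_pair(
        src_chrom: str,
        src_start: int,
        src_lo: int,
        src_hi: int,
        dst_chrom: str,
        dst_start: int,
        codes: np.ndarray,
    ) -> bool:
        """Plant the identical instance at the same in-peak offset in both
        genomes, or not at all."""
        for k in _SHIFTS:
            s, d = src_start + k, dst_start + k
            if s < src_lo or s + w > src_hi:
                continue
            if _free("source", src_chrom, s) and _free("target", dst_chrom, d):
                _write("source", src_chrom, s, codes)
                _write("target", dst_chrom, d, codes)
                return True
        return False

    motif_src = np.zeros(len(truth), dtype=bool)
    motif_dst = np.zeros(len(truth), dtype=bool)
    for i, row in enumerate(truth.itertuples(index=False)):
        codes = consensus_codes[row.factor]
        src_pos = row.summit - w // 2
        if len(range(row.start, row.end)) < w:
            warnings.warn(f"peak {row.name} shorter than motif; skipped")
            continue
        lo, hi = row.start, row.end
        if row.klass == "SC":
            offset = row.summit - row.start
            dst_pos = row.dst_start + offset - w // 2
            if cfg.motif_correlated:
                if rng.random() < cfg.motif_rate_sc:
                    ok = try_plant_pair(
                        row.chrom, src_pos, lo, hi, row.dst_chrom, dst_pos, codes
                    )
                    motif_src[i] = motif_dst[i] = ok
            else:
                if rng.random() < cfg.motif_rate_sc:
                    motif_src[i] = try_plant(
                        "source", row.chrom, src_pos, codes, lo, hi
                    )
                if rng.random() < cfg.motif_rate_target_unbound:
                    motif_dst[i] = try_plant(
                        "target",
                        row.dst_chrom,
                        dst_pos,
                        codes,
                        row.dst_start,
                        row.dst_start + (hi - lo),
                    )
        else:
            if rng.random() < cfg.motif_rate_unc:
                motif_src[i] = try_plant(
                    "source", row.chrom, src_pos, codes, lo, hi
                )
            if row.klass == "SU":
                offset = row.summit - row.start
                dst_pos = row.dst_start + offset - w // 2
                if rng.random() < cfg.motif_rate_target_unbound:
                    motif_dst[i] = try_plant(
                        "target",
                        row.dst_chrom,
                        dst_pos,
                        codes,
                        row.dst_start,
                        row.dst_start + (hi - lo),
                    )
    truth["motif_src"] = motif_src
    truth["motif_dst"] = motif_dst
    return pfms


# ---------------------------------------------------------------------------
# stage 5: annotations (genes, orthologs, repeats)


@dataclass
class Annotations:
    tss_source: list[TssRecord]
    tss_target: list[TssRecord]
    orthologs: list[tuple[str, str]]
    repeats_source: list[tuple[GenomicInterval, str]]


def plant_annotations(
    cfg: SynthConfig, scaffold: SyntenyScaffold, truth: pd.DataFrame
) -> Annotations:
    """Gene TSS sets with a one-to-one ortholog table, and repeat intervals.

    Genes falling inside aligned blocks get their ortholog TSS at the mapped
    position (so nearby peaks in both species hit orthologous genes); other
    genes get a random ortholog position.  Repeats combine a uniform
    background with instances planted fully inside peaks at class-dependent
    rates (highest for unsyntenic peaks).
    """
    rng = _stage_rng(cfg.seed, "annotations")
    src_sizes = dict(cfg.source_chroms)
    dst_sizes = dict(cfg.target_chroms)
    src_chroms = list(src_sizes)
    dst_chroms = list(dst_sizes)

    # aligned-block lookup for gene placement
    blocks = scaffold.aligned_blocks

    def image_of(chrom: str, pos: int) -> tuple[str, int] | None:
        for sc_, ss, size, dc, ds in blocks:
            if sc_ == chrom and ss <= pos < ss + size:
                return dc, ds + (pos - ss)
        return None

    tss_src, tss_dst, pairs = [], [], []
    probs = np.array([src_sizes[c] for c in src_chroms], dtype=float)
    probs /= probs.sum()
    for g in range(cfg.n_genes):
        chrom = src_chroms[int(rng.choice(len(src_chroms), p=probs))]
        pos = int(rng.integers(0, src_sizes[chrom]))
        strand = "+" if rng.random() < 0.5 else "-"
        a_name, b_name = f"mgene{g:04d}", f"hgene{g:04d}"
        img = image_of(chrom, pos)
        if img is None:
            d_chrom = dst_chroms[int(rng.integers(0, len(dst_chroms)))]
            d_pos = int(rng.integers(0, dst_sizes[d_chrom]))
        else:
            d_chrom, d_pos = img
        tss_src.append(TssRecord(a_name, chrom, pos, strand))
        tss_dst.append(TssRecord(b_name, d_chrom, d_pos, strand))
        pairs.append((a_name, b_name))

    families = list(REPEAT_FAMILIES)
    fam_w = np.array(cfg.repeat_family_weights, dtype=float)
    fam_w /= fam_w.sum()
    repeats: list[tuple[GenomicInterval, str]] = []
    n_bg = int(cfg.repeats_per_mb * sum(src_sizes.values()) / 1e6)
    for _ in range(n_bg):
        chrom = src_chroms[int(rng.choice(len(src_chroms), p=probs))]
        length = int(rng.integers(50, 401))
        start = int(rng.integers(0, src_sizes[chrom] - length))
        fam = families[int(rng.choice(len(families), p=fam_w))]
        repeats.append((GenomicInterval(chrom, start, start + length), fam))
    rate = dict(zip(_CLASSES, cfg.repeat_assoc_rate))
    for row in truth.itertuples(index=False):
        if rng.random() < rate[row.klass]:
            length = int(rng.integers(50, 121))
            start = row.start + int(rng.integers(0, row.end - row.start - length))
            fam = families[int(rng.choice(len(families), p=fam_w))]
            repeats.append((GenomicInterval(row.chrom, start, start + length), fam))
    repeats.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    return Annotations(tss_src, tss_dst, pairs, repeats)


# ---------------------------------------------------------------------------
# dataset assembly and emission


@dataclass
class SyntheticDataset:
    cfg: SynthConfig
    scaffold: SyntenyScaffold
    peaks: PeakSets
    truth: pd.DataFrame
    chromatin: ChromatinTracks | None = None
    pfms: dict[str, PFM] | None = None
    annotations: Annotations | None = None

    def source_genome(self) -> dict[str, str]:
        return self.scaffold.sequences("source")

    def target_genome(self) -> dict[str, str]:
        return self.scaffold.sequences("target")


def generate(
    cfg: SynthConfig,
    with_chromatin: bool = True,
    with_motifs: bool = True,
    with_annotations: bool = True,
) -> SyntheticDataset:
    """Run all generation stages (pure function of ``cfg``)."""
    scaffold = build_synteny(cfg)
    peaks, truth = plant_peaks(cfg, scaffold)
    ds = SyntheticDataset(cfg, scaffold, peaks, truth)
    if with_chromatin:
        ds.chromatin = plant_chromatin(cfg, scaffold, truth)
    if with_motifs:
        ds.pfms = plant_motifs(cfg, scaffold, truth)
    if with_annotations:
        ds.annotations = plant_annotations(cfg, scaffold, truth)
    return ds


def _write_marks_tsv(binned: BinnedMarks, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\t" + "\t".join(binned.mark_names) + "\n")
        for chrom, mat in binned.segments.items():
            starts = np.arange(len(mat)) * binned.bin_size
            for s, row in zip(starts, mat):
                fh.write(
                    f"{chrom}\t{s}\t" + "\t".join(str(int(x)) for x in row) + "\n"
                )


def emit_dataset(
    ds: SyntheticDataset, outdir: str | Path, force: bool = False
) -> dict[str, str]:
    """Write the dataset as a plain-text file tree; returns path -> sha256.

    Refuses a non-empty output directory unless ``force``.
    """
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    cfg = ds.cfg

    formats.write_fasta(ds.source_genome(), out / "source.fa")
    formats.write_fasta(ds.target_genome(), out / "target.fa")
    formats.write_chain(ds.scaffold.chains, out / "source_to_target.chain")
    formats.write_chrom_sizes(dict(cfg.source_chroms), out / "source.sizes")
    formats.write_chrom_sizes(dict(cfg.target_chroms), out / "target.sizes")
    peakdir = out / "peaks"
    peakdir.mkdir(exist_ok=True)
    for f in cfg.factors:
        formats.write_narrowpeak(
            ds.peaks.source[f], peakdir / f"{f}_{cfg.source_species}.narrowPeak"
        )
        formats.write_narrowpeak(
            ds.peaks.target[f], peakdir / f"{f}_{cfg.target_species}.narrowPeak"
        )
        formats.write_narrowpeak(
            ds.peaks.esc[f], peakdir / f"{f}_pluripotent.narrowPeak"
        )
    if ds.annotations is not None:
        ann = ds.annotations
        formats.write_bed_track(
            [(t.interval, t.gene) for t in ann.tss_source],
            out / "tss_source.bed",
        )
        formats.write_bed_track(
            [(t.interval, t.gene) for t in ann.tss_target],
            out / "tss_target.bed",
        )
        formats.write_ortholog_table(ann.orthologs, out / "orthologs.tsv")
        formats.write_bed_track(ann.repeats_source, out / "repeats_source.bed")
    if ds.chromatin is not None:
        _write_marks_tsv(ds.chromatin.source, out / "marks_source.tsv")
        _write_marks_tsv(ds.chromatin.target, out / "marks_target.tsv")
    if ds.pfms is not None:
        motifdir = out / "motifs"
        motifdir.mkdir(exist_ok=True)
        for f, pfm in ds.pfms.items():
            formats.write_jaspar_pfm(pfm, motifdir / f"{f}.jaspar")
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps({"seed": cfg.seed, "config": cfg.to_dict()}, indent=1)
    )
    return {
        str(p.relative_to(out)): formats.file_sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file()
    }
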