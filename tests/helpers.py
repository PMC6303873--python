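"""Independent oracles and random-instance generators for the test suite.

Everything here is deliberately naive (per-base maps, exhaustive
enumeration) so it can serve as ground truth for the optimized library
code.
"""

from __future__ import annotations

import numpy as np

from crosstf.formats import ChainAlignment, GenomicInterval


def random_chain(
    rng: np.random.Generator,
    chain_id: int = 1,
    t_name: str = "chrM",
    q_name: str = "chrH",
    minus_prob: float = 0.5,
) -> ChainAlignment:
    """A random valid chain: 1-6 blocks, random gaps, random strand."""
    n_blocks = int(rng.integers(1, 7))
    sizes = rng.integers(20, 400, n_blocks)
    dts = rng.integers(1, 200, n_blocks)
    dqs = rng.integers(1, 200, n_blocks)
    dts[-1] = dqs[-1] = 0
    t_span = int(sizes.sum() + dts.sum())
    q_span = int(sizes.sum() + dqs.sum())
    t_size = t_span + int(rng.integers(100, 2000))
    q_size = q_span + int(rng.integers(100, 2000))
    t_start = int(rng.integers(0, t_size - t_span + 1))
    q_start = int(rng.integers(0, q_size - q_span + 1))
    q_strand = "-" if rng.random() < minus_prob else "+"
    return ChainAlignment(
        score=float(rng.integers(1, 10_000)),
        t_name=t_name,
        t_size=t_size,
        t_strand="+",
        t_start=t_start,
        t_end=t_start + t_span,
        q_name=q_name,
        q_size=q_size,
        q_strand=q_strand,
        q_start=q_start,
        q_end=q_start + q_span,
        blocks=tuple(
            (int(s), int(dt), int(dq)) for s, dt, dq in zip(sizes, dts, dqs)
        ),
        chain_id=chain_id,
    )


def per_base_image_map(chain: ChainAlignment) -> dict[int, int]:
    """Literal target-position -> plus-strand query-position map."""
    out: dict[int, int] = {}
    t, q = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        for i in range(size):
            q_file = q + i
            if chain.q_strand == "-":
                out[t + i] = chain.q_size - q_file - 1
            else:
                out[t + i] = q_file
        t += size + dt
        q += size + dq
    return out


def brute_force_map(
    iv: GenomicInterval,
    chains: list[ChainAlignment],
    min_match: float = 0.5,
) -> tuple[str, int, int, float, int] | None:
    """Oracle for map_interval: per-base image sets over all chains.

    Returns (q_name, start, end, fraction, chain_id) for the best-covering
    chain (ties by score), or None on failure.
    """
    best = None
    for chain in chains:
        if chain.t_name != iv.chrom:
            continue
        imap = per_base_image_map(chain)
        images = [imap[p] for p in range(iv.start, iv.end) if p in imap]
        cover = len(images)
        key = (cover, chain.score)
        if images and (best is None or key > best[0]):
            best = (key, chain, images)
    if best is None:
        return None
    (cover, _), chain, images = best
    fraction = cover / len(iv)
    if fraction < min_match:
        return None
    return (
        chain.q_name,
        min(images),
        max(images) + 1,
        fraction,
        chain.chain_id,
    )


def brute_force_hmm_loglik(
    X: np.ndarray,
    initial: np.ndarray,
    trans: np.ndarray,
    emis: np.ndarray,
) -> float:
    """Sum over all K^T state paths of the joint probability (log)."""
    from itertools import product

    T = len(X)
    K = len(initial)
    total = 0.0
    for path in product(range(K), repeat=T):
        p = initial[path[0]]
        for t in range(1, T):
            p *= trans[path[t - 1], path[t]]
        for t in range(T):
            e = emis[path[t]]
            p *= np.prod(np.where(X[t] == 1, e, 1 - e))
        total += p
    return float(np.log(total))


def brute_force_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Exact tail by integer combinatorics."""
    from math import comb

    denom = comb(N, n)
    hi = min(K, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1)) / denom


def brute_force_auc(scores, labels) -> float:
    """Pairwise counting AUC with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
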