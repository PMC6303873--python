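"""Readers and writers for the plain-text genomics formats the pipeline touches.

Everything is kept in 0-based, half-open coordinates internally (BED
convention); conversion to/from other conventions happens only at the
parse/serialize boundary.  Chromosome names are matched verbatim — no
``chr`` aliasing.

Supported formats: ENCODE narrowPeak (strict 10-column BED6+4), UCSC chain,
BED3/4/6 label tracks, JASPAR PFM text, FASTA, and two tiny TSV dialects
(chrom sizes, ortholog pairs).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "GenomicInterval",
    "Peak",
    "ChainAlignment",
    "PFM",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_chain",
    "write_chain",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_bed_track",
    "write_bed_track",
    "read_genome",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_ortholog_table",
    "write_ortholog_table",
]

_ALPHABET = ("A", "C", "G", "T")


class FormatError(ValueError):
    """A file violates its format contract (message names the line)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record.

    ``neglog10_q`` (column 9) doubles as the peak-strength statistic used for
    the strength-quartile conservation analysis.  ``summit_offset`` is the
    0-based offset of the summit from ``interval.start`` (-1 = unknown).
    """

    interval: GenomicInterval
    name: str
    score: int = 0
    signal_value: float = 0.0
    neglog10_p: float = 0.0
    neglog10_q: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.summit_offset < -1:
            raise ValueError(f"peak {self.name}: summit_offset < -1")
        if self.summit_offset >= len(self.interval):
            raise ValueError(
                f"peak {self.name}: summit offset {self.summit_offset} "
                f">= length {len(self.interval)}"
            )
        for attr in ("signal_value", "neglog10_p", "neglog10_q"):
            if getattr(self, attr) < 0:
                raise ValueError(f"peak {self.name}: negative {attr}")

    @property
    def summit(self) -> int:
        """Absolute summit position (midpoint fallback when unknown)."""
        if self.summit_offset >= 0:
            return self.interval.start + self.summit_offset
        return self.interval.start + len(self.interval) // 2

    def moved_to(self, start: int) -> "Peak":
        """Copy of this peak re-placed at ``start`` (length preserved)."""
        iv = replace(self.interval, start=start, end=start + len(self.interval))
        return replace(self, interval=iv)


@dataclass(frozen=True)
class ChainAlignment:
    """One UCSC chain: a gapped pairwise alignment.

    ``blocks`` is an ordered list of ``(size, dt, dq)`` where ``dt``/``dq``
    are the unaligned gaps after the block on the target/query side; the last
    block has ``dt == dq == 0``.  Query coordinates are stored exactly as in
    the file: for ``q_strand == '-'`` they refer to the reverse-complemented
    query sequence (the coordinate flip happens in the mapper).
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[tuple[int, int, int], ...]
    chain_id: int

    def __post_init__(self) -> None:
        if self.t_strand != "+":
            raise ValueError(f"chain {self.chain_id}: t_strand must be '+'")
        if any(size <= 0 for size, _, _ in self.blocks):
            raise ValueError(f"chain {self.chain_id}: non-positive block size")
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if sizes + dts != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: target span {self.t_end - self.t_start} "
                f"!= blocks {sizes}+{dts}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: query span {self.q_end - self.q_start} "
                f"!= blocks {sizes}+{dqs}"
            )
        last = self.blocks[-1]
        if last[1] != 0 or last[2] != 0:
            raise ValueError(f"chain {self.chain_id}: final block has gaps")

    def aligned_blocks(self) -> list[tuple[int, int, int]]:
        """Per block: (t_start, t_end, q_start) in file coordinates."""
        out = []
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            out.append((t, t + size, q))
            t += size + dt
            q += size + dq
        return out


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: ``counts[pos][base]``, base order A,C,G,T."""

    name: str
    counts: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError(f"PFM {self.name}: empty matrix")
        for i, col in enumerate(self.counts):
            if any(c < 0 for c in col):
                raise ValueError(f"PFM {self.name}: negative count, column {i}")
            if sum(col) <= 0:
                raise ValueError(f"PFM {self.name}: all-zero column {i}")

    @property
    def width(self) -> int:
        return len(self.counts)

    def consensus(self) -> str:
        return "".join(
            _ALPHABET[max(range(4), key=lambda b: col[b])] for col in self.counts
        )


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read a strict 10-column ENCODE narrowPeak file.

    Files with fewer columns are rejected rather than guessed at: a silently
    invented summit would corrupt every summit-based rule downstream.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score = int(fields[4])
                signal, logp, logq = (float(fields[i]) for i in (6, 7, 8))
                summit = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                peak = Peak(
                    interval=GenomicInterval(fields[0], start, end, fields[5]),
                    name=fields[3],
                    score=score,
                    signal_value=signal,
                    neglog10_p=logp,
                    neglog10_q=logq,
                    summit_offset=summit,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def _fmt_float(x: float) -> str:
    # canonical float: shortest repr but always with a decimal point
    s = f"{x:.10g}"
    if "." not in s and "e" not in s and "inf" not in s and "nan" not in s:
        s += ".0"
    return s


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name,
                        str(p.score),
                        iv.strand,
                        _fmt_float(p.signal_value),
                        _fmt_float(p.neglog10_p),
                        _fmt_float(p.neglog10_q),
                        str(p.summit_offset),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain


def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Read a UCSC chain file; every chain is integrity-checked on load."""
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[tuple[int, int, int]] = []
    header_line = 0

    def _flush(lineno: int) -> None:
        nonlocal header, blocks
        if header is None:
            return
        if not blocks or blocks[-1][1] != 0 or blocks[-1][2] != 0:
            raise FormatError(
                f"{path}:{header_line}: chain not terminated by a bare size line"
            )
        try:
            chains.append(
                ChainAlignment(
                    score=float(header[1]),
                    t_name=header[2],
                    t_size=int(header[3]),
                    t_strand=header[4],
                    t_start=int(header[5]),
                    t_end=int(header[6]),
                    q_name=header[7],
                    q_size=int(header[8]),
                    q_strand=header[9],
                    q_start=int(header[10]),
                    q_end=int(header[11]),
                    blocks=tuple(blocks),
                    chain_id=int(header[12]),
                )
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: chain ending line {lineno} "
                f"(id {header[12]}): {exc}"
            ) from exc
        header, blocks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("chain"):
                _flush(lineno)
                header = line.split()
                header_line = lineno
                if len(header) != 13:
                    raise FormatError(
                        f"{path}:{lineno}: chain header needs 13 fields, "
                        f"got {len(header)}"
                    )
                continue
            if header is None:
                raise FormatError(f"{path}:{lineno}: block line before header")
            parts = line.split()
            try:
                nums = [int(x) for x in parts]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(nums) == 3:
                blocks.append((nums[0], nums[1], nums[2]))
            elif len(nums) == 1:
                blocks.append((nums[0], 0, 0))
            else:
                raise FormatError(
                    f"{path}:{lineno}: block line needs 1 or 3 integers"
                )
    _flush(lineno if chains or header else 0)
    return chains


def write_chain(chains: Iterable[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {_fmt_float(c.score)} {c.t_name} {c.t_size} "
                f"{c.t_strand} {c.t_start} {c.t_end} {c.q_name} {c.q_size} "
                f"{c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path: str | Path) -> PFM:
    """Read one motif in JASPAR 2016 text format.

    Expected layout: a ``>name`` line, then four rows ``A [ 1 2 3 ]`` in any
    row order (normalized to A,C,G,T).  Brackets are optional.
    """
    name = ""
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else "motif"
                continue
            base = line[0].upper()
            if base not in _ALPHABET:
                raise FormatError(f"{path}:{lineno}: unexpected row {line[0]!r}")
            if base in rows:
                raise FormatError(f"{path}:{lineno}: duplicate row {base}")
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                rows[base] = [float(x) for x in body.split()]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if set(rows) != set(_ALPHABET):
        raise FormatError(f"{path}: missing rows {set(_ALPHABET) - set(rows)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise FormatError(f"{path}: rows of unequal width {sorted(widths)}")
    counts = tuple(
        tuple(rows[b][i] for b in _ALPHABET) for i in range(widths.pop())
    )
    return PFM(name=name or "motif", counts=counts)


def write_jaspar_pfm(pfm: PFM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.name}\n")
        for b, base in enumerate(_ALPHABET):
            vals = " ".join(_fmt_float(col[b]) for col in pfm.counts)
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# BED tracks


def read_bed_track(
    path: str | Path, value_col: int = 4
) -> list[tuple[GenomicInterval, str]]:
    """Read a BED file as (interval, label) pairs.

    ``value_col`` is the 1-based column holding the label (default 4, the BED
    name column); rows shorter than ``value_col`` yield label ``""``.
    """
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            label = fields[value_col - 1] if len(fields) >= value_col else ""
            out.append((iv, label))
    return out


def write_bed_track(
    records: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, label in records:
            cols = [iv.chrom, str(iv.start), str(iv.end), label]
            if iv.strand != ".":
                cols += ["0", iv.strand]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA and small TSV tables


def read_genome(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Read a (multi-)FASTA into upper-cased sequences plus a size table."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        nonlocal name, chunks
        if name is not None:
            seqs[name] = "".join(chunks).upper()
        name, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                if name in seqs:
                    raise FormatError(f"{path}:{lineno}: duplicate record {name}")
                continue
            if name is None:
                raise FormatError(f"{path}:{lineno}: sequence before header")
            chunks.append(line)
    _flush()
    return seqs, {k: len(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'name\\tlength'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_ortholog_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column gene_a<TAB>gene_b ortholog table (one-to-one)."""
    pairs: list[tuple[str, str]] = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            a, b = fields
            if a in seen_a or b in seen_b:
                raise FormatError(f"{path}:{lineno}: gene listed twice")
            seen_a.add(a)
            seen_b.add(b)
            pairs.append((a, b))
    return pairs


def write_ortholog_table(
    pairs: Iterable[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file's contents (used for determinism checks)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
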