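"""Read-density coverage tracks.

Reads are extended to the expected fragment length (default 200 bp) and
accumulated into fixed-width genomic bins (default 25 bp); a fragment is
counted once in every bin it overlaps by at least one base.  Tracks can be
normalized per million mapped reads, as a ratio over an input-control track,
or by a plain scalar, and serialized as fixedStep wiggle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genome_io import ChromSizes, GenomicInterval, ReadRecord

DEFAULT_FRAGMENT_LENGTH = 200
DEFAULT_BIN_WIDTH = 25


@dataclass
class CoverageTrack:
    """Per-chromosome fixed-width-bin read densities.

    ``values[chrom]`` has ``ceil(length / bin_width)`` entries; the last bin
    may be partial.  ``normalization`` records how the values were produced:
    ``raw`` (fragment counts), ``per-million``, ``input-ratio`` or ``scalar``.
    """

    chrom_sizes: ChromSizes
    bin_width: int
    values: dict[str, np.ndarray]
    total_reads: int = 0
    normalization: str = "raw"
    track_id: str = ""

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, length in self.chrom_sizes.items():
            nb = n_bins(length, self.bin_width)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(nb)
            elif len(self.values[chrom]) != nb:
                raise ValueError(
                    f"{chrom}: expected {nb} bins, got {len(self.values[chrom])}"
                )

    def value_at(self, chrom: str, pos: int) -> float:
        """Density of the bin containing base ``pos`` (0 outside bounds)."""
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            return 0.0
        return float(self.values[chrom][pos // self.bin_width])

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Per-base mean density over [start, end), clipped to the chromosome."""
        w = self.bin_width
        start = max(0, start)
        end = min(end, self.chrom_sizes[chrom])
        if end <= start:
            return 0.0
        v = self.values[chrom]
        b0, b1 = start // w, (end - 1) // w
        if b0 == b1:
            return float(v[b0])
        total = v[b0] * ((b0 + 1) * w - start) + v[b1] * (end - b1 * w)
        if b1 > b0 + 1:
            total += float(v[b0 + 1 : b1].sum()) * w
        return float(total) / (end - start)

    def copy(self) -> "CoverageTrack":
        return replace(self, values={c: v.copy() for c, v in self.values.items()})


def n_bins(length: int, bin_width: int) -> int:
    return -(-length // bin_width)


def extend_reads(
    reads: Iterable[ReadRecord],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    chrom_sizes: ChromSizes | None = None,
) -> list[GenomicInterval]:
    """Extend each read from its 5' end to ``fragment_length`` bp.

    A '+' read becomes [5', 5'+L); a '-' read becomes [5'-L+1, 5'+1).
    Fragments are clipped to chromosome bounds when sizes are known.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    out: list[GenomicInterval] = []
    for read in reads:
        p5 = read.five_prime
        chrom = read.interval.chrom
        if read.interval.strand == "+":
            start, end = p5, p5 + fragment_length
        else:
            start, end = p5 - fragment_length + 1, p5 + 1
        start = max(0, start)
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        if end > start:
            out.append(GenomicInterval(chrom, start, end, read.interval.strand))
    return out


def bin_coverage(
    extended: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    bin_width: int = DEFAULT_BIN_WIDTH,
    track_id: str = "",
) -> CoverageTrack:
    """Count, per bin, the fragments overlapping it by >=1 bp."""
    values: dict[str, np.ndarray] = {}
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in chrom_sizes.items()}
    for iv in extended:
        if iv.chrom not in per_chrom:
            raise ValueError(f"fragment on unknown chromosome {iv.chrom!r}")
        per_chrom[iv.chrom].append((iv.start, min(iv.end, chrom_sizes[iv.chrom])))
    for chrom, length in chrom_sizes.items():
        nb = n_bins(length, bin_width)
        diff = np.zeros(nb + 1)
        frags = per_chrom[chrom]
        if frags:
            arr = np.asarray(frags)
            b0 = arr[:, 0] // bin_width
            b1 = (arr[:, 1] - 1) // bin_width
            np.add.at(diff, b0, 1.0)
            np.add.at(diff, b1 + 1, -1.0)
        values[chrom] = np.cumsum(diff)[:nb]
    return CoverageTrack(
        chrom_sizes, bin_width, values, total_reads=len(extended), track_id=track_id
    )


def bin_five_prime(
    reads: Sequence[ReadRecord],
    chrom_sizes: ChromSizes,
    bin_width: int = DEFAULT_BIN_WIDTH,
    track_id: str = "",
) -> CoverageTrack:
    """Alternative counting mode: each read counted only in its 5'-end bin."""
    values = {}
    for chrom, length in chrom_sizes.items():
        values[chrom] = np.zeros(n_bins(length, bin_width))
    for read in reads:
        p5 = read.five_prime
        chrom = read.interval.chrom
        if chrom in values and 0 <= p5 < chrom_sizes[chrom]:
            values[chrom][p5 // bin_width] += 1.0
    return CoverageTrack(chrom_sizes, bin_width, values, total_reads=len(reads), track_id=track_id)


def build_track(
    reads: Sequence[ReadRecord],
    chrom_sizes: ChromSizes,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    bin_width: int = DEFAULT_BIN_WIDTH,
    count_mode: str = "overlap",
    track_id: str = "",
) -> CoverageTrack:
    """Convenience: extend reads then bin them into a raw coverage track."""
    if count_mode == "overlap":
        frags = extend_reads(reads, fragment_length, chrom_sizes)
        return bin_coverage(frags, chrom_sizes, bin_width, track_id=track_id)
    if count_mode == "five-prime":
        return bin_five_prime(reads, chrom_sizes, bin_width, track_id=track_id)
    raise ValueError(f"unknown count_mode {count_mode!r}")


def normalize_track(
    track: CoverageTrack,
    mode: str,
    input_track: CoverageTrack | None = None,
    pseudocount: float = 1.0,
    scalar: float | None = None,
) -> CoverageTrack:
    """Return a normalized copy of ``track``.

    per-million: value * 1e6 / total_reads.
    input-ratio: (per-million value + pseudocount) / (per-million input + pseudocount).
    scalar: value / scalar.
    """
    if mode == "per-million":
        if track.normalization == "per-million":
            return track.copy()
        if track.normalization != "raw":
            raise ValueError("per-million requires a raw track")
        if track.total_reads <= 0:
            raise ValueError("per-million requires total_reads > 0")
        factor = 1e6 / track.total_reads
        out = track.copy()
        for chrom in out.values:
            out.values[chrom] *= factor
        out.normalization = "per-million"
        return out
    if mode == "input-ratio":
        if input_track is None:
            raise ValueError("input-ratio requires an input track")
        if (
            input_track.bin_width != track.bin_width
            or dict(input_track.chrom_sizes.items()) != dict(track.chrom_sizes.items())
        ):
            raise ValueError("ChIP and input tracks must share the same bin grid")
        chip = track if track.normalization == "per-million" else normalize_track(track, "per-million")
        inp = (
            input_track
            if input_track.normalization == "per-million"
            else normalize_track(input_track, "per-million")
        )
        out = chip.copy()
        for chrom in out.values:
            out.values[chrom] = (chip.values[chrom] + pseudocount) / (
                inp.values[chrom] + pseudocount
            )
        out.normalization = "input-ratio"
        return out
    if mode == "scalar":
        if not scalar:
            raise ValueError("scalar mode requires a non-zero scalar")
        out = track.copy()
        for chrom in out.values:
            out.values[chrom] /= scalar
        out.normalization = "scalar"
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# fixedStep wiggle serialization (the only place 1-based coordinates appear)
# ---------------------------------------------------------------------------

def write_wig(track: CoverageTrack, path: str | os.PathLike, precision: int = 4) -> None:
    """Write a track as fixedStep wiggle (1-based starts, step = span = bin)."""
    with open(path, "w") as fh:
        for chrom, _ in track.chrom_sizes.items():
            vals = track.values[chrom]
            if len(vals) == 0:
                continue
            fh.write(
                f"fixedStep chrom={chrom} start=1 step={track.bin_width} span={track.bin_width}\n"
            )
            fh.write("\n".join(f"{v:.{precision}f}".rstrip("0").rstrip(".") or "0" for v in vals))
            fh.write("\n")


def read_wig(
    path: str | os.PathLike,
    chrom_sizes: ChromSizes,
    track_id: str = "",
    total_reads: int = 0,
    normalization: str = "raw",
) -> CoverageTrack:
    """Parse a fixedStep wiggle back into a CoverageTrack."""
    values: dict[str, np.ndarray] = {}
    chrom: str | None = None
    bin_width: int | None = None
    buf: list[float] = []
    offset = 0

    def flush() -> None:
        nonlocal buf
        if chrom is None:
            return
        arr = values[chrom]
        idx = offset + np.arange(len(buf))
        arr[idx[idx < len(arr)]] = np.asarray(buf)[idx < len(arr)]
        buf = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                flush()
                kv = dict(part.split("=") for part in line.split()[1:])
                chrom = kv["chrom"]
                step = int(kv["step"])
                if bin_width is None:
                    bin_width = step
                elif step != bin_width:
                    raise ValueError("mixed bin widths in wiggle file")
                offset = (int(kv.get("start", 1)) - 1) // step
                if chrom not in values:
                    values[chrom] = np.zeros(n_bins(chrom_sizes[chrom], step))
            else:
                buf.append(float(line))
    flush()
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH
    return CoverageTrack(
        chrom_sizes, bin_width, values, total_reads=total_reads,
        normalization=normalization, track_id=track_id,
    )
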