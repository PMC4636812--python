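"""Density matrices around stranded reference points and metagene profiles.

Each anchor (TSS, peak summit or enhancer midpoint) contributes one matrix
row; columns are bin-width-spaced signed offsets spanning +/- flank, with
positive offsets always meaning downstream of the anchor (the offset axis is
reversed for '-' strand anchors).  Column values are point samples of the
track bin containing the offset position — no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .genome_io import GeneModel, GenomicInterval, PeakSet
from .track import CoverageTrack


@dataclass(frozen=True)
class Anchor:
    chrom: str
    pos: int
    strand: str
    id: str


@dataclass
class ReferencePointSet:
    """Stranded anchor coordinates for matrix extraction."""

    anchors: list[Anchor]
    kind: str = "TSS"  # TSS | peak-summit | enhancer-midpoint

    def __post_init__(self) -> None:
        ids = [a.id for a in self.anchors]
        if len(set(ids)) != len(ids):
            raise ValueError("anchor ids must be unique")

    def __len__(self) -> int:
        return len(self.anchors)

    @classmethod
    def from_tss(cls, genes: Iterable[GeneModel]) -> "ReferencePointSet":
        return cls(
            [Anchor(g.interval.chrom, g.tss, g.interval.strand, g.gene_id) for g in genes],
            kind="TSS",
        )

    @classmethod
    def from_peak_summits(cls, peaks: PeakSet) -> "ReferencePointSet":
        return cls(
            [Anchor(p.interval.chrom, p.summit, ".", p.peak_id) for p in peaks],
            kind="peak-summit",
        )

    @classmethod
    def from_midpoints(
        cls, intervals: Sequence[GenomicInterval], ids: Sequence[str] | None = None
    ) -> "ReferencePointSet":
        if ids is None:
            ids = [f"mid{i + 1}" for i in range(len(intervals))]
        return cls(
            [Anchor(iv.chrom, iv.midpoint, ".", i) for iv, i in zip(intervals, ids)],
            kind="enhancer-midpoint",
        )


@dataclass
class DensityMatrix:
    """anchors x offsets matrix of track densities."""

    ids: list[str]
    offsets: np.ndarray  # signed bp, symmetric about 0
    values: np.ndarray  # shape (n anchors, n offsets)
    track_id: str = ""
    flagged: set[str] = field(default_factory=set)  # anchors clipped at bounds

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.offsets)):
            raise ValueError("matrix shape does not match ids/offsets")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")


@dataclass
class MetaProfile:
    """Column-wise mean density as a function of offset from the anchors."""

    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets/values length mismatch")


def extract_matrix(
    track: CoverageTrack,
    refs: ReferencePointSet,
    flank: int,
    bin_width: int | None = None,
) -> DensityMatrix:
    """Sample ``track`` at bin-spaced offsets in [-flank, +flank] around anchors.

    Anchors whose window crosses a chromosome boundary are zero-padded and
    flagged.  For '-' strand anchors positive offsets run toward lower
    coordinates so that downstream is always positive.
    """
    if bin_width is None:
        bin_width = track.bin_width
    if flank % bin_width != 0:
        raise ValueError("flank must be a multiple of the bin width")
    if bin_width % track.bin_width != 0:
        raise ValueError("bin width must be a multiple of the track bin width")
    offsets = np.arange(-flank, flank + bin_width, bin_width, dtype=int)
    n, m = len(refs), len(offsets)
    out = np.zeros((n, m))
    flagged: set[str] = set()
    w = track.bin_width
    for i, a in enumerate(refs.anchors):
        if a.chrom not in track.chrom_sizes:
            raise ValueError(f"anchor {a.id}: unknown chromosome {a.chrom!r}")
        sign = -1 if a.strand == "-" else 1
        pos = a.pos + sign * offsets
        size = track.chrom_sizes[a.chrom]
        valid = (pos >= 0) & (pos < size)
        if not valid.all():
            flagged.add(a.id)
        vals = track.values[a.chrom]
        idx = np.clip(pos // w, 0, len(vals) - 1)
        out[i] = np.where(valid, vals[idx], 0.0)
    return DensityMatrix([a.id for a in refs.anchors], offsets, out, track.track_id, flagged)


def average_profile(matrix: DensityMatrix) -> MetaProfile:
    """Arithmetic column means of a density matrix."""
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot average an empty matrix")
    return MetaProfile(matrix.offsets.copy(), matrix.values.mean(axis=0), matrix.values.shape[0])


def profile_peak_offset(profile: MetaProfile, smoothing_window: int = 3) -> int:
    """Offset (bp) of the maximum of the moving-average-smoothed profile.

    Ties are broken toward offset 0, then downstream.  A constant profile has
    no peak and raises ValueError.
    """
    vals = profile.values.astype(float)
    if smoothing_window > 1:
        vals = uniform_filter1d(vals, size=smoothing_window, mode="nearest")
    if np.ptp(vals) == 0:
        raise ValueError("profile is constant; no peak")
    top = np.flatnonzero(vals == vals.max())
    cand = sorted(profile.offsets[top], key=lambda o: (abs(o), -np.sign(o)))
    return int(cand[0])


def matrix_to_frame(matrix: DensityMatrix):
    """Serialize as a pandas DataFrame (rows = anchors, columns = offsets)."""
    import pandas as pd

    return pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.offsets)
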