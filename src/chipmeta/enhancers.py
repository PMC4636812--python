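"""Enhancer stratification and super-enhancer meta-profiles.

Enhancers are ranked by acetylation signal (H3K27ac by convention) in a
window around their midpoint and split into quartiles I (highest) to IV;
factor-positive enhancers are identified by k-means clustering of midpoint
density matrices.  Variable-length super-enhancers are summarized on a
length-normalized axis: the body is divided into a fixed number of bins
(default 80) and flanked by fixed 50-bp bins over 4 kb on each side, with
the factor signal expressed as a ratio over the input control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import call_positive_clusters, kmeans_cluster
from .genome_io import GenomicInterval
from .matrix import MetaProfile, ReferencePointSet, average_profile, extract_matrix
from .track import CoverageTrack, normalize_track

QUARTILES = ("I", "II", "III", "IV")


@dataclass
class EnhancerRecord:
    enh_id: str
    interval: GenomicInterval
    rank_signal: float
    quartile: str

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class EnhancerClassification:
    positive_ids: list[str]
    negative_ids: list[str]
    assignment: object = None

    @property
    def n_total(self) -> int:
        return len(self.positive_ids) + len(self.negative_ids)

    @property
    def fraction(self) -> float:
        """Per-cent of enhancers positive for the factor."""
        return 100.0 * len(self.positive_ids) / max(1, self.n_total)


@dataclass
class ScaledMetaProfile:
    """Fixed-bin-count body profile with fixed-width flanks, input-normalized."""

    body: np.ndarray  # length = body_bins
    flank5: np.ndarray  # upstream of the start, left-to-right
    flank3: np.ndarray  # downstream of the end, left-to-right
    n_regions: int
    normalization: str = "input-ratio"


def _quartile_sizes(n: int) -> list[int]:
    base, extra = divmod(n, 4)
    return [base + (1 if i < extra else 0) for i in range(4)]


def rank_enhancers(
    enhancers: list[GenomicInterval],
    ranking_track: CoverageTrack,
    ids: list[str] | None = None,
    window: int = 1000,
) -> list[EnhancerRecord]:
    """Sort enhancers by mean signal within +/- ``window`` of their midpoint
    (descending; ties by id) and assign quartiles I (highest) .. IV."""
    if not enhancers:
        raise ValueError("empty enhancer list")
    if ids is None:
        ids = [f"enh{i + 1}" for i in range(len(enhancers))]
    scored = []
    for enh_id, iv in zip(ids, enhancers):
        mid = iv.midpoint
        scored.append((enh_id, iv, ranking_track.mean_over(iv.chrom, mid - window, mid + window)))
    scored.sort(key=lambda t: (-t[2], t[0]))
    sizes = _quartile_sizes(len(scored))
    records = []
    i = 0
    for quart, size in zip(QUARTILES, sizes):
        for enh_id, iv, sig in scored[i : i + size]:
            records.append(EnhancerRecord(enh_id, iv, sig, quart))
        i += size
    return records


def quartile_midpoint_profiles(
    records: list[EnhancerRecord],
    query_track: CoverageTrack,
    flank: int = 2000,
    bin_width: int | None = None,
) -> dict[str, MetaProfile]:
    """One average midpoint profile per quartile (unstranded anchors)."""
    out = {}
    for quart in QUARTILES:
        members = [r for r in records if r.quartile == quart]
        if not members:
            continue
        refs = ReferencePointSet.from_midpoints(
            [r.interval for r in members], [r.enh_id for r in members]
        )
        out[quart] = average_profile(extract_matrix(query_track, refs, flank, bin_width))
    return out


def classify_positive_enhancers(
    enhancers: list[GenomicInterval],
    tracks: dict[str, CoverageTrack],
    factor: str,
    k: int = 2,
    seed: int = 0,
    ids: list[str] | None = None,
    flank: int = 1000,
    bin_width: int | None = None,
    threshold: float = 2.0,
) -> EnhancerClassification:
    """Partition enhancers by k-means over midpoint density matrices of the
    given tracks and call the factor-positive clusters."""
    if factor not in tracks:
        raise ValueError(f"factor track {factor!r} not among the supplied tracks")
    if ids is None:
        ids = [f"enh{i + 1}" for i in range(len(enhancers))]
    refs = ReferencePointSet.from_midpoints(enhancers, ids)
    matrices = []
    for name, track in tracks.items():
        m = extract_matrix(track, refs, flank, bin_width)
        m.track_id = name
        matrices.append(m)
    assignment = kmeans_cluster(matrices, k=k, seed=seed)
    positive_clusters = call_positive_clusters(assignment, factor, threshold)
    positive, negative = [], []
    for enh_id, label in zip(assignment.ids, assignment.labels):
        (positive if label in positive_clusters else negative).append(enh_id)
    return EnhancerClassification(positive, negative, assignment)


def _body_bin_edges(start: int, end: int, n_bins: int) -> np.ndarray:
    """Split [start, end) into n_bins contiguous sub-intervals; the remainder
    bp go to the leftmost bins."""
    length = end - start
    base, extra = divmod(length, n_bins)
    widths = np.full(n_bins, base, dtype=int)
    widths[:extra] += 1
    return start + np.concatenate(([0], np.cumsum(widths)))


def scaled_superenhancer_profile(
    super_enhancers: list[GenomicInterval],
    factor_track: CoverageTrack,
    input_track: CoverageTrack,
    body_bins: int = 80,
    flank: int = 4000,
    flank_bin: int = 50,
    mode: str = "average-then-ratio",
) -> ScaledMetaProfile:
    """Length-normalized meta-profile over super-enhancer bodies and flanks.

    Per region the body is split into ``body_bins`` equal sub-intervals and
    per-bp mean factor and input densities (per million mapped reads) are
    computed per bin; the meta value is the across-region mean factor density
    divided by the across-region mean input density (``average-then-ratio``,
    default) or the across-region mean of per-region ratios
    (``ratio-then-average``).  Flank bins falling outside the chromosome are
    excluded from the averages.  Where both factor and input are zero the
    ratio is reported as 1 (no evidence either way); factor signal over a
    zero input is reported as +inf.
    """
    if not super_enhancers:
        raise ValueError("empty super-enhancer list")
    for iv in super_enhancers:
        if iv.length < body_bins:
            raise ValueError(
                f"super-enhancer {iv.chrom}:{iv.start}-{iv.end} shorter than {body_bins} bp"
            )
    if mode not in ("average-then-ratio", "ratio-then-average"):
        raise ValueError(f"unknown mode {mode!r}")

    def cpm(track: CoverageTrack) -> CoverageTrack:
        if track.normalization == "raw" and track.total_reads > 0:
            return normalize_track(track, "per-million")
        return track

    fac, inp = cpm(factor_track), cpm(input_track)
    n_flank_bins = flank // flank_bin
    shape = {"body": body_bins, "flank5": n_flank_bins, "flank3": n_flank_bins}
    num = {k: np.zeros(v) for k, v in shape.items()}
    den = {k: np.zeros(v) for k, v in shape.items()}
    cnt = {k: np.zeros(v) for k, v in shape.items()}

    def accumulate(key: str, idx: int, chrom: str, a: int, b: int, size: int) -> None:
        a2, b2 = max(0, a), min(b, size)
        if b2 <= a2:
            return
        f = fac.mean_over(chrom, a2, b2)
        g = inp.mean_over(chrom, a2, b2)
        if mode == "average-then-ratio":
            num[key][idx] += f
            den[key][idx] += g
        else:
            num[key][idx] += _safe_ratio(f, g)
            den[key][idx] += 1.0
        cnt[key][idx] += 1.0

    for iv in super_enhancers:
        size = fac.chrom_sizes[iv.chrom]
        edges = _body_bin_edges(iv.start, iv.end, body_bins)
        for b in range(body_bins):
            accumulate("body", b, iv.chrom, int(edges[b]), int(edges[b + 1]), size)
        for b in range(n_flank_bins):
            accumulate(
                "flank5", b, iv.chrom,
                iv.start - flank + b * flank_bin, iv.start - flank + (b + 1) * flank_bin, size,
            )
            accumulate(
                "flank3", b, iv.chrom,
                iv.end + b * flank_bin, iv.end + (b + 1) * flank_bin, size,
            )

    out = {}
    for key in shape:
        with np.errstate(invalid="ignore", divide="ignore"):
            if mode == "average-then-ratio":
                vals = np.array(
                    [_safe_ratio(n, d) for n, d in zip(num[key], den[key])]
                )
            else:
                vals = np.where(den[key] > 0, num[key] / np.maximum(den[key], 1), np.nan)
        vals = np.where(cnt[key] > 0, vals, np.nan)
        out[key] = vals
    return ScaledMetaProfile(out["body"], out["flank5"], out["flank3"], len(super_enhancers))


def _safe_ratio(f: float, g: float) -> float:
    """f/g with the 0/0 convention of 'no evidence' = 1."""
    if g > 0:
        return f / g
    return 1.0 if f == 0 else np.inf
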