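"""k-means partitioning of multi-track density matrices and co-occupancy.

Rows of each matrix are normalized (per-row division by the row mean plus a
pseudocount, which removes amplitude and keeps shape), the matrices are
concatenated column-wise over their shared anchors, and Lloyd's algorithm
with k-means++ initialization is run at a fixed seed.  Cluster semantics are
read off the per-cluster mean profiles of the *unnormalized* matrices, never
off label order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .genome_io import PeakSet
from .matrix import DensityMatrix


@dataclass
class ClusterAssignment:
    ids: list[str]
    k: int
    labels: np.ndarray  # values in 1..k, one per anchor
    seed: int
    # per track: (k, n_offsets) mean profile of the raw matrix per cluster
    profiles: dict[str, np.ndarray]
    offsets: dict[str, np.ndarray]
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sizes is None:
            self.sizes = np.array([(self.labels == c).sum() for c in range(1, self.k + 1)])
        if len(self.labels) != len(self.ids):
            raise ValueError("one label per anchor required")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")

    def members(self, cluster: int) -> list[str]:
        return [i for i, lab in zip(self.ids, self.labels) if lab == cluster]


@dataclass
class CooccupancyResult:
    reference: str
    query: str
    n_reference: int
    n_cobound: int
    mode: str  # "cluster" or "overlap"

    @property
    def fraction(self) -> float:
        """Per-cent of reference sites co-bound by the query factor."""
        if self.n_reference == 0:
            return 0.0
        return 100.0 * self.n_cobound / self.n_reference


def normalize_rows(values: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Divide each row by (row mean + pseudocount)."""
    means = values.mean(axis=1, keepdims=True)
    return values / (means + pseudocount)


def kmeans_cluster(
    matrices: list[DensityMatrix],
    k: int,
    seed: int = 0,
    row_normalization: str = "mean",
    pseudocount: float = 1.0,
    max_iter: int = 300,
    tol: float = 1e-4,
    n_init: int = 10,
) -> ClusterAssignment:
    """Cluster anchors on their concatenated multi-track density rows.

    All matrices must share the same anchor ids in the same order.  The
    assignment is deterministic given the seed; labels are renumbered 1..k by
    decreasing cluster size so equal inputs always yield equal labels.
    """
    if not matrices:
        raise ValueError("at least one matrix required")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if m.ids != ids:
            raise ValueError("matrices must share identical anchor ids and order")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} anchors")

    if row_normalization == "mean":
        blocks = [normalize_rows(m.values, pseudocount) for m in matrices]
    elif row_normalization in (None, "none"):
        blocks = [m.values for m in matrices]
    else:
        raise ValueError(f"unknown row_normalization {row_normalization!r}")
    X = np.hstack(blocks)
    if not X.any():
        raise ValueError("all-zero matrix cannot be clustered")

    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, random_state=seed,
        algorithm="lloyd", max_iter=max_iter, tol=tol,
    ).fit(X)
    raw = km.labels_

    # stable relabel: descending cluster size, ties by first occurrence
    order = sorted(
        range(k),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c)) if (raw == c).any() else len(raw)),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw])

    profiles = {}
    offsets = {}
    for m in matrices:
        prof = np.zeros((k, m.values.shape[1]))
        for c in range(1, k + 1):
            sel = labels == c
            if sel.any():
                prof[c - 1] = m.values[sel].mean(axis=0)
        key = m.track_id or f"track{len(profiles) + 1}"
        profiles[key] = prof
        offsets[key] = m.offsets
    return ClusterAssignment(list(ids), k, labels, seed, profiles, offsets)


def call_positive_clusters(
    assignment: ClusterAssignment,
    track_id: str,
    threshold: float = 2.0,
    central_bp: int = 100,
    flank_fraction: float = 0.25,
) -> set[int]:
    """Clusters whose mean central density clears the background.

    The background is the across-cluster median of each cluster's mean flank
    density (the outermost ``flank_fraction`` of columns on each side); a
    cluster is positive for the track when its mean density within
    +/- ``central_bp`` of the anchor is >= ``threshold`` x that background.
    """
    prof = assignment.profiles[track_id]
    offs = assignment.offsets[track_id]
    central = np.abs(offs) <= central_bp
    if not central.any():
        central = np.abs(offs) == np.abs(offs).min()
    n_edge = max(1, int(len(offs) * flank_fraction / 2))
    flank = np.zeros(len(offs), dtype=bool)
    flank[:n_edge] = flank[-n_edge:] = True

    centrals = prof[:, central].mean(axis=1)
    background = float(np.median(prof[:, flank].mean(axis=1)))
    positive = set()
    for c in range(assignment.k):
        val = centrals[c]
        if val <= 0:
            continue
        if background > 0:
            if val >= threshold * background:
                positive.add(c + 1)
        else:
            positive.add(c + 1)
    return positive


def cooccupancy_fraction(
    reference_peaks: PeakSet,
    assignment: ClusterAssignment | None = None,
    query_track_id: str | None = None,
    query_peaks: PeakSet | None = None,
    threshold: float = 2.0,
) -> CooccupancyResult:
    """Fraction of one factor's sites co-bound by another factor.

    Cluster mode (``assignment`` + ``query_track_id``): anchors falling in
    clusters called positive for the query track count as co-bound.  Overlap
    mode (``query_peaks``): a reference peak is co-bound when it overlaps a
    query peak by >= 1 bp.
    """
    n_ref = len(reference_peaks)
    if assignment is not None and query_track_id is not None:
        if len(assignment.ids) != n_ref:
            raise ValueError("assignment must cover exactly the reference peaks")
        positive = call_positive_clusters(assignment, query_track_id, threshold)
        n_co = int(np.isin(assignment.labels, sorted(positive)).sum())
        return CooccupancyResult(
            reference_peaks.name, query_track_id, n_ref, n_co, mode="cluster"
        )
    if query_peaks is not None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for q in query_peaks:
            by_chrom.setdefault(q.interval.chrom, []).append(
                (q.interval.start, q.interval.end)
            )
        for c in by_chrom:
            by_chrom[c].sort()
        n_co = 0
        for p in reference_peaks:
            ivs = by_chrom.get(p.interval.chrom)
            if not ivs:
                continue
            if any(p.interval.start < e and s < p.interval.end for s, e in ivs):
                n_co += 1
        return CooccupancyResult(
            reference_peaks.name, query_peaks.name, n_ref, n_co, mode="overlap"
        )
    raise ValueError("provide either (assignment, query_track_id) or query_peaks")
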