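"""Assign called peaks to genomic feature classes and to genes.

A peak is placed in exactly one category, evaluated at its summit, with the
precedence promoter-TSS > 5'UTR > 3'UTR > exon > intron > TTS > intergenic.
Genes are called bound when a peak summit lies within a window of their TSS;
the strongest qualifying peak (highest tag density) is recorded per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneModel, PeakSet

CATEGORIES = ("promoter-TSS", "5'UTR", "3'UTR", "exon", "intron", "TTS", "intergenic")

# strand-aware windows, in bp relative to the anchor (negative = upstream)
PROMOTER_WINDOW = (-1000, 100)
TTS_WINDOW = (-100, 1000)


@dataclass
class FeatureAnnotation:
    peak_id: str
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None  # signed, strand-aware; negative = upstream


class _GeneIndex:
    """Sorted TSS/TTS arrays plus interval trees for exon/UTR/gene lookup."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self.tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        self.trees: dict[str, dict[str, IntervalTree]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            per_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom, gs in per_chrom.items():
            gs_sorted = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self.tss[chrom] = (np.array([g.tss for g in gs_sorted]), gs_sorted)
            trees = {kind: IntervalTree() for kind in ("utr5", "utr3", "exon", "gene", "tts")}
            for g in gs:
                trees["gene"][g.interval.start : g.interval.end] = g
                for ex in g.exons:
                    trees["exon"][ex.start : ex.end] = g
                for u in g.utr5:
                    trees["utr5"][u.start : u.end] = g
                for u in g.utr3:
                    trees["utr3"][u.start : u.end] = g
                lo, hi = _strand_window(g.tts, g.interval.strand, TTS_WINDOW)
                trees["tts"][lo : hi + 1] = g
            self.trees[chrom] = trees

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Nearest gene by |summit - TSS|, with its signed strand-aware distance."""
        if chrom not in self.tss:
            return None
        arr, gs = self.tss[chrom]
        i = int(np.searchsorted(arr, pos))
        best = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                d = abs(pos - arr[j])
                if best is None or d < best[1] or (d == best[1] and gs[j].gene_id < best[0].gene_id):
                    best = (gs[j], d)
        if best is None:
            return None
        g = best[0]
        signed = pos - g.tss if g.interval.strand == "+" else g.tss - pos
        return g, int(signed)


def _strand_window(anchor: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    lo, hi = window
    if strand == "+":
        return anchor + lo, anchor + hi
    return anchor - hi, anchor - lo


def annotate_features(
    peaks: PeakSet,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> list[FeatureAnnotation]:
    """One category per peak, evaluated at the summit with fixed precedence."""
    index = _GeneIndex(genes)
    out: list[FeatureAnnotation] = []
    for p in peaks:
        chrom, summit = p.interval.chrom, p.summit
        near = index.nearest_tss(chrom, summit)
        nearest_gene = near[0].gene_id if near else None
        distance = near[1] if near else None

        category = "intergenic"
        trees = index.trees.get(chrom)
        if trees is not None:
            # promoter: any gene whose strand-aware promoter window holds the summit
            is_promoter = False
            for g in (iv.data for iv in trees["gene"][summit - 2000 : summit + 2001]):
                lo, hi = _strand_window(g.tss, g.interval.strand, promoter_window)
                if lo <= summit <= hi:
                    is_promoter = True
                    break
            if not is_promoter and near is not None:
                lo, hi = promoter_window
                if lo <= near[1] <= hi:
                    is_promoter = True
            if is_promoter:
                category = "promoter-TSS"
            elif trees["utr5"][summit]:
                category = "5'UTR"
            elif trees["utr3"][summit]:
                category = "3'UTR"
            elif trees["exon"][summit]:
                category = "exon"
            elif trees["gene"][summit]:
                category = "intron"
            elif trees["tts"][summit]:
                category = "TTS"
        out.append(FeatureAnnotation(p.peak_id, category, nearest_gene, distance))
    return out


def feature_percentages(annotations: list[FeatureAnnotation]) -> pd.Series:
    """Per-category percentages over all peaks (sums to 100)."""
    counts = pd.Series([a.category for a in annotations]).value_counts()
    counts = counts.reindex(CATEGORIES, fill_value=0)
    return 100.0 * counts / max(1, len(annotations))


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: list[GeneModel],
    window: int = 1000,
) -> pd.DataFrame:
    """Gene-binding table: a gene is bound when >=1 peak summit lies within
    +/- ``window`` bp (inclusive) of its TSS; the best peak is the qualifying
    peak with the highest tag density (ties by peak id).

    Returns a DataFrame with columns gene_id, bound, peak_id, tag_density.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.summit)
    summits = {c: np.array([p.summit for p in ps]) for c, ps in by_chrom.items()}

    rows = []
    for g in genes:
        chrom, tss = g.interval.chrom, g.tss
        best = None
        if chrom in by_chrom:
            arr = summits[chrom]
            lo = int(np.searchsorted(arr, tss - window, side="left"))
            hi = int(np.searchsorted(arr, tss + window, side="right"))
            for p in by_chrom[chrom][lo:hi]:
                key = (p.tag_density, p.peak_id)
                if best is None or (key[0], key[1]) > (best.tag_density, best.peak_id):
                    best = p
        rows.append(
            {
                "gene_id": g.gene_id,
                "bound": best is not None,
                "peak_id": best.peak_id if best else "",
                "tag_density": best.tag_density if best else 0.0,
            }
        )
    return pd.DataFrame(rows)


def nearest_peak_density(
    genes: list[GeneModel],
    peaks: PeakSet,
    window: int = 2000,
    side: str = "both",
) -> pd.Series:
    """Tag density of the nearest peak summit within ``window`` bp of each TSS.

    ``side`` restricts the search: 'both' (default, +/- window), 'downstream'
    or 'upstream' (strand-aware).  Genes without a qualifying peak get 0.
    Ties at equal distance go to the higher tag density, then peak id.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if side not in ("both", "downstream", "upstream"):
        raise ValueError(f"unknown side {side!r}")
    by_chrom: dict[str, list] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.summit)
    summits = {c: np.array([p.summit for p in ps]) for c, ps in by_chrom.items()}
    out = {}
    for g in genes:
        tss, strand = g.tss, g.interval.strand
        best = None  # ((abs distance, -tag, id), tag)
        chrom = g.interval.chrom
        candidates: list = []
        if chrom in by_chrom:
            arr = summits[chrom]
            lo = int(np.searchsorted(arr, tss - window, side="left"))
            hi = int(np.searchsorted(arr, tss + window, side="right"))
            candidates = by_chrom[chrom][lo:hi]
        for p in candidates:
            signed = p.summit - tss if strand == "+" else tss - p.summit
            if side == "downstream" and signed < 0:
                continue
            if side == "upstream" and signed > 0:
                continue
            if abs(signed) > window:  # window is symmetric pre-filter; keep for safety
                continue
            key = (abs(signed), -p.tag_density, p.peak_id)
            if best is None or key < best[0]:
                best = (key, p.tag_density)
        out[g.gene_id] = best[1] if best else 0.0
    return pd.Series(out, name="tag_density")
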