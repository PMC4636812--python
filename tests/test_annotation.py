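"""Peak-to-feature categories, gene-binding calls and nearest-peak density."""

import numpy as np
import pytest

from chipmeta import (
    GeneModel,
    GenomicInterval,
    PeakRecord,
    PeakSet,
    annotate_features,
    assign_peaks_to_genes,
    feature_percentages,
    nearest_peak_density,
)

CHROM_LEN = 100_000


def gene(gid, start, end, strand="+", exons=None, utr5=None, utr3=None):
    return GeneModel(
        gid, gid, GenomicInterval("chr1", start, end, strand),
        exons or [], utr5 or [], utr3 or [],
    )


def peak_at(summit, pid="p1", t=1.0):
    return PeakRecord(GenomicInterval("chr1", max(0, summit - 100), summit + 100), summit, t, pid)


@pytest.fixture
def gene_set():
    # + gene with exon/intron/UTR structure, and a distant - gene
    ex = [
        GenomicInterval("chr1", 10_000, 10_400, "+"),
        GenomicInterval("chr1", 12_000, 12_500, "+"),
        GenomicInterval("chr1", 14_500, 15_000, "+"),
    ]
    g1 = gene(
        "g1", 10_000, 15_000, "+", exons=ex,
        utr5=[GenomicInterval("chr1", 10_000, 10_200, "+")],
        utr3=[GenomicInterval("chr1", 14_800, 15_000, "+")],
    )
    g2 = gene("g2", 60_000, 70_000, "-")
    return [g1, g2]


class TestAnnotateFeatures:
    @pytest.mark.parametrize(
        "summit,expected",
        [
            (10_050, "promoter-TSS"),  # 50 bp downstream of the + TSS
            (9_500, "promoter-TSS"),  # 500 bp upstream
            (10_150, "5'UTR"),  # past the +100 promoter edge, inside the 5'UTR
            (10_300, "exon"),
            (12_100, "exon"),
            (13_000, "intron"),
            (14_900, "3'UTR"),
            (15_500, "TTS"),
            (40_000, "intergenic"),
            (69_980, "promoter-TSS"),  # 19 bp downstream of the - TSS (69999)
            (59_500, "TTS"),  # 500 bp downstream of the - gene 3' end
        ],
    )
    def test_category_precedence_at_summit(self, gene_set, summit, expected):
        peaks = PeakSet("f", [peak_at(summit)])
        (a,) = annotate_features(peaks, gene_set)
        assert a.category == expected

    def test_no_genes_all_intergenic(self):
        peaks = PeakSet("f", [peak_at(500), peak_at(5_000, "p2")])
        annos = annotate_features(peaks, [])
        assert all(a.category == "intergenic" for a in annos)

    def test_signed_distance_strand_aware(self, gene_set):
        (a,) = annotate_features(PeakSet("f", [peak_at(9_500)]), gene_set)
        assert a.nearest_gene == "g1" and a.distance_to_tss == -500
        (a,) = annotate_features(PeakSet("f", [peak_at(69_500)]), gene_set)
        assert a.nearest_gene == "g2" and a.distance_to_tss == 499

    def test_percentages_sum_to_100(self, gene_set):
        rng = np.random.default_rng(0)
        peaks = PeakSet(
            "f", [peak_at(int(s), f"p{i}") for i, s in enumerate(rng.integers(200, 99_000, 60))]
        )
        pct = feature_percentages(annotate_features(peaks, gene_set))
        assert pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_mirror_genome_leaves_categories_unchanged(self, gene_set):
        """Reflecting all coordinates and flipping strands is a symmetry of
        the category rules."""
        rng = np.random.default_rng(1)
        summits = [int(s) for s in rng.integers(200, 99_000, 80)]
        peaks = PeakSet("f", [peak_at(s, f"p{i}") for i, s in enumerate(summits)])
        direct = [a.category for a in annotate_features(peaks, gene_set)]

        def flip_iv(iv):
            return GenomicInterval(
                iv.chrom, CHROM_LEN - iv.end, CHROM_LEN - iv.start,
                {"+": "-", "-": "+"}.get(iv.strand, "."),
            )

        mirrored_genes = [
            GeneModel(
                g.gene_id, g.name, flip_iv(g.interval),
                [flip_iv(e) for e in g.exons],
                [flip_iv(u) for u in g.utr5],
                [flip_iv(u) for u in g.utr3],
            )
            for g in gene_set
        ]
        mirrored_peaks = PeakSet(
            "f",
            [
                PeakRecord(flip_iv(p.interval), CHROM_LEN - 1 - p.summit, p.tag_density, p.peak_id)
                for p in peaks
            ],
        )
        mirrored = [a.category for a in annotate_features(mirrored_peaks, mirrored_genes)]
        assert direct == mirrored


class TestAssignPeaksToGenes:
    def test_summit_at_tss_bound(self, gene_set):
        table = assign_peaks_to_genes(PeakSet("f", [peak_at(10_000)]), gene_set)
        assert bool(table.set_index("gene_id").loc["g1", "bound"])

    def test_window_boundary_inclusive(self, gene_set):
        at_edge = assign_peaks_to_genes(PeakSet("f", [peak_at(11_000)]), gene_set, window=1000)
        past_edge = assign_peaks_to_genes(PeakSet("f", [peak_at(11_001)]), gene_set, window=1000)
        assert bool(at_edge.set_index("gene_id").loc["g1", "bound"])
        assert not bool(past_edge.set_index("gene_id").loc["g1", "bound"])

    def test_best_peak_is_highest_tag_density(self, gene_set):
        peaks = PeakSet("f", [peak_at(10_100, "weak", 5.0), peak_at(9_900, "strong", 50.0)])
        row = assign_peaks_to_genes(peaks, gene_set).set_index("gene_id").loc["g1"]
        assert row["peak_id"] == "strong" and row["tag_density"] == 50.0

    def test_monotone_in_window(self, gene_set):
        rng = np.random.default_rng(2)
        peaks = PeakSet(
            "f", [peak_at(int(s), f"p{i}") for i, s in enumerate(rng.integers(200, 99_000, 50))]
        )
        bound = {}
        for w in (250, 1000, 4000):
            t = assign_peaks_to_genes(peaks, gene_set, window=w)
            bound[w] = set(t[t["bound"]]["gene_id"])
        assert bound[250] <= bound[1000] <= bound[4000]


class TestNearestPeakDensity:
    def test_nearest_not_strongest(self, gene_set):
        peaks = PeakSet("f", [peak_at(10_100, "near", 50.0), peak_at(10_900, "far", 500.0)])
        d = nearest_peak_density(gene_set, peaks, window=2000)
        assert d["g1"] == 50.0

    def test_no_peak_within_window_gives_zero(self, gene_set):
        peaks = PeakSet("f", [peak_at(40_000, "p", 9.0)])
        d = nearest_peak_density(gene_set, peaks, window=2000)
        assert d["g1"] == 0.0 and d["g2"] == 0.0

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(3)
        genes = [
            gene(f"g{i}", int(s), int(s) + 500, "+" if i % 2 else "-")
            for i, s in enumerate(sorted(rng.choice(CHROM_LEN - 600, 30, replace=False)))
        ]
        peaks = PeakSet(
            "f",
            [
                peak_at(int(s), f"p{i}", float(t))
                for i, (s, t) in enumerate(
                    zip(rng.integers(200, 99_000, 40), rng.uniform(1, 100, 40))
                )
            ],
        )
        got = nearest_peak_density(genes, peaks, window=2000)
        for g in genes:
            cands = [
                (abs(p.summit - g.tss), -p.tag_density, p.peak_id, p.tag_density)
                for p in peaks
                if abs(p.summit - g.tss) <= 2000
            ]
            expected = min(cands)[3] if cands else 0.0
            assert got[g.gene_id] == expected

    def test_downstream_only_mode(self, gene_set):
        # peak upstream of the + TSS must be ignored in downstream mode
        peaks = PeakSet("f", [peak_at(9_800, "up", 7.0)])
        assert nearest_peak_density(gene_set, peaks, window=2000, side="downstream")["g1"] == 0.0
        assert nearest_peak_density(gene_set, peaks, window=2000, side="both")["g1"] == 7.0
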