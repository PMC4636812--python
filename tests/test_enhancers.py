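"""Enhancer quartiles, factor-positive classification and SE meta-profiles."""

import numpy as np
import pytest

from chipmeta import (
    ChromSizes,
    GenomicInterval,
    average_profile,
    classify_positive_enhancers,
    extract_matrix,
    quartile_midpoint_profiles,
    rank_enhancers,
    scaled_superenhancer_profile,
)
from chipmeta.matrix import ReferencePointSet

from conftest import make_track

SIZES = ChromSizes({"chr1": 400_000})


def enhancers_every(step=10_000, n=8, width=1_000, start=20_000):
    return [
        GenomicInterval("chr1", start + i * step, start + i * step + width) for i in range(n)
    ]


def track_with_signals(enhs, heights, width=500):
    t = make_track(SIZES, bin_width=25, track_id="sig")
    v = t.values["chr1"]
    for iv, h in zip(enhs, heights):
        mid = iv.midpoint
        lo, hi = (mid - width) // 25, (mid + width) // 25
        v[lo:hi] += h
    return t


class TestRankEnhancers:
    def test_quartiles_of_eight(self):
        enhs = enhancers_every()
        t = track_with_signals(enhs, [8, 7, 6, 5, 4, 3, 2, 1])
        recs = rank_enhancers(enhs, t)
        assert [r.quartile for r in recs] == ["I", "I", "II", "II", "III", "III", "IV", "IV"]
        assert recs[0].rank_signal > recs[-1].rank_signal

    def test_all_equal_signals_id_tie_break(self):
        enhs = enhancers_every()
        t = track_with_signals(enhs, [3] * 8)
        recs = rank_enhancers(enhs, t)
        assert [r.enh_id for r in recs] == sorted(r.enh_id for r in recs)

    def test_planted_strata_recovered(self):
        rng = np.random.default_rng(0)
        enhs = enhancers_every(n=40, step=8_000)
        strata = np.repeat([20.0, 10.0, 4.0, 1.0], 10)
        heights = strata + rng.uniform(-0.3, 0.3, 40)
        t = track_with_signals(enhs, heights)
        recs = rank_enhancers(enhs, t, ids=[f"e{i:02d}" for i in range(40)])
        for rec in recs:
            idx = int(rec.enh_id[1:])
            expected = ["I", "II", "III", "IV"][idx // 10]
            assert rec.quartile == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rank_enhancers([], make_track(SIZES))

    def test_partition_laws(self):
        enhs = enhancers_every(n=11, step=8_000)
        t = track_with_signals(enhs, range(11, 0, -1))
        recs = rank_enhancers(enhs, t)
        counts = {q: sum(r.quartile == q for r in recs) for q in "I II III IV".split()}
        assert sorted(counts.values()) == [2, 3, 3, 3]
        assert len({r.enh_id for r in recs}) == 11


class TestQuartileProfiles:
    def test_profiles_ordered_when_query_is_ranking_track(self):
        enhs = enhancers_every(n=16, step=8_000)
        t = track_with_signals(enhs, np.linspace(16, 1, 16))
        recs = rank_enhancers(enhs, t)
        profiles = quartile_midpoint_profiles(recs, t, flank=1000)
        centres = {q: p.values[len(p.values) // 2] for q, p in profiles.items()}
        assert centres["I"] > centres["II"] > centres["III"] > centres["IV"]

    def test_single_quartile_equals_plain_average(self):
        enhs = enhancers_every(n=8)
        t = track_with_signals(enhs, range(8, 0, -1))
        recs = rank_enhancers(enhs, t)
        profiles = quartile_midpoint_profiles(recs, t, flank=1000)
        members = [r for r in recs if r.quartile == "I"]
        refs = ReferencePointSet.from_midpoints(
            [r.interval for r in members], [r.enh_id for r in members]
        )
        direct = average_profile(extract_matrix(t, refs, 1000))
        np.testing.assert_array_equal(profiles["I"].values, direct.values)


class TestClassifyPositive:
    def test_zero_factor_track_fraction_zero(self):
        enhs = enhancers_every(n=12, step=8_000)
        mark = track_with_signals(enhs, [5] * 12)
        factor = make_track(SIZES, track_id="factor")
        res = classify_positive_enhancers(
            enhs, {"factor": factor, "mark": mark}, factor="factor", k=2, seed=0
        )
        assert res.fraction == 0.0 and len(res.positive_ids) == 0

    def test_partition_positive_union_negative(self):
        rng = np.random.default_rng(1)
        enhs = enhancers_every(n=20, step=8_000)
        factor = track_with_signals(enhs, rng.uniform(0, 10, 20))
        res = classify_positive_enhancers(enhs, {"factor": factor}, factor="factor", k=2, seed=0)
        assert res.n_total == 20
        assert set(res.positive_ids).isdisjoint(res.negative_ids)
        assert len(res.positive_ids) + len(res.negative_ids) == 20

    def test_planted_positive_fraction_recovered(self):
        rng = np.random.default_rng(2)
        enhs = enhancers_every(n=40, step=8_000)
        flags = np.zeros(40, dtype=bool)
        flags[rng.choice(40, 10, replace=False)] = True  # 25 % positive
        heights = np.where(flags, 10.0, 0.0) + rng.uniform(0, 0.3, 40)
        base = track_with_signals(enhs, heights)
        base.values["chr1"] += 1.0  # uniform background
        res = classify_positive_enhancers(enhs, {"factor": base}, factor="factor", k=2, seed=0)
        assert res.fraction == pytest.approx(25.0, abs=3.0)
        planted = {f"enh{i + 1}" for i in np.flatnonzero(flags)}
        assert set(res.positive_ids) == planted


class TestScaledSuperEnhancerProfile:
    def regions(self):
        return [
            GenomicInterval("chr1", 50_000, 62_000),
            GenomicInterval("chr1", 100_000, 105_500),
            GenomicInterval("chr1", 200_000, 228_123),
        ]

    def test_factor_equals_input_flat_ones(self):
        t = make_track(SIZES, fill=4.0, total_reads=1000)
        prof = scaled_superenhancer_profile(self.regions(), t, t)
        np.testing.assert_array_equal(prof.body, 1.0)
        np.testing.assert_array_equal(prof.flank5, 1.0)
        np.testing.assert_array_equal(prof.flank3, 1.0)
        assert len(prof.body) == 80 and len(prof.flank5) == 80

    def test_constant_tracks_ratio(self):
        fac = make_track(SIZES, fill=6.0, total_reads=0)
        inp = make_track(SIZES, fill=2.0, total_reads=0)
        prof = scaled_superenhancer_profile(self.regions(), fac, inp)
        np.testing.assert_allclose(prof.body, 3.0)
        np.testing.assert_allclose(prof.flank3, 3.0)

    def test_enrichment_inside_bodies_only(self):
        fac = make_track(SIZES, fill=2.0, total_reads=0)
        inp = make_track(SIZES, fill=2.0, total_reads=0)
        for iv in self.regions():
            fac.values["chr1"][iv.start // 25 : iv.end // 25] = 6.0
        prof = scaled_superenhancer_profile(self.regions(), fac, inp)
        assert prof.body.mean() == pytest.approx(3.0, rel=0.02)
        assert prof.flank5.mean() == pytest.approx(1.0, rel=0.05)

    def test_scaling_invariance(self):
        """Doubling a region's length with proportionally stretched signal
        leaves the body meta-profile unchanged."""
        sizes = ChromSizes({"chr1": 1_000_000})
        n_bins = 160
        base = np.sin(np.linspace(0, np.pi, n_bins)) + 2.0
        t1 = make_track(sizes, bin_width=25)
        t2 = make_track(sizes, bin_width=25)
        start = 100_000
        length = n_bins * 25
        t1.values["chr1"][start // 25 : start // 25 + n_bins] = base
        t2.values["chr1"][start // 25 : start // 25 + 2 * n_bins] = np.repeat(base, 2)
        inp1 = make_track(sizes, fill=1.0)
        r1 = [GenomicInterval("chr1", start, start + length)]
        r2 = [GenomicInterval("chr1", start, start + 2 * length)]
        p1 = scaled_superenhancer_profile(r1, t1, inp1)
        p2 = scaled_superenhancer_profile(r2, t2, inp1)
        np.testing.assert_allclose(p1.body, p2.body, rtol=1e-12)

    def test_short_region_rejected_by_name(self):
        t = make_track(SIZES, fill=1.0)
        with pytest.raises(ValueError, match="chr1:100-150"):
            scaled_superenhancer_profile([GenomicInterval("chr1", 100, 150)], t, t)

    def test_ratio_then_average_mode_on_constants(self):
        fac = make_track(SIZES, fill=6.0)
        inp = make_track(SIZES, fill=2.0)
        prof = scaled_superenhancer_profile(self.regions(), fac, inp, mode="ratio-then-average")
        np.testing.assert_allclose(prof.body, 3.0)
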