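"""Canonical simulation scenarios exercising the whole pipeline.

Each scenario fixes the study conditions — genome size, site counts,
enrichment over background, planted effect sizes — and runs the relevant
analysis end to end, returning both the planted truth and the recovered
estimate.  They are used by the validation suite and the example scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import nearest_peak_density
from .cluster import cooccupancy_fraction, kmeans_cluster
from .enhancers import classify_positive_enhancers, scaled_superenhancer_profile
from .expression import group_density_summary, rank_expression_quintiles
from .matrix import ReferencePointSet, average_profile, extract_matrix, profile_peak_offset
from .simulate import (
    FactorSpec,
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_reads,
    true_peak_set,
)
from .track import build_track, normalize_track


def _cpm_tracks(config, sim, reads, names):
    return {
        name: normalize_track(
            build_track(reads[name], sim.chrom_sizes, track_id=name), "per-million"
        )
        for name in names
    }


# ---------------------------------------------------------------------------
# TSS offset + co-binding (two factors, 2,000 sites, ~10x enrichment)
# ---------------------------------------------------------------------------

@dataclass
class TssScenarioResult:
    peak_offset_bp: int
    planted_offset_bp: float
    cobind_cluster_pct: float
    cobind_overlap_pct: float
    planted_cobind_pct: float
    n_reference_sites: int


def tss_cobinding_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chr1": 20_000_000},
        n_genes=4_000,
        gene_length=(1_500, 3_000),
        min_gap=500,
        n_enhancers=400,
        n_super_enhancers=20,
        factors=[
            FactorSpec("A", frac_genes_bound=0.5, tss_offset_mean=200.0,
                       tss_offset_sd=50.0, reads_per_site=50.0, background_reads=200_000),
            FactorSpec("B", frac_genes_bound=0.5, tss_offset_mean=200.0,
                       tss_offset_sd=50.0, reads_per_site=50.0, background_reads=200_000),
        ],
        co_binding={("A", "B"): 0.6},
    )


def run_tss_cobinding(seed: int) -> TssScenarioResult:
    """Recover the planted +200 bp TSS offset and the planted 60 % co-binding
    between two factors, at 2,000 reference sites."""
    config = tss_cobinding_config(seed)
    sim = simulate_annotation(config)
    reads = simulate_reads(config, sim)
    tracks = _cpm_tracks(config, sim, reads, ["A", "B"])

    profile = average_profile(
        extract_matrix(tracks["A"], ReferencePointSet.from_tss(sim.genes), flank=1000)
    )
    offset = profile_peak_offset(profile)

    ref_peaks = true_peak_set(sim, "A")
    refs = ReferencePointSet.from_peak_summits(ref_peaks)
    matrices = [extract_matrix(tracks[f], refs, flank=1000) for f in ("A", "B")]
    assignment = kmeans_cluster(matrices, k=2, seed=seed)
    cluster_res = cooccupancy_fraction(ref_peaks, assignment=assignment, query_track_id="B")
    overlap_res = cooccupancy_fraction(ref_peaks, query_peaks=true_peak_set(sim, "B"))

    bound_a = sim.truth.bound_genes("A")
    bound_b = sim.truth.bound_genes("B")
    planted = 100.0 * len(bound_a & bound_b) / len(bound_a)
    return TssScenarioResult(
        peak_offset_bp=offset,
        planted_offset_bp=config.factors[0].tss_offset_mean,
        cobind_cluster_pct=cluster_res.fraction,
        cobind_overlap_pct=overlap_res.fraction,
        planted_cobind_pct=planted,
        n_reference_sites=len(ref_peaks),
    )


# ---------------------------------------------------------------------------
# enhancer positivity (2,000 enhancers, 25 % factor-positive)
# ---------------------------------------------------------------------------

@dataclass
class EnhancerScenarioResult:
    fraction_pct: float
    planted_pct: float
    n_enhancers: int
    n_correct: int


def enhancer_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chr1": 12_000_000},
        n_genes=100,
        gene_length=(1_000, 2_000),
        n_enhancers=2_000,
        enhancer_length=(600, 1_200),
        n_super_enhancers=10,
        se_length=(5_000, 10_000),
        factors=[
            FactorSpec("A", frac_genes_bound=0.1, reads_per_site=50.0,
                       background_reads=120_000, frac_enhancers_bound=0.25),
            FactorSpec("mark", frac_genes_bound=0.1, reads_per_site=50.0,
                       background_reads=120_000, frac_enhancers_bound=1.0),
        ],
    )


def run_enhancer_classification(seed: int) -> EnhancerScenarioResult:
    """Recover the planted fraction of factor-positive enhancers by k-means
    over midpoint density matrices of the factor and a pan-enhancer mark."""
    config = enhancer_config(seed)
    sim = simulate_annotation(config)
    reads = simulate_reads(config, sim)
    tracks = _cpm_tracks(config, sim, reads, ["A", "mark"])
    res = classify_positive_enhancers(
        sim.enhancers, tracks, factor="A", k=2, seed=seed, ids=sim.enhancer_ids
    )
    planted = sim.truth.bound_enhancers("A")
    n_correct = len(planted & set(res.positive_ids)) + (
        res.n_total - len(planted | set(res.positive_ids))
    )
    return EnhancerScenarioResult(
        fraction_pct=res.fraction,
        planted_pct=100.0 * len(planted) / config.n_enhancers,
        n_enhancers=config.n_enhancers,
        n_correct=n_correct,
    )


# ---------------------------------------------------------------------------
# super-enhancer scaled profile (3x planted body enrichment)
# ---------------------------------------------------------------------------

@dataclass
class SuperEnhancerScenarioResult:
    flatness_max_abs_dev: float  # factor==input self-ratio, exact check
    body_mean: float
    flank_mean: float
    planted_enrichment: float
    n_regions: int


def superenhancer_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chr1": 5_000_000},
        n_genes=50,
        gene_length=(1_000, 2_000),
        n_enhancers=50,
        n_super_enhancers=10,
        se_length=(5_000, 10_000),
        factors=[
            FactorSpec("A", frac_genes_bound=0.0, background_reads=100_000,
                       se_enrichment=3.0)
        ],
    )


def run_superenhancer_profile(seed: int) -> SuperEnhancerScenarioResult:
    """Self-ratio flatness plus recovery of a uniform 3x body enrichment."""
    config = superenhancer_config(seed)
    sim = simulate_annotation(config)
    reads = simulate_reads(config, sim)
    factor = build_track(reads["A"], sim.chrom_sizes, track_id="A")
    inp = build_track(reads["input"], sim.chrom_sizes, track_id="input")

    flat = scaled_superenhancer_profile(sim.super_enhancers, factor, factor)
    dev = max(
        float(np.nanmax(np.abs(seg - 1.0)))
        for seg in (flat.body, flat.flank5, flat.flank3)
    )
    prof = scaled_superenhancer_profile(sim.super_enhancers, factor, inp)
    flank = np.concatenate([prof.flank5, prof.flank3])
    return SuperEnhancerScenarioResult(
        flatness_max_abs_dev=dev,
        body_mean=float(np.nanmean(prof.body)),
        flank_mean=float(np.nanmean(flank)),
        planted_enrichment=config.factors[0].se_enrichment,
        n_regions=config.n_super_enhancers,
    )


# ---------------------------------------------------------------------------
# expression quintiles under planted density-expression coupling
# ---------------------------------------------------------------------------

@dataclass
class ExpressionScenarioResult:
    group_sizes: list[int]
    group_medians: list[float]
    monotone_decreasing: bool
    n_genes: int


def expression_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        chrom_sizes={"chr1": 12_000_000},
        n_genes=5_000,
        gene_length=(1_000, 2_000),
        min_gap=200,
        n_enhancers=0,
        n_super_enhancers=0,
        factors=[FactorSpec("A", frac_genes_bound=1.0, reads_per_site=50.0,
                            background_reads=0)],
        expression_coupling=0.5,
    )


def run_expression_coupling(seed: int) -> ExpressionScenarioResult:
    """Quintile medians of nearest-peak tag density under a planted positive
    occupancy-expression coupling."""
    config = expression_config(seed)
    sim = simulate_annotation(config)
    expr = simulate_expression(sim)
    peaks = true_peak_set(sim, "A")
    density = nearest_peak_density(sim.genes, peaks, window=2000)
    groups = rank_expression_quintiles(expr)
    summaries = group_density_summary(density, groups)
    medians = [s.median for s in summaries]
    monotone = all(a > b for a, b in zip(medians, medians[1:]))
    return ExpressionScenarioResult(
        group_sizes=groups.sizes,
        group_medians=medians,
        monotone_decreasing=monotone,
        n_genes=config.n_genes,
    )
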