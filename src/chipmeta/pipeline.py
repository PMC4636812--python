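"""Config-driven recipes reproducing each figure-level analysis.

Each recipe reads its inputs through genome_io, runs the corresponding
module functions, and writes numeric TSVs plus a ``manifest.json`` recording
every parameter and decision value actually used, so a run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import annotation as ann
from . import cluster as clu
from . import enhancers as enh
from . import expression as expr
from . import simulate as sim_mod
from .genome_io import (
    ChromSizes,
    read_bed,
    read_expression_table,
    read_gene_annotation,
    read_peaks_bed,
)
from .matrix import (
    ReferencePointSet,
    average_profile,
    extract_matrix,
    matrix_to_frame,
    profile_peak_offset,
)
from .track import build_track, normalize_track, read_wig

RECIPES = (
    "tss-heatmap",
    "tss-profile",
    "cooccupancy",
    "annotate",
    "expression",
    "enhancers",
    "superenhancer",
    "end-to-end-synthetic",
)


@dataclass
class PipelineConfig:
    recipe: str
    outdir: str
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; known: {', '.join(RECIPES)}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            recipe=raw["recipe"],
            outdir=raw.get("outdir", "chipmeta_out"),
            inputs=raw.get("inputs", {}) or {},
            params=raw.get("params", {}) or {},
            seed=int(raw.get("seed", 0)),
        )


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()


def _load_track(config: PipelineConfig, key: str, chrom_sizes: ChromSizes, used: dict):
    """A track input may be a wiggle file or a BED of aligned reads."""
    path = config.inputs[key]
    if path.endswith((".wig", ".wiggle")):
        return read_wig(path, chrom_sizes, track_id=key)
    reads = read_bed(path, chrom_sizes, as_reads=True)
    fragment = int(config.params.get("fragment_length", 200))
    bin_width = int(config.params.get("bin_width", 25))
    used.update(fragment_length=fragment, bin_width=bin_width, count_mode="overlap")
    return build_track(reads, chrom_sizes, fragment, bin_width, track_id=key)


def run_recipe(config: PipelineConfig) -> dict:
    """Execute a recipe; returns the manifest (also written to outdir)."""
    missing = [p for p in config.inputs.values() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
    os.makedirs(config.outdir, exist_ok=True)
    used: dict = {}
    outputs = _DISPATCH[config.recipe](config, used)
    manifest = {
        "recipe": config.recipe,
        "seed": config.seed,
        "inputs": dict(sorted(config.inputs.items())),
        "params_used": dict(sorted(used.items())),
        "outputs": sorted(outputs),
    }
    manifest["hash"] = manifest_hash(manifest)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# recipe bodies
# ---------------------------------------------------------------------------

def _out(config, name):
    return os.path.join(config.outdir, name)


def _tss_common(config: PipelineConfig, used: dict):
    chrom_sizes = ChromSizes.read(config.inputs["chrom_sizes"])
    genes = read_gene_annotation(config.inputs["genes"])
    track = _load_track(config, "track", chrom_sizes, used)
    if track.normalization == "raw" and track.total_reads > 0:
        track = normalize_track(track, "per-million")
        used["normalization"] = "per-million"
    flank = int(config.params.get("flank", 1000))
    bin_width = int(config.params.get("matrix_bin", track.bin_width))
    used.update(flank=flank, matrix_bin=bin_width)
    refs = ReferencePointSet.from_tss(genes)
    return extract_matrix(track, refs, flank, bin_width)


def _recipe_tss_profile(config, used):
    matrix = _tss_common(config, used)
    profile = average_profile(matrix)
    smoothing = int(config.params.get("smoothing_window", 3))
    used["smoothing_window"] = smoothing
    offset = profile_peak_offset(profile, smoothing)
    pd.DataFrame({"offset_bp": profile.offsets, "mean_density": profile.values}).to_csv(
        _out(config, "profile.tsv"), sep="\t", index=False
    )
    pd.DataFrame([{"n_anchors": profile.n_anchors, "peak_offset_bp": offset}]).to_csv(
        _out(config, "summary.tsv"), sep="\t", index=False
    )
    return ["profile.tsv", "summary.tsv"]


def _recipe_tss_heatmap(config, used):
    matrix = _tss_common(config, used)
    matrix_to_frame(matrix).to_csv(_out(config, "matrix.tsv"), sep="\t")
    return ["matrix.tsv"]


def _recipe_cooccupancy(config, used):
    ref = read_peaks_bed(config.inputs["reference_peaks"], name="reference")
    query = read_peaks_bed(config.inputs["query_peaks"], name="query")
    res = clu.cooccupancy_fraction(ref, query_peaks=query)
    used["mode"] = "overlap"
    pd.DataFrame(
        [
            {
                "reference": res.reference,
                "query": res.query,
                "n_reference": res.n_reference,
                "n_cobound": res.n_cobound,
                "fraction_pct": res.fraction,
                "mode": res.mode,
            }
        ]
    ).to_csv(_out(config, "cooccupancy.tsv"), sep="\t", index=False)
    return ["cooccupancy.tsv"]


def _recipe_annotate(config, used):
    peaks = read_peaks_bed(config.inputs["peaks"])
    genes = read_gene_annotation(config.inputs["genes"])
    annos = ann.annotate_features(peaks, genes)
    window = int(config.params.get("tss_window", 1000))
    used.update(tss_window=window, promoter_window=list(ann.PROMOTER_WINDOW))
    table = ann.assign_peaks_to_genes(peaks, genes, window)
    pd.DataFrame([a.__dict__ for a in annos]).to_csv(
        _out(config, "annotation.tsv"), sep="\t", index=False
    )
    ann.feature_percentages(annos).rename("percent").to_csv(_out(config, "categories.tsv"), sep="\t")
    table.to_csv(_out(config, "gene_binding.tsv"), sep="\t", index=False)
    return ["annotation.tsv", "categories.tsv", "gene_binding.tsv"]


def _recipe_expression(config, used):
    records = read_expression_table(config.inputs["expression"])
    peaks = read_peaks_bed(config.inputs["peaks"])
    genes = read_gene_annotation(config.inputs["genes"])
    window = int(config.params.get("density_window", 2000))
    side = config.params.get("density_side", "both")
    used.update(density_window=window, density_side=side, log2_pseudocount=expr.LOG2_PSEUDOCOUNT)
    groups = expr.rank_expression_quintiles(records)
    density = ann.nearest_peak_density(genes, peaks, window, side)
    summaries = expr.group_density_summary(density, groups)
    bound = set(ann.assign_peaks_to_genes(peaks, genes).query("bound")["gene_id"])
    comparison = expr.compare_bound_vs_all(records, bound) if bound else None
    expr.summaries_to_frame(summaries).to_csv(_out(config, "group_density.tsv"), sep="\t", index=False)
    groups.labels.rename("group").to_csv(_out(config, "expression_groups.tsv"), sep="\t")
    if comparison:
        pd.DataFrame([comparison.__dict__]).to_csv(
            _out(config, "bound_vs_all.tsv"), sep="\t", index=False
        )
    return ["group_density.tsv", "expression_groups.tsv"] + (
        ["bound_vs_all.tsv"] if comparison else []
    )


def _recipe_enhancers(config, used):
    chrom_sizes = ChromSizes.read(config.inputs["chrom_sizes"])
    regions = read_bed(config.inputs["enhancers"], chrom_sizes)
    rank_track = _load_track(config, "rank_track", chrom_sizes, used)
    factor_track = _load_track(config, "factor_track", chrom_sizes, used)
    k = int(config.params.get("k", 2))
    used.update(k=k, rank_window=1000, seed=config.seed)
    records = enh.rank_enhancers(regions, rank_track)
    profiles = enh.quartile_midpoint_profiles(records, factor_track)
    result = enh.classify_positive_enhancers(
        regions,
        {"factor": factor_track, "rank": rank_track},
        factor="factor",
        k=k,
        seed=config.seed,
    )
    pd.DataFrame(
        [
            {"enh_id": r.enh_id, "chrom": r.interval.chrom, "start": r.interval.start,
             "end": r.interval.end, "rank_signal": r.rank_signal, "quartile": r.quartile}
            for r in records
        ]
    ).to_csv(_out(config, "enhancer_quartiles.tsv"), sep="\t", index=False)
    prof_frames = []
    for quart, p in profiles.items():
        prof_frames.append(
            pd.DataFrame({"quartile": quart, "offset_bp": p.offsets, "mean_density": p.values})
        )
    pd.concat(prof_frames).to_csv(_out(config, "quartile_profiles.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"n_total": result.n_total, "n_positive": len(result.positive_ids),
          "fraction_pct": result.fraction}]
    ).to_csv(_out(config, "enhancer_classification.tsv"), sep="\t", index=False)
    return ["enhancer_quartiles.tsv", "quartile_profiles.tsv", "enhancer_classification.tsv"]


def _recipe_superenhancer(config, used):
    chrom_sizes = ChromSizes.read(config.inputs["chrom_sizes"])
    regions = read_bed(config.inputs["regions"], chrom_sizes)
    factor_track = _load_track(config, "factor_track", chrom_sizes, used)
    input_track = _load_track(config, "input_track", chrom_sizes, used)
    body_bins = int(config.params.get("body_bins", 80))
    flank = int(config.params.get("flank", 4000))
    flank_bin = int(config.params.get("flank_bin", 50))
    mode = config.params.get("ratio_mode", "average-then-ratio")
    used.update(body_bins=body_bins, flank=flank, flank_bin=flank_bin, ratio_mode=mode)
    profile = enh.scaled_superenhancer_profile(
        regions, factor_track, input_track, body_bins, flank, flank_bin, mode
    )
    rows = (
        [("flank5", i, v) for i, v in enumerate(profile.flank5)]
        + [("body", i, v) for i, v in enumerate(profile.body)]
        + [("flank3", i, v) for i, v in enumerate(profile.flank3)]
    )
    pd.DataFrame(rows, columns=["segment", "bin", "enrichment"]).to_csv(
        _out(config, "se_profile.tsv"), sep="\t", index=False
    )
    return ["se_profile.tsv"]


def _recipe_end_to_end(config, used):
    """Simulate a complete dataset and run every analysis stage on it."""
    sim_config = sim_mod.SimulationConfig(seed=config.seed, **config.params.get("simulation", {}))
    used["simulation"] = sim_config.__dict__.copy()
    sim = sim_mod.simulate_annotation(sim_config)
    reads = sim_mod.simulate_reads(sim_config, sim)
    expression = sim_mod.simulate_expression(sim)
    fixture_dir = os.path.join(config.outdir, "fixtures")
    sim_mod.write_dataset(sim, reads, expression, fixture_dir)

    tracks = {
        name: normalize_track(
            build_track(rs, sim.chrom_sizes, track_id=name), "per-million"
        )
        for name, rs in reads.items()
    }
    primary = sim.truth.primary_factor
    outputs = []

    refs = ReferencePointSet.from_tss(sim.genes)
    matrix = extract_matrix(tracks[primary], refs, flank=1000)
    profile = average_profile(matrix)
    offset = profile_peak_offset(profile)
    pd.DataFrame({"offset_bp": profile.offsets, "mean_density": profile.values}).to_csv(
        _out(config, "tss_profile.tsv"), sep="\t", index=False
    )
    outputs.append("tss_profile.tsv")

    peaks = sim_mod.true_peak_set(sim, primary)
    annos = ann.annotate_features(peaks, sim.genes)
    ann.feature_percentages(annos).rename("percent").to_csv(_out(config, "categories.tsv"), sep="\t")
    outputs.append("categories.tsv")

    groups = expr.rank_expression_quintiles(expression)
    density = ann.nearest_peak_density(sim.genes, peaks)
    expr.summaries_to_frame(expr.group_density_summary(density, groups)).to_csv(
        _out(config, "group_density.tsv"), sep="\t", index=False
    )
    outputs.append("group_density.tsv")

    se_profile = enh.scaled_superenhancer_profile(
        sim.super_enhancers, tracks[primary], tracks["input"]
    )
    pd.DataFrame(
        {"segment": ["body"] * len(se_profile.body), "bin": range(len(se_profile.body)),
         "enrichment": se_profile.body}
    ).to_csv(_out(config, "se_profile.tsv"), sep="\t", index=False)
    outputs.append("se_profile.tsv")

    pd.DataFrame([{"n_genes": len(sim.genes), "tss_peak_offset_bp": offset,
                   "n_peaks": len(peaks)}]).to_csv(
        _out(config, "summary.tsv"), sep="\t", index=False
    )
    outputs.append("summary.tsv")
    return outputs


_DISPATCH = {
    "tss-profile": _recipe_tss_profile,
    "tss-heatmap": _recipe_tss_heatmap,
    "cooccupancy": _recipe_cooccupancy,
    "annotate": _recipe_annotate,
    "expression": _recipe_expression,
    "enhancers": _recipe_enhancers,
    "superenhancer": _recipe_superenhancer,
    "end-to-end-synthetic": _recipe_end_to_end,
}
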