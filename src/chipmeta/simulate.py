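"""Synthetic genome, read-set and expression generator with ground truth.

The generator lays out a small genome (one 5-Mb chromosome by default) with
non-overlapping genes, enhancers and super-enhancers, plants factor binding
sites with a configurable strand-aware TSS offset (the downstream shift seen
for elongation-coupled factors), a configurable pairwise co-binding fraction
between factors, uniform-background input reads at matched depth, and FPKM
values rank-coupled to promoter binding strength.  Everything is a pure
function of the seed.

Read model: a bound site emits Poisson(reads_per_site x site strength)
reads whose 5' positions are Normal(site center, sd) with random strand, so
that after 200-bp extension the coverage summit sits at the planted center.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome_io import (
    ChromSizes,
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    PeakRecord,
    PeakSet,
    ReadRecord,
    write_bed,
    write_expression_table,
    write_gene_annotation_gtf,
)


@dataclass
class FactorSpec:
    """Binding behaviour of one simulated ChIP factor."""

    name: str
    frac_genes_bound: float = 0.3
    tss_offset_mean: float = 200.0  # bp downstream of the TSS, strand-aware
    tss_offset_sd: float = 50.0  # spread of read 5' ends around the site
    reads_per_site: float = 50.0
    background_reads: int = 50_000
    frac_enhancers_bound: float = 0.0
    se_enrichment: float = 1.0  # uniform fold over background inside SE bodies

    def __post_init__(self) -> None:
        for frac in (self.frac_genes_bound, self.frac_enhancers_bound):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"factor {self.name}: fractions must lie in [0, 1]")
        if self.se_enrichment < 1.0:
            raise ValueError(f"factor {self.name}: se_enrichment must be >= 1")


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 5_000_000})
    n_genes: int = 500
    gene_length: tuple[int, int] = (2_000, 8_000)
    min_gap: int = 500
    n_enhancers: int = 400
    enhancer_length: tuple[int, int] = (500, 1_500)
    n_super_enhancers: int = 20
    se_length: tuple[int, int] = (5_000, 30_000)
    factors: list[FactorSpec] = field(default_factory=lambda: [FactorSpec("factorA")])
    # symmetric pairwise co-binding: fraction of the first factor's bound
    # genes also bound by the second factor
    co_binding: dict = field(default_factory=dict)
    expression_coupling: float = 0.5  # Spearman target, binding strength vs FPKM
    expression_noise: float = 1.0
    read_length: int = 36

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        for (a, b), c in self.co_binding.items():
            if a not in names or b not in names:
                raise ValueError(f"co_binding names unknown factor in ({a}, {b})")
            if not 0.0 <= c <= 1.0:
                raise ValueError("co-binding fractions must lie in [0, 1]")
        if not 0.0 <= self.expression_coupling <= 1.0:
            raise ValueError("expression_coupling must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by factor name."""

    gene_ids: list[str]
    enhancer_ids: list[str]
    se_ids: list[str]
    gene_bound: dict[str, dict[str, bool]]
    gene_strength: dict[str, dict[str, float]]
    gene_site: dict[str, dict[str, int]]  # planted site center, bound genes only
    enhancer_bound: dict[str, dict[str, bool]]
    enhancer_strength: dict[str, dict[str, float]]
    se_enrichment: dict[str, dict[str, float]]
    primary_factor: str

    def bound_genes(self, factor: str) -> set[str]:
        return {g for g, b in self.gene_bound[factor].items() if b}

    def bound_enhancers(self, factor: str) -> set[str]:
        return {e for e, b in self.enhancer_bound[factor].items() if b}

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True, default=str)


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    chrom_sizes: ChromSizes
    genes: list[GeneModel]
    enhancer_ids: list[str]
    enhancers: list[GenomicInterval]
    se_ids: list[str]
    super_enhancers: list[GenomicInterval]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# annotation layout
# ---------------------------------------------------------------------------

def _layout_chrom(rng, length, features, min_gap):
    """Place features (list of (kind, idx, feat_len)) non-overlapping along one
    chromosome with random gaps; returns (kind, idx, start, end) tuples."""
    total = sum(f[2] for f in features)
    n = len(features)
    free = length - total - (n + 1) * min_gap
    if free < 0:
        raise ValueError(
            f"genome too small: need {total + (n + 1) * min_gap} bp, have {length}"
        )
    order = list(range(n))
    rng.shuffle(order)
    gaps = min_gap + rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    cursor = 0
    placed = []
    for slot, fi in enumerate(order):
        cursor += int(gaps[slot])
        kind, idx, flen = features[fi]
        placed.append((kind, idx, cursor, cursor + flen))
        cursor += flen
    return placed


def _make_exons(rng, chrom, start, end, strand):
    n_exons = int(rng.integers(2, 6))
    n_seg = 2 * n_exons - 1
    length = end - start
    if length < n_seg:
        return [GenomicInterval(chrom, start, end, strand)]
    seg = rng.multinomial(length - n_seg, np.full(n_seg, 1.0 / n_seg)) + 1
    edges = start + np.concatenate(([0], np.cumsum(seg)))
    return [
        GenomicInterval(chrom, int(edges[i]), int(edges[i + 1]), strand)
        for i in range(0, n_seg, 2)
    ]


def _sample_bound(rng, n_items: int, fraction: float) -> np.ndarray:
    n_bound = int(round(fraction * n_items))
    flags = np.zeros(n_items, dtype=bool)
    if n_bound:
        flags[rng.choice(n_items, size=n_bound, replace=False)] = True
    return flags


def simulate_annotation(config: SimulationConfig) -> SimulatedGenome:
    """Build the genome layout and plant all binding flags and strengths."""
    rng = np.random.default_rng([config.seed, 0])
    chrom_sizes = ChromSizes(dict(config.chrom_sizes))

    features = []
    features += [("gene", i, int(rng.integers(*config.gene_length))) for i in range(config.n_genes)]
    features += [
        ("enh", i, int(rng.integers(*config.enhancer_length))) for i in range(config.n_enhancers)
    ]
    features += [
        ("se", i, int(rng.integers(*config.se_length))) for i in range(config.n_super_enhancers)
    ]

    chroms = list(chrom_sizes.items())
    lengths = np.array([l for _, l in chroms], dtype=float)
    assigned = rng.choice(len(chroms), size=len(features), p=lengths / lengths.sum())
    genes_raw, enh_raw, se_raw = {}, {}, {}
    for ci, (chrom, length) in enumerate(chroms):
        mine = [features[j] for j in range(len(features)) if assigned[j] == ci]
        for kind, idx, start, end in _layout_chrom(rng, length, mine, config.min_gap):
            {"gene": genes_raw, "enh": enh_raw, "se": se_raw}[kind][idx] = (chrom, start, end)

    genes = []
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        chrom, start, end = genes_raw[i]
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:0{width}d}"
        genes.append(
            GeneModel(gid, gid, GenomicInterval(chrom, start, end, strand),
                      _make_exons(rng, chrom, start, end, strand))
        )
    enhancer_ids = [f"enh{i + 1}" for i in range(config.n_enhancers)]
    enhancers = [GenomicInterval(*enh_raw[i]) for i in range(config.n_enhancers)]
    se_ids = [f"se{i + 1}" for i in range(config.n_super_enhancers)]
    supers = [GenomicInterval(*se_raw[i]) for i in range(config.n_super_enhancers)]

    # --- plant binding -----------------------------------------------------
    gene_bound, gene_strength, gene_site = {}, {}, {}
    enh_bound, enh_strength, se_enr = {}, {}, {}
    ref_flags: np.ndarray | None = None
    ref_name = config.factors[0].name if config.factors else ""
    for fi, spec in enumerate(config.factors):
        n = config.n_genes
        pair = (ref_name, spec.name)
        if fi == 0 or pair not in config.co_binding:
            flags = _sample_bound(rng, n, spec.frac_genes_bound)
        else:
            c = config.co_binding[pair]
            n_i = int(round(spec.frac_genes_bound * n))
            n_co = min(int(round(c * int(ref_flags.sum()))), n_i)
            ref_idx = np.flatnonzero(ref_flags)
            other_idx = np.flatnonzero(~ref_flags)
            if n_i - n_co > len(other_idx):
                raise ValueError("co-binding constraint infeasible at these fractions")
            flags = np.zeros(n, dtype=bool)
            flags[rng.choice(ref_idx, size=n_co, replace=False)] = True
            if n_i - n_co:
                flags[rng.choice(other_idx, size=n_i - n_co, replace=False)] = True
        if fi == 0:
            ref_flags = flags
        strengths = np.where(flags, rng.lognormal(0.0, 0.5, n), 0.0)
        gene_bound[spec.name] = {g.gene_id: bool(b) for g, b in zip(genes, flags)}
        gene_strength[spec.name] = {g.gene_id: float(s) for g, s in zip(genes, strengths)}
        sites = {}
        for g, b in zip(genes, flags):
            if b:
                delta = int(round(spec.tss_offset_mean))
                sites[g.gene_id] = g.tss + (delta if g.interval.strand == "+" else -delta)
        gene_site[spec.name] = sites

        eflags = _sample_bound(rng, config.n_enhancers, spec.frac_enhancers_bound)
        estr = np.where(eflags, rng.lognormal(0.0, 0.5, config.n_enhancers), 0.0)
        enh_bound[spec.name] = {e: bool(b) for e, b in zip(enhancer_ids, eflags)}
        enh_strength[spec.name] = {e: float(s) for e, s in zip(enhancer_ids, estr)}
        se_enr[spec.name] = {s: float(spec.se_enrichment) for s in se_ids}

    truth = GroundTruth(
        gene_ids=[g.gene_id for g in genes],
        enhancer_ids=enhancer_ids,
        se_ids=se_ids,
        gene_bound=gene_bound,
        gene_strength=gene_strength,
        gene_site=gene_site,
        enhancer_bound=enh_bound,
        enhancer_strength=enh_strength,
        se_enrichment=se_enr,
        primary_factor=ref_name,
    )
    return SimulatedGenome(
        config, chrom_sizes, genes, enhancer_ids, enhancers, se_ids, supers, truth
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _uniform_positions(rng, chrom_sizes: ChromSizes, n: int):
    chroms = list(chrom_sizes.items())
    offsets = np.concatenate(([0], np.cumsum([l for _, l in chroms])))
    flat = rng.integers(0, offsets[-1], size=n)
    which = np.searchsorted(offsets, flat, side="right") - 1
    return [(chroms[w][0], int(p - offsets[w])) for w, p in zip(which, flat)]


def _make_read(chrom: str, p5: int, strand: str, read_len: int, size: int) -> ReadRecord | None:
    p5 = int(min(max(p5, 0), size - 1))
    if strand == "+":
        start, end = p5, min(p5 + read_len, size)
    else:
        start, end = max(0, p5 - read_len + 1), p5 + 1
    if end <= start:
        return None
    return ReadRecord(GenomicInterval(chrom, start, end, strand))


def simulate_reads(
    config: SimulationConfig, sim: SimulatedGenome
) -> dict[str, list[ReadRecord]]:
    """Emit per-factor read sets plus a background-only input at matched depth."""
    rng = np.random.default_rng([config.seed, 1])
    rl = config.read_length
    enh_by_id = dict(zip(sim.enhancer_ids, sim.enhancers))
    gene_chrom = {g.gene_id: g.interval.chrom for g in sim.genes}
    out: dict[str, list[ReadRecord]] = {}

    def emit(reads, chrom, center, n, sd):
        size = sim.chrom_sizes[chrom]
        p5 = np.rint(rng.normal(center, sd, n)).astype(int)
        strands = rng.random(n) < 0.5
        for p, plus in zip(p5, strands):
            r = _make_read(chrom, p, "+" if plus else "-", rl, size)
            if r is not None:
                reads.append(r)

    for spec in config.factors:
        reads: list[ReadRecord] = []
        truth = sim.truth
        for gid, center in truth.gene_site[spec.name].items():
            n = int(rng.poisson(spec.reads_per_site * truth.gene_strength[spec.name][gid]))
            emit(reads, gene_chrom[gid], center, n, spec.tss_offset_sd)
        for eid, bound in truth.enhancer_bound[spec.name].items():
            if not bound:
                continue
            iv = enh_by_id[eid]
            n = int(rng.poisson(spec.reads_per_site * truth.enhancer_strength[spec.name][eid]))
            emit(reads, iv.chrom, iv.midpoint, n, spec.tss_offset_sd)
        if spec.se_enrichment > 1.0:
            bg_density = spec.background_reads / sim.chrom_sizes.total
            for iv in sim.super_enhancers:
                n = int(rng.poisson((spec.se_enrichment - 1.0) * bg_density * iv.length))
                pos = rng.integers(iv.start, iv.end, size=n)
                strands = rng.random(n) < 0.5
                size = sim.chrom_sizes[iv.chrom]
                for p, plus in zip(pos, strands):
                    r = _make_read(iv.chrom, int(p), "+" if plus else "-", rl, size)
                    if r is not None:
                        reads.append(r)
        for chrom, p in _uniform_positions(rng, sim.chrom_sizes, spec.background_reads):
            r = _make_read(chrom, p, "+" if rng.random() < 0.5 else "-", rl,
                           sim.chrom_sizes[chrom])
            if r is not None:
                reads.append(r)
        out[spec.name] = reads

    depth = max((len(r) for r in out.values()), default=50_000)
    input_reads: list[ReadRecord] = []
    for chrom, p in _uniform_positions(rng, sim.chrom_sizes, depth):
        r = _make_read(chrom, p, "+" if rng.random() < 0.5 else "-", rl, sim.chrom_sizes[chrom])
        if r is not None:
            input_reads.append(r)
    out["input"] = input_reads
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    sim: SimulatedGenome,
    coupling: float | None = None,
    noise: float | None = None,
    log_mean: float = 1.0,
    log_sd: float = 1.5,
) -> list[ExpressionRecord]:
    """Log-normal FPKM values rank-coupled to primary-factor binding strength.

    The Gaussian-copula weight w = 2 sin(pi c / 6) makes the Spearman
    correlation with binding strength approximately equal the requested
    coupling c (at noise 1); with noise 0 the FPKM is a deterministic
    monotone function of strength, giving perfect rank agreement.
    """
    config = sim.config
    c = config.expression_coupling if coupling is None else coupling
    noise = config.expression_noise if noise is None else noise
    rng = np.random.default_rng([config.seed, 2])
    strengths = np.array(
        [sim.truth.gene_strength[sim.truth.primary_factor][g] for g in sim.truth.gene_ids]
    )
    n = len(strengths)
    scores = stats.norm.ppf(stats.rankdata(strengths, method="average") / (n + 1))
    w = 2.0 * np.sin(np.pi * min(c, 1.0) / 6.0)
    if noise == 0:
        z = scores if c > 0 else np.zeros(n)
    else:
        z = w * scores + np.sqrt(max(0.0, 1.0 - w * w)) * noise * rng.standard_normal(n)
    fpkm = np.exp(log_mean + log_sd * z)
    return [ExpressionRecord(g, float(v)) for g, v in zip(sim.truth.gene_ids, fpkm)]


# ---------------------------------------------------------------------------
# conveniences
# ---------------------------------------------------------------------------

def true_peak_set(sim: SimulatedGenome, factor: str, half_width: int = 200) -> PeakSet:
    """The planted binding sites of a factor as a peak set: summit at the
    planted center, tag density = expected reads per site."""
    spec = {f.name: f for f in sim.config.factors}[factor]
    gene_chrom = {g.gene_id: g.interval.chrom for g in sim.genes}
    peaks = []
    for gid, center in sorted(sim.truth.gene_site[factor].items()):
        chrom = gene_chrom[gid]
        size = sim.chrom_sizes[chrom]
        iv = GenomicInterval(chrom, max(0, center - half_width), min(size, center + half_width))
        summit = int(min(max(center, iv.start), iv.end - 1))
        peaks.append(
            PeakRecord(iv, summit, spec.reads_per_site * sim.truth.gene_strength[factor][gid],
                       peak_id=f"{factor}:{gid}")
        )
    return PeakSet(factor, peaks)


def write_dataset(
    sim: SimulatedGenome,
    reads: dict[str, list[ReadRecord]] | None,
    expression: list[ExpressionRecord] | None,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write every simulated file in the formats the pipeline consumes."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    sim.chrom_sizes.write(p("chrom.sizes"))
    write_gene_annotation_gtf(sim.genes, p("genes.gtf"))
    write_bed(sim.enhancers, p("enhancers.bed"), names=sim.enhancer_ids)
    write_bed(sim.super_enhancers, p("super_enhancers.bed"), names=sim.se_ids)
    sim.truth.to_json(p("ground_truth.json"))
    if reads is not None:
        for name, rs in reads.items():
            write_bed(rs, p(f"reads_{name}.bed"))
    if expression is not None:
        write_expression_table(expression, p("expression.tsv"))
    return paths
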