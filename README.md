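# chipmeta

Genome-wide ChIP-seq density analysis for factor-occupancy studies:
binned coverage tracks from extended reads, reference-point density
matrices and metagene profiles, k-means co-occupancy clustering,
peak-to-feature and peak-to-gene annotation, binding-versus-expression
integration, and enhancer / super-enhancer meta-profiles — plus a
ground-truth synthetic-data generator so the whole pipeline can be
validated without any sequencing data.

It is written for the kind of question asked of chromatin regulators such
as the Tip60/NuA4 histone-acetyltransferase complex in embryonic stem
cells: where does the factor sit relative to transcription start sites,
which other factors co-occupy its sites, do bound genes run hotter
transcriptionally, and is the factor recruited to enhancers and
super-enhancers?

## The computations

**Coverage tracks.** Each uniquely aligned read is extended from its 5′
end to the expected fragment length *L* (default 200 bp) and counted into
fixed-width bins *w* (default 25 bp); a fragment contributes to every bin
it overlaps by ≥ 1 bp. Tracks can be normalized per million mapped reads
(CPM), as a ratio over an input-control track, or by a scalar.

**Density matrices and profiles.** For a set of stranded anchors
(TSSs, peak summits, enhancer midpoints) a matrix
*M<sub>ij</sub>* = track density at anchor *i*, signed offset *j* ∈
[−flank, +flank] is extracted, with the offset axis reversed on the −
strand so that positive always means downstream. The column mean is the
metagene profile; its smoothed argmax is the binding-offset estimate
(e.g. a factor peaking ≈ 200 bp downstream of the TSS).

**Co-occupancy.** Matrices of several tracks over shared anchors are
row-normalized, concatenated and partitioned by k-means (Lloyd,
k-means++ at a fixed seed). Clusters whose central density clears
2× the flank background are "positive" for a track; the co-bound
fraction of a reference factor's sites is the share of anchors in
query-positive clusters. A stricter ≥ 1-bp peak-interval overlap mode is
reported alongside.

**Annotation and expression.** Peak summits are assigned one category by
precedence promoter-TSS > 5′UTR > 3′UTR > exon > intron > TTS >
intergenic (promoter window −1 kb/+100 bp around the TSS); genes with a
summit within ±1 kb of their TSS are "bound". Genes are ranked into five
FPKM quintiles of equal size, per-quintile occupancy is summarized as
notched boxplot statistics (notch = 1.58 · IQR/√n), and bound genes are
compared with all genes by a two-sided Wilcoxon rank-sum test on
log₂(FPKM + 0.1).

**Enhancers.** Enhancers are ranked by acetylation signal around their
midpoint into quartiles I–IV; factor-positive enhancers are called by
k-means over midpoint matrices. Variable-length super-enhancers are
profiled on a scaled axis: 80 equal body bins per region plus 4-kb
flanks in 50-bp bins, as mean factor density ÷ mean input density per
bin (both CPM).

**Synthetic data.** The generator lays out a small genome (5 Mb, 500
genes, 400 enhancers, 20 super-enhancers of 5–30 kb by default), plants
factor binding at a configurable fraction of TSSs with a strand-aware
offset (default +200 ± 50 bp), realizes pairwise co-binding exactly,
emits Normal-around-site reads over a uniform background with a matched
input, and couples FPKM to promoter binding strength through a Gaussian
copula with a Spearman target. Every output is a pure function of the
seed.

## Worked example

```python
from chipmeta import (SimulationConfig, simulate_annotation, simulate_reads,
                      build_track, normalize_track, ReferencePointSet,
                      extract_matrix, average_profile, profile_peak_offset)

config = SimulationConfig(seed=2, chrom_sizes={"chr1": 5_000_000})
sim = simulate_annotation(config)
reads = simulate_reads(config, sim)
track = normalize_track(build_track(reads["factorA"], sim.chrom_sizes), "per-million")
profile = average_profile(extract_matrix(track, ReferencePointSet.from_tss(sim.genes), flank=1000))
print(profile_peak_offset(profile))
```

prints `200`: the metagene profile over all 500 TSSs peaks 200 bp
downstream of the start sites, exactly where the generator planted the
factor. The scripts under `examples/` walk through each capability the
same way — tracks and wiggle output, TSS metagenes, co-binding
(planted 60 % → estimated 59–60 %), annotation and expression quintiles,
enhancer quartiles (planted 25 % positive → estimated ≈ 25 %), and
super-enhancer profiles (planted 3× body enrichment → ≈ 2.9× after
depth normalization) — e.g.:

```sh
python examples/03_cobinding.py
```

A thin CLI mirrors the common entry points
(`chipmeta track|matrix|simulate|run`); `chipmeta run --config
pipeline.yaml` executes a named figure-level recipe and writes numeric
TSVs plus a manifest recording every parameter used.

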