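"""Build a binned read-density track from simulated reads and write wiggle.

Reads are extended to the 200-bp expected fragment length and counted into
25-bp bins; the track is then scaled to reads-per-million and serialized as
fixedStep wiggle for a genome browser.
"""

from chipmeta import (
    SimulationConfig,
    build_track,
    normalize_track,
    simulate_annotation,
    simulate_reads,
    write_wig,
)

config = SimulationConfig(seed=1, n_genes=200, n_enhancers=100, n_super_enhancers=5,
                          chrom_sizes={"chr1": 2_000_000})
sim = simulate_annotation(config)
reads = simulate_reads(config, sim)

track = build_track(reads["factorA"], sim.chrom_sizes, fragment_length=200, bin_width=25)
cpm = normalize_track(track, "per-million")
write_wig(cpm, "factorA.wig")

gene = next(g for g in sim.genes if sim.truth.gene_bound["factorA"][g.gene_id])
print(f"track: {track.total_reads} reads, {len(track.values['chr1'])} bins of 25 bp")
print(f"raw density at a bound TSS ({gene.gene_id}): {track.value_at('chr1', gene.tss):.0f}")
print(f"per-million density at the same bin:        {cpm.value_at('chr1', gene.tss):.2f}")
print("wrote factorA.wig — densities at a bound promoter stand well above the "
      "uniform background, which sits near the genome-wide mean.")
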