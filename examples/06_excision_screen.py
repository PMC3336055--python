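"""Screen a mutant panel for element excisions, classify the footprints
left behind, and estimate the de novo excision frequency."""

import mitekit as mk
from mitekit import synthetic as syn
from mitekit.excision import screen_panel

families = mk.simulate_families(6, seed=3)
cfg = syn.SimulationConfig(seed=3, n_insertions=109, genome_length=110_000)
genome, truth = syn.simulate_genome_with_insertions(cfg, families)

# three de novo excisions (one homozygous, two heterozygous) plus one locus
# whose empty allele already segregates in 14 of 60 lines before mutagenesis
planted = [
    ("line51", truth[0].locus_id, "hom_empty", "substitution"),
    ("line13", truth[1].locus_id, "het", "tsd_insertion"),
    ("line49", truth[2].locus_id, "het", "substitution"),
]
pre = truth[3].locus_id
planted += [
    (f"line{k:02d}", pre, "hom_empty", "tir_tsd_insertion")
    for k in (4, 6, 10, 18, 21, 23, 27, 32, 34, 45, 53, 58, 60, 7)
]
panel, refs = syn.simulate_mutant_panel(genome, truth, 60, planted, seed=3)
events, freq, flagged = screen_panel(panel, refs)

print(f"panel: {freq.lines} lines x {freq.loci} loci")
print(f"pre-existing-variant loci excluded from event count: {flagged}")
for e in events:
    print(f"  {e.line_id} @ {e.locus_id}: {e.zygosity}, footprint={e.footprint}")
print(f"de novo excision frequency: {freq.frequency:.6f} -> {freq.report()} "
      f"({freq.events} events / {freq.lines} lines x {freq.ploidy} haploids x {freq.loci} loci)")
# Footprints are the small scars excision leaves: a single-base
# substitution, or a di-nucleotide insertion copied from the TSD or from
# the TIR terminus plus a TSD base.
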