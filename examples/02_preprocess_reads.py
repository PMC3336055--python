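"""Turn raw enrichment reads into deduplicated per-locus flank pairs.

Masks linkers, clips masked and low-quality bases in one Mott pass, masks
the element footprint, extracts flanks and greedily clusters them by locus.
"""

import mitekit as mk
from mitekit import preprocessing as pp
from mitekit import synthetic as syn

families = mk.simulate_families(6, seed=1)
cfg = syn.SimulationConfig(seed=1, n_insertions=60, genome_length=70_000)
genome, truth = syn.simulate_genome_with_insertions(cfg, families)
reads = syn.simulate_enrichment_reads(genome, truth, cfg, n_reads=240)

linkers = [("linker", lk) for lk in syn.DEFAULT_LINKERS]
elements = [("element", f.consensus) for f in families]
pairs = []
for read in pp.length_filter(reads):
    fp = pp.preprocess_read(read, linkers, elements)
    if fp is not None and not fp.single_flank:
        pairs.append(fp)
clusters = pp.cluster_loci(pairs)

print(f"reads in: {len(reads)}, flank pairs out: {len(pairs)}")
print(f"locus clusters: {len(clusters)} (planted loci: {len(truth)})")
biggest = max(clusters, key=lambda c: len(c.members))
print(f"largest cluster: {len(biggest.members)} reads -> representative "
      f"{biggest.representative.locus_id}")
# Each cluster stands for one genomic insertion site; its representative
# flank pair is what gets annotated downstream.
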