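"""Simulate a MITE-bearing genome and an enrichment-library read set.

Builds six element subfamilies over a pool of seven TIR sequences, plants
504 insertions at AT-rich sites of a 300 kb background (286 of them with
perfectly matching TSD copies), and draws linker-flanked reads.
"""

import numpy as np

import mitekit as mk
from mitekit import synthetic as syn
from mitekit._seq import gc_fraction

families = mk.simulate_families(6, seed=1)
cfg = syn.SimulationConfig(seed=1)
genome, truth = syn.simulate_genome_with_insertions(cfg, families)
reads = syn.simulate_enrichment_reads(genome, truth, cfg, n_reads=500)

print(f"genome: {len(genome):,} bp, GC {gc_fraction(genome):.3f}")
print(f"insertions planted: {len(truth)}")
print(f"  perfect TSD copies : {sum(t.perfect_tsd for t in truth)}")
print(f"  1-9 TSD mismatches : {sum(not t.perfect_tsd for t in truth)}")
elem_gc = np.mean([gc_fraction(t.element_seq) for t in truth])
print(f"element GC {elem_gc:.3f} vs background target {cfg.background_gc}")
print(f"reads: {len(reads)} ({sum(r.read_id.startswith('decoy') for r in reads)} decoys)")
# A perfect TSD means the 9-mer left of the element equals the 9-mer right
# of it: the signature of a recent insertion that downstream TSD calling
# must recover.
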