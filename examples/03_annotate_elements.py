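"""Annotate planted elements: TSD calls, TIR complementarity, the IUPAC
TIR consensus library and the pairing-pattern table."""

import mitekit as mk
from mitekit import annotation as ann
from mitekit import synthetic as syn
from mitekit._seq import revcomp

families = mk.simulate_families(6, seed=1)
cfg = syn.SimulationConfig(seed=1)
genome, truth = syn.simulate_genome_with_insertions(cfg, families)

elements = []
for t in truth:
    left = genome[t.genome_position - 30 : t.genome_position + 9]
    eend = t.genome_position + 9 + len(t.element_seq)
    right = genome[eend : eend + 39]
    tsd = ann.detect_tsd(left, right)
    elements.append(ann.MiteElement(t.locus_id, t.element_seq, tsd, ann.detect_tir(t.element_seq)))

perfect = [e for e in elements if e.tsd.perfect]
print(f"TSD calls: {len(perfect)} perfect / {len(elements) - len(perfect)} mismatched")

stats = ann.element_stats(perfect)
print(f"elements: mean {stats.mean_length} bp ({stats.min_length}-{stats.max_length}), "
      f"GC {100 * stats.mean_gc:.1f}%")

tirs = [e.tir.left for e in perfect] + [revcomp(e.tir.right) for e in perfect]
consensuses, uniques = ann.build_tir_consensus(tirs)
print(f"TIR library: {len(consensuses)} consensuses, {len(uniques)} unique 25-mers")
for c in consensuses:
    print(f"  {c.consensus_id}: {c.iupac} ({c.members} members)")

counts, remainder = ann.classify_pairing(perfect, consensuses)
print("pairing patterns (left TIR consensus - right TIR consensus: elements):")
for (a, b), n in sorted(counts.items(), key=lambda kv: -kv[1]):
    print(f"  {a}-{b}: {n}")
# Ambiguity codes in a consensus (S=G/C, M=A/C, Y=C/T...) mark positions
# where member TIRs disagree; a pairing pattern is the pair of consensus
# ids seen at an element's two ends.
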