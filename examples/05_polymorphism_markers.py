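"""Insertion-polymorphism markers: in-silico PCR genotyping and the
four-line pairwise polymorphism summary."""

from mitekit import markers as mks
from mitekit import synthetic as syn

# the published pairwise polymorphic-marker counts among four peanut lines
# (three Virginia types and the Spanish type Kintoki), 411 markers tested
targets = {
    ("Nakateyutaka", "YI-0311"): 58,
    ("Nakateyutaka", "Satonoka"): 30,
    ("YI-0311", "Satonoka"): 77,
    ("Nakateyutaka", "Kintoki"): 124,
    ("YI-0311", "Kintoki"): 147,
    ("Satonoka", "Kintoki"): 106,
}
matrix = syn.simulate_marker_matrix(4, 411, targets, seed=1)
groups = {
    "four_lines": list(targets),
    "virginia": [p for p in targets if "Kintoki" not in p],
    "virginia_vs_spanish": [p for p in targets if "Kintoki" in p],
}
s = mks.polymorphism_summary(matrix, groups, n_tested=411)
print("pairwise polymorphic markers (count, % of 411):")
for pair, n in sorted(s.pairwise.items()):
    print(f"  {pair[0]} vs {pair[1]}: {n} ({s.pairwise_pct[pair]}%)")
for g in groups:
    print(f"average {g}: {s.group_averages[g]} ({s.group_pct[g]}%)")

# a single marker seen through in-silico PCR: ~205 bp band-size shift
# between insertion-bearing and empty alleles
fams = __import__("mitekit").simulate_families(1, seed=2)
import numpy as np
from mitekit._seq import random_dna, revcomp

rng = np.random.default_rng(2)
left, right = random_dna(rng, 150, 0.39), random_dna(rng, 150, 0.39)
tsd = "TATAATTAT"
full = left + tsd + fams[0].consensus + tsd + right
empty = left + tsd + right
pp = mks.PrimerPair("demo", full[30:50], revcomp(full[-50:-30]))
for name, template in [("insertion allele", full), ("empty allele", empty)]:
    sizes = [a.size for a in mks.in_silico_pcr(template, pp)]
    print(f"{name}: product sizes {sizes}")
# The ~205 bp offset between the two products is the element itself plus
# one TSD copy; that shift is what scores a marker as insertion vs empty.
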