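# Methods

`mitekit` analyses miniature inverted-repeat transposable elements (MITEs)
of the peanut *AhMITE1* type: short (~200 bp) non-autonomous DNA
transposons bounded by 25 bp terminal inverted repeats (TIRs) and flanked
by an AT-rich 9 bp target-site duplication (TSD). The package covers the
whole desk workflow — enrichment-library read preprocessing, TSD/TIR
annotation, TIR consensus and pairing-pattern tables, subfamily phylogeny,
insertion-polymorphism markers, and excision-footprint screening — and
ships a ground-truthed simulator so that every stage can be validated
end to end.

## The synthetic study conditions

The generator (`mitekit.synthetic`) emulates the statistical structure of
a real MITE survey; its defaults are the study conditions the analysis is
tested under.

- **Families.** Six subfamilies drawn over a pool of seven 25 bp TIR
  sequences. The canonical pairing layout reuses TIRs across patterns:
  one family pairs a TIR with itself, one TIR appears in three distinct
  patterns, and two families share a full pairing while differing in
  internal sequence — so the pattern→subfamily map is deliberately not
  injective. Default mixture weights are (29, 142, 55, 24, 13, 10)/273.
  Family consensus lengths lie in [201, 223] bp with a geometric tilt
  toward the short end (family means a few bases above 201), giving
  realized mean element lengths around 205 bp. Internal sequences are
  resampled until every family pair is below 90% identity outside the
  TIRs; pool TIRs are kept ≥ 10 mismatches apart so downstream clustering
  cannot merge them.
- **GC targeting.** Element sequence is composed with an exact G+C count
  at 30.1%; the background genome is sampled i.i.d. at 38.9%. Exact
  composition (rather than i.i.d. sampling) keeps the element-GC
  invariant within ±0.02 even with only six family draws.
- **Insertions.** An insertion site is a 9-mer with AT fraction ≥ 6/9
  (the "AT-rich" rule; the threshold is a package choice that leaves
  sites abundant). The resident 9-mer is duplicated around the element.
  A fraction 286/504 of insertions — allocated exactly, not binomially —
  are planted unmutated; the rest receive 1–9 substitutions in the right
  TSD copy and element substitutions at 2% per base, emulating older
  insertions. Family membership is likewise allocated exactly by largest
  remainder, so realized mixture proportions equal the weights and
  recovery tests can assert equality rather than approximation.
- **Reads.** Enrichment reads are linker + genomic fragment + linker with
  30–140 bp flanks per side. Phred qualities rise logistically from Q10
  at the read ends to Q40 inside (midpoint 8 bases, scale 3); only the
  Q20 threshold matters downstream. 20% of reads are element-free decoys
  emulating imperfect enrichment. Read errors default to zero; the
  recovery criteria are defined at zero read error.
- **What the simulator does not model.** Chromatograms and base-calling,
  restriction-site biases of library construction, PCR chemistry and
  stutter, homoeologous duplication of loci between subgenomes, and
  structural variation other than clean element insertion/excision.
  Passing tests therefore demonstrate correctness of the analysis logic
  under idealised noise, not robustness to every artefact of real trace
  data.

## Preprocessing

- **Quality trimming** is the Mott maximal-scoring-subsequence rule:
  +1 for bases at Phred ≥ 20, −2 below; the retained read is the
  contiguous window maximising the score, emptied when the best score is
  below 10. Ties prefer the longer, then the leftmost window. Masked
  bases are assigned quality 0 first, so vector/linker masking and
  quality clipping happen in one pass.
- **Masking** is exact-seed (10 bases) plus ungapped extension at
  +1/−2 to a local maximum on either strand, masking intervals that
  reach score 18; element masking uses the stricter 12/20. Extension
  ties prefer the longer interval. This seed-and-extend operator is a
  deliberately simplified, fully specified stand-in for banded
  Smith–Waterman masking tools; it reproduces the parameter semantics
  (minimum match, penalty, minimum score) at desk scale. Masking records
  intervals only — original bases stay retrievable.
- **Flank extraction** splits the read around the longest
  element-labelled interval; reads with the element at an end yield a
  single flank and are flagged, as are multi-element reads.
- **Locus clustering** is greedy: flank pairs in decreasing total flank
  length (ties lexicographic by sequence then id, for determinism) join
  the first cluster whose representative matches on either flank at
  ≥ 95% identity over the shorter sequence (infix alignment, so the
  shorter sequence is fully covered). This replaces contig assembly: at
  enrichment-library scale, reads from one locus share a flank suffix
  anchored at the element boundary, which infix identity captures
  without overlap-layout-consensus machinery. Flanks from both sides are
  clustered jointly.

## Annotation

- **TSD calling** compares the 9-mer suffix of the left flank with the
  9-mer prefix of the right flank — exact adjacency, no offset search —
  reporting Hamming mismatches and AT fraction. A 0-mismatch call marks
  a "new" insertion; these form the analysis set for TIR and subfamily
  work.
- **TIR calling** scores position i of the first 25 bases against
  position 25−1−i of the last 25: a full match when exactly
  complementary, a semi match when the IUPAC sets still intersect under
  complementation.
- **TIR consensuses** come from single-linkage clustering of the 572
  end 25-mers (both ends, right end reverse-complemented into TIR
  orientation) at Hamming ≤ 3. Clusters of ≥ 2 members emit an IUPAC
  consensus — plain base where unanimous, else the minimal covering
  ambiguity code, with no frequency cutoff (observed real libraries show
  only 2-fold codes, which this rule reproduces) — and singletons are
  reported verbatim as unique. Consensus ids are ranked by membership.
- **Pairing patterns** assign each element end to the nearest consensus
  by count of IUPAC-incompatible positions (ties to the larger
  consensus, then lexicographic id; unassigned beyond 3 mismatches) and
  tabulate (left, right) pairs, with an explicit unique remainder.
- **Statistics.** GC excludes ambiguity codes from numerator and
  denominator; mean length is reported to one decimal.

## Phylogeny and subfamilies

- **Distance** is the p-distance of a pairwise global alignment
  (mismatch 1, gap open 2, gap extend 0.5; gap columns excluded). A
  pairwise p-distance stands in for a full multiple alignment plus
  model-based distances: defensible at the ~200 bp, < 50% divergence
  scale this package targets, and exactly Hamming/n in the indel-free
  case.
- **Neighbor joining** is the Saitou–Nei agglomeration on the Q
  criterion with the standard branch-length formulas, ties broken by the
  lexicographically smallest label pair, negative branch estimates
  clamped to zero with the raw value retained on the node
  (`raw_length`). On additive matrices the output reproduces the
  generating tree's patristic distances to 1e−9 (property-tested, and
  cross-checked against an independent implementation).
- **Subfamilies** are single-linkage components at p ≤ 0.15 — a default
  at which the simulator's default mutation loads keep families whole
  while separating them — with clusters under 3 members left unassigned
  (mirroring surveys in which a minority of elements fall outside every
  named subfamily). Per-subfamily consensuses use a medoid-anchored
  alignment: members are aligned to the minimal-total-distance member,
  columns indexed by medoid positions (insertions relative to the medoid
  dropped), and the same unanimity/IUPAC rule as for TIRs applied
  per column.

## Markers

- **In-silico PCR** matches the forward primer on the plus strand and
  the reverse primer on the minus strand downstream, IUPAC-aware, with
  at most one internal mismatch and an exactly matching 3′-terminal
  base — a matching rule standing in for annealing stringency, since
  thermodynamics are out of scope. Product size spans both primer
  footprints. The implementation is verified against an independent
  every-offset scan.
- **Band patterns** are the sorted deduplicated product sizes per line;
  allele calls read a ~205 ± 25 bp size difference as insertion vs empty
  allele, a line showing both bands as heterozygous. Double bands from
  duplicated loci stay within one pattern label rather than splitting
  into two markers.
- **Polymorphism summaries** count markers whose pattern labels differ
  per line pair; group averages are arithmetic means over member pairs
  and percentages are 100 × value / n_tested, all rounded half-up to one
  decimal. Rounding half-up is locked by tests; note that an average of
  125.666… therefore prints as 125.7, whereas truncation would print
  125.6 — both yield the same percentage (30.6) at n = 411.
- **Exact-discordance matrices.** The generator realises a target set of
  pairwise discordance counts exactly by treating each locus as a set
  partition of the lines and solving an integer allocation over all
  partitions (MILP), preferring fewer polymorphic and fewer multi-state
  loci. Targets must satisfy the triangle inequality; a triple whose
  counts sum to an odd number is unrealisable with two-state loci alone
  (each two-state locus contributes an even amount to a triple's total),
  so the construction emits ≥ 3-state loci exactly where needed.

## Excision screening

- **Genotyping** compares band sizes to the two reference allele sizes
  (full: flank + TSD + element + TSD + flank; empty: flank + one TSD +
  flank) at ±25 bp; alleles closer than twice the tolerance raise an
  error rather than guessing.
- **Footprints.** An excised allele is globally aligned to the empty
  reconstruction. No edits → clean; one substitution → substitution; one
  2 bp insertion is classified by reconstruction — the insertion is a
  TSD footprint if the observed allele equals the empty allele with the
  TSD's first or last dinucleotide inserted anywhere, and a TIR+TSD
  footprint for the TIR-terminal base plus a TSD base — because
  insertions at a repeat junction have several equal-score alignment
  placements and the aligned substring alone is not trustworthy.
  Anything else is complex.
- **Frequency.** De novo excision frequency = events / (lines × ploidy ×
  loci). A heterozygous line contributes one event (one mutated
  haplotype); a homozygous-empty line also contributes one by default (a
  single ancestral excision followed by selfing), with `hom_empty_events=2`
  exposed for the alternative convention. Loci whose empty allele recurs
  in more than 10% of lines are flagged as pre-existing variation and
  excluded from the event count but kept in the denominator; the 10%
  threshold is a frequency heuristic for what is, in a real experiment,
  established by external evidence.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based closed only in
  GFF3 output.
- All randomness flows through `numpy.random.default_rng` seeds; a
  pipeline run derives per-stage seeds from one master seed by hashing,
  and identical configurations produce byte-identical artifacts
  (manifest-verified).
- Problem sizes in tests and the reproduction script: the full
  504-insertion simulation for TSD/TIR/pairing work, 140 elements for
  subfamily recovery, a 60-line × 109-locus panel for excision, and a
  411-marker four-line matrix for polymorphism summaries. The pipeline's
  default phylogeny stage subsamples to 120 elements; at that size the
  rarest family can drop below the 3-member threshold and be reported
  unassigned, which is expected behaviour, not failure.
- Known limitations: no chromatogram parsing, no true contig assembly,
  no primer design, no bootstrap supports, no modelling of homoeologous
  double bands beyond the pattern label, and footprint classes are fixed
  to the four observed types (clean, substitution, TSD-derived and
  TIR+TSD-derived dinucleotide insertion) plus a complex catch-all.
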