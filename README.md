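# mitekit

Toolkit for characterising **miniature inverted-repeat transposable
elements (MITEs)** — short non-autonomous DNA transposons like peanut's
*AhMITE1* family — from enrichment-library reads through annotation,
classification, marker genotyping and excision screening.

A MITE insertion leaves two structural signatures: a **target-site
duplication** (TSD; here an AT-rich 9 bp direct repeat on both sides of
the element) and **terminal inverted repeats** (TIRs; here 25 bp, the
element's last bases being the approximate reverse complement of its
first). `mitekit` works from those signatures:

- **`mitekit.synthetic`** — genomes, enrichment reads, mutant panels and
  marker matrices with full ground truth (six subfamilies over a
  seven-TIR pool, element GC ≈ 30% in a 39% background, 286/504
  insertions with perfect TSDs, rare excisions with footprints).
- **`mitekit.preprocessing`** — Mott quality trimming (+1 at Phred ≥ 20,
  −2 below), seed-and-extend vector/linker/element masking, length
  filtering, flank extraction, greedy locus deduplication.
- **`mitekit.annotation`** — TSD calls (Hamming on the junction 9-mers),
  TIR complementarity (full vs IUPAC-compatible semi matches), IUPAC TIR
  consensus libraries, pairing-pattern tables, length/GC statistics.
- **`mitekit.phylogeny`** — alignment p-distances, Saitou–Nei neighbor
  joining (Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)),
  single-linkage subfamily assignment with per-subfamily consensuses.
- **`mitekit.markers`** — IUPAC-aware in-silico PCR (3′-exact, ≤ 1
  internal mismatch), band-pattern genotyping, pairwise polymorphism
  summaries.
- **`mitekit.excision`** — locus genotyping from band sizes, footprint
  classification (clean / substitution / TSD-derived / TIR+TSD-derived
  dinucleotide insertion / complex), de novo excision frequency
  = events / (lines × ploidy × loci).
- **`mitekit.pipeline` + `mitekit` CLI** — orchestrated end-to-end runs
  with manifests, byte-identical under a fixed seed.

See `docs/methods.md` for the models, parameters and design choices.

## Worked example

Screening a 60-line mutant panel over 109 element loci with three planted
de novo excisions (`examples/06_excision_screen.py`):

```text
panel: 60 lines x 109 loci
pre-existing-variant loci excluded from event count: ['site0003']
  line51 @ site0000: hom_empty, footprint=substitution
  line13 @ site0001: het, footprint=tsd_insertion
  line49 @ site0002: het, footprint=substitution
de novo excision frequency: 0.000229 -> 0.00023 (3 events / 60 lines x 2 haploids x 109 loci)
```

Each event is a line × locus where the element has excised; the footprint
is the scar it left (a base substitution, or a dinucleotide copied from
the TSD). One locus, empty in 14 of 60 lines, is flagged as variation
that pre-dates mutagenesis and is excluded from the event count. The
frequency divides events by the number of assayed haploid loci.

The other examples each exercise one capability and print what they
compute: `01_simulate_library.py` (ground-truthed simulation),
`02_preprocess_reads.py` (reads → loci), `03_annotate_elements.py`
(TSD/TIR/pairing tables), `04_subfamily_tree.py` (neighbor joining and
subfamilies), `05_polymorphism_markers.py` (in-silico PCR and the
four-line polymorphism summary).

A CLI mirrors the pipeline stages:

```bash
mitekit all --seed 1 --outdir run1       # simulate → … → excision
mitekit annotate --seed 1 --outdir run2  # just simulation + annotation
```

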