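"""Excision detection in mutant panels and footprint classification.

When a DNA transposon excises it usually leaves a footprint at the empty
site: either nothing (clean), a single-base substitution, or a short
insertion copied from the target-site duplication (TSD) or from the TIR
terminus plus a TSD base. This module genotypes each line x locus, aligns
empty alleles against the expected empty-site reconstruction, classifies
the footprint, and estimates the per-allele de novo excision frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .markers import BandPattern

__all__ = [
    "LocusReference",
    "ExcisionEvent",
    "FrequencyEstimate",
    "genotype_locus",
    "call_footprint",
    "excision_frequency",
    "screen_panel",
]

FOOTPRINT_CLASSES = ("clean", "substitution", "tsd_insertion", "tir_tsd_insertion", "complex")


@dataclass(frozen=True)
class LocusReference:
    """Both alleles at one insertion locus.

    ``full_allele`` is flank + TSD + element + TSD + flank as carried by
    insertion-bearing lines; ``empty_allele`` is the same locus with the
    element and one TSD copy removed, i.e. the pre-insertion state.
    """

    locus_id: str
    full_allele: str
    empty_allele: str
    tsd: str
    tir_terminal: str = ""

    @classmethod
    def from_parts(cls, locus_id: str, left_flank: str, tsd: str, element: str, right_flank: str) -> "LocusReference":
        return cls(
            locus_id=locus_id,
            full_allele=left_flank + tsd + element + tsd + right_flank,
            empty_allele=left_flank + tsd + right_flank,
            tsd=tsd,
            tir_terminal=element[-1] if element else "",
        )


@dataclass(frozen=True)
class ExcisionEvent:
    locus_id: str
    line_id: str
    zygosity: str                      # het | hom_empty
    footprint: str                     # one of FOOTPRINT_CLASSES
    edits: tuple[tuple[int, str, str], ...] = ()


@dataclass(frozen=True)
class FrequencyEstimate:
    events: int
    lines: int
    loci: int
    ploidy: int
    frequency: float

    def report(self, sig: int = 2) -> str:
        return f"{self.frequency:.{sig}g}"


def genotype_locus(
    band_pattern: BandPattern,
    reference: LocusReference,
    size_tolerance: int = 25,
) -> str:
    """Zygosity from band sizes against the two reference allele sizes.

    Returns ``hom_insert`` | ``hom_empty`` | ``het`` | ``no_call``.
    """
    full_size = len(reference.full_allele)
    empty_size = len(reference.empty_allele)
    if abs(full_size - empty_size) < 2 * size_tolerance:
        raise ValueError(
            f"{reference.locus_id}: allele sizes {full_size}/{empty_size} too close "
            f"to resolve at ±{size_tolerance}"
        )
    has_full = any(abs(s - full_size) <= size_tolerance for s in band_pattern.amplicon_sizes)
    has_empty = any(abs(s - empty_size) <= size_tolerance for s in band_pattern.amplicon_sizes)
    if has_full and has_empty:
        return "het"
    if has_full:
        return "hom_insert"
    if has_empty:
        return "hom_empty"
    return "no_call"


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-3,
    extend_gap_score=-0.5,
)


def _alignment_edits(ref: str, obs: str) -> list[tuple[int, str, str]]:
    """Edit list from a global alignment, as (ref position, ref, alt).

    Substitutions are single-base; runs of inserted/deleted bases are one
    edit each, insertions anchored at the ref position they precede
    (ref string "-", alt the inserted run).
    """
    aln = _ALIGNER.align(ref, obs)[0]
    ra, oa = aln[0], aln[1]
    edits: list[tuple[int, str, str]] = []
    rpos = 0
    i = 0
    while i < len(ra):
        if ra[i] != "-" and oa[i] != "-":
            if ra[i] != oa[i]:
                edits.append((rpos, ra[i], oa[i]))
            rpos += 1
            i += 1
        elif ra[i] == "-":
            j = i
            while j < len(ra) and ra[j] == "-":
                j += 1
            edits.append((rpos, "-", oa[i:j]))
            i = j
        else:
            j = i
            while j < len(ra) and oa[j] == "-":
                j += 1
            edits.append((rpos, ra[i:j], "-"))
            rpos += j - i
            i = j
    return edits


def call_footprint(observed_allele: str, reference: LocusReference) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """Classify the footprint of an excised allele.

    The observed allele is globally aligned to the empty-site
    reconstruction. Zero edits is a clean excision; one substitution is a
    substitution footprint; a single di-nucleotide insertion matching a
    prefix or suffix of the TSD is a ``tsd_insertion``; one matching the
    TIR-terminal base followed by a TSD base is ``tir_tsd_insertion``;
    any other edit pattern is ``complex``.
    """
    obs = observed_allele.upper()
    ref = reference.empty_allele.upper()
    if reference.full_allele.upper() in obs or (
        len(obs) >= len(reference.full_allele) - 5
    ):
        raise ValueError(f"{reference.locus_id}: observed allele still carries the element")
    edits = _alignment_edits(ref, obs)
    footprint = _classify_edits(edits, obs, ref, reference)
    return footprint, tuple(edits)


def _insertion_of(candidate: str, ref: str, obs: str) -> bool:
    """True when obs equals ref with ``candidate`` inserted somewhere.

    Checked by reconstruction rather than from the alignment's inserted
    substring, because insertions in repeat context (a TSD junction is one)
    have several equal-score alignment placements."""
    if len(obs) != len(ref) + len(candidate):
        return False
    # first differing position bounds the leftmost feasible placement
    # any valid placement p has obs[:p] == ref[:p], so p <= first mismatch;
    # repeat context can slide it left, bounded here by the repeat run length
    lo = next((i for i in range(len(ref)) if ref[i] != obs[i]), len(ref))
    for p in range(lo, max(-1, lo - 30), -1):
        if obs == ref[:p] + candidate + ref[p:]:
            return True
    return False


def _classify_edits(
    edits: list[tuple[int, str, str]],
    obs: str,
    ref: str,
    reference: LocusReference,
) -> str:
    if not edits:
        return "clean"
    if len(edits) == 1:
        pos, r, a = edits[0]
        if len(r) == 1 and len(a) == 1 and r != "-" and a != "-":
            return "substitution"
        if r == "-" and len(a) == 2:
            tsd = reference.tsd.upper()
            tirb = reference.tir_terminal.upper()
            for cand in (tsd[:2], tsd[-2:]):
                if _insertion_of(cand, ref, obs):
                    return "tsd_insertion"
            for cand in ((tirb + tsd[0], tirb + tsd[-1]) if tirb else ()):
                if _insertion_of(cand, ref, obs):
                    return "tir_tsd_insertion"
            return "complex"
    return "complex"


def excision_frequency(events: int, lines: int, loci: int, ploidy: int = 2) -> FrequencyEstimate:
    """De novo excision frequency: events per assayed haploid locus,
    events / (lines x ploidy x loci)."""
    if lines <= 0 or loci <= 0 or ploidy <= 0:
        raise ValueError("lines, loci and ploidy must be positive")
    if events < 0 or events > lines * ploidy * loci:
        raise ValueError(f"events={events} outside [0, lines*ploidy*loci]")
    return FrequencyEstimate(
        events=events,
        lines=lines,
        loci=loci,
        ploidy=ploidy,
        frequency=events / (lines * ploidy * loci),
    )


def screen_panel(
    panel: dict[str, dict[str, tuple[str, str]]],
    references: dict[str, LocusReference],
    preexisting_fraction: float = 0.10,
    ploidy: int = 2,
    hom_empty_events: int = 1,
) -> tuple[list[ExcisionEvent], FrequencyEstimate, list[str]]:
    """Genotype every line x locus and count de novo excisions.

    ``panel`` maps line -> locus -> diploid allele pair (sequences).
    Loci whose empty allele recurs in more than ``preexisting_fraction``
    of lines are flagged as pre-existing variation (segregating before
    mutagenesis) and excluded from the event count, but stay in the
    frequency denominator. A heterozygous line contributes one event; a
    homozygous-empty line contributes ``hom_empty_events`` (default 1: a
    single ancestral excision followed by selfing).
    """
    lines = sorted(panel)
    loci = sorted(references)
    per_locus_calls: dict[str, dict[str, tuple[str, str | None, tuple]]] = {}
    for locus_id in loci:
        ref = references[locus_id]
        calls: dict[str, tuple[str, str | None, tuple]] = {}
        for line_id in lines:
            hap1, hap2 = panel[line_id][locus_id]
            states = []
            footprints = []
            for hap in (hap1, hap2):
                if _carries_element(hap, ref):
                    states.append("insert")
                    footprints.append((None, ()))
                else:
                    states.append("empty")
                    footprints.append(call_footprint(hap, ref))
            if states == ["insert", "insert"]:
                calls[line_id] = ("hom_insert", None, ())
            elif "insert" in states:
                fp = footprints[states.index("empty")]
                calls[line_id] = ("het", fp[0], fp[1])
            else:
                fp = footprints[0]
                calls[line_id] = ("hom_empty", fp[0], fp[1])
        per_locus_calls[locus_id] = calls

    events: list[ExcisionEvent] = []
    flagged: list[str] = []
    n_events = 0
    for locus_id in loci:
        calls = per_locus_calls[locus_id]
        empty_lines = [ln for ln, (z, _, _) in calls.items() if z in ("het", "hom_empty")]
        if len(empty_lines) > preexisting_fraction * len(lines):
            flagged.append(locus_id)
            continue
        for line_id in empty_lines:
            zyg, fp, edits = calls[line_id]
            events.append(
                ExcisionEvent(locus_id=locus_id, line_id=line_id, zygosity=zyg, footprint=fp, edits=edits)
            )
            n_events += 1 if zyg == "het" else hom_empty_events
    freq = excision_frequency(n_events, len(lines), len(loci), ploidy)
    return events, freq, flagged


def _carries_element(allele: str, ref: LocusReference) -> bool:
    """A haplotype carries the insertion when it is closer in length to the
    full allele than to the empty reconstruction."""
    full, empty = len(ref.full_allele), len(ref.empty_allele)
    return abs(len(allele) - full) < abs(len(allele) - empty)
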