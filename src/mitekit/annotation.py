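"""Element annotation: target-site duplications, terminal inverted repeats,
TIR consensus libraries, pairing patterns and descriptive statistics.

A MITE insertion duplicates a short target 9-mer on both sides of the element
(the TSD) and is bounded by a 25 bp terminal inverted repeat (TIR): the last
25 bases of the element are (approximately) the reverse complement of the
first 25. These structural signatures, not coding content, define the family.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._seq import (
    at_fraction,
    covering_code,
    gc_fraction,
    hamming,
    iupac_compatible,
    iupac_set,
    revcomp,
)

__all__ = [
    "TsdCall",
    "TirCall",
    "TirConsensus",
    "MiteElement",
    "ElementStats",
    "detect_tsd",
    "detect_tir",
    "build_tir_consensus",
    "assign_to_consensus",
    "classify_pairing",
    "element_stats",
]


@dataclass(frozen=True)
class TsdCall:
    """The two copies of a predicted target-site duplication."""

    left: str
    right: str
    mismatches: int
    at_fraction: float

    @property
    def perfect(self) -> bool:
        return self.mismatches == 0


@dataclass(frozen=True)
class TirCall:
    """The two 25-mers at the element ends and their complementarity.

    ``full_matches`` counts positions where the left base exactly
    complements the opposing right base; ``semi_matches`` counts the
    remaining positions whose IUPAC sets are still complementarity-
    compatible. Full positions are by construction a subset of the
    semi-compatible ones, so full + semi <= TIR length.
    """

    left: str
    right: str
    full_matches: int
    semi_matches: int
    left_consensus: str | None = None
    right_consensus: str | None = None


@dataclass(frozen=True)
class TirConsensus:
    consensus_id: str
    iupac: str
    members: int


@dataclass(frozen=True)
class MiteElement:
    locus_id: str
    element_seq: str
    tsd: TsdCall | None
    tir: TirCall | None
    subfamily: str | None = None

    @property
    def length(self) -> int:
        return len(self.element_seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.element_seq)

    @property
    def pairing_pattern(self) -> tuple[str, str] | None:
        if self.tir is None or self.tir.left_consensus is None or self.tir.right_consensus is None:
            return None
        return (self.tir.left_consensus, self.tir.right_consensus)


@dataclass(frozen=True)
class ElementStats:
    n: int
    mean_length: float
    min_length: int
    max_length: int
    mean_gc: float


def detect_tsd(left_flank: str, right_flank: str, tsd_length: int = 9) -> TsdCall:
    """Compare the flank 9-mers immediately adjacent to the element.

    The candidate TSD copies are the ``tsd_length`` suffix of the left
    flank and the same-length prefix of the right flank; no offset search
    is performed. AT fraction is reported from the left copy.
    """
    if len(left_flank) < tsd_length or len(right_flank) < tsd_length:
        raise ValueError(
            f"flanks of {len(left_flank)}/{len(right_flank)} bases are too short "
            f"for a {tsd_length} bp TSD"
        )
    left = left_flank[-tsd_length:].upper()
    right = right_flank[:tsd_length].upper()
    return TsdCall(
        left=left,
        right=right,
        mismatches=hamming(left, right),
        at_fraction=at_fraction(left),
    )


def detect_tir(element_seq: str, tir_length: int = 25) -> TirCall:
    """Score the inverted-repeat complementarity of the element's ends.

    Position i of the left TIR is a full match when it exactly complements
    position (tir_length - 1 - i) of the right TIR, and a semi match when
    the IUPAC sets of the two bases remain compatible under complementation.
    """
    seq = element_seq.upper()
    if len(seq) < 2 * tir_length:
        raise ValueError(f"element of {len(seq)} bases too short for {tir_length} bp TIRs")
    left = seq[:tir_length]
    right = seq[-tir_length:]
    full = semi = 0
    for i in range(tir_length):
        a = left[i]
        b = right[tir_length - 1 - i]
        comp_sets = iupac_set(revcomp(b))
        if a in "ACGT" and b in "ACGT" and a == revcomp(b):
            full += 1
        elif iupac_set(a) & comp_sets:
            semi += 1
    return TirCall(left=left, right=right, full_matches=full, semi_matches=semi)


def _single_linkage_hamming(seqs: list[str], max_mismatch: int) -> list[list[int]]:
    """Single-linkage components under Hamming distance <= max_mismatch."""
    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if hamming(seqs[i], seqs[j]) <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def iupac_consensus(seqs: list[str]) -> str:
    """Column-wise consensus: the plain base where unanimous, otherwise the
    minimal IUPAC code covering every observed base (no frequency cutoff)."""
    if not seqs:
        raise ValueError("cannot build a consensus of nothing")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("consensus requires equal-length sequences")
    out = []
    for col in zip(*(s.upper() for s in seqs)):
        uniq = set(col)
        out.append(col[0] if len(uniq) == 1 else covering_code(uniq))
    return "".join(out)


def build_tir_consensus(
    tirs: list[str],
    max_cluster_mismatch: int = 3,
    min_members: int = 2,
    tir_length: int = 25,
) -> tuple[list[TirConsensus], list[str]]:
    """Cluster TIR 25-mers and emit IUPAC consensuses plus unique leftovers.

    Single-linkage at Hamming <= ``max_cluster_mismatch``; clusters with at
    least ``min_members`` members yield a consensus, everything else is
    returned verbatim as unique. Consensus ids are assigned by decreasing
    membership (TIR1 = largest), ties by lexicographic consensus string.
    """
    for t in tirs:
        if len(t) != tir_length:
            raise ValueError(f"TIR {t!r} is not {tir_length} bases long")
    seqs = [t.upper() for t in tirs]
    groups = _single_linkage_hamming(seqs, max_cluster_mismatch)
    keep = [g for g in groups if len(g) >= min_members]
    uniques = sorted(seqs[i] for g in groups if len(g) < min_members for i in g)
    built = sorted(
        ((iupac_consensus([seqs[i] for i in g]), len(g)) for g in keep),
        key=lambda cm: (-cm[1], cm[0]),
    )
    consensuses = [
        TirConsensus(consensus_id=f"TIR{k + 1}", iupac=cons, members=m)
        for k, (cons, m) in enumerate(built)
    ]
    return consensuses, uniques


def assign_to_consensus(
    tir: str,
    consensuses: list[TirConsensus],
    max_cluster_mismatch: int = 3,
) -> str | None:
    """Nearest consensus by count of IUPAC-incompatible positions.

    Ties go to the consensus with more members, then lexicographic id;
    returns ``None`` when no consensus is within ``max_cluster_mismatch``.
    """
    best: tuple[int, int, str] | None = None
    for cons in consensuses:
        d = sum(
            0 if iupac_compatible(a, b) else 1 for a, b in zip(tir.upper(), cons.iupac)
        )
        key = (d, -cons.members, cons.consensus_id)
        if best is None or key < best:
            best = key
    if best is None or best[0] > max_cluster_mismatch:
        return None
    return best[2]


def classify_pairing(
    elements: list[MiteElement],
    consensuses: list[TirConsensus],
    max_cluster_mismatch: int = 3,
) -> tuple[dict[tuple[str, str], int], list[MiteElement]]:
    """Tabulate (left consensus, right consensus) pairing patterns.

    Each element's left TIR, and the reverse complement of its right TIR
    (so both ends are read in TIR orientation), are assigned to the nearest
    consensus. Elements with an unassignable end fall into the unique
    remainder. The same pattern may occur in more than one subfamily, so
    pattern -> subfamily is reported, never assumed injective.
    """
    counts: Counter[tuple[str, str]] = Counter()
    remainder: list[MiteElement] = []
    for el in elements:
        if el.tir is None:
            remainder.append(el)
            continue
        left_id = assign_to_consensus(el.tir.left, consensuses, max_cluster_mismatch)
        right_id = assign_to_consensus(revcomp(el.tir.right), consensuses, max_cluster_mismatch)
        if left_id is None or right_id is None:
            remainder.append(el)
        else:
            counts[(left_id, right_id)] += 1
    return dict(counts), remainder


def annotate_tir_consensuses(
    elements: list[MiteElement],
    consensuses: list[TirConsensus],
    max_cluster_mismatch: int = 3,
) -> list[MiteElement]:
    """Return elements with their TIR calls labelled by nearest consensus."""
    out = []
    for el in elements:
        if el.tir is None:
            out.append(el)
            continue
        tir = TirCall(
            left=el.tir.left,
            right=el.tir.right,
            full_matches=el.tir.full_matches,
            semi_matches=el.tir.semi_matches,
            left_consensus=assign_to_consensus(el.tir.left, consensuses, max_cluster_mismatch),
            right_consensus=assign_to_consensus(
                revcomp(el.tir.right), consensuses, max_cluster_mismatch
            ),
        )
        out.append(MiteElement(el.locus_id, el.element_seq, el.tsd, tir, el.subfamily))
    return out


def element_stats(elements: list[MiteElement]) -> ElementStats:
    """Length and GC summary over a set of annotated elements."""
    if not elements:
        raise ValueError("element_stats requires a non-empty element list")
    lengths = [el.length for el in elements]
    gcs = [el.gc for el in elements]
    return ElementStats(
        n=len(elements),
        mean_length=round(sum(lengths) / len(lengths), 1),
        min_length=min(lengths),
        max_length=max(lengths),
        mean_gc=sum(gcs) / len(gcs),
    )
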