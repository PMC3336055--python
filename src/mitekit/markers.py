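"""Insertion-polymorphism markers: in-silico PCR, band-pattern genotyping
and the pairwise polymorphism summary.

A primer pair flanking a MITE insertion amplifies a product roughly one
element length (~205 bp) larger from an insertion-bearing allele than from
the corresponding empty allele, so band-size differences of about the
element length read out presence/absence of the insertion per line.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

from ._seq import iupac_match, revcomp

__all__ = [
    "PrimerPair",
    "Amplicon",
    "BandPattern",
    "MarkerMatrix",
    "PolymorphismSummary",
    "in_silico_pcr",
    "score_marker",
    "polymorphism_summary",
    "round_half_up",
]


@dataclass(frozen=True)
class PrimerPair:
    marker_id: str
    forward: str
    reverse: str
    expected_size_range: tuple[int, int] = (300, 600)

    def __post_init__(self):
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"{self.marker_id}: primers must be >= 15 bases")
        lo, hi = self.expected_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"{self.marker_id}: bad expected size range {self.expected_size_range}")


@dataclass(frozen=True)
class Amplicon:
    start: int   # 0-based, start of forward-primer footprint
    end: int     # half-open, end of reverse-primer footprint
    size: int


@dataclass(frozen=True)
class BandPattern:
    marker_id: str
    line_id: str
    amplicon_sizes: tuple[int, ...]

    def __post_init__(self):
        sizes = tuple(sorted(set(self.amplicon_sizes)))
        object.__setattr__(self, "amplicon_sizes", sizes)
        if sizes and sizes[0] <= 0:
            raise ValueError("amplicon sizes must be positive")

    @property
    def is_null(self) -> bool:
        return not self.amplicon_sizes

    @property
    def label(self) -> str:
        return "null" if self.is_null else "/".join(str(s) for s in self.amplicon_sizes)


@dataclass(frozen=True)
class MarkerMatrix:
    """Categorical band-pattern labels over lines x markers."""

    lines: tuple[str, ...]
    markers: tuple[str, ...]
    patterns: dict[tuple[str, str], str]

    def __post_init__(self):
        missing = [
            (ln, mk) for ln in self.lines for mk in self.markers if (ln, mk) not in self.patterns
        ]
        if missing:
            raise ValueError(f"marker matrix incomplete: missing {missing[:3]}...")

    def pairwise_discordance(self) -> dict[tuple[str, str], int]:
        """Markers whose pattern labels differ, per unordered line pair."""
        out = {}
        for a, b in combinations(self.lines, 2):
            out[(a, b)] = sum(
                self.patterns[(a, mk)] != self.patterns[(b, mk)] for mk in self.markers
            )
        return out


@dataclass(frozen=True)
class PolymorphismSummary:
    n_tested: int
    pairwise: dict[tuple[str, str], int]
    pairwise_pct: dict[tuple[str, str], float]
    group_averages: dict[str, float]
    group_pct: dict[str, float]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 125.65 -> 125.7, not banker's 125.6)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _match_positions(template: str, primer: str, max_mismatch: int, three_prime_end: int) -> list[int]:
    """Plus-strand offsets where the primer binds IUPAC-aware.

    ``three_prime_end`` is the primer index (0 or len-1, template
    orientation) that must match exactly; internal mismatches up to
    ``max_mismatch`` are allowed elsewhere.
    """
    m = len(primer)
    hits = []
    for off in range(len(template) - m + 1):
        window = template[off : off + m]
        if not iupac_match(primer[three_prime_end], window[three_prime_end]):
            continue
        mm = sum(not iupac_match(p, t) for p, t in zip(primer, window))
        if mm <= max_mismatch:
            hits.append(off)
    return hits


def in_silico_pcr(
    template: str,
    primers: PrimerPair,
    max_mismatch: int = 1,
    max_product: int = 3000,
) -> list[Amplicon]:
    """Predict PCR products from primer binding sites.

    The forward primer is matched on the plus strand and the reverse
    primer on the minus strand downstream of it; matching is IUPAC-aware
    with at most ``max_mismatch`` mismatches and an exactly matching
    3'-terminal base (a stand-in for annealing stringency). Product size
    spans both primer footprints, outer edge to outer edge.
    """
    t = template.upper()
    fwd = primers.forward.upper()
    # reverse primer on the minus strand == its reverse complement on the plus
    rev_rc = revcomp(primers.reverse.upper())
    f_hits = _match_positions(t, fwd, max_mismatch, three_prime_end=len(fwd) - 1)
    # the reverse primer's 3' end maps to the plus-strand START of its footprint
    r_hits = _match_positions(t, rev_rc, max_mismatch, three_prime_end=0)
    out = []
    for f in f_hits:
        for r in r_hits:
            end = r + len(rev_rc)
            size = end - f
            if r >= f + len(fwd) and size <= max_product:
                out.append(Amplicon(start=f, end=end, size=size))
    return sorted(out, key=lambda a: (a.start, a.end))


def score_marker(
    amplicons_per_line: dict[str, list[Amplicon]],
    marker_id: str = "marker",
    insertion_size: int = 205,
    size_tolerance: int = 25,
) -> tuple[dict[str, BandPattern], str]:
    """Band patterns per line plus a marker class.

    Classes: ``null`` (no product in any line), ``monomorphic``
    (identical patterns across lines), ``polymorphic`` (any two lines
    whose band sets differ). When two bands across lines differ by
    roughly the element length (± ``size_tolerance``), the larger is the
    insertion allele; a line showing both at once carries the
    heterozygous pattern.
    """
    patterns = {
        ln: BandPattern(marker_id, ln, tuple(a.size for a in amps))
        for ln, amps in amplicons_per_line.items()
    }
    labels = {p.label for p in patterns.values()}
    if labels == {"null"}:
        return patterns, "null"
    if len(labels) == 1:
        return patterns, "monomorphic"
    return patterns, "polymorphic"


def allele_calls(
    patterns: dict[str, BandPattern],
    insertion_size: int = 205,
    size_tolerance: int = 25,
) -> dict[str, str]:
    """Call insertion/empty/het per line from band sizes.

    The insertion and empty allele sizes are inferred as the pair of
    observed sizes differing by ``insertion_size`` ± ``size_tolerance``;
    lines showing only the larger are ``insertion``, only the smaller
    ``empty``, both ``het``, and anything else ``ambiguous``.
    """
    sizes = sorted({s for p in patterns.values() for s in p.amplicon_sizes})
    pair = None
    for i, small in enumerate(sizes):
        for large in sizes[i + 1 :]:
            if abs((large - small) - insertion_size) <= size_tolerance:
                pair = (small, large)
                break
        if pair:
            break
    calls = {}
    for ln, p in patterns.items():
        if pair is None:
            calls[ln] = "ambiguous" if p.amplicon_sizes else "null"
            continue
        small, large = pair
        has_small = small in p.amplicon_sizes
        has_large = large in p.amplicon_sizes
        if has_small and has_large:
            calls[ln] = "het"
        elif has_large:
            calls[ln] = "insertion"
        elif has_small:
            calls[ln] = "empty"
        elif p.is_null:
            calls[ln] = "null"
        else:
            calls[ln] = "ambiguous"
    return calls


def polymorphism_summary(
    matrix: MarkerMatrix,
    groups: dict[str, list[tuple[str, str]]],
    n_tested: int,
) -> PolymorphismSummary:
    """Pairwise polymorphic-marker counts with group averages.

    Percentages are 100 x count / ``n_tested``; averages are arithmetic
    means over the member pairs. Everything is reported to one decimal,
    rounded half-up.
    """
    pairwise = matrix.pairwise_discordance()
    if n_tested < max(pairwise.values(), default=0):
        raise ValueError("n_tested smaller than an observed pairwise count")

    def norm(pair: tuple[str, str]) -> tuple[str, str]:
        if pair in pairwise:
            return pair
        swapped = (pair[1], pair[0])
        if swapped in pairwise:
            return swapped
        raise KeyError(f"line pair {pair} not in matrix")

    pct = {p: round_half_up(100 * c / n_tested) for p, c in pairwise.items()}
    group_avg, group_pct = {}, {}
    for gname, pairs in groups.items():
        counts = [pairwise[norm(p)] for p in pairs]
        avg = sum(counts) / len(counts)
        group_avg[gname] = round_half_up(avg)
        group_pct[gname] = round_half_up(100 * avg / n_tested)
    return PolymorphismSummary(
        n_tested=n_tested,
        pairwise=pairwise,
        pairwise_pct=pct,
        group_averages=group_avg,
        group_pct=group_pct,
    )
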