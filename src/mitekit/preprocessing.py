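"""Read preprocessing for MITE enrichment libraries.

Turns raw enrichment-library reads into per-locus flank pairs through four
steps: Mott-style quality trimming, seed-and-extend masking of vector/linker
and element sequence, a maximum-length filter, flank extraction around the
element footprint, and greedy deduplication of flank pairs into loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib

from ._seq import revcomp

__all__ = [
    "Read",
    "MaskedRead",
    "FlankPair",
    "LocusCluster",
    "trim_by_quality",
    "mask_matches",
    "length_filter",
    "extract_flanks",
    "cluster_loci",
]


@dataclass(frozen=True)
class Read:
    """A called read with per-base Phred qualities."""

    read_id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.read_id}: {len(self.bases)} bases vs {len(self.qualities)} qualities")
        if self.qualities and not (0 <= min(self.qualities) and max(self.qualities) <= 93):
            raise ValueError(f"{self.read_id}: Phred scores must lie in [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MaskedRead:
    """A read with masked intervals recorded as 0-based half-open spans.

    Original bases stay retrievable: masking only records intervals, each
    tagged with its source (``vector`` | ``linker`` | ``element``).
    """

    read_id: str
    bases: str
    intervals: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    def __post_init__(self):
        for start, end, _label in self.intervals:
            if not (0 <= start < end <= len(self.bases)):
                raise ValueError(f"{self.read_id}: interval ({start},{end}) out of bounds")

    def masked_lowercase(self) -> str:
        chars = list(self.bases.upper())
        for start, end, _ in self.intervals:
            for i in range(start, end):
                chars[i] = chars[i].lower()
        return "".join(chars)

    def intervals_for(self, label: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


@dataclass(frozen=True)
class FlankPair:
    """The sequences flanking one element occurrence on a read.

    ``left_flank`` lies 5' of the element on the read's reported strand.
    ``single_flank`` marks reads where the element touches a read end;
    ``multi_hit`` marks reads carrying more than one element interval.
    """

    locus_id: str
    left_flank: str
    right_flank: str
    element_segment: str | None = None
    single_flank: bool = False
    multi_hit: bool = False

    @property
    def total_flank_length(self) -> int:
        return len(self.left_flank) + len(self.right_flank)


@dataclass(frozen=True)
class LocusCluster:
    cluster_id: str
    members: tuple[FlankPair, ...]
    representative: FlankPair


def trim_by_quality(read: Read, q_threshold: int = 20, min_length: int = 10) -> Read:
    """Clip low-quality ends with the maximal-scoring-subsequence rule.

    Each base scores +1 when its Phred value is >= ``q_threshold`` and -2
    otherwise; the retained read is the contiguous stretch maximising the
    total score (Mott trimming). A best score below ``min_length`` empties
    the read. Ties prefer the longer, then the leftmost window.
    """
    # prefix-sum scan; for each end keep the earliest minimal prefix so that
    # equal-score windows prefer the longer, then the leftmost one
    best_score, best = 0, (0, 0)
    prefix = 0
    min_prefix, min_idx = 0, 0
    for i, q in enumerate(read.qualities):
        prefix += 1 if q >= q_threshold else -2
        score = prefix - min_prefix
        cand = (min_idx, i + 1)
        if score > best_score or (
            score == best_score and (cand[1] - cand[0]) > (best[1] - best[0])
        ):
            best_score, best = score, cand
        if prefix < min_prefix:
            min_prefix, min_idx = prefix, i + 1
    if best_score < min_length:
        return replace(read, bases="", qualities=())
    s, e = best
    return replace(read, bases=read.bases[s:e], qualities=read.qualities[s:e])


def _merge_intervals(intervals: list[tuple[int, int, str]]) -> tuple[tuple[int, int, str], ...]:
    """Merge overlapping/adjacent intervals sharing a label."""
    out: list[tuple[int, int, str]] = []
    for start, end, label in sorted(intervals):
        if out and out[-1][2] == label and start <= out[-1][1]:
            prev = out[-1]
            out[-1] = (prev[0], max(prev[1], end), label)
        else:
            out.append((start, end, label))
    return tuple(out)


def _extend_seed(seq: str, pat: str, qpos: int, ppos: int, seedlen: int, mismatch_penalty: int) -> tuple[int, int, int]:
    """Ungapped extension of an exact seed to its local score maximum.

    Returns (start, end, score) on the query, scoring +1 per match and
    ``mismatch_penalty`` per mismatch in both directions.
    """
    # ties in extension score prefer the longer interval (mask more)
    score = seedlen
    best_right, cur = qpos + seedlen, score
    i, j = qpos + seedlen, ppos + seedlen
    while i < len(seq) and j < len(pat):
        cur += 1 if seq[i] == pat[j] else mismatch_penalty
        i += 1
        j += 1
        if cur >= score:
            score, best_right = cur, i
    best_left, cur = qpos, score
    i, j = qpos - 1, ppos - 1
    while i >= 0 and j >= 0:
        cur += 1 if seq[i] == pat[j] else mismatch_penalty
        if cur >= score:
            score, best_left = cur, i
        i -= 1
        j -= 1
    return best_left, best_right, score


def mask_matches(
    seq: str,
    patterns: list[tuple[str, str]],
    min_match: int = 10,
    min_score: int = 18,
    mismatch_penalty: int = -2,
    read_id: str = "seq",
) -> MaskedRead:
    """Mask every interval locally similar to any pattern, on either strand.

    Similarity is exact-seed (``min_match`` bases) plus ungapped extension
    under +1/``mismatch_penalty`` scoring; an interval is masked when its
    extension score reaches ``min_score``. Element masking in the published
    protocol used a longer seed and higher score threshold (12/20) than
    vector/linker masking (10/18); pass those through the parameters.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    for label, pat in patterns:
        if len(pat) < min_match:
            raise ValueError(f"pattern {label!r} shorter than min_match={min_match}")
    sequ = seq.upper()
    hits: list[tuple[int, int, str]] = []
    for label, pat in patterns:
        for oriented in (pat.upper(), revcomp(pat.upper())):
            seed_index: dict[str, list[int]] = {}
            for j in range(len(oriented) - min_match + 1):
                seed_index.setdefault(oriented[j : j + min_match], []).append(j)
            seen_spans: set[tuple[int, int]] = set()
            for i in range(len(sequ) - min_match + 1):
                kmer = sequ[i : i + min_match]
                for j in seed_index.get(kmer, ()):
                    start, end, score = _extend_seed(sequ, oriented, i, j, min_match, mismatch_penalty)
                    if score >= min_score and (start, end) not in seen_spans:
                        seen_spans.add((start, end))
                        hits.append((start, end, label))
    return MaskedRead(read_id=read_id, bases=seq, intervals=_merge_intervals(hits))


def zero_masked_qualities(read: Read, masked: MaskedRead) -> Read:
    """Set the quality of every masked base to zero, so a following
    Mott trim clips masked sequence together with low-quality sequence."""
    qs = list(read.qualities)
    for start, end, _ in masked.intervals:
        for i in range(start, end):
            qs[i] = 0
    return replace(read, qualities=tuple(qs))


def preprocess_read(
    read: Read,
    linker_patterns: list[tuple[str, str]],
    element_patterns: list[tuple[str, str]],
    q_threshold: int = 20,
    min_length: int = 10,
) -> FlankPair | None:
    """Canonical per-read pipeline: mask vector/linker, clip masked and
    low-quality sequence in one Mott pass, mask the element with the
    stricter seed/score settings, then split into flanks."""
    m1 = mask_matches(read.bases, linker_patterns, 10, 18, -2, read_id=read.read_id)
    clipped = trim_by_quality(zero_masked_qualities(read, m1), q_threshold, min_length)
    if not len(clipped):
        return None
    m2 = mask_matches(clipped.bases, element_patterns, 12, 20, -2, read_id=read.read_id)
    return extract_flanks(m2)


def length_filter(reads: list[Read], max_length: int = 1000) -> list[Read]:
    """Drop reads strictly longer than ``max_length`` bases, keeping order."""
    return [r for r in reads if len(r) <= max_length]


def extract_flanks(masked: MaskedRead) -> FlankPair | None:
    """Split a masked read around its element footprint.

    The longest element-labelled interval defines the element; everything
    5' of it (minus any vector/linker mask touching the read end) is the
    left flank and everything 3' the right flank. Returns ``None`` when no
    element interval exists.
    """
    element_spans = masked.intervals_for("element")
    if not element_spans:
        return None
    multi = len(element_spans) > 1
    start, end = max(element_spans, key=lambda se: (se[1] - se[0], -se[0]))
    # clip linker/vector masks anchored at the read ends off the flanks
    non_elem = [(s, e) for s, e, lab in masked.intervals if lab != "element"]
    left_cut = 0
    for s, e in sorted(non_elem):
        if s <= left_cut and e <= start:
            left_cut = max(left_cut, e)
    right_cut = len(masked.bases)
    for s, e in sorted(non_elem, reverse=True):
        if e >= right_cut and s >= end:
            right_cut = min(right_cut, s)
    left = masked.bases[left_cut:start]
    right = masked.bases[end:right_cut]
    single = (len(left) == 0) or (len(right) == 0)
    return FlankPair(
        locus_id=masked.read_id,
        left_flank=left,
        right_flank=right,
        element_segment=masked.bases[start:end],
        single_flank=single,
        multi_hit=multi,
    )


def _flank_similar(a: str, b: str, identity: float, min_overlap: float) -> bool:
    """True when the shorter sequence aligns within the longer at the
    required identity. Infix alignment always spans the whole shorter
    sequence, so the ``min_overlap`` fraction is satisfied by construction."""
    if not a or not b:
        return False
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return False
    return 1 - dist / len(short) >= identity


def cluster_loci(
    flank_pairs: list[FlankPair],
    identity: float = 0.95,
    min_overlap: float = 0.8,
) -> list[LocusCluster]:
    """Greedy deduplication of flank pairs into loci.

    Pairs are processed by decreasing total flank length (ties broken
    lexicographically by sequence then id, for determinism) and joined to
    the first existing cluster whose representative matches on either
    flank at >= ``identity`` over >= ``min_overlap`` of the shorter
    sequence. The representative is the longest member.
    """
    ordered = sorted(
        flank_pairs,
        key=lambda fp: (-fp.total_flank_length, fp.left_flank + fp.right_flank, fp.locus_id),
    )
    clusters: list[list[FlankPair]] = []
    for fp in ordered:
        placed = False
        for members in clusters:
            rep = members[0]
            if _flank_similar(fp.left_flank, rep.left_flank, identity, min_overlap) or _flank_similar(
                fp.right_flank, rep.right_flank, identity, min_overlap
            ):
                members.append(fp)
                placed = True
                break
        if not placed:
            clusters.append([fp])
    out = []
    for k, members in enumerate(clusters):
        rep = max(members, key=lambda fp: (fp.total_flank_length, fp.left_flank + fp.right_flank))
        out.append(LocusCluster(cluster_id=f"locus{k:04d}", members=tuple(members), representative=rep))
    return out
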