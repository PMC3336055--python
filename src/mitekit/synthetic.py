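"""Synthetic genomes, enrichment libraries, mutant panels and marker
matrices with known ground truth.

The generator emulates the structure of a peanut-style MITE family:
elements of 201-223 bp bounded by 25 bp terminal inverted repeats, AT-rich
9 bp target-site duplications, element GC around 30% inside a 39% GC
background, six subfamilies drawn from a pool of seven TIR sequences (one
TIR shared between pairings), a majority of insertions with perfectly
matching TSD copies, and rare excision events that leave footprints.
Every downstream stage can be validated against the emitted truth records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import LinearConstraint, milp

import edlib

from ._seq import at_fraction, hamming, iupac_match, mutate, random_dna, random_dna_exact_gc, revcomp
from .markers import MarkerMatrix
from .preprocessing import Read
from .excision import LocusReference

__all__ = [
    "FamilySpec",
    "InsertionTruth",
    "SimulationConfig",
    "simulate_families",
    "simulate_genome_with_insertions",
    "simulate_enrichment_reads",
    "simulate_mutant_panel",
    "simulate_marker_matrix",
    "DEFAULT_LINKERS",
    "DEFAULT_PROBE",
]

# enrichment-library linker pair and degenerate hybridisation probe used as
# defaults by the simulated protocol (M = A/C)
DEFAULT_LINKERS = ("GTTTAGCCTTGTAGCAGAAGC", "GCTTCTGCTACAAGGCTAAAC")
DEFAULT_PROBE = "AAGGTGGATACTACMATGAAGAT"

# realised pairing counts of the six default families (subfamily mixture
# proportions over 273 assigned elements)
DEFAULT_FAMILY_WEIGHTS = (29, 142, 55, 24, 13, 10)
# (left TIR, right TIR) pool indices per family; families 4 and 6 share a
# pairing and TIR6 (index 5) appears in three patterns
DEFAULT_PAIRINGS = ((0, 0), (1, 2), (3, 4), (5, 6), (0, 5), (5, 6))


@dataclass(frozen=True)
class FamilySpec:
    """One element subfamily: consensus plus its TIR pairing."""

    family_id: str
    consensus: str
    tir_left: str
    tir_right: str
    weight: float

    def __post_init__(self):
        if not self.consensus.startswith(self.tir_left):
            raise ValueError(f"{self.family_id}: consensus must begin with its left TIR")
        if not self.consensus.endswith(revcomp(self.tir_right)):
            raise ValueError(f"{self.family_id}: consensus must end with the reverse complement of its right TIR")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"{self.family_id}: weight outside [0,1]")


@dataclass
class InsertionTruth:
    """Ground truth for one planted insertion.

    ``genome_position`` is the 0-based start of the left TSD copy in the
    final (insertion-bearing) genome; the element occupies
    [genome_position + tsd_length, genome_position + tsd_length + len).
    """

    locus_id: str
    genome_position: int
    family_id: str
    tsd: str
    tsd_right: str
    element_seq: str
    planted_mutations: list[tuple[int, str, str]] = field(default_factory=list)
    excised_in: dict[str, str] = field(default_factory=dict)

    @property
    def tsd_mismatches(self) -> int:
        return hamming(self.tsd, self.tsd_right)

    @property
    def perfect_tsd(self) -> bool:
        return self.tsd_mismatches == 0


@dataclass
class SimulationConfig:
    genome_length: int = 300_000
    n_insertions: int = 504
    element_gc: float = 0.301
    background_gc: float = 0.389
    tsd_length: int = 9
    tir_length: int = 25
    mismatch_load: float = 0.02
    fraction_perfect_tsd: float = 286 / 504
    read_error_rate: float = 0.0
    at_rich_threshold: float = 6 / 9
    decoy_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("element_gc", "background_gc", "mismatch_load", "fraction_perfect_tsd",
                     "read_error_rate", "at_rich_threshold", "decoy_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        for name in ("genome_length", "tsd_length", "tir_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_insertions < 0:
            raise ValueError("n_insertions must be >= 0")


def _tir_pool(rng: np.random.Generator, size: int, tir_length: int, gc: float, min_sep: int = 10) -> list[str]:
    """Mutually well-separated TIR sequences so downstream clustering cannot
    merge distinct pool members (pairwise Hamming >= min_sep)."""
    pool: list[str] = []
    while len(pool) < size:
        cand = random_dna_exact_gc(rng, tir_length, gc)
        if all(hamming(cand, p) >= min_sep for p in pool):
            pool.append(cand)
    return pool


def simulate_families(
    n_families: int,
    seed: int,
    element_gc: float = 0.301,
    tir_length: int = 25,
    length_range: tuple[int, int] = (201, 223),
    weights: tuple[float, ...] | None = None,
) -> list[FamilySpec]:
    """Draw subfamily consensuses over a shared pool of TIR sequences.

    Pairings follow the canonical six-family layout (one TIR recurring in
    several patterns, two families sharing a full pairing) cycled for
    other family counts. Internal sequences are resampled until every
    family pair is below 90% identity outside the TIRs.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    pool = _tir_pool(rng, 7, tir_length, element_gc)
    pairings = [DEFAULT_PAIRINGS[i % len(DEFAULT_PAIRINGS)] for i in range(n_families)]
    if weights is None:
        if n_families == len(DEFAULT_FAMILY_WEIGHTS):
            w = np.array(DEFAULT_FAMILY_WEIGHTS, dtype=float)
        else:
            w = np.ones(n_families)
        weights = tuple(w / w.sum())
    families: list[FamilySpec] = []
    internals: list[str] = []
    for k in range(n_families):
        li, ri = pairings[k]
        # lengths pile up near the short end of the range (family means a
        # few bases above the minimum, occasional long outliers)
        lo, hi = length_range
        length = int(lo + min(hi - lo, rng.geometric(0.22) - 1))
        internal_len = length - 2 * tir_length
        while True:
            internal = random_dna_exact_gc(rng, internal_len, element_gc)
            identities = (
                1 - edlib.align(internal, other, mode="NW", task="distance")["editDistance"]
                / max(len(internal), len(other))
                for other in internals
            )
            if all(ident < 0.9 for ident in identities):
                break
        internals.append(internal)
        consensus = pool[li] + internal + revcomp(pool[ri])
        families.append(
            FamilySpec(
                family_id=f"fam{k + 1}",
                consensus=consensus,
                tir_left=pool[li],
                tir_right=pool[ri],
                weight=float(weights[k]),
            )
        )
    return families


def _largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation matching the weights exactly in proportion."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def simulate_genome_with_insertions(
    config: SimulationConfig,
    families: list[FamilySpec],
) -> tuple[str, list[InsertionTruth]]:
    """Plant element insertions at AT-rich sites of a random background.

    At each chosen site the resident 9-mer is duplicated around the
    element (the TSD). A fraction of insertions — ``fraction_perfect_tsd``,
    allocated exactly — are planted unmutated ("new" insertions); the rest
    receive 1-9 mismatches in the right TSD copy and substitutions in the
    element at ``mismatch_load`` per base ("old" insertions). Family
    membership is allocated exactly in proportion to the family weights.
    """
    rng = np.random.default_rng(config.seed)
    genome = random_dna(rng, config.genome_length, config.background_gc)
    if config.n_insertions == 0:
        return genome, []

    tsd_len = config.tsd_length
    max_elem = max(len(f.consensus) for f in families)
    spacing = max_elem + 2 * tsd_len + 120  # room for flanks between loci
    candidates = []
    last = -spacing
    for p in range(60, config.genome_length - spacing - 60):
        if p - last < spacing:
            continue
        if at_fraction(genome[p : p + tsd_len]) >= config.at_rich_threshold:
            candidates.append(p)
            last = p
    if len(candidates) < config.n_insertions:
        raise ValueError(
            f"only {len(candidates)} AT-rich insertion sites available for "
            f"{config.n_insertions} requested insertions; increase genome_length"
        )
    sites = np.sort(rng.choice(len(candidates), size=config.n_insertions, replace=False))
    positions = [candidates[i] for i in sites]

    weights = np.array([f.weight for f in families], dtype=float)
    fam_counts = _largest_remainder_counts(weights, config.n_insertions)
    fam_ids = np.repeat(np.arange(len(families)), fam_counts)
    rng.shuffle(fam_ids)

    n_perfect = int(round(config.fraction_perfect_tsd * config.n_insertions))
    perfect = np.zeros(config.n_insertions, dtype=bool)
    perfect[rng.choice(config.n_insertions, size=n_perfect, replace=False)] = True

    pieces: list[str] = []
    truth: list[InsertionTruth] = []
    prev = 0
    offset = 0
    for k, p in enumerate(positions):
        fam = families[int(fam_ids[k])]
        tsd = genome[p : p + tsd_len]
        if perfect[k]:
            element, muts = fam.consensus, []
            tsd_right = tsd
        else:
            element, muts = mutate(rng, fam.consensus, config.mismatch_load)
            n_mm = int(rng.integers(1, tsd_len + 1))
            mm_pos = rng.choice(tsd_len, size=n_mm, replace=False)
            tr = list(tsd)
            for i in mm_pos:
                tr[i] = str(rng.choice([b for b in "ACGT" if b != tsd[i]]))
            tsd_right = "".join(tr)
        pieces.append(genome[prev : p + tsd_len])
        pieces.append(element + tsd_right)
        truth.append(
            InsertionTruth(
                locus_id=f"site{k:04d}",
                genome_position=p + offset,
                family_id=fam.family_id,
                tsd=tsd,
                tsd_right=tsd_right,
                element_seq=element,
                planted_mutations=muts,
            )
        )
        offset += len(element) + tsd_len
        prev = p + tsd_len
    pieces.append(genome[prev:])
    return "".join(pieces), truth


def _quality_profile(length: int, q_high: int = 40, q_low: int = 10, midpoint: float = 8.0, scale: float = 3.0) -> tuple[int, ...]:
    """Phred values rising logistically from the read ends toward the middle."""
    qs = []
    for i in range(length):
        d = min(i, length - 1 - i)
        q = q_low + (q_high - q_low) / (1 + np.exp(-(d - midpoint) / scale))
        qs.append(int(round(q)))
    return tuple(qs)


def _probe_hits_element(probe: str, element: str) -> bool:
    for target in (element, revcomp(element)):
        for off in range(len(target) - len(probe) + 1):
            if all(iupac_match(p, t) for p, t in zip(probe, target[off : off + len(probe)])):
                return True
    return False


def simulate_enrichment_reads(
    genome: str,
    truth: list[InsertionTruth],
    config: SimulationConfig,
    n_reads: int = 1000,
    probe: str | None = None,
    linkers: tuple[str, str] = DEFAULT_LINKERS,
    min_flank: int = 30,
    max_flank: int = 140,
) -> list[Read]:
    """Reads from an enrichment library: linker + element-bearing fragment +
    linker, with Phred qualities degrading toward the read ends.

    A ``config.decoy_fraction`` of reads are element-free background
    fragments, emulating imperfect enrichment. When a probe is given it
    must match at least one planted element under IUPAC semantics.
    """
    rng = np.random.default_rng(config.seed + 1)
    if n_reads == 0:
        return []
    if probe is not None and truth and not any(
        _probe_hits_element(probe, t.element_seq) for t in truth
    ):
        raise ValueError("probe matches no planted element under IUPAC semantics")
    n_decoy = int(round(config.decoy_fraction * n_reads))
    n_signal = n_reads - n_decoy
    reads: list[Read] = []
    for k in range(n_signal):
        t = truth[k % len(truth)]
        elem_start = t.genome_position + config.tsd_length
        elem_end = elem_start + len(t.element_seq)
        left_ext = int(rng.integers(min_flank, max_flank + 1)) + config.tsd_length
        right_ext = int(rng.integers(min_flank, max_flank + 1)) + config.tsd_length
        start = max(0, elem_start - left_ext)
        end = min(len(genome), elem_end + right_ext)
        frag = genome[start:end]
        bases = linkers[0] + frag + linkers[1]
        if config.read_error_rate > 0:
            bases, _ = mutate(rng, bases, config.read_error_rate)
        reads.append(Read(read_id=f"read{k:05d}_{t.locus_id}", bases=bases, qualities=_quality_profile(len(bases))))
    for k in range(n_decoy):
        length = int(rng.integers(200, 500))
        while True:
            start = int(rng.integers(0, max(1, len(genome) - length)))
            window = (start, start + length)
            if not any(
                t.genome_position < window[1] and window[0] < t.genome_position + 2 * config.tsd_length + len(t.element_seq)
                for t in truth
            ):
                break
        bases = linkers[0] + genome[start : start + length] + linkers[1]
        if config.read_error_rate > 0:
            bases, _ = mutate(rng, bases, config.read_error_rate)
        reads.append(Read(read_id=f"decoy{k:05d}", bases=bases, qualities=_quality_profile(len(bases))))
    return reads


FOOTPRINT_BUILDERS = ("clean", "substitution", "tsd_insertion", "tir_tsd_insertion")


def build_locus_references(
    genome: str,
    truth: list[InsertionTruth],
    tsd_length: int = 9,
    flank: int = 150,
) -> dict[str, LocusReference]:
    """Full/empty allele pairs for each planted locus, cut from the genome."""
    refs = {}
    for t in truth:
        p = t.genome_position
        left = genome[max(0, p - flank) : p]
        elem_start = p + tsd_length
        elem_end = elem_start + len(t.element_seq)
        right = genome[elem_end + tsd_length : elem_end + tsd_length + flank]
        refs[t.locus_id] = LocusReference(
            locus_id=t.locus_id,
            full_allele=left + t.tsd + t.element_seq + t.tsd_right + right,
            empty_allele=left + t.tsd + right,
            tsd=t.tsd,
            tir_terminal=t.element_seq[-1],
        )
    return refs


def _footprint_allele(ref: LocusReference, footprint: str, rng: np.random.Generator) -> str:
    """The empty allele carrying the requested footprint edit at the
    excision junction (junction = 3' end of the retained TSD copy)."""
    empty = ref.empty_allele
    junction = empty.index(ref.tsd) + len(ref.tsd) if ref.tsd in empty else len(empty) // 2
    if footprint == "clean":
        return empty
    if footprint == "substitution":
        pos = junction - len(ref.tsd) - 2  # a flank base just 5' of the TSD
        old = empty[pos]
        new = {"T": "C", "C": "T", "A": "G", "G": "A"}[old.upper()]
        return empty[:pos] + new + empty[pos + 1 :]
    if footprint == "tsd_insertion":
        return empty[:junction] + ref.tsd[:2] + empty[junction:]
    if footprint == "tir_tsd_insertion":
        return empty[:junction] + ref.tir_terminal + ref.tsd[0] + empty[junction:]
    raise ValueError(f"unknown footprint class {footprint!r}")


def simulate_mutant_panel(
    genome: str,
    loci: list[InsertionTruth],
    n_lines: int,
    planted_events: list[tuple[str, str, str, str]],
    seed: int,
    tsd_length: int = 9,
    flank: int = 150,
) -> tuple[dict[str, dict[str, tuple[str, str]]], dict[str, LocusReference]]:
    """Diploid allele sequences for a mutant panel.

    ``planted_events`` entries are (line_id, locus_id, zygosity, footprint
    class) with zygosity ``het`` or ``hom_empty``; every other line x locus
    carries two insertion-bearing haplotypes. Lines are named line01..;
    duplicate (line, locus) events raise a conflict error.
    """
    rng = np.random.default_rng(seed)
    lines = [f"line{k + 1:02d}" for k in range(n_lines)]
    refs = build_locus_references(genome, loci, tsd_length, flank)
    seen: set[tuple[str, str]] = set()
    events_by_key: dict[tuple[str, str], tuple[str, str]] = {}
    for line_id, locus_id, zygosity, footprint in planted_events:
        if line_id not in lines:
            raise ValueError(f"unknown line {line_id!r}")
        if locus_id not in refs:
            raise ValueError(f"unknown locus {locus_id!r}")
        if (line_id, locus_id) in seen:
            raise ValueError(f"conflicting duplicate event for ({line_id}, {locus_id})")
        seen.add((line_id, locus_id))
        events_by_key[(line_id, locus_id)] = (zygosity, footprint)
        next(t for t in loci if t.locus_id == locus_id).excised_in[line_id] = footprint
    panel: dict[str, dict[str, tuple[str, str]]] = {}
    for line_id in lines:
        panel[line_id] = {}
        for t in loci:
            ref = refs[t.locus_id]
            ev = events_by_key.get((line_id, t.locus_id))
            if ev is None:
                panel[line_id][t.locus_id] = (ref.full_allele, ref.full_allele)
            else:
                zyg, footprint = ev
                excised = _footprint_allele(ref, footprint, rng)
                if zyg == "het":
                    panel[line_id][t.locus_id] = (ref.full_allele, excised)
                elif zyg == "hom_empty":
                    panel[line_id][t.locus_id] = (excised, excised)
                else:
                    raise ValueError(f"unknown zygosity {zyg!r}")
    return panel, refs


def _set_partitions(items: list[str]):
    """All partitions of a small label set (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def simulate_marker_matrix(
    n_lines: int,
    n_loci: int,
    target_pairwise_discordance: dict[tuple[str, str], int],
    seed: int,
) -> MarkerMatrix:
    """A band-pattern matrix whose pairwise discordance counts equal the
    targets exactly.

    Each locus assigns lines a categorical pattern; a locus is discordant
    for a pair when the patterns differ, so a locus corresponds to a set
    partition of the lines and the construction solves an exact integer
    allocation over all partitions (multi-state patterns appear whenever
    two-state loci cannot realise the targets, e.g. when a triple's
    pairwise counts sum to an odd number). Remaining loci are monomorphic.
    """
    lines = sorted({ln for pair in target_pairwise_discordance for ln in pair})
    if len(lines) != n_lines:
        raise ValueError(f"targets name {len(lines)} lines but n_lines={n_lines}")
    targets = {}
    for (a, b), v in target_pairwise_discordance.items():
        key = (a, b) if a < b else (b, a)
        targets[key] = int(v)
    pairs = list(combinations(lines, 2))
    if set(targets) != set(pairs):
        raise ValueError("targets must cover every unordered line pair exactly once")
    for a, b, c in combinations(lines, 3):
        dab, dac, dbc = targets[(a, b)], targets[(a, c)], targets[(b, c)]
        if dab > dac + dbc or dac > dab + dbc or dbc > dab + dac:
            raise ValueError(f"infeasible targets: triangle inequality fails for ({a}, {b}, {c})")

    parts = [p for p in _set_partitions(lines) if len(p) > 1]
    A = np.zeros((len(pairs), len(parts)))
    for j, part in enumerate(parts):
        block_of = {ln: i for i, blk in enumerate(part) for ln in blk}
        for i, (a, b) in enumerate(pairs):
            A[i, j] = 1.0 if block_of[a] != block_of[b] else 0.0
    b_vec = np.array([targets[p] for p in pairs], dtype=float)
    # prefer fewer polymorphic loci, and among those fewer multi-state ones
    cost = np.array([1.0 + 0.01 * (len(p) - 2) for p in parts])
    constraints = [
        LinearConstraint(A, b_vec, b_vec),
        LinearConstraint(np.ones(len(parts)), 0, n_loci),
    ]
    res = milp(c=cost, constraints=constraints, integrality=np.ones(len(parts)))
    if not res.success:
        raise ValueError("infeasible targets: no multi-state construction fits within n_loci")
    counts = np.round(res.x).astype(int)

    rng = np.random.default_rng(seed)
    locus_parts: list[list[list[str]]] = []
    for j, c in enumerate(counts):
        locus_parts.extend([parts[j]] * int(c))
    locus_parts.extend([[list(lines)]] * (n_loci - len(locus_parts)))
    order = rng.permutation(len(locus_parts))
    markers = tuple(f"m{k + 1:04d}" for k in range(n_loci))
    patterns: dict[tuple[str, str], str] = {}
    state_names = "ABCDEFGHIJ"
    for k, idx in enumerate(order):
        part = locus_parts[idx]
        for i, blk in enumerate(sorted(part, key=min)):
            for ln in blk:
                patterns[(ln, markers[k])] = state_names[i]
    matrix = MarkerMatrix(lines=tuple(lines), markers=markers, patterns=patterns)
    realised = matrix.pairwise_discordance()
    assert all(realised[p] == targets[p] for p in pairs), "internal: discordance targets not met"
    return matrix
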