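"""Small DNA helpers shared across the package: IUPAC set algebra, GC content,
reverse complement, and GC-targeted random sequence generation."""

from __future__ import annotations

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

# code -> frozenset of plain bases it covers (e.g. "S" -> {G, C})
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
# frozenset of plain bases -> minimal covering IUPAC code
SETS_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

PLAIN = "ACGT"


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def complement(base: str) -> str:
    return str(Seq(base).complement())


def iupac_set(base: str) -> frozenset[str]:
    try:
        return IUPAC_SETS[base.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC DNA code: {base!r}") from None


def covering_code(bases) -> str:
    """Minimal IUPAC code whose base set equals the union of the given bases."""
    union = frozenset().union(*(iupac_set(b) for b in bases))
    return SETS_TO_CODE[union]


def iupac_compatible(a: str, b: str) -> bool:
    """True when the IUPAC base sets of a and b intersect."""
    return bool(iupac_set(a) & iupac_set(b))


def iupac_match(pattern_base: str, plain_base: str) -> bool:
    """True when a plain template base is covered by an IUPAC primer base."""
    return plain_base.upper() in iupac_set(pattern_base)


def gc_fraction(seq: str) -> float:
    """G+C over unambiguous A/C/G/T calls; ambiguity codes are excluded from
    both numerator and denominator."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in PLAIN)
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


def at_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in PLAIN)
    if acgt == 0:
        return float("nan")
    return (s.count("A") + s.count("T")) / acgt


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with expected GC content ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(PLAIN), size=length, p=p))


def random_dna_exact_gc(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence whose G+C count is exactly round(gc * length)."""
    n_gc = int(round(gc * length))
    bases = [str(b) for b in rng.choice(["G", "C"], size=n_gc)] + [
        str(b) for b in rng.choice(["A", "T"], size=length - n_gc)
    ]
    rng.shuffle(bases)
    return "".join(bases)


def mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply i.i.d. substitutions at the given per-base rate.

    Returns the mutated sequence and the list of (offset, original, new) edits.
    """
    bases = list(seq)
    edits: list[tuple[int, str, str]] = []
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for i in hits:
        old = bases[i]
        new = rng.choice([b for b in PLAIN if b != old.upper()])
        bases[i] = str(new)
        edits.append((int(i), old, str(new)))
    return "".join(bases), edits
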