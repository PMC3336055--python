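"""File-format adapters: FASTA, FASTQ (Phred+33), GFF3, BED, PHYLIP square,
Newick and TSV. Thin wrappers over Biopython and pandas with positioned
validation errors; every writer round-trips through its reader."""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylogeny import DistanceMatrix
from .preprocessing import MaskedRead, Read

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


def _check_dna(seq: str, record_id: str, path) -> None:
    bad = set(seq.upper()) - IUPAC_DNA
    if bad:
        raise ValueError(f"{path}: record {record_id!r} contains non-IUPAC characters {sorted(bad)}")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        _check_dna(seq, rec.id, path)
        out[rec.id] = seq
    return out


def write_fasta(path, seqs: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path) -> list[Read]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = str(rec.seq)
            _check_dna(seq, rec.id, path)
            reads.append(Read(rec.id, seq, tuple(rec.letter_annotations["phred_quality"])))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return reads


def write_fastq(path, reads: list[Read]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_masked_fasta(path, masked: list[MaskedRead]) -> None:
    """Lowercase-masked FASTA representation of masked reads."""
    write_fasta(path, {m.read_id: m.masked_lowercase() for m in masked})


def write_bed(path, masked: list[MaskedRead]) -> None:
    """Masked intervals as BED (0-based half-open, name = mask source)."""
    with open(path, "w") as fh:
        for m in masked:
            for start, end, label in m.intervals:
                fh.write(f"{m.read_id}\t{start}\t{end}\t{label}\n")


def write_gff3(path, elements, tsd_length: int = 9) -> None:
    """Element annotations as GFF3: one parent feature per element with
    child TIR and TSD features (1-based fully-closed coordinates, as the
    format requires; element coordinates are locus-local)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            n = el.length
            eid = el.locus_id
            fh.write(f"{eid}\tmitekit\tmobile_genetic_element\t1\t{n}\t.\t+\t.\tID={eid}\n")
            if el.tir is not None:
                t = len(el.tir.left)
                fh.write(f"{eid}\tmitekit\tterminal_inverted_repeat\t1\t{t}\t.\t+\t.\tID={eid}.tirL;Parent={eid}\n")
                fh.write(f"{eid}\tmitekit\tterminal_inverted_repeat\t{n - t + 1}\t{n}\t.\t-\t.\tID={eid}.tirR;Parent={eid}\n")


def write_phylip(path, dm: DistanceMatrix) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, lab in enumerate(dm.labels):
            row = " ".join(f"{dm.d[i, j]:.6f}" for j in range(len(dm.labels)))
            fh.write(f"{lab[:10]:<10} {row}\n")


def read_phylip(path) -> DistanceMatrix:
    import numpy as np

    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(labels) != n:
        raise ValueError(f"{path}: header says {n} taxa, found {len(labels)}")
    return DistanceMatrix(labels=tuple(labels), d=np.array(rows))


def write_newick(path, tree) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_primer_tsv(path):
    """Primer table: columns marker_id, forward, reverse[, size_min, size_max]."""
    from .markers import PrimerPair

    df = read_tsv(path)
    required = {"marker_id", "forward", "reverse"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: primer table needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        size_range = (
            (int(row["size_min"]), int(row["size_max"]))
            if "size_min" in df.columns
            else (300, 600)
        )
        out.append(PrimerPair(row["marker_id"], row["forward"], row["reverse"], size_range))
    return out
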