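"""End-to-end orchestration of the synthetic MITE analysis.

Stages: simulate -> preprocess -> annotate -> phylo -> markers -> excision.
Each stage writes its artifacts under the run directory and contributes
counts to the run report; a manifest of output hashes makes reruns with the
same configuration verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, excision, io, markers, phylogeny, preprocessing, synthetic
from ._seq import revcomp

STAGES = ("simulate", "preprocess", "annotate", "phylo", "markers", "excision")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "mitekit_run"
    stages: tuple[str, ...] = STAGES
    # simulation scale
    genome_length: int = 300_000
    n_insertions: int = 504
    n_families: int = 6
    n_reads: int = 800
    element_gc: float = 0.301
    background_gc: float = 0.389
    fraction_perfect_tsd: float = 286 / 504
    mismatch_load: float = 0.02
    read_error_rate: float = 0.0
    decoy_fraction: float = 0.2
    # analysis parameters
    q_threshold: int = 20
    max_read_length: int = 1000
    cluster_identity: float = 0.95
    max_cluster_mismatch: int = 3
    subfamily_max_within: float = 0.15
    subfamily_min_size: int = 3
    phylo_max_elements: int = 120
    # excision panel
    panel_lines: int = 60
    panel_loci: int = 109
    preexisting_fraction: float = 0.10

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in data:
            data = {**data, "stages": tuple(data["stages"])}
        return cls(**data)


@dataclass
class RunReport:
    config: dict
    counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "counts": self.counts, "tables": self.tables, "manifest": self.manifest},
            indent=2,
            sort_keys=True,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    counts = report.counts

    (out / "config.txt").write_text(
        "".join(f"{k}={v}\n" for k, v in sorted(asdict(config).items()))
    )

    # ---- simulate -------------------------------------------------------
    sim_cfg = synthetic.SimulationConfig(
        genome_length=config.genome_length,
        n_insertions=config.n_insertions,
        element_gc=config.element_gc,
        background_gc=config.background_gc,
        fraction_perfect_tsd=config.fraction_perfect_tsd,
        mismatch_load=config.mismatch_load,
        read_error_rate=config.read_error_rate,
        decoy_fraction=config.decoy_fraction,
        seed=_stage_seed(config.seed, "simulate"),
    )
    families = synthetic.simulate_families(
        config.n_families, seed=_stage_seed(config.seed, "families"), element_gc=config.element_gc
    )
    genome, truth = synthetic.simulate_genome_with_insertions(sim_cfg, families)
    reads = synthetic.simulate_enrichment_reads(genome, truth, sim_cfg, n_reads=config.n_reads)
    if "simulate" in config.stages:
        io.write_fasta(out / "genome.fasta", {"genome": genome})
        io.write_fastq(out / "reads.fastq", reads)
        io.write_tsv(
            out / "truth.tsv",
            pd.DataFrame(
                {
                    "locus_id": [t.locus_id for t in truth],
                    "genome_position": [t.genome_position for t in truth],
                    "family_id": [t.family_id for t in truth],
                    "tsd": [t.tsd for t in truth],
                    "tsd_mismatches": [t.tsd_mismatches for t in truth],
                    "element_length": [len(t.element_seq) for t in truth],
                }
            ),
        )
    counts["insertions"] = len(truth)
    counts["reads"] = len(reads)

    # ---- preprocess -----------------------------------------------------
    masked_reads: list[preprocessing.MaskedRead] = []
    flank_pairs: list[preprocessing.FlankPair] = []
    clusters: list[preprocessing.LocusCluster] = []
    if "preprocess" in config.stages:
        linker_patterns = [("linker", lk) for lk in synthetic.DEFAULT_LINKERS]
        element_patterns = [("element", f.consensus) for f in families]
        kept = preprocessing.length_filter(reads, config.max_read_length)
        trimmed = []
        for r in kept:
            m1 = preprocessing.mask_matches(r.bases, linker_patterns, 10, 18, -2, read_id=r.read_id)
            clipped = preprocessing.trim_by_quality(
                preprocessing.zero_masked_qualities(r, m1), config.q_threshold
            )
            if len(clipped):
                trimmed.append(clipped)
        for r in trimmed:
            m2 = preprocessing.mask_matches(r.bases, element_patterns, 12, 20, -2, read_id=r.read_id)
            masked_reads.append(m2)
            fp = preprocessing.extract_flanks(m2)
            if fp is not None and not fp.single_flank:
                flank_pairs.append(fp)
        clusters = preprocessing.cluster_loci(flank_pairs, config.cluster_identity)
        io.write_masked_fasta(out / "masked.fasta", masked_reads)
        io.write_bed(out / "masked.bed", masked_reads)
        io.write_tsv(
            out / "clusters.tsv",
            pd.DataFrame(
                {
                    "cluster_id": [c.cluster_id for c in clusters],
                    "n_members": [len(c.members) for c in clusters],
                    "representative_id": [c.representative.locus_id for c in clusters],
                }
            ),
        )
        counts["reads_after_trim"] = len(trimmed)
        counts["flank_pairs"] = len(flank_pairs)
        counts["loci"] = len(clusters)

    # ---- annotate -------------------------------------------------------
    elements: list[annotation.MiteElement] = []
    consensuses: list[annotation.TirConsensus] = []
    if "annotate" in config.stages:
        for t in truth:
            left = genome[max(0, t.genome_position - 60) : t.genome_position + sim_cfg.tsd_length]
            estart = t.genome_position + sim_cfg.tsd_length
            eend = estart + len(t.element_seq)
            right = genome[eend : eend + 60 + sim_cfg.tsd_length]
            tsd = annotation.detect_tsd(left, right, sim_cfg.tsd_length)
            tir = annotation.detect_tir(t.element_seq, sim_cfg.tir_length)
            elements.append(annotation.MiteElement(t.locus_id, t.element_seq, tsd, tir))
        perfect = [el for el in elements if el.tsd.perfect]
        tirs = [el.tir.left for el in perfect] + [revcomp(el.tir.right) for el in perfect]
        consensuses, uniques = annotation.build_tir_consensus(tirs, config.max_cluster_mismatch)
        perfect = annotation.annotate_tir_consensuses(perfect, consensuses, config.max_cluster_mismatch)
        pairing, remainder = annotation.classify_pairing(perfect, consensuses, config.max_cluster_mismatch)
        stats = annotation.element_stats(perfect)
        io.write_fasta(out / "tir_consensus.fasta", {c.consensus_id: c.iupac for c in consensuses})
        io.write_gff3(out / "elements.gff3", perfect)
        report.tables["pairing"] = {f"{a}-{b}": n for (a, b), n in sorted(pairing.items())}
        report.tables["element_stats"] = asdict(stats)
        counts["elements"] = len(elements)
        counts["perfect_tsd"] = len(perfect)
        counts["tir_consensuses"] = len(consensuses)
        counts["unique_tirs"] = len(uniques)
        elements = perfect

    # ---- phylo ----------------------------------------------------------
    if "phylo" in config.stages and elements:
        rng = np.random.default_rng(_stage_seed(config.seed, "phylo"))
        subset = elements
        if len(subset) > config.phylo_max_elements:
            idx = np.sort(rng.choice(len(subset), size=config.phylo_max_elements, replace=False))
            subset = [subset[i] for i in idx]
        seqs = {el.locus_id: el.element_seq for el in subset}
        dm = phylogeny.distance_matrix(seqs)
        tree = phylogeny.neighbor_joining(dm)
        assignment = phylogeny.assign_subfamilies(
            dm, seqs, config.subfamily_max_within, config.subfamily_min_size
        )
        io.write_phylip(out / "distances.phylip", dm)
        io.write_newick(out / "tree.nwk", tree)
        io.write_tsv(
            out / "subfamilies.tsv",
            pd.DataFrame(
                {
                    "locus_id": list(assignment.assignment),
                    "subfamily": [assignment.assignment[k] or "unassigned" for k in assignment.assignment],
                }
            ),
        )
        counts["subfamilies"] = assignment.n_subfamilies

    # ---- markers --------------------------------------------------------
    if "markers" in config.stages:
        refs = synthetic.build_locus_references(genome, truth[: min(24, len(truth))], sim_cfg.tsd_length)
        rng = np.random.default_rng(_stage_seed(config.seed, "markers"))
        lines = ("lineA", "lineB", "lineC", "lineD")
        matrix_patterns: dict[tuple[str, str], str] = {}
        marker_ids = []
        n_poly = 0
        for locus_id, ref in refs.items():
            fwd = ref.full_allele[20:40]
            rev = revcomp(ref.full_allele[-40:-20])
            pp = markers.PrimerPair(locus_id, fwd, rev)
            present = {ln: bool(rng.integers(0, 2)) for ln in lines}
            if not any(present.values()):
                present[lines[0]] = True
            amps = {
                ln: markers.in_silico_pcr(ref.full_allele if present[ln] else ref.empty_allele, pp)
                for ln in lines
            }
            patterns, klass = markers.score_marker(amps, marker_id=locus_id)
            n_poly += klass == "polymorphic"
            marker_ids.append(locus_id)
            for ln in lines:
                matrix_patterns[(ln, locus_id)] = patterns[ln].label
        matrix = markers.MarkerMatrix(lines=lines, markers=tuple(marker_ids), patterns=matrix_patterns)
        groups = {"all_pairs": [(a, b) for i, a in enumerate(lines) for b in lines[i + 1 :]]}
        summary = markers.polymorphism_summary(matrix, groups, n_tested=len(marker_ids))
        report.tables["polymorphism"] = {
            "pairwise": {f"{a}|{b}": v for (a, b), v in summary.pairwise.items()},
            "group_averages": summary.group_averages,
            "group_pct": summary.group_pct,
        }
        counts["markers_tested"] = len(marker_ids)
        counts["markers_polymorphic"] = int(n_poly)

    # ---- excision -------------------------------------------------------
    if "excision" in config.stages:
        loci = truth[: config.panel_loci]
        if len(loci) < config.panel_loci:
            raise ValueError("not enough simulated loci for the requested panel")
        if config.panel_lines < 4 or config.panel_loci < 4:
            raise ValueError("excision stage needs at least 4 panel lines and loci")
        lines = [f"line{k + 1:02d}" for k in range(config.panel_lines)]
        # one homozygous-empty and two heterozygous de novo excisions
        planted = [
            (lines[0], loci[0].locus_id, "hom_empty", "substitution"),
            (lines[1], loci[1].locus_id, "het", "tsd_insertion"),
            (lines[2], loci[2].locus_id, "het", "substitution"),
        ]
        # one locus segregating empty alleles before mutagenesis, in just
        # under a quarter of lines (clearly above the pre-existing threshold)
        pre_locus = loci[3].locus_id
        n_pre = max(int(round(14 / 60 * config.panel_lines)),
                    int(config.preexisting_fraction * config.panel_lines) + 1)
        planted += [
            (ln, pre_locus, "hom_empty", "tir_tsd_insertion") for ln in lines[-n_pre:]
        ]
        panel, refs = synthetic.simulate_mutant_panel(
            genome,
            loci,
            config.panel_lines,
            planted,
            seed=_stage_seed(config.seed, "excision"),
            tsd_length=sim_cfg.tsd_length,
        )
        events, freq, flagged = excision.screen_panel(
            panel, refs, preexisting_fraction=config.preexisting_fraction
        )
        io.write_tsv(
            out / "excision_events.tsv",
            pd.DataFrame(
                {
                    "locus_id": [e.locus_id for e in events],
                    "line_id": [e.line_id for e in events],
                    "zygosity": [e.zygosity for e in events],
                    "footprint": [e.footprint for e in events],
                }
            ),
        )
        report.tables["excision_frequency"] = {
            "events": freq.events,
            "lines": freq.lines,
            "loci": freq.loci,
            "ploidy": freq.ploidy,
            "frequency": freq.frequency,
            "reported": freq.report(),
        }
        counts["excision_events"] = freq.events
        counts["preexisting_loci"] = len(flagged)

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "report.json":
            report.manifest[path.name] = _sha256(path)
    (out / "report.json").write_text(report.to_json())
    return report
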