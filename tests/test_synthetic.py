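"""Generator invariants: family structure, insertion mechanics, read
simulation, mutant panels and exact-discordance marker matrices."""

import numpy as np
import pytest

import mitekit as mk
from mitekit import synthetic as syn
from mitekit._seq import at_fraction, gc_fraction, hamming, revcomp


class TestSimulateFamilies:
    def test_six_families_length_range(self, families6):
        assert len(families6) == 6
        for f in families6:
            assert 201 <= len(f.consensus) <= 223
            assert f.consensus.startswith(f.tir_left)
            assert f.consensus.endswith(revcomp(f.tir_right))
        assert sum(f.weight for f in families6) == pytest.approx(1.0)

    def test_single_family_accepted(self):
        fams = mk.simulate_families(1, seed=2)
        assert len(fams) == 1

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            mk.simulate_families(0, seed=1)

    def test_tir_sharing_between_families(self, families6):
        # exhaustive comparison of emitted TIR strings: the canonical layout
        # shares one full pairing between two families and reuses one TIR
        tirs = [(f.tir_left, f.tir_right) for f in families6]
        assert tirs[3] == tirs[5]  # same pairing, distinct internal sequence
        assert families6[3].consensus != families6[5].consensus
        all_tirs = [t for pair in tirs for t in pair]
        assert len(set(all_tirs)) == 7

    def test_reproducible(self):
        a = mk.simulate_families(6, seed=42)
        b = mk.simulate_families(6, seed=42)
        assert a == b

    def test_families_mutually_distinguishable(self, families6):
        import edlib

        for i, f in enumerate(families6):
            for g in families6[i + 1 :]:
                a = f.consensus[25:-25]
                b = g.consensus[25:-25]
                d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
                assert 1 - d / max(len(a), len(b)) < 0.9


class TestSimulateGenome:
    def test_paper_scale_perfect_imperfect_split(self, families6):
        cfg = syn.SimulationConfig(seed=7)
        genome, truth = syn.simulate_genome_with_insertions(cfg, families6)
        assert len(truth) == 504
        assert sum(t.perfect_tsd for t in truth) == 286
        imperfect = [t for t in truth if not t.perfect_tsd]
        assert len(imperfect) == 218
        assert all(1 <= t.tsd_mismatches <= 9 for t in imperfect)

    def test_zero_insertions_identity(self, families6):
        cfg = syn.SimulationConfig(seed=1, n_insertions=0, genome_length=5000)
        genome, truth = syn.simulate_genome_with_insertions(cfg, families6)
        assert len(genome) == 5000 and truth == []

    def test_tsd_duplication_substring_invariant(self, small_sim):
        cfg, genome, truth = small_sim
        for t in truth:
            p, e = t.genome_position, len(t.element_seq)
            assert genome[p : p + 9] == t.tsd
            assert genome[p + 9 + e : p + 18 + e] == t.tsd_right
            assert genome[p + 9 : p + 9 + e] == t.element_seq

    def test_tsd_sites_at_rich(self, small_sim):
        cfg, _, truth = small_sim
        assert all(at_fraction(t.tsd) >= cfg.at_rich_threshold for t in truth)

    def test_gc_targeting(self, families6):
        cfg = syn.SimulationConfig(seed=21, n_insertions=120, genome_length=150_000)
        genome, truth = syn.simulate_genome_with_insertions(cfg, families6)
        elem_gc = np.mean([gc_fraction(t.element_seq) for t in truth])
        assert abs(elem_gc - cfg.element_gc) <= 0.02
        # background: regions outside planted loci
        bg_cfg = syn.SimulationConfig(seed=21, n_insertions=0, genome_length=150_000)
        bg, _ = syn.simulate_genome_with_insertions(bg_cfg, families6)
        assert abs(gc_fraction(bg) - cfg.background_gc) <= 0.02

    def test_truth_roundtrip_exact_substring(self, small_sim):
        _, genome, truth = small_sim
        for t in truth[:20]:
            # exact substring search recovers the planted copy (identical
            # family copies may occur earlier, so search from the locus)
            assert genome.find(t.element_seq, t.genome_position) == t.genome_position + 9

    def test_insufficient_sites_error(self, families6):
        cfg = syn.SimulationConfig(seed=1, n_insertions=50, genome_length=8_000)
        with pytest.raises(ValueError, match="AT-rich insertion sites"):
            syn.simulate_genome_with_insertions(cfg, families6)

    def test_byte_identical_reproducibility(self, families6):
        cfg = syn.SimulationConfig(seed=33, n_insertions=20, genome_length=30_000)
        g1, t1 = syn.simulate_genome_with_insertions(cfg, families6)
        g2, t2 = syn.simulate_genome_with_insertions(cfg, families6)
        assert g1 == g2
        assert [x.element_seq for x in t1] == [x.element_seq for x in t2]


class TestSimulateReads:
    def test_zero_reads(self, small_sim):
        cfg, genome, truth = small_sim
        assert syn.simulate_enrichment_reads(genome, truth, cfg, n_reads=0) == []

    def test_linkers_and_decoys(self, small_sim):
        cfg, genome, truth = small_sim
        reads = syn.simulate_enrichment_reads(genome, truth, cfg, n_reads=50)
        assert len(reads) == 50
        n_decoy = sum(r.read_id.startswith("decoy") for r in reads)
        assert n_decoy == round(cfg.decoy_fraction * 50)
        for r in reads[:5]:
            assert r.bases.startswith(syn.DEFAULT_LINKERS[0])
            assert r.bases.endswith(syn.DEFAULT_LINKERS[1])
            assert len(r.qualities) == len(r.bases)
            # qualities degrade toward the ends
            mid = len(r) // 2
            assert r.qualities[0] < 20 <= r.qualities[mid]

    def test_probe_validation(self, small_sim):
        cfg, genome, truth = small_sim
        with pytest.raises(ValueError, match="probe"):
            syn.simulate_enrichment_reads(
                genome, truth, cfg, n_reads=10, probe="GGGGGGGGGGGGGGGGGGGG"
            )

    def test_matching_probe_accepted(self, small_sim, families6):
        cfg, genome, truth = small_sim
        probe = families6[0].consensus[30:53]
        reads = syn.simulate_enrichment_reads(genome, truth, cfg, n_reads=10, probe=probe)
        assert len(reads) == 10


class TestSimulateMutantPanel:
    def test_no_events_all_reference(self, small_sim):
        _, genome, truth = small_sim
        panel, refs = syn.simulate_mutant_panel(genome, truth[:5], 4, [], seed=1)
        for line in panel.values():
            for locus_id, (h1, h2) in line.items():
                assert h1 == h2 == refs[locus_id].full_allele

    def test_aa_insertion_differs_by_two_bases(self, small_sim):
        _, genome, truth = small_sim
        t = next(x for x in truth if x.tsd.startswith("AA"))
        planted = [("line01", t.locus_id, "hom_empty", "tsd_insertion")]
        panel, refs = syn.simulate_mutant_panel(genome, [t], 2, planted, seed=1)
        allele = panel["line01"][t.locus_id][0]
        empty = refs[t.locus_id].empty_allele
        assert len(allele) == len(empty) + 2
        import edlib

        assert edlib.align(allele, empty, mode="NW", task="distance")["editDistance"] == 2

    def test_duplicate_event_conflict(self, small_sim):
        _, genome, truth = small_sim
        ev = [
            ("line01", truth[0].locus_id, "het", "clean"),
            ("line01", truth[0].locus_id, "hom_empty", "clean"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            syn.simulate_mutant_panel(genome, truth[:3], 2, ev, seed=1)

    def test_unknown_line_or_locus_rejected(self, small_sim):
        _, genome, truth = small_sim
        with pytest.raises(ValueError, match="unknown line"):
            syn.simulate_mutant_panel(genome, truth[:3], 2, [("line99", truth[0].locus_id, "het", "clean")], seed=1)
        with pytest.raises(ValueError, match="unknown locus"):
            syn.simulate_mutant_panel(genome, truth[:3], 2, [("line01", "nope", "het", "clean")], seed=1)


class TestSimulateMarkerMatrix:
    def test_exact_targets_brute_force_verified(self):
        targets = {("a", "b"): 5, ("a", "c"): 7, ("b", "c"): 8}
        m = syn.simulate_marker_matrix(3, 30, targets, seed=1)
        d = m.pairwise_discordance()
        assert d == {("a", "b"): 5, ("a", "c"): 7, ("b", "c"): 8}

    def test_all_zero_targets_identical_lines(self):
        targets = {("a", "b"): 0, ("a", "c"): 0, ("b", "c"): 0}
        m = syn.simulate_marker_matrix(3, 10, targets, seed=1)
        for mk_ in m.markers:
            assert len({m.patterns[(ln, mk_)] for ln in m.lines}) == 1

    def test_odd_parity_triple_requires_multistate(self):
        # 5+6+8 = 19 is odd: two-state loci alone contribute an even total
        # over a triple, so at least one locus must show >= 3 states
        targets = {("a", "b"): 5, ("a", "c"): 6, ("b", "c"): 8}
        m = syn.simulate_marker_matrix(3, 25, targets, seed=2)
        states = [len({m.patterns[(ln, mk_)] for ln in m.lines}) for mk_ in m.markers]
        assert max(states) >= 3
        assert m.pairwise_discordance() == targets

    def test_small_cases_brute_force_parity(self, rng):
        # exhaustive check on tiny binary matrices: every realisable binary
        # triple has even pairwise-count sum
        from itertools import product

        for cols in product([(0, 0, 0), (0, 0, 1), (0, 1, 0), (1, 0, 0)], repeat=3):
            total = 0
            for a, b in [(0, 1), (0, 2), (1, 2)]:
                total += sum(c[a] != c[b] for c in cols)
            assert total % 2 == 0

    def test_triangle_violation_named(self):
        targets = {("a", "b"): 10, ("a", "c"): 1, ("b", "c"): 1}
        with pytest.raises(ValueError, match="triangle"):
            syn.simulate_marker_matrix(3, 50, targets, seed=1)

    def test_infeasible_within_n_loci(self):
        targets = {("a", "b"): 50, ("a", "c"): 50, ("b", "c"): 50}
        with pytest.raises(ValueError, match="n_loci"):
            syn.simulate_marker_matrix(3, 10, targets, seed=1)

    def test_reproducible(self):
        targets = {("a", "b"): 4, ("a", "c"): 6, ("b", "c"): 6}
        m1 = syn.simulate_marker_matrix(3, 20, targets, seed=9)
        m2 = syn.simulate_marker_matrix(3, 20, targets, seed=9)
        assert m1.patterns == m2.patterns
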