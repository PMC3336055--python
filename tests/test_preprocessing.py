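"""Quality trimming, masking, flank extraction and locus clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitekit import synthetic as syn
from mitekit._seq import revcomp
from mitekit.preprocessing import (
    FlankPair,
    MaskedRead,
    Read,
    cluster_loci,
    extract_flanks,
    length_filter,
    mask_matches,
    preprocess_read,
    trim_by_quality,
)


def brute_force_trim(quals, q_threshold=20, min_length=10):
    """O(n^2) oracle: enumerate every substring, maximise (score, length,
    leftmost) under +1 for q >= threshold and -2 otherwise."""
    n = len(quals)
    best = (0, 0, 0)
    window = (0, 0)
    for s in range(n):
        sc = 0
        for e in range(s + 1, n + 1):
            sc += 1 if quals[e - 1] >= q_threshold else -2
            key = (sc, e - s, -s)
            if key > best:
                best, window = key, (s, e)
    return (0, 0) if best[0] < min_length else window


class TestTrimByQuality:
    def test_all_high_quality_read_unchanged(self):
        r = Read("r", "ACGT" * 5, (30,) * 20)
        assert trim_by_quality(r) == r

    def test_all_low_quality_read_emptied(self):
        r = Read("r", "ACGT" * 5, (10,) * 20)
        t = trim_by_quality(r)
        assert t.bases == "" and t.qualities == ()

    def test_block_pattern_matches_brute_force(self):
        quals = (20,) * 30 + (10,) * 5 + (30,) * 30
        r = Read("r", "A" * 65, quals)
        s, e = brute_force_trim(quals)
        t = trim_by_quality(r)
        assert t.qualities == quals[s:e]

    @given(st.lists(st.sampled_from([5, 15, 25, 40]), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, quals):
        quals = tuple(quals)
        r = Read("r", "A" * len(quals), quals)
        t = trim_by_quality(r)
        s, e = brute_force_trim(quals)
        assert t.qualities == quals[s:e]

    @given(st.lists(st.integers(0, 60), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_trim_is_contiguous_slice_and_never_longer(self, quals):
        quals = tuple(quals)
        r = Read("r", "C" * len(quals), quals)
        t = trim_by_quality(r)
        assert len(t) <= len(r)
        if t.qualities:
            # the trimmed qualities occur as a contiguous slice
            joined = ",".join(map(str, quals))
            assert ",".join(map(str, t.qualities)) in joined

    def test_empty_read_passes_through(self):
        r = Read("r", "", ())
        assert trim_by_quality(r).bases == ""


def brute_force_mask(seq, pattern, min_match=10, min_score=18, penalty=-2):
    """Diagonal-scan oracle: best-scoring ungapped segment per diagonal,
    kept when it reaches min_score and contains an exact >= min_match run."""
    seq = seq.upper()
    hits = []
    for oriented in (pattern.upper(), revcomp(pattern.upper())):
        m = len(oriented)
        for diag in range(-m + 1, len(seq)):
            positions = [
                (i, j)
                for j, i in ((j, diag + j) for j in range(m))
                if 0 <= i < len(seq)
            ]
            if not positions:
                continue
            scores = [1 if seq[i] == oriented[j] else penalty for i, j in positions]
            # maximise (score, length), ties to the leftmost start
            best = (0, 0, None, None)
            for s in range(len(scores)):
                total = 0
                for e in range(s, len(scores)):
                    total += scores[e]
                    if (total, e - s + 1) > (best[0], best[1]):
                        best = (total, e - s + 1, s, e)
            score, _, s, e = best
            if s is None or score < min_score:
                continue
            run = longest = 0
            for k in range(s, e + 1):
                run = run + 1 if scores[k] == 1 else 0
                longest = max(longest, run)
            if longest >= min_match:
                hits.append((positions[s][0], positions[e][0] + 1))
    return sorted(set(hits))


class TestMaskMatches:
    LINKER = "GTTTAGCCTTGTAGCAGAAGC"

    def test_verbatim_linker_masked(self, rng):
        seq = syn.random_dna(rng, 80, 0.4) + self.LINKER + syn.random_dna(rng, 80, 0.4)
        masked = mask_matches(seq, [("linker", self.LINKER)])
        assert any(
            seq[s:e] == self.LINKER and lab == "linker" for s, e, lab in masked.intervals
        )

    def test_no_shared_kmer_no_mask(self):
        seq = "A" * 200
        masked = mask_matches(seq, [("linker", "G" * 21)])
        assert masked.intervals == ()

    def test_pattern_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError):
            mask_matches("ACGTACGTACGT", [("linker", "ACGT")])

    def test_planted_pattern_with_central_mismatch_matches_diagonal_oracle(self, rng):
        pattern = syn.random_dna(rng, 30, 0.5)
        mutated = pattern[:15] + ("A" if pattern[15] != "A" else "C") + pattern[16:]
        seq = syn.random_dna(rng, 1000, 0.5) + mutated + syn.random_dna(rng, 1000, 0.5)
        masked = mask_matches(seq, [("vector", pattern)])
        oracle = brute_force_mask(seq, pattern)
        got = [(s, e) for s, e, _ in masked.intervals]
        # the oracle interval containing the plant must be recovered exactly
        plant = (1000, 1030)
        assert plant in oracle
        assert plant in got

    def test_reverse_strand_match_masked(self, rng):
        pattern = syn.random_dna(rng, 25, 0.5)
        seq = syn.random_dna(rng, 60, 0.5) + revcomp(pattern) + syn.random_dna(rng, 60, 0.5)
        masked = mask_matches(seq, [("element", pattern)])
        assert (60, 85) in [(s, e) for s, e, _ in masked.intervals]

    def test_masking_is_idempotent(self, rng):
        pattern = syn.random_dna(rng, 30, 0.5)
        seq = syn.random_dna(rng, 300, 0.5) + pattern + syn.random_dna(rng, 300, 0.5)
        first = mask_matches(seq, [("element", pattern)])
        second = mask_matches(first.bases, [("element", pattern)])
        assert first.intervals == second.intervals

    def test_original_bases_retrievable(self):
        seq = "ACGT" * 10 + self.LINKER + "TTTT"
        masked = mask_matches(seq, [("linker", self.LINKER)])
        assert masked.bases == seq
        assert masked.masked_lowercase().upper() == seq.upper()


class TestLengthFilter:
    def test_boundary_kept_and_overlong_removed(self):
        keep = Read("a", "A" * 1000, (30,) * 1000)
        drop = Read("b", "A" * 1001, (30,) * 1001)
        assert length_filter([keep, drop]) == [keep]

    def test_mixed_list_count(self, rng):
        reads = [
            Read(f"r{i}", "A" * n, (30,) * n)
            for i, n in enumerate(rng.integers(900, 1101, size=40))
        ]
        out = length_filter(reads)
        assert len(out) == sum(len(r) <= 1000 for r in reads)
        assert out == [r for r in reads if len(r) <= 1000]


class TestExtractFlanks:
    def test_flank_lengths_by_construction(self):
        masked = MaskedRead("r", "A" * 60 + "C" * 100 + "G" * 80, ((60, 160, "element"),))
        fp = extract_flanks(masked)
        assert len(fp.left_flank) == 60 and len(fp.right_flank) == 80
        assert not fp.single_flank

    def test_element_at_read_start_flagged_single_flank(self):
        masked = MaskedRead("r", "C" * 100 + "G" * 80, ((0, 100, "element"),))
        fp = extract_flanks(masked)
        assert fp.left_flank == "" and fp.single_flank

    def test_no_element_interval_returns_none(self):
        masked = MaskedRead("r", "ACGT" * 30, ((0, 21, "linker"),))
        assert extract_flanks(masked) is None

    def test_multi_hit_takes_longest_and_flags(self):
        bases = "A" * 20 + "C" * 30 + "T" * 20 + "C" * 60 + "G" * 20
        masked = MaskedRead("r", bases, ((20, 50, "element"), (70, 130, "element")))
        fp = extract_flanks(masked)
        assert fp.multi_hit
        assert fp.element_segment == "C" * 60

    def test_simulated_library_flanks_map_to_truth(self, clean_sim, families6):
        cfg, genome, truth = clean_sim
        reads = syn.simulate_enrichment_reads(genome, truth, cfg, n_reads=120)
        lk = [("linker", l) for l in syn.DEFAULT_LINKERS]
        el = [("element", f.consensus) for f in families6]
        truth_by = {t.locus_id: t for t in truth}
        total = within1 = 0
        for r in reads:
            fp = preprocess_read(r, lk, el)
            if fp is None or fp.single_flank or r.read_id.startswith("decoy"):
                continue
            t = truth_by[r.read_id.split("_")[1]]
            estart = t.genome_position + cfg.tsd_length
            eend = estart + len(t.element_seq)
            total += 1
            left_ok = genome[estart - len(fp.left_flank) - 1 : estart + 1].find(fp.left_flank) >= 0
            right_ok = genome[eend - 1 : eend + len(fp.right_flank) + 1].find(fp.right_flank) >= 0
            within1 += left_ok and right_ok
        assert total > 50
        assert within1 / total >= 0.95

    def test_strand_symmetry(self, rng):
        element = syn.random_dna(rng, 80, 0.3)
        left = syn.random_dna(rng, 50, 0.4)
        right = syn.random_dna(rng, 70, 0.4)
        fwd = mask_matches(left + element + right, [("element", element)], 12, 20)
        rev = mask_matches(revcomp(left + element + right), [("element", element)], 12, 20)
        fp_f = extract_flanks(fwd)
        fp_r = extract_flanks(rev)
        assert fp_r.left_flank == revcomp(fp_f.right_flank)
        assert fp_r.right_flank == revcomp(fp_f.left_flank)


class TestClusterLoci:
    def test_identical_pairs_form_one_cluster(self):
        fp = FlankPair("a", "ACGTACGTACGTACGTACGT", "TTGCATTGCATTGCATTGCA")
        fp2 = FlankPair("b", fp.left_flank, fp.right_flank)
        clusters = cluster_loci([fp, fp2])
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_clustering_is_a_partition(self, rng):
        fps = [
            FlankPair(f"p{i}", syn.random_dna(rng, 60, 0.4), syn.random_dna(rng, 60, 0.4))
            for i in range(25)
        ]
        clusters = cluster_loci(fps)
        seen = [m.locus_id for c in clusters for m in c.members]
        assert sorted(seen) == sorted(fp.locus_id for fp in fps)

    def test_simulated_library_recovers_distinct_loci(self, clean_sim, families6):
        cfg, genome, truth = clean_sim
        # >= 3x coverage of 50 loci at zero read error
        subset = truth[:50]
        reads = syn.simulate_enrichment_reads(genome, subset, cfg, n_reads=188)
        lk = [("linker", l) for l in syn.DEFAULT_LINKERS]
        el = [("element", f.consensus) for f in families6]
        fps = [
            fp
            for fp in (
                preprocess_read(r, lk, el) for r in reads if r.read_id.startswith("read")
            )
            if fp is not None and not fp.single_flank
        ]
        clusters = cluster_loci(fps)
        sampled = {fp.locus_id.split("_")[1] for fp in fps}
        assert len(clusters) == len(sampled) == 50
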