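import math

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import rhodoscan as rs
from rhodoscan import _kernels as K
from rhodoscan.recruit import (
    KmerIndex,
    align_to_profile,
    calibrate_cutoff,
    recruit_sample,
    screen_candidates,
    six_frame_translate,
)
from conftest import brute_force_local


def revcomp(seq):
    return seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


class TestSixFrameTranslate:
    def test_stop_codon_splits_frame(self):
        frags = six_frame_translate("ATGGCATAAATGGCA", min_len=2)
        plus1 = [f.peptide for f in frags if f.frame == 1]
        assert plus1 == ["MA", "MA"]
        offsets = [f.offset for f in frags if f.frame == 1]
        assert offsets == [0, 9]

    def test_reverse_strand_recovers_peptide(self):
        fwd = "ATGGCAGATTGGCATAAA"  # MADWHK in frame +1
        frags = six_frame_translate(revcomp(fwd), min_len=6)
        assert any(f.peptide == "MADWHK" and f.frame < 0 for f in frags)

    def test_all_n_read_yields_nothing(self):
        assert six_frame_translate("N" * 60, min_len=2) == []

    def test_n_codon_translates_to_x(self):
        frags = six_frame_translate("ATGNNNGCAATGGCAGCA", min_len=5)
        plus1 = [f.peptide for f in frags if f.frame == 1]
        assert plus1 == ["MXAMAA"]

    def test_non_nucleotide_characters_error(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            six_frame_translate("ATGRYK" * 10)

    def test_min_len_filter(self):
        frags = six_frame_translate("ATGGCATAAATGGCA", min_len=3)
        assert [f for f in frags if f.frame == 1] == []


class TestScreenCandidates:
    def test_reference_substring_survives(self):
        frags = six_frame_translate("ATGGCAGATTGGCATAAA", min_len=6)
        ref = "WWMADWHKWW"
        survivors = screen_candidates(frags, [ref], k=4)
        assert any(f.peptide == "MADWHK" for f in survivors)

    def test_unrelated_fragment_dropped(self):
        frags = six_frame_translate("ATGGCAGATTGGCATAAA", min_len=6)
        assert screen_candidates(frags, ["PPPPPPPPPP"], k=4) == []

    def test_short_fragment_dropped_with_warning(self, tiny_profile):
        idx = KmerIndex(["ACDEFGH"], k=6)
        with pytest.warns(UserWarning, match="shorter than k"):
            assert idx.hits("ACD") is False

    def test_empty_reference_set_error(self):
        with pytest.raises(ValueError, match="empty reference"):
            KmerIndex([], k=4)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="k must be"):
            KmerIndex(["ACDE"], k=2)


class TestAlignToProfile:
    def test_consensus_peptide_score(self, tiny_profile):
        aln = align_to_profile("ACDE", tiny_profile)
        assert aln.bit_score == pytest.approx(4 * math.log2(16.2), rel=1e-12)
        assert aln.profile_span == (1, 4)
        assert aln.column_residues == {1: "A", 2: "C", 3: "D", 4: "E"}

    def test_hopeless_peptide_unaligned(self, tiny_profile):
        assert align_to_profile("WWWW", tiny_profile) is None

    def test_x_scores_background(self, tiny_profile):
        a = align_to_profile("AXDE", tiny_profile)
        assert a.bit_score == pytest.approx(3 * math.log2(16.2), rel=1e-12)
        assert a.column_residues[2] == "X"

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            L = int(rng.integers(1, 9))
            n = int(rng.integers(2, 13))
            S = rng.normal(-0.5, 2.0, size=(L, 22))
            S[:, 20:] = 0.0
            pep = rng.integers(0, 20, size=n).astype(np.int8)
            go, ge = 4.0, 1.0
            expected = brute_force_local(pep, S, go, ge)
            got = K.local_align_score(pep, np.ascontiguousarray(S), go, ge)
            assert got == pytest.approx(max(expected, 0.0), abs=1e-9)

    def test_traceback_score_equals_score_only(self, small_setup):
        _, refset, profiles, _, _ = small_setup
        p = profiles["PR"]
        rng = np.random.default_rng(3)
        for _ in range(20):
            pep = rng.integers(0, 20, size=30).astype(np.int8)
            s1 = K.local_align_score(pep, p.score_matrix22(), p.gap_open, p.gap_extend)
            s2, first, last, _ = K.local_align_traceback(
                pep, p.score_matrix22(), p.gap_open, p.gap_extend
            )
            assert s1 == pytest.approx(s2, abs=1e-9)
            if s2 > 0:
                assert 1 <= first <= last <= p.length


class TestCalibrateCutoff:
    def test_deterministic(self, tiny_profile, small_setup):
        _, _, profiles, _, _ = small_setup
        c1 = calibrate_cutoff(profiles["PR"], decoy_count=2000, target_fpr=1e-3, seed=1)
        c2 = calibrate_cutoff(profiles["PR"], decoy_count=2000, target_fpr=1e-3, seed=1)
        assert c1 == c2

    def test_empirical_fpr_on_fresh_decoys(self, small_setup):
        _, _, profiles, _, _ = small_setup
        p = profiles["PR"]
        n, fpr = 5000, 0.01
        cutoff = calibrate_cutoff(p, decoy_count=n, fragment_len=30, target_fpr=fpr, seed=1)
        rng = np.random.default_rng(99)
        fresh = rng.choice(20, size=(n, 30), p=p.background).astype(np.int8)
        concat = np.ascontiguousarray(fresh.reshape(-1))
        offsets = np.arange(0, (n + 1) * 30, 30, dtype=np.int64)
        scores = K.score_batch(concat, offsets, p.score_matrix22(), p.gap_open, p.gap_extend)
        emp = (scores >= cutoff).mean()
        se = math.sqrt(fpr * (1 - fpr) / n)
        assert emp <= fpr + 3 * se

    def test_floor_of_ten_bits(self, tiny_profile):
        # a 4-column profile cannot produce decoy scores near 10 bits often;
        # the returned cutoff is floored
        c = calibrate_cutoff(tiny_profile, decoy_count=1000, fragment_len=10, target_fpr=0.1, seed=0)
        assert c >= 10.0

    def test_insufficient_decoys(self, tiny_profile):
        with pytest.raises(ValueError, match="decoy_count"):
            calibrate_cutoff(tiny_profile, decoy_count=10)

    def test_fpr_range(self, tiny_profile):
        with pytest.raises(ValueError, match="target_fpr"):
            calibrate_cutoff(tiny_profile, target_fpr=0.5)


class TestRecruitSample:
    def test_sensitivity_on_clean_reads(self, small_setup):
        spec, refset, profiles, cutoffs, refs = small_setup
        clean = rs.CommunitySpec(
            spec.taxa, read_length=100, error_rate=0.0, background_fraction=0.0, seed=1
        )
        reads, truth = rs.simulate_reads(clean, refset, 3000, "DNA", seed=21)
        rr = recruit_sample(reads, profiles, cutoffs, refs)
        truth_counts = truth["source"].value_counts()
        for m in ("PR", "recA"):
            assert rr.counts[m] >= 0.95 * truth_counts[m]

    def test_strand_symmetry(self, small_setup):
        spec, refset, profiles, cutoffs, refs = small_setup
        reads, _ = rs.simulate_reads(spec, refset, 2000, "DNA", seed=22)
        rr_fwd = recruit_sample(reads, profiles, cutoffs, refs, collect_markers=())
        flipped = [(rid, revcomp(seq)) for rid, seq in reads]
        rr_rev = recruit_sample(flipped, profiles, cutoffs, refs, collect_markers=())
        assert rr_fwd.counts == rr_rev.counts

    def test_counts_monotone_in_cutoff(self, small_setup):
        spec, refset, profiles, cutoffs, refs = small_setup
        reads, _ = rs.simulate_reads(spec, refset, 2000, "DNA", seed=23)
        base = recruit_sample(reads, profiles, cutoffs, refs, collect_markers=())
        harder = {m: c + 15.0 for m, c in cutoffs.items()}
        strict = recruit_sample(reads, profiles, harder, refs, collect_markers=())
        for m in cutoffs:
            assert strict.counts[m] <= base.counts[m]

    def test_chimera_goes_to_higher_scoring_marker(self, small_setup):
        spec, refset, profiles, cutoffs, refs = small_setup
        # a read that is half PR, half recA: more PR codons -> PR must win
        pr_gene = refset.genes[("t0", "PR")]
        recA_gene = refset.genes[("t0", "recA")]
        chimera = pr_gene[:120] + recA_gene[:60]
        rr = recruit_sample([("chimera", chimera)], profiles, cutoffs, refs)
        assert rr.counts["PR"] == 1
        assert sum(rr.counts.values()) == 1

    def test_marker_order_breaks_exact_ties(self, small_setup):
        # identical profiles for two markers -> identical scores -> the
        # canonical marker order (PR before recA) decides
        _, refset, profiles, cutoffs, refs = small_setup
        aln = refset.alignments["PR"]
        twin_profiles = {"PR": profiles["PR"], "recA": profiles["PR"]}
        twin_refs = {"PR": refs["PR"], "recA": refs["PR"]}
        twin_cutoffs = {"PR": cutoffs["PR"], "recA": cutoffs["PR"]}
        read = refset.genes[("t1", "PR")][90:190]
        rr = recruit_sample([("twin", read)], twin_profiles, twin_cutoffs, twin_refs)
        assert rr.counts["PR"] == 1
        assert rr.counts["recA"] == 0

    def test_batch_agrees_with_operation_level_path(self, small_setup):
        spec, refset, profiles, cutoffs, refs = small_setup
        reads, _ = rs.simulate_reads(spec, refset, 300, "DNA", seed=24)
        rr = recruit_sample(reads, profiles, cutoffs, refs)
        for m, recs in rr.reads.items():
            for rec in recs:
                seq = dict(reads)[rec.read_id]
                frags = six_frame_translate(seq, min_len=15)
                best = 0.0
                for f in frags:
                    a = align_to_profile(f, profiles[m])
                    if a is not None:
                        best = max(best, a.bit_score)
                assert rec.bit_score == pytest.approx(best, abs=1e-9)
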