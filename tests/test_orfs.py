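"""ORF discovery, contig retention, and annotation rules."""

import numpy as np
import pytest

from _oracles import STOP_CASSETTE, brute_force_orfs, longest_orf_codons, revcomp
from virosift.orfs import Orf, annotate_orfs, find_orfs, triage_contig


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestFindOrfs:
    def test_hand_countable_example(self):
        orfs = find_orfs("ATGAAATAA", min_codons=1)
        plus1 = [o for o in orfs if o.frame == 1]
        assert len(plus1) == 1
        assert (plus1[0].start, plus1[0].end) == (0, 6)
        assert plus1[0].translation == "MK"
        assert plus1[0].length_codons == 2

    def test_sequence_shorter_than_a_codon_is_empty(self):
        assert find_orfs("AT", min_codons=1) == []
        assert find_orfs("", min_codons=1) == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="ACGTN"):
            find_orfs("ATGRYA")

    def test_lowercase_accepted(self):
        assert find_orfs("atgaaataa") == find_orfs("ATGAAATAA")

    def test_n_codons_translate_to_x_and_never_terminate(self):
        # TAN could resolve to a stop but must be treated as non-stop X
        orfs = find_orfs("ATGTANAAATAA", min_codons=1)
        plus1 = [o for o in orfs if o.frame == 1]
        assert len(plus1) == 1
        assert plus1[0].translation == "MXK"

    def test_min_codons_filters_short_runs(self):
        orfs = find_orfs("ATGAAATAA", min_codons=3)
        assert all(o.length_codons >= 3 for o in orfs)
        assert not any(o.frame == 1 for o in orfs)

    def test_start_anchored_mode(self):
        # run TTT ATG AAA ends at TAA; AUG-anchored ORF starts at the ATG
        orfs = find_orfs("TTTATGAAATAA", min_codons=1, require_start=True)
        plus1 = [o for o in orfs if o.frame == 1]
        assert len(plus1) == 1
        assert (plus1[0].start, plus1[0].end, plus1[0].translation) == (3, 9, "MK")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_n_containing_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, int(rng.integers(30, 400)), alphabet="ACGTN")
        got = {(o.frame, o.start, o.end) for o in find_orfs(seq, min_codons=1)}
        assert got == brute_force_orfs(seq, 1)

    def test_bruteforce_equivalence_battery(self):
        """Exact agreement with an independent six-frame enumerator over
        1000 random sequences spanning 30-3000 nt."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            seq = random_dna(rng, int(rng.integers(30, 3001)))
            got = {(o.frame, o.start, o.end) for o in find_orfs(seq, min_codons=1)}
            assert got == brute_force_orfs(seq, 1)

    def test_reverse_complement_symmetry(self):
        """ORF codon-length multisets agree between a sequence and its
        reverse complement, with frames mirrored."""
        rng = np.random.default_rng(777)
        for _ in range(100):
            seq = random_dna(rng, int(rng.integers(30, 1000)))
            fwd = find_orfs(seq, min_codons=1)
            rev = find_orfs(revcomp(seq), min_codons=1)
            assert sorted(o.length_codons for o in fwd) == sorted(
                o.length_codons for o in rev
            )
            fwd_by_sign = sorted(
                (np.sign(o.frame), o.length_codons) for o in fwd
            )
            rev_mirrored = sorted(
                (-np.sign(o.frame), o.length_codons) for o in rev
            )
            assert fwd_by_sign == rev_mirrored

    def test_translations_have_no_internal_stop(self):
        rng = np.random.default_rng(42)
        seq = random_dna(rng, 900)
        for orf in find_orfs(seq, min_codons=1):
            assert "*" not in orf.translation
            assert len(orf.translation) == orf.length_codons
            assert (orf.end - orf.start) % 3 == 0


def boundary_contig(n_codons):
    """Contig >=500 nt whose longest six-frame ORF is n_codons + 3.

    The all-frame stop cassette bounds a poly-alanine run; the junction
    contributes three extra stop-free codons (verified by the oracle)."""
    core = STOP_CASSETTE * 3 + "GCT" * n_codons + STOP_CASSETTE * 3
    while len(core) < 510:
        core += STOP_CASSETTE
    return core


class TestTriage:
    def test_longest_orf_at_retention_threshold_is_retained(self):
        contig = boundary_contig(147)
        assert longest_orf_codons(contig) == 150  # construction check
        result = triage_contig("c1", contig)
        assert result.longest_orf_codons == 150
        assert result.retained

    def test_one_codon_short_is_discarded(self):
        contig = boundary_contig(146)
        assert longest_orf_codons(contig) == 149
        result = triage_contig("c1", contig)
        assert result.longest_orf_codons == 149
        assert not result.retained

    def test_contig_under_length_floor_excluded_before_orf_analysis(self):
        contig = ("GCT" * 200)[:499]
        result = triage_contig("c1", contig)
        assert result.length_nt == 499
        assert not result.retained
        assert result.longest_orf_codons == 0
        assert result.concatenated_translation == ""

    def test_concatenated_translation_joins_by_frame_then_start(self):
        contig = boundary_contig(147)
        result = triage_contig("c1", contig)
        orfs = find_orfs(contig, min_codons=1, contig_id="c1")
        assert result.concatenated_translation == "".join(
            o.translation for o in orfs
        )

    def test_raising_min_orf_codons_never_rescues_a_contig(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            contig = random_dna(rng, int(rng.integers(500, 2000)))
            retained = [
                triage_contig("c", contig, min_orf_codons=k).retained
                for k in (50, 100, 150, 200)
            ]
            # once lost, never regained as the threshold rises
            assert retained == sorted(retained, reverse=True)


def _orf(start_aa, length_aa, contig="c"):
    return Orf(contig, 1, start_aa * 3, (start_aa + length_aa) * 3, "A" * length_aa)


class TestAnnotation:
    def test_short_orf_without_similarity_not_annotated(self):
        calls = annotate_orfs([_orf(0, 99)])
        assert not calls[0].annotated
        assert calls[0].reason == "short_non_similar"

    def test_long_orf_annotated(self):
        calls = annotate_orfs([_orf(0, 100)])
        assert calls[0].annotated
        assert calls[0].reason == "long_enough"

    def test_sub200_nested_orf_disregarded(self):
        big, small = _orf(0, 500), _orf(100, 150)
        calls = {c.orf: c for c in annotate_orfs([big, small])}
        assert calls[big].annotated
        assert not calls[small].annotated
        assert calls[small].reason == "nested_disregarded"

    def test_nested_orf_rescued_by_similarity(self):
        big, small = _orf(0, 500), _orf(100, 150)
        calls = {c.orf: c for c in annotate_orfs([big, small], {small: True})}
        assert calls[small].annotated
        assert calls[small].reason == "similarity_rescue"

    def test_nested_orf_of_200_aa_or_more_kept(self):
        big, mid = _orf(0, 500), _orf(100, 200)
        calls = {c.orf: c for c in annotate_orfs([big, mid])}
        assert calls[mid].annotated
        assert calls[mid].reason == "long_enough"

    def test_short_orf_rescued_by_similarity(self):
        orf = _orf(0, 60)
        calls = annotate_orfs([orf], {orf: True})
        assert calls[0].annotated
        assert calls[0].reason == "similarity_rescue"
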