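import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degrinscan.motifs import (
    DEFAULT_MOTIFS,
    MotifPattern,
    PatternError,
    default_patterns,
    scan_collection,
    scan_sequence,
)
from degrinscan.seqio import SequenceRecord
from degrinscan.signal import SignalPrediction

from oracle import oracle_scan, random_protein


def rec(residues, ident="s"):
    return SequenceRecord(ident, residues)


def as_tuples(matches):
    return {
        (m.tripeptide, m.motif_start, m.left_cys_pos, m.right_cys_pos,
         m.left_spacer, m.right_spacer)
        for m in matches
    }


class TestScanSequence:
    def test_minimal_flanked_motif(self):
        (m,) = scan_sequence(rec("CRGDC"), default_patterns())
        assert (m.motif_start, m.left_cys_pos, m.right_cys_pos) == (2, 1, 5)
        assert (m.left_spacer, m.right_spacer) == (0, 0)

    def test_spacer_boundary_sixteen_accepted(self):
        seq = "C" + "A" * 16 + "RGD" + "A" * 16 + "C"
        (m,) = scan_sequence(rec(seq), default_patterns())
        assert (m.left_spacer, m.right_spacer) == (16, 16)

    def test_spacer_seventeen_rejected(self):
        assert scan_sequence(rec("C" + "A" * 17 + "RGDC"), default_patterns()) == []
        assert scan_sequence(rec("CRGD" + "A" * 17 + "C"), default_patterns()) == []

    def test_no_cysteines_no_match(self):
        assert scan_sequence(rec("ARGDA"), default_patterns()) == []

    def test_shared_middle_cysteine(self):
        # one cysteine serves as right flank of the first motif and left
        # flank of the second
        matches = scan_sequence(rec("CRGDCRGDC"), default_patterns())
        assert len(matches) == 2
        first, second = matches
        assert (first.motif_start, first.left_cys_pos, first.right_cys_pos) == (2, 1, 5)
        assert (second.motif_start, second.left_cys_pos, second.right_cys_pos) == (6, 5, 9)

    def test_innermost_flanks_reported(self):
        seq = "CAC" + "RGD" + "ACA" + "C"
        (m,) = scan_sequence(rec(seq), default_patterns())
        assert (m.left_cys_pos, m.right_cys_pos) == (3, 8)

    def test_flank_strictly_outside_motif(self):
        # user motif containing C: its own cysteines cannot flank it
        pat = [MotifPattern("CAC")]
        assert scan_sequence(rec("ACACA"), pat) == []
        (m,) = scan_sequence(rec("CCACC"), pat)
        assert (m.left_cys_pos, m.right_cys_pos) == (1, 5)

    def test_x_never_matches_motif_position(self):
        assert scan_sequence(rec("CRGXC"), default_patterns()) == []

    def test_overlaps_signal_flag(self):
        seq = "C" + "RGD" + "C" + "A" * 20
        sig = SignalPrediction("s", True, 10, 0.5)
        (m,) = scan_sequence(rec(seq), default_patterns(), sig)
        assert m.overlaps_signal
        sig2 = SignalPrediction("s", True, 1, 0.5)
        (m2,) = scan_sequence(rec(seq), default_patterns(), sig2)
        assert not m2.overlaps_signal

    def test_require_flanks_false_reports_unflanked(self):
        pat = [MotifPattern("RGD", require_flanks=False)]
        (m,) = scan_sequence(rec("ARGDA"), pat)
        assert (m.left_cys_pos, m.right_cys_pos) == (0, 0)

    def test_sorted_by_position_then_tripeptide(self):
        seq = "C" + "KGD" + "RGD" + "C"
        matches = scan_sequence(rec(seq), default_patterns())
        starts = [(m.motif_start, m.tripeptide) for m in matches]
        assert starts == sorted(starts)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(PatternError):
            MotifPattern("RG")
        with pytest.raises(PatternError):
            MotifPattern("RGX")
        with pytest.raises(PatternError):
            scan_sequence(rec("CRGDC"), [])
        with pytest.raises(PatternError):
            scan_sequence(rec("CRGDC"), [MotifPattern("RGD"), MotifPattern("RGD")])


class TestOracleEquivalence:
    def test_seeded_random_sequences_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            seq = random_protein(rng, int(rng.integers(20, 401)), cys_freq=0.08)
            got = as_tuples(scan_sequence(rec(seq), default_patterns()))
            assert got == oracle_scan(seq, DEFAULT_MOTIFS)

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet="ACRGDKTSWMLVE", min_size=3, max_size=80))
    def test_adversarial_alphabet_matches_oracle(self, seq):
        # alphabet skewed toward motif letters and cysteines
        got = as_tuples(scan_sequence(rec(seq, "h"), default_patterns()))
        assert got == oracle_scan(seq, DEFAULT_MOTIFS)

    def test_spacer_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = random_protein(rng, 150, cys_freq=0.10)
            prev: set = set()
            for bound in (0, 4, 8, 16, 32, len(seq)):
                pats = default_patterns(max_left_spacer=bound, max_right_spacer=bound)
                cur = as_tuples(scan_sequence(rec(seq), pats))
                assert {t[:2] for t in prev} <= {t[:2] for t in cur}
                prev = cur
            # with unbounded spacers, every occurrence with >=1 Cys each side hits
            unbounded = oracle_scan(seq, DEFAULT_MOTIFS, len(seq), len(seq))
            assert {t[:2] for t in prev} == {t[:2] for t in unbounded}

    def test_pattern_order_irrelevant(self):
        rng = np.random.default_rng(3)
        seq = random_protein(rng, 300, cys_freq=0.12)
        fwd = as_tuples(scan_sequence(rec(seq), default_patterns(DEFAULT_MOTIFS)))
        rev = as_tuples(scan_sequence(rec(seq), default_patterns(DEFAULT_MOTIFS[::-1])))
        assert fwd == rev

    def test_match_invariants_hold(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            seq = random_protein(rng, 200, cys_freq=0.10)
            for m in scan_sequence(rec(seq), default_patterns()):
                assert seq[m.motif_start - 1 : m.motif_start + 2] == m.tripeptide
                assert seq[m.left_cys_pos - 1] == "C" and seq[m.right_cys_pos - 1] == "C"
                assert m.left_cys_pos < m.motif_start < m.motif_start + 2 < m.right_cys_pos
                assert 0 <= m.left_spacer <= 16 and 0 <= m.right_spacer <= 16
                assert m.left_spacer == m.motif_start - m.left_cys_pos - 1
                assert m.right_spacer == m.right_cys_pos - (m.motif_start + 2) - 1


class TestScanCollection:
    def test_counts_include_zero_match_records(self):
        records = [rec("CRGDC", "a"), rec("AAAA", "b"), rec("GGGG", "c")]
        table = scan_collection(records, default_patterns())
        assert table.n_matches == 1
        assert table.counts == {"a": 1, "b": 0, "c": 0}

    def test_empty_collection(self):
        table = scan_collection([], default_patterns())
        assert table.n_matches == 0 and table.counts == {}

    def test_fixture_counts_exact(self, small_proteome):
        records, ledger = small_proteome
        table = scan_collection(records, default_patterns())
        assert table.n_matches == len(ledger.motif_entries(detectable=True))
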