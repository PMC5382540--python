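import numpy as np
import pytest

from redoxmir.sequences import revcomp
from redoxmir.targets import (
    GAP_M, GAP_T, MATCH, MISMATCH, WOBBLE, align_duplex, classify_inhibition,
    expectation_score, scan_transcript,
)
from oracles import min_expectation_enum

MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def _site(mirna=MIRNA):
    """Perfectly complementary target window for a miRNA."""
    return revcomp(mirna)


def _mutate_site(site, mirna_pos, mirna=MIRNA, wobble=False):
    """Edit the site base facing the given miRNA position (1-based)."""
    idx = len(site) - mirna_pos  # antiparallel: miRNA 5' faces site 3'
    m_base = mirna[mirna_pos - 1]
    if wobble:
        new = {"G": "T", "T": "G"}[m_base]  # G:U partner
    else:
        new = {"A": "C", "C": "A", "G": "C", "T": "A"}[site[idx]]
    return site[:idx] + new + site[idx + 1 :]


class TestAlignDuplex:
    def test_perfect_window_all_match(self):
        dup = align_duplex(MIRNA, _site())
        assert [s for _, s in dup.states] == [MATCH] * len(MIRNA)
        assert [p for p, _ in dup.states] == list(range(1, len(MIRNA) + 1))

    def test_single_substitution_single_mismatch(self):
        dup = align_duplex(MIRNA, _mutate_site(_site(), 7))
        states = [s for _, s in dup.states]
        assert states.count(MISMATCH) == 1 and states.count(MATCH) == len(MIRNA) - 1

    def test_single_deletion_one_gap_rest_match(self):
        site = _site()
        dup = align_duplex(MIRNA, site[:8] + site[9:])  # one target base deleted
        states = [s for _, s in dup.states]
        assert states.count(GAP_T) == 1
        assert states.count(MATCH) == len(MIRNA) - 1

    def test_window_length_outside_band_rejected(self):
        with pytest.raises(ValueError):
            align_duplex(MIRNA, _site() + "ACGTAC")


class TestExpectationScore:
    def test_perfect_duplex_scores_zero(self):
        assert expectation_score(align_duplex(MIRNA, _site())) == 0.0

    def test_seed_wobble_doubled(self):
        # G:U at miRNA position 5: 0.5 x 2 = 1.0
        site = _mutate_site(_site(), 5, wobble=True)
        assert expectation_score(align_duplex(MIRNA, site)) == 1.0

    def test_mismatch_outside_seed_not_doubled(self):
        site = _mutate_site(_site(), 18)
        assert expectation_score(align_duplex(MIRNA, site)) == 1.0

    def test_two_seed_mismatches_score_four(self):
        site = _mutate_site(_mutate_site(_site(), 5), 11)
        assert expectation_score(align_duplex(MIRNA, site)) == 4.0

    def test_positions_beyond_hspsize_unscored(self):
        mirna = MIRNA + "AGA"  # 24 nt; positions 21-24 partly unscored
        site = _mutate_site(_site(mirna), 22, mirna=mirna)
        assert expectation_score(align_duplex(mirna, site)) == 0.0

    def test_agrees_with_exhaustive_alignment_oracle(self):
        rng = np.random.default_rng(7)
        bases = list("ACGT")
        for _ in range(200):
            L = int(rng.integers(8, 13))
            m = "".join(rng.choice(bases, size=L))
            wl = L + int(rng.integers(-1, 2))
            w = "".join(rng.choice(bases, size=wl))
            got = expectation_score(align_duplex(m, w, hspsize=20))
            assert got == pytest.approx(min_expectation_enum(m, w), abs=1e-9)


class TestClassifyInhibition:
    def test_central_mismatch_is_translational(self):
        dup = align_duplex(MIRNA, _mutate_site(_site(), 10))
        assert classify_inhibition(dup) == "translational"

    def test_mismatch_outside_central_range_is_cleavage(self):
        dup = align_duplex(MIRNA, _mutate_site(_site(), 8))
        assert classify_inhibition(dup) == "cleavage"

    def test_perfect_duplex_is_cleavage(self):
        assert classify_inhibition(align_duplex(MIRNA, _site())) == "cleavage"

    def test_central_wobble_still_cleavage(self):
        # position 9 of MIRNA is C; use a miRNA with G at position 10
        mirna = MIRNA[:9] + "G" + MIRNA[10:]
        site = _mutate_site(_site(mirna), 10, mirna=mirna, wobble=True)
        dup = align_duplex(mirna, site)
        assert WOBBLE in [s for _, s in dup.states]
        assert classify_inhibition(dup) == "cleavage"


class TestScanTranscript:
    def test_planted_perfect_site_found_once_at_zero(self):
        rng = np.random.default_rng(8)
        bg = "".join(rng.choice(list("ACGT"), size=400))
        t = bg[:150] + _site() + bg[150:]
        sites = scan_transcript(MIRNA, "tx1", t)
        assert len(sites) == 1
        s = sites[0]
        assert s.expectation == 0.0
        assert t[s.site_start : s.site_end] == _site()
        assert s.flank_up_seq == t[s.site_start - 17 : s.site_start]
        assert s.flank_down_seq == t[s.site_end : s.site_end + 13]

    def test_random_transcripts_rarely_hit_cutoff(self):
        rng = np.random.default_rng(9)
        empty = 0
        for _ in range(100):
            t = "".join(rng.choice(list("ACGT"), size=1000))
            m = "".join(rng.choice(list("ACGT"), size=21))
            if not scan_transcript(m, "tx", t):
                empty += 1
        assert empty >= 95

    def test_site_above_cutoff_not_emitted(self):
        rng = np.random.default_rng(10)
        bg = "".join(rng.choice(list("ACGT"), size=300))
        bad = _mutate_site(_mutate_site(_site(), 5), 11)  # score 4.0
        t = bg[:100] + bad + bg[100:]
        assert scan_transcript(MIRNA, "tx", t) == []

    def test_flanks_truncated_at_transcript_ends(self):
        t = _site() + "ACGTA"
        (s,) = scan_transcript(MIRNA, "tx", t)
        assert s.flank_up_seq == "" and s.flank_down_seq == "ACGTA"

    def test_added_mismatch_never_lowers_expectation(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            m = "".join(rng.choice(list("ACGT"), size=21))
            site = revcomp(m)
            prev = expectation_score(align_duplex(m, site))
            order = rng.permutation(len(m))[:4]
            for pos in order:
                site = _mutate_site(site, int(pos) + 1, mirna=m)
                cur = expectation_score(align_duplex(m, site))
                assert cur >= prev - 1e-9
                prev = cur
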