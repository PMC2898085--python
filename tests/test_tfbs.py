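import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stridemod.tfbs import (PWM, PromoterPair, conservation_mask,
                            conserved_hits, read_jaspar, reverse_complement,
                            scan_pwm, tfbs_enrichment, write_jaspar)


def simple_pwm(consensus="ACGTCA", match=85):
    return PWM.from_consensus("TEST", consensus, match_count=match)


def brute_force_scan(seq, pwm, cutoff, both_strands=True):
    """Score every window of every strand directly from the log-odds."""
    lo = pwm.log_odds
    L = pwm.length
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        for i in range(len(s) - L + 1):
            raw = sum(lo[enc[s[i + j]], j] for j in range(L))
            rel = (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)
            if rel >= cutoff:
                pos = i if strand == "+" else len(seq) - i - L
                hits.append((pos, strand, round(raw, 9)))
    return sorted(hits)


class TestConservationMask:
    def test_identical_sequences_fully_conserved(self):
        pair = PromoterPair("g", "ACGT" * 30, "ACGT" * 30, tss=0)
        assert conservation_mask(pair, window_bp=50).all()

    def test_fully_gapped_ortholog_unconserved(self):
        pair = PromoterPair("g", "ACGT" * 30, "-" * 120, tss=0)
        assert not conservation_mask(pair, window_bp=50).any()

    def test_conserved_block_in_divergent_flank(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        n, start, width = 300, 120, 60
        target = "".join(rng.choice(list(bases), n))
        ortho = list("".join(rng.choice(list(bases), n)))  # ~25% identity
        block = np.arange(start, start + width)
        keep = rng.random(width) < 0.8                      # 80% identity block
        for pos, same in zip(block, keep):
            ortho[pos] = target[pos] if same else ortho[pos]
        pair = PromoterPair("g", target, "".join(ortho), tss=0)
        window = 50
        mask = conservation_mask(pair, window_bp=window, threshold=0.70)
        # oracle: direct enumeration of qualifying windows
        match = np.array([t == o for t, o in zip(target, ortho)])
        expected = np.zeros(n, dtype=bool)
        for s in range(n - window + 1):
            if match[s:s + window].mean() >= 0.70:
                expected[s:s + window] = True
        np.testing.assert_array_equal(mask, expected)
        assert mask[start + width // 2]

    def test_gap_columns_dropped_from_target_coordinates(self):
        pair = PromoterPair("g", "AC-GT" * 24, "AC-GT" * 24, tss=0)
        mask = conservation_mask(pair, window_bp=20)
        assert mask.size == len(pair.target_ungapped)

    def test_window_longer_than_alignment_rejected(self):
        pair = PromoterPair("g", "ACGT", "ACGT", tss=0)
        with pytest.raises(ValueError):
            conservation_mask(pair, window_bp=50)


class TestScan:
    def test_sequence_shorter_than_motif(self):
        assert scan_pwm("ACG", simple_pwm()) == []

    def test_consensus_scores_relative_one(self):
        pwm = simple_pwm("ACGTCA")
        seq = "TTTT" + pwm.consensus + "TTTT"
        hits = [h for h in scan_pwm(seq, pwm, min_relative_score=0.99)
                if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].start == 4
        assert hits[0].rel_score == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        pwm = simple_pwm("GATTAC")
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 200))
            got = sorted((h.start, h.strand, round(h.score, 9))
                         for h in scan_pwm(seq, pwm, min_relative_score=0.6))
            assert got == brute_force_scan(seq, pwm, 0.6)

    def test_tss_offset_shifts_coordinates(self):
        pwm = simple_pwm("ACGTCA")
        seq = "TT" + pwm.consensus
        hit = scan_pwm(seq, pwm, min_relative_score=0.99, tss=5,
                       both_strands=False)[0]
        assert hit.start == -3
        assert hit.end == -3 + pwm.length

    def test_n_bases_score_as_background(self):
        pwm = simple_pwm("ACGTCA")
        full = scan_pwm(pwm.consensus, pwm, min_relative_score=0.0,
                        both_strands=False)[0]
        with_n = scan_pwm("N" + pwm.consensus[1:], pwm,
                          min_relative_score=0.0, both_strands=False)[0]
        assert with_n.score == pytest.approx(
            full.score - pwm.log_odds[0, 0])


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=10, max_size=60))
def test_scan_strand_symmetry(seq):
    """Scanning the reverse complement mirrors positions, keeps scores."""
    pwm = simple_pwm("GATTAC")
    fwd = scan_pwm(seq, pwm, min_relative_score=0.0)
    rev = scan_pwm(reverse_complement(seq), pwm, min_relative_score=0.0)
    assert sorted((h.start, round(h.score, 6)) for h in fwd) == \
        sorted((len(seq) - h.end, round(h.score, 6)) for h in rev)


class TestConservedHits:
    def test_all_false_mask_gives_nothing(self):
        pwm = simple_pwm()
        seq = "TT" + pwm.consensus + "TT"
        pair = PromoterPair("g", seq, seq, tss=0)
        mask = np.zeros(len(seq), dtype=bool)
        assert conserved_hits(pair, pwm, mask=mask) == []

    def test_cap_keeps_top_scoring(self):
        pwm = simple_pwm("ACGTCA")
        seq = ("TT" + pwm.consensus) * 60
        pair = PromoterPair("g", seq, seq, tss=0)
        hits = conserved_hits(pair, pwm, cap=50, min_relative_score=0.99)
        assert len(hits) == 50
        assert all(h.rel_score == pytest.approx(1.0) for h in hits)

    def test_equals_brute_force_filter_sort_truncate(self):
        rng = np.random.default_rng(3)
        pwm = simple_pwm("GATTAC")
        seq = "".join(rng.choice(list("ACGT"), 400))
        pair = PromoterPair("g", seq, seq, tss=0)
        mask = rng.random(400) < 0.6
        got = conserved_hits(pair, pwm, mask=mask, cap=5,
                             min_relative_score=0.5)
        all_hits = scan_pwm(seq, pwm, min_relative_score=0.5)
        kept = [h for h in all_hits if mask[h.start:h.start + 6].all()]
        kept.sort(key=lambda h: (-h.score, h.start, h.strand))
        expected = sorted(kept[:5], key=lambda h: (h.start, h.strand))
        assert [(h.start, h.strand) for h in got] == \
            [(h.start, h.strand) for h in expected]
        assert all(h.conserved for h in got)


class TestEnrichment:
    def test_equal_presence_rates_fold_one(self):
        presence = {f"g{i}": i % 2 == 0 for i in range(40)}
        fg = [f"g{i}" for i in range(10)]
        bg = [f"g{i}" for i in range(40)]
        res = tfbs_enrichment(fg, bg, presence)
        assert res.fold == pytest.approx(1.0)

    def test_worked_example_fold_and_tail(self):
        bg = [f"g{i}" for i in range(100)]
        fg = bg[:10]
        presence = {g: False for g in bg}
        for g in fg[:8]:
            presence[g] = True
        for g in bg[10:22]:
            presence[g] = True
        res = tfbs_enrichment(fg, bg, presence)
        assert res.fold == pytest.approx((8 / 10) / (20 / 100))
        assert res.p == pytest.approx(
            float(stats.hypergeom.sf(7, 100, 20, 10)), rel=1e-12)

    def test_zero_background_presence_flags_infinite(self):
        bg = [f"g{i}" for i in range(20)]
        res = tfbs_enrichment(bg[:5], bg, {g: False for g in bg})
        assert res.K == 0 and not res.infinite_fold

    def test_foreground_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            tfbs_enrichment(["x"], ["a", "b"], {})

    def test_shuffled_foreground_calibrated(self):
        rng = np.random.default_rng(9)
        bg = [f"g{i}" for i in range(200)]
        presence = {g: bool(rng.random() < 0.3) for g in bg}
        false_pos = 0
        n_shuffles = 100
        for _ in range(n_shuffles):
            fg = list(rng.choice(bg, size=30, replace=False))
            if tfbs_enrichment(fg, bg, presence).p < 0.05:
                false_pos += 1
        assert false_pos / n_shuffles <= 0.07


class TestJasparIO:
    def test_round_trip(self, tmp_path):
        pwms = [PWM.from_consensus("MA0001", "ACGTACGT", name="motif1"),
                PWM.from_consensus("MA0002", "TTGACA", name="motif2")]
        path = tmp_path / "pwms.jaspar"
        write_jaspar(pwms, path)
        back = read_jaspar(path)
        assert set(back) == {"MA0001", "MA0002"}
        np.testing.assert_allclose(back["MA0001"].counts, pwms[0].counts)
        assert back["MA0002"].consensus == "TTGACA"
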