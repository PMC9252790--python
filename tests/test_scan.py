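"""Tests for the variant scanner: joint score, window maxima, per-TF
combination and sequence-pair extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varbind.models import reverse_complement
from varbind.scan import (
    ScanConfig,
    ScanError,
    ScanOutcome,
    SequencePair,
    Variant,
    best_window_score,
    combine_per_tf,
    joint_score,
    scan_variant,
    variant_to_sequence_pair,
)
from varbind.synth import make_pcm, make_tffm_for_pcm
from varbind.models import pcm_to_pwm, BackgroundDistribution


def _planted_background(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def sharp_pwm():
    """High-information 8-mer PWM with an unambiguous consensus."""
    pcm = make_pcm(seed=123, length=8, concentration=60.0, tf_name="SHARP",
                   model_id="SHARP.1")
    return pcm_to_pwm(pcm, BackgroundDistribution.uniform(), 1.0)


class TestJointScore:
    def test_equal_scores_give_exact_zero(self):
        assert joint_score(0.7, 0.7) == 0.0
        assert joint_score(0.0, 0.0) == 0.0
        assert joint_score(1.0, 1.0) == 0.0

    def test_extreme_loss_and_gain(self):
        # WT=1, MT=0: F = -(1+a)/a + 1 = -10 at a=0.1
        expected = 2.0 / (1.0 + 2.0 ** 20) - 1.0
        assert joint_score(1.0, 0.0, 0.1) == pytest.approx(expected, abs=1e-12)
        assert joint_score(0.0, 1.0, 0.1) == pytest.approx(-expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ScanError):
            joint_score(1.2, 0.5)
        with pytest.raises(ScanError):
            joint_score(0.5, -0.1)
        with pytest.raises(ScanError):
            joint_score(0.5, 0.5, alpha=0.0)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.01, 2.0))
    def test_antisymmetry_and_bounds(self, a, b, alpha):
        s_ab = joint_score(a, b, alpha)
        s_ba = joint_score(b, a, alpha)
        assert s_ab == pytest.approx(-s_ba, abs=1e-12)
        assert -1.0 < s_ab < 1.0

    def test_monotone_in_mt_at_fixed_wt(self):
        mt = np.linspace(0, 1, 501)
        for wt in (0.0, 0.3, 0.9, 1.0):
            s = joint_score(np.full_like(mt, wt), mt)
            assert np.all(np.diff(s) >= 0)

    def test_sign_agrees_with_score_difference(self):
        rng = np.random.default_rng(2)
        wt, mt = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        s = joint_score(wt, mt)
        assert np.all(np.sign(s) == np.sign(mt - wt))


class TestVariantParsing:
    def test_chromosomal_notation_round_trip(self):
        v = Variant.from_string("1:160001799G>C")
        assert (v.chrom, v.pos, v.ref, v.alt) == ("1", 160001799, "G", "C")
        assert str(v) == "1:160001799G>C"

    @pytest.mark.parametrize("bad", ["1:123G", "chr1:0A>C", "1:5N>C",
                                     "1:5A>A", "nonsense"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(ScanError):
            Variant.from_string(bad)

    def test_sequence_pair_derives_variant(self):
        pair = SequencePair.from_sequences("ACGTACGT", "ACGAACGT")
        assert (pair.variant_offset, pair.ref, pair.alt) == (3, "T", "A")

    def test_sequence_pair_indel_left_anchored(self):
        pair = SequencePair.from_sequences("ACGTTT", "ACGTT")
        assert pair.ref[0] == pair.alt[0]
        assert len(pair.ref) == len(pair.alt) + 1


class TestBestWindow:
    def test_planted_consensus_found_at_zero_offset(self, sharp_pwm):
        rng = np.random.default_rng(0)
        flank = _planted_background(rng, 30)
        seq = flank + sharp_pwm.consensus() + _planted_background(rng, 30)
        hit = best_window_score(sharp_pwm, seq, 30)
        assert hit.score == 1.0 and hit.offset == 0 and hit.strand == "+"

    def test_reverse_complement_found_on_minus_strand(self, sharp_pwm):
        rng = np.random.default_rng(1)
        flank = _planted_background(rng, 30)
        seq = flank + reverse_complement(sharp_pwm.consensus()) + \
            _planted_background(rng, 30)
        hit = best_window_score(sharp_pwm, seq, 30)
        assert hit.score == 1.0 and hit.offset == 0 and hit.strand == "-"

    @pytest.mark.parametrize("offset,found", [(15, True), (16, False),
                                              (-15, True), (-16, False)])
    def test_window_range_boundary(self, sharp_pwm, offset, found):
        rng = np.random.default_rng(3)
        anchor = 40
        seq = list(_planted_background(rng, 100))
        start = anchor + offset
        seq[start:start + sharp_pwm.length] = list(sharp_pwm.consensus())
        hit = best_window_score(sharp_pwm, "".join(seq), anchor)
        assert (hit.score == 1.0) is found

    def test_no_valid_window_warns_and_scores_zero(self, sharp_pwm):
        with pytest.warns(UserWarning, match="no scorable window"):
            hit = best_window_score(sharp_pwm, "ACGT", 2)
        assert hit.score == 0.0 and hit.offset is None


class TestScanVariant:
    def test_change_outside_windows_gives_zero_for_all_models(self, sharp_pwm,
                                                              toy_tffm):
        rng = np.random.default_rng(4)
        wt = _planted_background(rng, 120)
        # change a base far beyond the window+motif reach of the anchor
        pos = 100
        mt = wt[:pos] + ("A" if wt[pos] != "A" else "C") + wt[pos + 1:]
        pair = SequencePair(wt, mt, variant_offset=30)
        for o in scan_variant(pair, [sharp_pwm, toy_tffm]):
            assert o.WT == o.MT and o.S == 0.0

    def test_destroying_consensus_gives_negative_s(self, sharp_pwm):
        rng = np.random.default_rng(5)
        cons = sharp_pwm.consensus()
        anti = sharp_pwm.anti_consensus()
        wt = _planted_background(rng, 40) + cons + _planted_background(rng, 40)
        off = 40 + 3
        mt = wt[:off] + anti[3] + wt[off + 1:]
        pair = SequencePair(wt, mt, off, ref=wt[off], alt=anti[3])
        (outcome,) = scan_variant(pair, [sharp_pwm])
        assert outcome.WT == 1.0 and outcome.MT < 1.0 and outcome.S < 0

    def test_creating_consensus_gives_positive_s(self, sharp_pwm):
        rng = np.random.default_rng(6)
        cons = sharp_pwm.consensus()
        anti = sharp_pwm.anti_consensus()
        broken = cons[:3] + anti[3] + cons[4:]
        mt_flank = _planted_background(rng, 40)
        wt = mt_flank + broken + _planted_background(rng, 40)
        off = 40 + 3
        mt = wt[:off] + cons[3] + wt[off + 1:]
        pair = SequencePair(wt, mt, off, ref=anti[3], alt=cons[3])
        (outcome,) = scan_variant(pair, [sharp_pwm])
        assert outcome.MT == 1.0 and outcome.S > 0

    def test_long_deletion_rejected(self, sharp_pwm):
        wt = "A" * 40 + "C" * 40
        pair = SequencePair(wt, wt[:20] + wt[55:], 20, ref=wt[20:56],
                            alt=wt[20])
        with pytest.raises(ScanError, match="deletion abolishes"):
            scan_variant(pair, [sharp_pwm], ScanConfig())

    def test_strand_invariance_with_mapped_range(self, sharp_pwm, toy_tffm):
        """Scanning the reverse complement of both sequences with the
        RC-mapped window-start range reproduces WT, MT and S exactly."""
        rng = np.random.default_rng(7)
        wt = _planted_background(rng, 90)
        off = 45
        mt = wt[:off] + ("G" if wt[off] != "G" else "T") + wt[off + 1:]
        cfg = ScanConfig()
        for model in (sharp_pwm, toy_tffm):
            L, m = model.length, 1
            fwd_wt = best_window_score(model, wt, off, cfg)
            fwd_mt = best_window_score(model, mt, off, cfg)
            rc_off = len(wt) - off - m
            mapped = (m - L - cfg.window_halfwidth, m - L + cfg.window_halfwidth)
            rc_wt = best_window_score(model, reverse_complement(wt), rc_off,
                                      cfg, start_range=mapped)
            rc_mt = best_window_score(model, reverse_complement(mt), rc_off,
                                      cfg, start_range=mapped)
            assert rc_wt.score == pytest.approx(fwd_wt.score, abs=1e-12)
            assert rc_mt.score == pytest.approx(fwd_mt.score, abs=1e-12)

    def test_strand_invariance_on_interior_site(self, sharp_pwm):
        """With the best windows well inside the range, default-config RC
        scanning gives the same scores."""
        rng = np.random.default_rng(8)
        cons = sharp_pwm.consensus()
        wt = _planted_background(rng, 40) + cons + _planted_background(rng, 40)
        off = 40 + 2
        mt = wt[:off] + sharp_pwm.anti_consensus()[2] + wt[off + 1:]
        pair = SequencePair(wt, mt, off)
        (fwd,) = scan_variant(pair, [sharp_pwm])
        rc_pair = SequencePair(reverse_complement(wt), reverse_complement(mt),
                               len(wt) - off - 1)
        (rc,) = scan_variant(rc_pair, [sharp_pwm])
        assert (rc.WT, rc.MT) == pytest.approx((fwd.WT, fwd.MT), abs=1e-12)
        assert rc.S == pytest.approx(fwd.S, abs=1e-12)


def _outcome(tf, kind, s):
    return ScanOutcome(model_id=f"{tf}.{kind}", tf_name=tf, model_kind=kind,
                       source="test", WT=0.5, MT=0.5, S=s,
                       best_wt_offset=0, best_wt_strand="+",
                       best_mt_offset=0, best_mt_strand="+")


class TestCombinePerTf:
    def test_mean_of_two_tffms(self):
        preds = combine_per_tf([_outcome("TFX", "TFFM_first", 0.5),
                                _outcome("TFX", "TFFM_detailed", -0.5)])
        assert preds[0].combined_S == 0.0
        assert preds[0].n_models_used == 2

    def test_tffm_only_excludes_pwm(self):
        outs = [_outcome("TFX", "TFFM_first", 0.8), _outcome("TFX", "PWM", -0.8)]
        (pred,) = combine_per_tf(outs, tffm_only=True)
        assert pred.combined_S == pytest.approx(0.8)
        assert pred.n_models_used == 1 and pred.tffm_only_used

    def test_all_models_averages_both(self):
        outs = [_outcome("TFX", "TFFM_first", 0.8), _outcome("TFX", "PWM", -0.8)]
        (pred,) = combine_per_tf(outs, tffm_only=False)
        assert pred.combined_S == 0.0 and pred.n_models_used == 2

    def test_pwm_only_factor_falls_back_to_pwms(self):
        (pred,) = combine_per_tf([_outcome("TFY", "PWM", 0.4)], tffm_only=True)
        assert pred.combined_S == pytest.approx(0.4)
        assert not pred.tffm_only_used

    def test_sorted_by_magnitude(self):
        preds = combine_per_tf([_outcome("A", "PWM", 0.1),
                                _outcome("B", "PWM", -0.9)], tffm_only=False)
        assert [p.tf_name for p in preds] == ["B", "A"]


class TestVariantToSequencePair:
    GENOME = {"7": "ACGT" * 50}

    def test_span_arithmetic(self):
        v = Variant("7", 100, self.GENOME["7"][99], "T"
                    if self.GENOME["7"][99] != "T" else "A")
        pair = variant_to_sequence_pair(v, self.GENOME, ScanConfig(),
                                        max_model_length=10)
        assert len(pair.wt_seq) == 49
        assert pair.variant_offset == 24
        assert pair.wt_seq[24] == v.ref

    def test_reference_mismatch_rejected(self):
        base = self.GENOME["7"][99]
        wrong = "C" if base != "C" else "G"
        v = Variant("7", 100, wrong, "T")
        with pytest.raises(ScanError, match="reference allele does not match"):
            variant_to_sequence_pair(v, self.GENOME, ScanConfig(), 10)

    def test_left_edge_clipping(self):
        v = Variant("7", 3, self.GENOME["7"][2], "A"
                    if self.GENOME["7"][2] != "A" else "C")
        pair = variant_to_sequence_pair(v, self.GENOME, ScanConfig(), 10)
        assert pair.variant_offset == 2
        assert len(pair.wt_seq) == 2 + 1 + 24

    def test_unknown_chromosome(self):
        with pytest.raises(ScanError, match="unknown chromosome"):
            variant_to_sequence_pair(Variant("99", 5, "A", "C"),
                                     self.GENOME, ScanConfig(), 5)

    def test_chr_prefix_normalized(self):
        v = Variant("chr7", 100, self.GENOME["7"][99], "T"
                    if self.GENOME["7"][99] != "T" else "A")
        pair = variant_to_sequence_pair(v, self.GENOME, ScanConfig(), 10)
        assert pair.variant_offset == 24
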