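"""Hairpin evaluation: energy arithmetic, criterion rejections, threshold
monotonicity, and star detection."""

from __future__ import annotations

import numpy as np
import pytest

from seedmir.fold import SecondaryStructure, fold
from seedmir.hairpin import (
    HairpinCandidate,
    HairpinThresholds,
    MatureNotInWindow,
    Rejection,
    compute_energies,
    detect_star,
    evaluate_candidate,
    extract_windows,
    gc_percent,
    revcomp,
)
from seedmir.preprocess import SmallRNATag

COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
NONPAIR = {"A": "AGC", "C": "ACU", "G": "AG", "U": "CU"}


def make_precursor(seed=0, n_mismatch=0, loop_len=30, arm="5p", mature_len=21):
    """Stem-first construction: mature + loop + near-perfect star."""
    rng = np.random.default_rng(seed)
    mature = "".join(rng.choice(list("ACGU"), mature_len))
    star = [COMP[b] for b in reversed(mature)]
    if n_mismatch:
        for p in rng.choice(np.arange(3, mature_len - 3), n_mismatch, replace=False):
            star[mature_len - 1 - int(p)] = str(rng.choice(list(NONPAIR[mature[int(p)]])))
    loop = "".join(rng.choice(list("ACGU"), loop_len))
    if arm == "5p":
        pre = mature + loop + "".join(star)
    else:
        pre = "".join(star) + loop + mature
    return pre, mature


class TestComputeEnergies:
    def test_amfe_and_mfei_formula(self):
        s = SecondaryStructure("GCAU" * 25, "." * 100, -50.0)  # 50% GC
        mfe, amfe, mfei = compute_energies(s, s.sequence)
        assert (mfe, amfe, mfei) == (-50.0, -50.0, -1.0)

    def test_zero_mfe(self):
        s = SecondaryStructure("GCAU" * 25, "." * 100, 0.0)
        assert compute_energies(s, s.sequence)[1:] == (0.0, 0.0)

    def test_mfei_at_47_percent_gc(self):
        seq = "G" * 47 + "A" * 53
        s = SecondaryStructure(seq, "." * 100, -61.15)
        assert compute_energies(s, seq)[2] == pytest.approx(-61.15 / 47, abs=1e-6)

    def test_gc_free_sequence_rejected(self):
        s = SecondaryStructure("AU" * 50, "." * 100, -5.0)
        with pytest.raises(ValueError, match="MFEI"):
            compute_energies(s, s.sequence)

    def test_gc_percent(self):
        assert gc_percent("GGCC") == 100.0
        assert gc_percent("AUAU") == 0.0
        assert gc_percent("") == 0.0


class TestEvaluateCandidate:
    def test_valid_precursor_accepted(self):
        pre, mature = make_precursor(seed=3, n_mismatch=1)
        res = evaluate_candidate(pre, mature)
        assert isinstance(res, HairpinCandidate)
        assert res.mfe <= -20
        assert 5 <= res.distance <= 240
        assert res.n_mismatch <= 6
        assert res.arm == "5p"

    def test_3p_arm_detected(self):
        pre, mature = make_precursor(seed=5, arm="3p")
        res = evaluate_candidate(pre, mature)
        assert isinstance(res, HairpinCandidate)
        assert res.arm == "3p"

    def test_seven_mismatches_rejected(self):
        for seed in range(5):
            pre, mature = make_precursor(seed=seed, n_mismatch=7, loop_len=28)
            res = evaluate_candidate(pre, mature)
            assert isinstance(res, Rejection)
            if res.reason == "too_many_mismatches":
                return
        pytest.fail("no construct produced a mismatch-count rejection")

    def test_distance_241_rejected(self):
        pre, mature = make_precursor(seed=2, loop_len=241)
        res = evaluate_candidate(pre, mature)
        assert isinstance(res, Rejection)
        assert res.reason == "bad_distance"

    def test_distance_4_rejected(self):
        pre, mature = make_precursor(seed=2, loop_len=4)
        res = evaluate_candidate(pre, mature)
        assert isinstance(res, Rejection)
        # a 4-nt gap may also preclude any clean one-arm duplex
        assert res.reason in ("bad_distance", "not_hairpin", "structural_break")

    def test_weak_stem_rejected_on_mfe(self):
        """An A/U-only stem cannot reach -20 kcal/mol."""
        rng = np.random.default_rng(8)
        mature = "".join(rng.choice(list("AU"), 21))
        pre = mature + "".join(rng.choice(list("ACGU"), 30)) + "".join(
            COMP[b] for b in reversed(mature)
        )
        res = evaluate_candidate(pre, mature)
        assert isinstance(res, Rejection)
        assert res.reason in ("mfe_too_high", "mfei_too_low", "no_star")

    def test_mature_24nt_never_accepted(self):
        pre, mature = make_precursor(seed=9, mature_len=24)
        res = evaluate_candidate(pre, mature)
        assert isinstance(res, Rejection)
        assert res.reason == "bad_mature_length"

    def test_mature_absent_is_error_not_rejection(self):
        pre, _ = make_precursor(seed=1)
        with pytest.raises(MatureNotInWindow):
            evaluate_candidate(pre, "ACGUACGUACGUACGUACGUA")

    def test_unpaired_mature_has_no_star(self):
        window = "A" * 120
        res = evaluate_candidate(window, "A" * 21, thresholds=HairpinThresholds())
        assert isinstance(res, Rejection)
        assert res.reason == "no_star"

    def test_accepted_candidate_self_consistent(self):
        """Re-check every reported quantity of an accepted candidate with
        independent code walking the pair table."""
        cand = None
        for seed in range(13, 30):  # skip constructs too weak to accept
            pre, mature = make_precursor(seed=seed, n_mismatch=2)
            cand = evaluate_candidate(pre, mature)
            if isinstance(cand, HairpinCandidate):
                break
        assert isinstance(cand, HairpinCandidate)
        pt = cand.structure.pair_table()
        m0, m1 = cand.mature_span
        s0, s1 = cand.star_span
        # mature on one arm: all its partners inside the star span
        partners = [pt[i] for i in range(m0, m1) if pt[i] >= 0 and s0 <= pt[i] < s1]
        assert len(partners) == (m1 - m0) - cand.n_mismatch
        assert partners == sorted(partners, reverse=True)
        assert sum(1 for i in range(s0, s1) if pt[i] < 0) == cand.n_unpaired
        gap = s0 - m1 if s0 >= m1 else m0 - s1
        assert gap == cand.distance
        assert cand.amfe == pytest.approx(cand.mfe * 100 / len(cand.precursor))
        assert cand.mfei == pytest.approx(cand.amfe / gc_percent(cand.precursor))

    def test_threshold_loosening_is_monotone(self):
        """Relaxing any single threshold never turns an accepted candidate
        into a rejection."""
        default = HairpinThresholds()
        looser = [
            HairpinThresholds(max_mismatch=10),
            HairpinThresholds(max_unpaired=10),
            HairpinThresholds(min_distance=1, max_distance=400),
            HairpinThresholds(mfe_max=-5.0),
            HairpinThresholds(mature_len_min=18, mature_len_max=25),
            HairpinThresholds(mfei_floor=0.2),
        ]
        for seed in range(12):
            pre, mature = make_precursor(seed=seed, n_mismatch=seed % 3)
            if isinstance(evaluate_candidate(pre, mature, thresholds=default), HairpinCandidate):
                for t in looser:
                    assert isinstance(
                        evaluate_candidate(pre, mature, thresholds=t), HairpinCandidate
                    ), f"accepted candidate lost under looser {t}"


class TestExtractWindows:
    GENOME = {"chr1": "".join(np.random.default_rng(0).choice(list("ACGT"), 2000))}

    def test_window_size_cap(self):
        hit = ("chr1", 1000, 1021, "+")
        for w, off, locus, trunc in extract_windows(hit, self.GENOME, flank=250):
            assert len(w) <= 250 + 21 + 250
            assert not trunc
            assert w[off : off + 21] == self.GENOME["chr1"][1000:1021].replace("T", "U")

    def test_genome_start_truncates(self):
        hit = ("chr1", 5, 26, "+")
        windows = extract_windows(hit, self.GENOME, flank=250)
        assert any(trunc for _, _, _, trunc in windows)

    def test_minus_strand_window_contains_revcomp_tag(self):
        tag = revcomp(self.GENOME["chr1"][700:721])
        hit = ("chr1", 700, 721, "-")
        for w, off, _, _ in extract_windows(hit, self.GENOME, flank=100):
            assert w[off : off + 21] == tag.replace("T", "U")


class TestDetectStar:
    def test_star_tag_recorded(self):
        pre, mature = make_precursor(seed=21)
        cand = evaluate_candidate(pre, mature)
        assert isinstance(cand, HairpinCandidate)
        star_seq = cand.precursor[slice(*cand.star_span)].replace("U", "T")
        tags = [SmallRNATag(star_seq, (4, 3)), SmallRNATag("ACGT" * 5, (9, 0))]
        out = detect_star([cand], tags)
        assert out[0].star_reads == 7
        assert out[0].star_tags == [star_seq]

    def test_no_star_tag(self):
        pre, mature = make_precursor(seed=22)
        cand = evaluate_candidate(pre, mature)
        out = detect_star([cand], [SmallRNATag("ACGTACGTACGTACGTACGT", (1, 1))])
        assert out[0].star_reads == 0
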