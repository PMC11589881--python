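"""Hydrophobicity scale scoring: orderings, additivity and the window scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memtail import HydrophobicityScale, UnknownResidueError
from memtail.scale import DEFAULT_HELIX_LENGTHS, STANDARD_AA

HYDROPHOBIC = "LIFVW"
POLAR_CHARGED = "DEKRNQ"

aa_text = st.text(alphabet=STANDARD_AA, max_size=40)


class TestResidueDg:
    def test_total_over_standard_alphabet(self, scale):
        for aa in STANDARD_AA:
            assert np.isfinite(scale.residue_dg(aa))

    def test_leucine_more_favorable_than_asparagine(self, scale):
        assert scale.residue_dg("L") < scale.residue_dg("N")

    @pytest.mark.parametrize("bad", ["U", "X", "B", "Z", "a", "*"])
    def test_nonstandard_letter_rejected_by_name(self, scale, bad):
        with pytest.raises(UnknownResidueError, match=bad if bad != "*" else None):
            scale.residue_dg(bad)

    def test_hydrophobic_below_polar_on_shipped_scale(self, scale):
        worst_hydrophobic = max(scale.residue_dg(a) for a in HYDROPHOBIC)
        best_polar = min(scale.residue_dg(a) for a in POLAR_CHARGED)
        assert worst_hydrophobic < best_polar


class TestTailHydrophilicity:
    def test_empty_sum_is_zero(self, scale):
        assert scale.tail_hydrophilicity("") == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(s1=aa_text, s2=aa_text)
    def test_additive_over_concatenation(self, scale, s1, s2):
        total = scale.tail_hydrophilicity(s1) + scale.tail_hydrophilicity(s2)
        assert scale.tail_hydrophilicity(s1 + s2) == pytest.approx(total)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(s=aa_text)
    def test_appending_asparagine_strictly_increases(self, scale, s):
        assert scale.tail_hydrophilicity(s + "N") > scale.tail_hydrophilicity(s)

    def test_extension_orderings_match_experiment(self, scale):
        """GSGS is the mild extension; HSDS tracks 4xN; the opsin tag is hydrophilic."""
        gsgs = scale.tail_hydrophilicity("GSGS")
        nnnn = scale.tail_hydrophilicity("NNNN")
        hsds = scale.tail_hydrophilicity("HSDS")
        opsin = scale.tail_hydrophilicity("GPNFYVPFSNKTG")
        assert gsgs < nnnn
        assert gsgs < hsds
        assert abs(hsds - nnnn) < abs(gsgs - nnnn)
        assert opsin > 0
        assert opsin > gsgs


class TestSegmentDg:
    def test_poly_leu_window_is_favorable(self, scale):
        # oracle: 19 x the shipped Leu value
        expected = 19 * scale.residue_dg("L")
        score = scale.segment_dg("L" * 19, 1, 19, positional=False)
        assert score.dg_app == pytest.approx(expected)
        assert score.dg_app < 0
        assert scale.segment_dg("L" * 19, 1, 19).dg_app < 0

    def test_flat_fallback_is_plain_sum(self, scale):
        seq = "LIVNQKAGSTWYFMHEDCRP"
        score = scale.segment_dg(seq, 2, 19, positional=False)
        assert score.dg_app == pytest.approx(scale.tail_hydrophilicity(seq[1:20]))

    def test_poly_asn_less_favorable_than_poly_leu(self, scale):
        for positional in (True, False):
            dg_n = scale.segment_dg("N" * 19, 1, 19, positional=positional).dg_app
            dg_l = scale.segment_dg("L" * 19, 1, 19, positional=positional).dg_app
            assert dg_n > dg_l

    def test_window_out_of_bounds(self, scale):
        with pytest.raises(ValueError, match="out of bounds"):
            scale.segment_dg("L" * 20, 5, 19)


def brute_force_min_dg(scale, seq, tm_center, slack, lengths):
    """Independent exhaustive scan over (center, length) via cumulative sums."""
    vals = np.array([scale.residue_dg(a) for a in seq])
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    best = None
    for length in lengths:
        half = (length - 1) // 2
        for center in range(tm_center - slack, tm_center + slack + 1):
            start = center - half
            end = start + length - 1
            if start < 1 or end > len(seq):
                continue
            dg = csum[end] - csum[start - 1]
            if best is None or dg < best[0]:
                best = (dg, start, end)
    return best


class TestMinDgNearCenter:
    def test_degenerate_scan_equals_centered_window(self, scale):
        seq = "NQKL" * 20
        got = scale.min_dg_near_center(seq, 40, slack=0, lengths=[19])
        want = scale.segment_dg(seq, 40 - 9, 19)
        assert got == want

    def test_recenters_onto_offset_hydrophobic_patch(self, scale):
        # hydrophilic background with a Leu patch centred at 33 (annotated 30)
        seq = list("N" * 60)
        seq[33 - 10 : 33 + 9] = "L" * 19
        seq = "".join(seq)
        got = scale.min_dg_near_center(seq, 30, slack=5, lengths=[19],
                                       positional=False)
        oracle = brute_force_min_dg(scale, seq, 30, 5, [19])
        assert (got.start, got.end) == (oracle[1], oracle[2])
        assert got.center == 33

    def test_never_worse_than_centered_window(self, scale):
        rng = np.random.default_rng(42)
        letters = list(STANDARD_AA)
        for _ in range(25):
            seq = "".join(rng.choice(letters, size=60))
            got = scale.min_dg_near_center(seq, 30, slack=5)
            centered = scale.segment_dg(seq, 30 - 10, 21)
            assert got.dg_app <= centered.dg_app + 1e-12

    def test_matches_exhaustive_oracle_on_random_sequences(self, scale):
        rng = np.random.default_rng(7)
        letters = list(STANDARD_AA)
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=60))
            center = int(rng.integers(12, 49))
            got = scale.min_dg_near_center(
                seq, center, slack=5, positional=False
            )
            want = brute_force_min_dg(
                scale, seq, center, 5, DEFAULT_HELIX_LENGTHS
            )
            assert got.dg_app == pytest.approx(want[0])
            # the returned window attains the minimum (ties may resolve to
            # a different but equally scoring window)
            attained = brute_force_min_dg(
                scale, seq, got.center, 0, [got.length]
            )
            assert attained[0] == pytest.approx(want[0])
            assert not got.truncated

    def test_tm_too_close_to_terminus_flags_truncated_window(self, scale):
        got = scale.min_dg_near_center("L" * 12, 3, slack=5)
        assert got.truncated
        assert got.start >= 1 and got.end <= 12
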