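"""Stop-loss variant extension: translation, HGVS parsing, re-classification."""

import numpy as np
import pytest

from memtail import (
    NonstopVariant,
    TailProfile,
    apply_nonstop,
    classify_effect,
    parse_hgvs_c,
    parse_hgvs_p,
)
from memtail.variant_nonstop import (
    STOP_CODONS,
    NoTerminatingCodonError,
    NotANonstopVariantError,
)
from memtail.synthetic_data import make_cds, reachable_first_residues

GENETIC_CODE = {
    # independent table for the brute-force oracle
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def brute_force_extension(cds, hgvs_c):
    """Oracle: mutate, translate the whole ORF from base 1, return the extension."""
    pos, ref, alt = parse_hgvs_c(hgvs_c)
    assert cds[pos - 1] == ref
    seq = cds[: pos - 1] + alt + cds[pos:]
    protein = []
    for i in range(0, len(seq) - 2, 3):
        aa = GENETIC_CODE[seq[i : i + 3]]
        if aa == "*":
            return "".join(protein)
        protein.append(aa)
    raise AssertionError("no stop codon in oracle translation")


class TestHgvsParsing:
    def test_coding_variant(self):
        assert parse_hgvs_c("c.467A>T") == (467, "A", "T")

    def test_protein_ter_variant(self):
        assert parse_hgvs_p("p.Ter156Leu") == (155, "L")

    @pytest.mark.parametrize("bad", ["c.467A-T", "p.Ter156", "467A>T"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_hgvs_c(bad)
        with pytest.raises(ValueError):
            parse_hgvs_p(bad)


class TestApplyNonstop:
    def test_toy_cds_extension(self):
        v = NonstopVariant(
            "toy", "ATGAAATAATTTTGA", hgvs_c="c.7T>C", wt_protein_len=2
        )
        ext = apply_nonstop(v)
        assert ext.wt_seq == "MK"
        assert ext.extension_seq == "QF"
        assert ext.new_seq == "MKQF"

    def test_variant_outside_stop_codon_rejected(self):
        v = NonstopVariant(
            "t", "ATGAAATAATTTTGA", hgvs_c="c.4A>C", wt_protein_len=2
        )
        with pytest.raises(NotANonstopVariantError, match="not a nonstop"):
            apply_nonstop(v)

    def test_stop_to_stop_substitution_rejected(self):
        # TAA -> TGA still terminates
        v = NonstopVariant(
            "t", "ATGAAATAATTTTGA", hgvs_c="c.8A>G", wt_protein_len=2
        )
        with pytest.raises(NotANonstopVariantError):
            apply_nonstop(v)

    def test_no_downstream_stop_rejected(self):
        v = NonstopVariant(
            "t", "ATGAAATAATTTTTT", hgvs_c="c.7T>C", wt_protein_len=2
        )
        with pytest.raises(NoTerminatingCodonError):
            apply_nonstop(v)

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            NonstopVariant(
                "t", "ATGAAATAATTTTGA", hgvs_c="c.7A>C", wt_protein_len=2
            )

    def test_matches_brute_force_oracle_on_random_cds(self):
        rng = np.random.default_rng(99)
        first_pool = sorted(reachable_first_residues())
        aa_pool = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(150):
            protein = "".join(rng.choice(aa_pool, size=int(rng.integers(5, 40))))
            ext = first_pool[int(rng.integers(0, len(first_pool)))] + "".join(
                rng.choice(aa_pool, size=int(rng.integers(0, 20)))
            )
            v = make_cds(protein, ext, rng=rng)
            got = apply_nonstop(v)
            want = brute_force_extension(v.cds_seq, v.hgvs_c)
            assert got.wt_seq + got.extension_seq == want
            assert got.extension_seq == ext


def cext_profile(tail_seq, tail_dg, tail_len=None):
    return TailProfile(
        id="p", tail_seq=tail_seq, tail_len=tail_len or len(tail_seq),
        tail_dg=tail_dg, orientation="C_ext", route="posttranslational",
        penultimate_loop_dg=0.0, n_tail_dg=0.0,
    )


class TestClassifyEffect:
    def test_c_cyt_flag_is_undefined(self, scale):
        prof = TailProfile(
            id="p", tail_seq="KRSNDE", tail_len=6,
            tail_dg=scale.tail_hydrophilicity("KRSNDE"),
            orientation="C_cyt", route="posttranslational",
            penultimate_loop_dg=0.0, n_tail_dg=0.0,
        )
        eff = classify_effect(prof, "NNNN", scale=scale)
        assert eff.misinsertion_flag is None
        assert eff.route_after == "posttranslational"

    def test_hydrophilic_extension_flags_misinsertion(self, scale):
        whf = scale.tail_hydrophilicity("WHF")
        eff = classify_effect(cext_profile("WHF", whf), "NNNN", scale=scale)
        assert eff.new_tail_len == 7
        assert eff.new_tail_dg == pytest.approx(
            whf + scale.tail_hydrophilicity("NNNN")
        )
        assert eff.new_tail_dg > 5.5
        assert eff.misinsertion_flag is True
        assert eff.flag_at_lower is True and eff.flag_at_upper is True

    def test_mild_extension_does_not_flag(self, scale):
        whf = scale.tail_hydrophilicity("WHF")
        eff = classify_effect(cext_profile("WHF", whf), "GSGS", scale=scale)
        assert eff.misinsertion_flag is False

    def test_long_extension_allows_cotranslational_insertion(self, scale):
        whf = scale.tail_hydrophilicity("WHF")
        eff = classify_effect(cext_profile("WHF", whf), "N" * 60, scale=scale)
        assert eff.route_after == "cotranslational_capable"
        assert eff.misinsertion_flag is False

    def test_tail_dg_additivity(self, scale):
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            wt = "".join(rng.choice(aa, size=5))
            ext = "".join(rng.choice(aa, size=8))
            prof = cext_profile(wt, scale.tail_hydrophilicity(wt))
            eff = classify_effect(prof, ext, scale=scale)
            assert eff.new_tail_dg == pytest.approx(
                scale.tail_hydrophilicity(wt + ext)
            )

    def test_hydrophilic_residues_never_decrease_dg(self, scale):
        prof = cext_profile("WHF", scale.tail_hydrophilicity("WHF"))
        base = classify_effect(prof, "", scale=scale)
        for ext in ["N", "ND", "NDEKR", "KKKK"]:
            eff = classify_effect(prof, ext, scale=scale)
            assert eff.new_tail_dg >= base.new_tail_dg
            assert eff.new_tail_len >= base.new_tail_len


def test_stop_codons_are_the_standard_three():
    assert STOP_CODONS == {"TAA", "TAG", "TGA"}
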