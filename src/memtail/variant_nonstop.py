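"""Stop-loss (nonstop) variant analysis.

A nonstop mutation converts a stop codon into a sense codon, so translation
continues until the next in-frame stop.  For membrane proteins whose last TM
sits near the C-terminus, the appended stretch lengthens and usually
hydrophilises the C-tail; for C_ext proteins that still require
posttranslational insertion (extended tail < 45 residues), a summed tail
ΔG^app above the insertion-capacity threshold (≈5–6 kcal/mol in E. coli)
predicts cTM misinsertion.

Variants are accepted as coding HGVS-like strings (``c.{pos}{ref}>{alt}``)
paired with an explicit CDS, or at the protein level (``p.Ter{N}{Aaa}``)
with a user-supplied extension peptide.  Only the standard genetic code is
supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq1

from .ctail import ROUTE_COTRANS, ROUTE_POST, ORIENT_CEXT, RouteParams, TailProfile
from .scale import HydrophobicityScale

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

MISINSERTION_THRESHOLD = 5.5  # kcal/mol, midpoint of the reported 5–6 band
MISINSERTION_BAND = (5.0, 6.0)

_HGVS_C = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_HGVS_P = re.compile(r"^p\.Ter(\d+)([A-Z][a-z]{2})$")


class NotANonstopVariantError(ValueError):
    pass


class NoTerminatingCodonError(ValueError):
    pass


def parse_hgvs_c(s: str) -> tuple[int, str, str]:
    """Parse ``c.{pos}{ref}>{alt}`` → (1-based coding position, ref, alt)."""
    m = _HGVS_C.match(s.strip())
    if not m:
        raise ValueError(f"cannot parse coding variant {s!r} (expected c.NX>Y)")
    return int(m.group(1)), m.group(2), m.group(3)


def parse_hgvs_p(s: str) -> tuple[int, str]:
    """Parse ``p.Ter{N}{Aaa}`` → (wild-type protein length, replacement residue).

    ``Ter`` at codon N means N−1 encoded residues precede the stop, so
    ``p.Ter156Leu`` gives wild-type length 155 with first extension residue L.
    """
    m = _HGVS_P.match(s.strip())
    if not m:
        raise ValueError(f"cannot parse protein variant {s!r} (expected p.TerNXaa)")
    ter_codon = int(m.group(1))
    aa = seq1(m.group(2))
    if aa == "X" or len(aa) != 1:
        raise ValueError(f"unknown amino-acid code in {s!r}")
    return ter_codon - 1, aa


@dataclass
class NonstopVariant:
    """A CDS plus a stop-loss variant.

    ``cds_seq`` must include the stop codon and enough 3′ UTR to reach the
    next in-frame stop; ``wt_protein_len`` may be given directly or derived
    from ``hgvs_p``.
    """

    transcript_id: str
    cds_seq: str
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    wt_protein_len: int | None = None

    def __post_init__(self) -> None:
        self.cds_seq = self.cds_seq.upper().replace("U", "T")
        if self.wt_protein_len is None:
            if self.hgvs_p is None:
                raise ValueError(
                    f"{self.transcript_id}: need wt_protein_len or hgvs_p"
                )
            self.wt_protein_len, _ = parse_hgvs_p(self.hgvs_p)
        if len(self.cds_seq) < 3 * (self.wt_protein_len + 1):
            raise ValueError(
                f"{self.transcript_id}: CDS too short for protein of "
                f"{self.wt_protein_len} residues plus stop"
            )
        if self.hgvs_c is not None:
            pos, ref, _ = parse_hgvs_c(self.hgvs_c)
            if pos > len(self.cds_seq):
                raise ValueError(f"{self.transcript_id}: variant beyond CDS")
            if self.cds_seq[pos - 1] != ref:
                raise ValueError(
                    f"{self.transcript_id}: stated ref {ref!r} does not match "
                    f"CDS base {self.cds_seq[pos - 1]!r} at c.{pos}"
                )


@dataclass
class ExtendedProtein:
    """Result of applying a nonstop variant: the extended translation product."""

    transcript_id: str
    wt_seq: str
    extension_seq: str

    @property
    def new_seq(self) -> str:
        return self.wt_seq + self.extension_seq


@dataclass
class VariantEffect:
    """Re-classification of the C-terminus after a nonstop extension."""

    extension_seq: str
    wt_tail_len: int
    new_tail_len: int
    wt_tail_dg: float
    new_tail_dg: float
    route_after: str
    misinsertion_flag: bool | None  # None for C_cyt proteins
    threshold_used: float
    flag_at_lower: bool | None = None  # at the 5 kcal/mol bound
    flag_at_upper: bool | None = None  # at the 6 kcal/mol bound


def _translate_codon(codon: str) -> str | None:
    """One-letter amino acid, or None for a stop codon."""
    if codon in STOP_CODONS:
        return None
    try:
        return standard_dna_table.forward_table[codon]
    except KeyError:
        raise ValueError(f"untranslatable codon {codon!r}") from None


def apply_nonstop(variant: NonstopVariant) -> ExtendedProtein:
    """Extend translation through a mutated stop codon to the next in-frame stop.

    The coding variant must fall inside the stop codon and must abolish it
    (:class:`NotANonstopVariantError` otherwise).  Translation proceeds in
    frame from the mutated stop position until the next stop codon within
    the provided sequence (:class:`NoTerminatingCodonError` if none).
    """
    wt_len = variant.wt_protein_len
    cds = variant.cds_seq
    stop_start = 3 * wt_len  # 0-based index of the stop codon's first base
    stop_codon = cds[stop_start : stop_start + 3]
    if stop_codon not in STOP_CODONS:
        raise ValueError(
            f"{variant.transcript_id}: codon at position {wt_len + 1} is "
            f"{stop_codon!r}, not a stop codon — check wt_protein_len"
        )
    if variant.hgvs_c is None:
        raise ValueError(
            f"{variant.transcript_id}: a coding variant (hgvs_c) is required "
            "to apply a nonstop extension from a CDS"
        )
    pos, _, alt = parse_hgvs_c(variant.hgvs_c)
    if not stop_start + 1 <= pos <= stop_start + 3:
        raise NotANonstopVariantError(
            f"{variant.transcript_id}: c.{pos} does not hit the stop codon "
            f"(c.{stop_start + 1}-{stop_start + 3}) — not a nonstop variant"
        )
    mutated = list(cds)
    mutated[pos - 1] = alt
    mutated_cds = "".join(mutated)
    new_stop_codon = mutated_cds[stop_start : stop_start + 3]
    if new_stop_codon in STOP_CODONS:
        raise NotANonstopVariantError(
            f"{variant.transcript_id}: substitution leaves a stop codon "
            f"({new_stop_codon}) — not a nonstop variant"
        )

    wt_seq = []
    for i in range(0, stop_start, 3):
        aa = _translate_codon(cds[i : i + 3])
        if aa is None:
            raise ValueError(
                f"{variant.transcript_id}: premature stop at codon {i // 3 + 1}"
            )
        wt_seq.append(aa)

    extension = []
    i = stop_start
    while True:
        codon = mutated_cds[i : i + 3]
        if len(codon) < 3:
            raise NoTerminatingCodonError(
                f"{variant.transcript_id}: no in-frame stop codon downstream "
                "of the mutated stop within the provided sequence"
            )
        aa = _translate_codon(codon)
        if aa is None:
            break
        extension.append(aa)
        i += 3

    ext_seq = "".join(extension)
    if variant.hgvs_p is not None:
        _, first_aa = parse_hgvs_p(variant.hgvs_p)
        if ext_seq and ext_seq[0] != first_aa:
            raise ValueError(
                f"{variant.transcript_id}: protein variant says Ter->"
                f"{first_aa} but CDS gives {ext_seq[0]!r}"
            )
    return ExtendedProtein(
        transcript_id=variant.transcript_id,
        wt_seq="".join(wt_seq),
        extension_seq=ext_seq,
    )


def classify_effect(
    wt_profile: TailProfile,
    extension_seq: str,
    params: RouteParams | None = None,
    threshold: float = MISINSERTION_THRESHOLD,
    scale: HydrophobicityScale | None = None,
) -> VariantEffect:
    """Re-classify the C-terminus after appending a nonstop extension.

    The new tail is the wild-type tail plus the extension; its ΔG^app is
    additive.  The insertion route reapplies the <45-residue rule.  For
    C_ext proteins, misinsertion is flagged when the extended protein still
    requires posttranslational insertion but the new tail hydrophilicity
    exceeds the threshold; flags at both band edges (5 and 6 kcal/mol) are
    reported alongside.  For C_cyt proteins the flag is undefined (None).
    """
    scale = scale or HydrophobicityScale.default()
    params = params or RouteParams()
    ext_dg = scale.tail_hydrophilicity(extension_seq)
    new_tail_len = wt_profile.tail_len + len(extension_seq)
    new_tail_dg = wt_profile.tail_dg + ext_dg
    route_after = (
        ROUTE_POST
        if new_tail_len < params.cotranslational_min_tail
        else ROUTE_COTRANS
    )
    if wt_profile.orientation == ORIENT_CEXT:
        still_post = route_after == ROUTE_POST
        flag = still_post and new_tail_dg > threshold
        flag_lo = still_post and new_tail_dg > MISINSERTION_BAND[0]
        flag_hi = still_post and new_tail_dg > MISINSERTION_BAND[1]
    else:
        flag = flag_lo = flag_hi = None
    return VariantEffect(
        extension_seq=extension_seq,
        wt_tail_len=wt_profile.tail_len,
        new_tail_len=new_tail_len,
        wt_tail_dg=wt_profile.tail_dg,
        new_tail_dg=new_tail_dg,
        route_after=route_after,
        misinsertion_flag=flag,
        threshold_used=threshold,
        flag_at_lower=flag_lo,
        flag_at_upper=flag_hi,
    )
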