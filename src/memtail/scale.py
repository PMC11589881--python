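"""ΔG^app scoring against the biological hydrophobicity scale.

The biological hydrophobicity scale assigns each of the 20 standard amino
acids an apparent free energy of membrane insertion (ΔG^app, kcal/mol) for a
residue positioned at the middle of the membrane.  Negative values favour
insertion (hydrophobic residues such as Leu and Ile); positive values oppose
it (charged and polar residues such as Asp and Lys).  Two derived quantities
are used throughout the package:

* **loop/tail hydrophilicity** — the sum of mid-membrane ΔG^app values over
  all residues of a loop or terminal tail; large positive sums mark segments
  that resist translocation across the membrane;
* **TM segment ΔG^app** — the score of a candidate helix window, under an
  optional positional model that down-weights contributions away from the
  window centre (a Gaussian profile emulating the position dependence of
  insertion free energies across the bilayer).

The scale ships as a TSV data file (``data/biological_hydrophobicity.tsv``,
columns ``residue``, ``dg_mid`` and the positional width ``sigma``); the code
never hard-codes coefficient values.  Selenocysteine (``U``) must be replaced
by Cys *before* scoring — :func:`HydrophobicityScale.residue_dg` rejects it
explicitly, as it rejects every non-standard letter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_HELIX_LENGTHS: tuple[int, ...] = tuple(range(19, 24))
"""Candidate helix window lengths scanned by :meth:`min_dg_near_center`."""


class UnknownResidueError(ValueError):
    """Raised when a sequence letter is outside the 20 standard amino acids."""

    def __init__(self, aa: str):
        self.aa = aa
        if aa == "U":
            msg = (
                "unknown residue 'U' (selenocysteine): substitute U->C "
                "before scoring"
            )
        else:
            msg = f"unknown residue {aa!r}: not one of the 20 standard amino acids"
        super().__init__(msg)


@dataclass(frozen=True)
class SegmentScore:
    """ΔG^app of one candidate helix window (1-based inclusive coordinates)."""

    start: int
    end: int
    dg_app: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if not math.isfinite(self.dg_app):
            raise ValueError("dg_app must be finite")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class HydrophobicityScale:
    """Per-residue mid-membrane ΔG^app values plus a positional profile.

    Parameters
    ----------
    per_residue_mid
        Mapping of each of the 20 standard one-letter codes to its
        mid-membrane ΔG^app contribution (kcal/mol).
    positional_sigma
        Optional per-residue Gaussian width (residues) for the positional
        model.  When ``None`` the scale only supports flat (mid-only)
        segment scoring.
    source_tag
        Free-text provenance of the coefficient file.
    """

    def __init__(
        self,
        per_residue_mid: Mapping[str, float],
        positional_sigma: Mapping[str, float] | None = None,
        source_tag: str = "",
    ):
        got = set(per_residue_mid)
        want = set(STANDARD_AA)
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise ValueError(
                f"scale must cover exactly the 20 standard amino acids; "
                f"missing={missing} extra={extra}"
            )
        for aa, v in per_residue_mid.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite dg_mid for {aa!r}")
        self.per_residue_mid = {aa: float(v) for aa, v in per_residue_mid.items()}
        if positional_sigma is not None:
            if set(positional_sigma) != want:
                raise ValueError("positional_sigma must cover all 20 amino acids")
            positional_sigma = {aa: float(v) for aa, v in positional_sigma.items()}
            if any(v <= 0 for v in positional_sigma.values()):
                raise ValueError("positional widths must be positive")
        self.positional_sigma = positional_sigma
        self.source_tag = source_tag

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path) -> "HydrophobicityScale":
        """Load a scale from a TSV file (columns: residue, dg_mid[, sigma])."""
        df = pd.read_csv(path, sep="\t")
        if "residue" not in df.columns or "dg_mid" not in df.columns:
            raise ValueError(
                f"scale file {path} must have 'residue' and 'dg_mid' columns"
            )
        mid = dict(zip(df["residue"], df["dg_mid"]))
        sigma = dict(zip(df["residue"], df["sigma"])) if "sigma" in df.columns else None
        return cls(mid, sigma, source_tag=str(path))

    @classmethod
    def default(cls) -> "HydrophobicityScale":
        """The shipped biological hydrophobicity scale."""
        return _load_default()

    # -------------------------------------------------------------- scoring
    def residue_dg(self, aa: str) -> float:
        """Mid-membrane ΔG^app (kcal/mol) of a single residue.

        Raises :class:`UnknownResidueError` for any letter outside the 20
        standard amino acids, including B/Z/X and (deliberately) U.
        """
        try:
            return self.per_residue_mid[aa]
        except KeyError:
            raise UnknownResidueError(aa) from None

    def tail_hydrophilicity(self, seq: str) -> float:
        """Summed mid-membrane ΔG^app over a loop or tail sequence.

        Additive over concatenation; the empty string scores 0.  Positive
        sums mark hydrophilic segments.
        """
        return float(sum(self.residue_dg(aa) for aa in seq))

    def _positional_weight(self, aa: str, offset: float) -> float:
        sigma = self.positional_sigma[aa]
        return math.exp(-(offset * offset) / (2.0 * sigma * sigma))

    def segment_dg(
        self, seq: str, start: int, length: int, positional: bool = True
    ) -> SegmentScore:
        """ΔG^app of the helix window ``seq[start .. start+length-1]`` (1-based).

        With the positional model enabled (and available), each residue's
        mid-membrane value is weighted by a Gaussian of its offset from the
        window centre; otherwise the score degrades to the plain sum of
        mid-membrane values over the window.
        """
        if length < 1:
            raise ValueError("window length must be >= 1")
        end = start + length - 1
        if start < 1 or end > len(seq):
            raise ValueError(
                f"window [{start}, {end}] out of bounds for sequence of "
                f"length {len(seq)}"
            )
        window = seq[start - 1 : end]
        if positional and self.positional_sigma is not None:
            mid = (length - 1) / 2.0
            dg = sum(
                self.residue_dg(aa) * self._positional_weight(aa, i - mid)
                for i, aa in enumerate(window)
            )
        else:
            dg = sum(self.residue_dg(aa) for aa in window)
        return SegmentScore(start=start, end=end, dg_app=float(dg))

    def min_dg_near_center(
        self,
        seq: str,
        tm_center: int,
        slack: int = 5,
        lengths: Iterable[int] = DEFAULT_HELIX_LENGTHS,
        positional: bool = True,
    ) -> SegmentScore:
        """Minimal segment ΔG^app over windows centred within ±slack of a TM centre.

        Scans every allowed window length and every centre within ``slack``
        residues of ``tm_center`` (clipped to the sequence bounds) and keeps
        the window with the minimal ΔG^app.  When no candidate window fits —
        the TM lies too close to a terminus for any allowed length — the
        largest window that does fit near the centre is scored instead and
        returned with ``truncated=True``.
        """
        if slack < 0:
            raise ValueError("slack must be >= 0")
        if not 1 <= tm_center <= len(seq):
            raise ValueError(f"tm_center {tm_center} outside sequence")
        lengths = sorted(set(int(x) for x in lengths))
        if not lengths or lengths[0] < 1:
            raise ValueError("window lengths must be positive")
        n = len(seq)
        best: SegmentScore | None = None
        for length in lengths:
            half = (length - 1) // 2
            for center in range(tm_center - slack, tm_center + slack + 1):
                start = center - half
                if start < 1 or start + length - 1 > n:
                    continue
                score = self.segment_dg(seq, start, length, positional=positional)
                if best is None or score.dg_app < best.dg_app:
                    best = score
        if best is not None:
            return best
        # Fallback: nothing fits — score the largest fitting window, flagged.
        for length in range(min(lengths[-1], n), 0, -1):
            half = (length - 1) // 2
            start = min(max(tm_center - half, 1), n - length + 1)
            score = self.segment_dg(seq, start, length, positional=positional)
            return SegmentScore(score.start, score.end, score.dg_app, truncated=True)
        raise AssertionError("unreachable: non-empty sequence always fits length 1")


@lru_cache(maxsize=1)
def _load_default() -> HydrophobicityScale:
    ref = resources.files("memtail.data").joinpath("biological_hydrophobicity.tsv")
    with resources.as_file(ref) as path:
        scale = HydrophobicityScale.from_tsv(path)
    scale.source_tag = "biological hydrophobicity scale (shipped)"
    return scale


def substitute_selenocysteine(seq: str) -> tuple[str, int]:
    """Replace selenocysteine (U) with Cys; returns (new_seq, n_substituted)."""
    n = seq.count("U")
    return (seq.replace("U", "C"), n) if n else (seq, 0)
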