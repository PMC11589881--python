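"""Sequence and topology I/O plus the canonical topology data model.

Coordinates are 1-based and inclusive everywhere (UniProt feature
convention).  A membrane topology is an ordered list of non-overlapping TM
segments plus the membrane side of the N-terminus ("in" = cytosolic,
"out" = extracytosolic); loop sides then alternate deterministically across
each TM.  Predictor outputs may carry a missing topology — absence of data
is a value, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import groupby

import pandas as pd
from Bio import SeqIO

from .scale import substitute_selenocysteine

logger = logging.getLogger(__name__)

SIDE_IN = "in"
SIDE_OUT = "out"
PREDICTOR_SOURCES = ("cctop", "tmalphafold", "polyphobius")

MIN_PROTEIN_LEN = 18
MAX_PROTEIN_LEN = 10_000


def flip(side: str) -> str:
    if side == SIDE_IN:
        return SIDE_OUT
    if side == SIDE_OUT:
        return SIDE_IN
    raise ValueError(f"invalid membrane side {side!r}")


@dataclass
class ProteinRecord:
    """One protein sequence (post U→C substitution) with optional annotations."""

    id: str
    sequence: str
    organism: str = ""
    organelle: str | None = None  # "mitochondrial" | "peroxisomal" | None
    signal_peptide_end: int | None = None  # 1-based last signal-peptide residue

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length_ok(self) -> bool:
        """False when the protein falls outside the 18–10,000 residue range."""
        return MIN_PROTEIN_LEN <= len(self.sequence) <= MAX_PROTEIN_LEN


@dataclass
class TMSegment:
    """One transmembrane helix, 1-based inclusive coordinates."""

    start: int
    end: int
    dg_app: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid TM segment [{self.start}, {self.end}]")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Topology:
    """Ordered TM segments plus the membrane side of the N-terminus."""

    segments: list[TMSegment]
    n_term_side: str

    def __post_init__(self) -> None:
        if self.n_term_side not in (SIDE_IN, SIDE_OUT):
            raise ValueError(f"invalid n_term_side {self.n_term_side!r}")
        if not self.segments:
            raise ValueError("topology must contain at least one TM segment")
        prev = None
        for seg in self.segments:
            if prev is not None and seg.start <= prev.end + 1:
                raise ValueError(
                    f"TM segments overlap or touch: [{prev.start},{prev.end}] "
                    f"then [{seg.start},{seg.end}] (need >=1 loop residue)"
                )
            prev = seg

    @property
    def n_tm(self) -> int:
        return len(self.segments)

    @property
    def c_term_side(self) -> str:
        """Side of the C-terminus: the N-side flipped once per TM."""
        side = self.n_term_side
        for _ in self.segments:
            side = flip(side)
        return side

    def side_after_tm(self, k: int) -> str:
        """Membrane side of the loop following the k-th TM (1-based)."""
        side = self.n_term_side
        for _ in range(k):
            side = flip(side)
        return side


@dataclass
class PredictorOutput:
    """Topology from one predictor; ``topology=None`` means missing data."""

    source: str
    topology: Topology | None
    meta: dict = field(default_factory=dict)
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.source not in PREDICTOR_SOURCES:
            raise ValueError(
                f"unknown predictor source {self.source!r}; "
                f"expected one of {PREDICTOR_SOURCES}"
            )


@dataclass
class Loop:
    """A non-TM stretch (N-tail, inter-TM loop, or C-tail)."""

    side: str
    start: int
    end: int  # end < start encodes an empty loop
    sequence: str

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


# --------------------------------------------------------------------- FASTA
def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records from FASTA, substituting U→C (logged).

    Records outside the 18–10,000 residue range are kept but exposed via
    ``ProteinRecord.length_ok`` — filtering happens downstream.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_sub_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, n_sub = substitute_selenocysteine(str(rec.seq).upper())
        n_sub_total += n_sub
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_sub_total:
        logger.info("substituted %d selenocysteine (U) residues by C", n_sub_total)
    return records


# ----------------------------------------------------- TOPCONS-style strings
def read_topology_string(
    protein_id: str, topo_string: str, source: str = "polyphobius"
) -> PredictorOutput:
    """Parse a TOPCONS-dialect per-residue topology string.

    Alphabet: ``i`` (cytosolic), ``o`` (extracytosolic), ``M`` (TM helix),
    ``S`` (signal peptide, leading run only).  Maximal runs of ``M`` are TM
    segments; the N-terminal side comes from the first non-S, non-M
    character.  The signal-peptide end (if any) is recorded in
    ``meta["signal_peptide_end"]``.
    """
    allowed = set("ioMS")
    bad = set(topo_string) - allowed
    if bad:
        raise ValueError(
            f"{protein_id}: invalid topology characters {sorted(bad)!r}"
        )
    if not topo_string:
        raise ValueError(f"{protein_id}: empty topology string")

    sp_end = 0
    while sp_end < len(topo_string) and topo_string[sp_end] == "S":
        sp_end += 1
    body = topo_string[sp_end:]
    if "S" in body:
        raise ValueError(
            f"{protein_id}: 'S' permitted only as a leading signal-peptide run"
        )
    if not body:
        raise ValueError(f"{protein_id}: topology string is all signal peptide")
    if body[0] == "M":
        raise ValueError(
            f"{protein_id}: TM run at the N-terminus with no flanking side "
            "information"
        )

    n_term_side = SIDE_IN if body[0] == "i" else SIDE_OUT
    segments: list[TMSegment] = []
    pos = sp_end  # 0-based index into topo_string
    expected_side = body[0]
    for char, run in groupby(topo_string[sp_end:]):
        run_len = len(list(run))
        if char == "M":
            segments.append(TMSegment(start=pos + 1, end=pos + run_len))
            expected_side = "i" if expected_side == "o" else "o"
        elif char != expected_side:
            raise ValueError(
                f"{protein_id}: loop side {char!r} at position {pos + 1} "
                f"breaks alternation (expected {expected_side!r})"
            )
        pos += run_len

    if not segments:
        raise ValueError(f"{protein_id}: no TM segments in topology string")
    topo = Topology(segments=segments, n_term_side=n_term_side)
    meta: dict = {}
    if sp_end:
        meta["signal_peptide_end"] = sp_end
    return PredictorOutput(
        source=source, topology=topo, meta=meta, protein_id=protein_id
    )


def topology_to_string(
    topology: Topology, length: int, signal_peptide_end: int = 0
) -> str:
    """Render a topology as a TOPCONS-dialect string of the given length."""
    if topology.segments[-1].end > length:
        raise ValueError("topology extends beyond the stated sequence length")
    chars = []
    side = topology.n_term_side
    seg_iter = iter(topology.segments)
    seg = next(seg_iter, None)
    pos = 1
    while pos <= length:
        if seg is not None and pos == seg.start:
            chars.extend("M" * seg.length)
            pos = seg.end + 1
            side = flip(side)
            seg = next(seg_iter, None)
        else:
            chars.append("i" if side == SIDE_IN else "o")
            pos += 1
    s = "".join(chars)
    if signal_peptide_end:
        s = "S" * signal_peptide_end + s[signal_peptide_end:]
    return s


# ------------------------------------------------------------- segment TSVs
_REQUIRED_COLS = ("id", "source", "n_term_side", "start", "end")


def read_segment_table(path) -> list[PredictorOutput]:
    """Read per-predictor TM segment tables from TSV.

    Expected header: ``id  source  n_term_side  start  end  [tests_passed]``,
    one row per TM segment.  Rows are grouped by (id, source) into one
    :class:`PredictorOutput` each; the TMAlphaFold quality-test count (if
    present) lands in ``meta["tests_passed"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "source": str})
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    outputs: list[PredictorOutput] = []
    for (pid, source), grp in df.groupby(["id", "source"], sort=True):
        segments = []
        tests_passed = None
        for idx, row in grp.sort_values("start").iterrows():
            line_no = idx + 2  # header is line 1
            try:
                start, end = int(row["start"]), int(row["end"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {line_no}: non-integer start/end"
                ) from None
            try:
                segments.append(TMSegment(start=start, end=end))
            except ValueError as e:
                raise ValueError(f"{path}: line {line_no}: {e}") from None
            if "tests_passed" in grp.columns and pd.notna(row["tests_passed"]):
                tests_passed = int(row["tests_passed"])
        n_term_side = str(grp["n_term_side"].iloc[0])
        first_line = grp.index.min() + 2
        try:
            topo = Topology(segments=segments, n_term_side=n_term_side)
        except ValueError as e:
            raise ValueError(f"{path}: rows from line {first_line}: {e}") from None
        meta = {} if tests_passed is None else {"tests_passed": tests_passed}
        outputs.append(
            PredictorOutput(
                source=source, topology=topo, meta=meta, protein_id=pid
            )
        )
    return outputs


def write_segment_table(outputs: list[PredictorOutput], path) -> None:
    """Inverse of :func:`read_segment_table` (missing topologies are skipped)."""
    rows = []
    for out in outputs:
        if out.topology is None:
            continue
        for seg in out.topology.segments:
            rows.append(
                {
                    "id": out.protein_id,
                    "source": out.source,
                    "n_term_side": out.topology.n_term_side,
                    "start": seg.start,
                    "end": seg.end,
                    "tests_passed": out.meta.get("tests_passed", ""),
                }
            )
    pd.DataFrame(rows, columns=list(_REQUIRED_COLS) + ["tests_passed"]).to_csv(
        path, sep="\t", index=False
    )


# -------------------------------------------------------------------- loops
def loops_of(topology: Topology, record: ProteinRecord) -> list[Loop]:
    """Derive all non-TM stretches, N-tail and C-tail included.

    Loops tile every non-TM residue of the sequence; sides alternate from
    the N-terminal side across each TM.  Signal-peptide residues (when
    annotated on the record) are excluded from the N-tail sequence.
    """
    n = len(record.sequence)
    if topology.segments[-1].end > n:
        raise ValueError(
            f"{record.id}: topology extends beyond sequence length {n}"
        )
    loops: list[Loop] = []
    side = topology.n_term_side
    sp_end = record.signal_peptide_end or 0

    # N-tail (signal peptide excised)
    first = topology.segments[0]
    n_tail_start = sp_end + 1
    n_tail_end = first.start - 1
    loops.append(
        Loop(
            side=side,
            start=n_tail_start,
            end=n_tail_end,
            sequence=record.sequence[n_tail_start - 1 : n_tail_end],
        )
    )

    for k in range(topology.n_tm):
        side = flip(side)
        start = topology.segments[k].end + 1
        end = (
            topology.segments[k + 1].start - 1
            if k + 1 < topology.n_tm
            else n
        )
        loops.append(
            Loop(
                side=side,
                start=start,
                end=end,
                sequence=record.sequence[start - 1 : end],
            )
        )
    return loops
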