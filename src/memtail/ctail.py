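"""C-terminus characterisation and cohort assembly.

The C-tail is the stretch following the last (C-terminal-most) TM.  Its
membrane side determines the topology class — C_cyt (cytosolic C-terminus)
versus C_ext (extracytosolic) — and its length determines the insertion
route: tails shorter than ~45 residues finish translation inside the
ribosome exit tunnel and must insert posttranslationally, longer tails
permit cotranslational insertion.  Cohorts are built by filtering a
proteome to translocon-inserted multispanning proteins (length in range,
≥3 TMs, non-organellar) and profiling each retained protein.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import pandas as pd

from .consensus import ConsensusTopology
from .scale import HydrophobicityScale
from .topology_io import (
    SIDE_IN,
    ProteinRecord,
    Topology,
    loops_of,
)

ORIENT_CCYT = "C_cyt"
ORIENT_CEXT = "C_ext"
ROUTE_POST = "posttranslational"
ROUTE_COTRANS = "cotranslational_capable"


@dataclass(frozen=True)
class RouteParams:
    """Cohort filters and the co-/post-translational length threshold."""

    cotranslational_min_tail: int = 45  # residues
    min_tms: int = 3
    min_len: int = 18
    max_len: int = 10_000

    def __post_init__(self) -> None:
        if min(
            self.cotranslational_min_tail, self.min_tms, self.min_len, self.max_len
        ) <= 0:
            raise ValueError("all RouteParams must be positive")


@dataclass
class TailProfile:
    """Per-protein C-terminus profile."""

    id: str
    tail_seq: str
    tail_len: int
    tail_dg: float  # summed ΔG^app, kcal/mol
    orientation: str  # C_cyt | C_ext
    route: str  # posttranslational | cotranslational_capable
    penultimate_loop_dg: float
    n_tail_dg: float
    n_tm: int = 0
    quality: str | None = None


def _topology_of(consensus: ConsensusTopology | Topology) -> Topology:
    return consensus.topology if isinstance(consensus, ConsensusTopology) else consensus


def profile(
    record: ProteinRecord,
    consensus: ConsensusTopology | Topology,
    scale: HydrophobicityScale | None = None,
    params: RouteParams | None = None,
) -> TailProfile:
    """Build the :class:`TailProfile` of one protein.

    The tail starts at the residue immediately after the consensus C-terminal
    TM.  Orientation follows loop-side parity (C-side "in" → C_cyt); the
    route applies the strict ``tail_len < 45`` rule.  The penultimate loop is
    the loop preceding the last TM (for single-TM proteins this is the
    N-tail).
    """
    scale = scale or HydrophobicityScale.default()
    params = params or RouteParams()
    topo = _topology_of(consensus)
    loops = loops_of(topo, record)
    c_tail = loops[-1]
    penultimate = loops[-2]

    tail_dg = scale.tail_hydrophilicity(c_tail.sequence)
    orientation = ORIENT_CCYT if c_tail.side == SIDE_IN else ORIENT_CEXT
    route = (
        ROUTE_POST
        if c_tail.length < params.cotranslational_min_tail
        else ROUTE_COTRANS
    )
    quality = (
        consensus.quality if isinstance(consensus, ConsensusTopology) else None
    )
    return TailProfile(
        id=record.id,
        tail_seq=c_tail.sequence,
        tail_len=c_tail.length,
        tail_dg=tail_dg,
        orientation=orientation,
        route=route,
        penultimate_loop_dg=scale.tail_hydrophilicity(penultimate.sequence),
        n_tail_dg=scale.tail_hydrophilicity(loops[0].sequence),
        n_tm=topo.n_tm,
        quality=quality,
    )


def filter_proteome(
    records: Iterable[ProteinRecord],
    consensus_map: Mapping[str, ConsensusTopology | Topology],
    params: RouteParams | None = None,
    exclusion_list: Iterable[str] = (),
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Filter to translocon-inserted multispanning proteins.

    Filters apply in order: length (18–10,000 residues) → TM count (≥3) →
    organelle exclusion (user-supplied ID list, or an organelle tag on the
    record).  Returns the retained records and per-filter removal counts;
    records without a consensus topology are counted under ``no_topology``.
    """
    params = params or RouteParams()
    excluded_ids = set(exclusion_list)
    counts = {"length": 0, "tm": 0, "organelle": 0, "no_topology": 0}
    retained: list[ProteinRecord] = []
    for rec in records:
        n = len(rec.sequence)
        if n < params.min_len or n > params.max_len:
            counts["length"] += 1
            continue
        cons = consensus_map.get(rec.id)
        if cons is None:
            counts["no_topology"] += 1
            continue
        if _topology_of(cons).n_tm < params.min_tms:
            counts["tm"] += 1
            continue
        if rec.id in excluded_ids or rec.organelle in (
            "mitochondrial",
            "peroxisomal",
        ):
            counts["organelle"] += 1
            continue
        retained.append(rec)
    return retained, counts


def cohort_table(profiles: Iterable[TailProfile]) -> pd.DataFrame:
    """One row per protein, deterministically ordered by id."""
    rows = [asdict(p) for p in profiles]
    columns = [
        "id", "tail_seq", "tail_len", "tail_dg", "orientation", "route",
        "penultimate_loop_dg", "n_tail_dg", "n_tm", "quality",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("id", kind="mergesort").reset_index(drop=True)


def write_cohort_table(profiles: Iterable[TailProfile], path) -> None:
    cohort_table(profiles).to_csv(path, sep="\t", index=False, float_format="%.4f")
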