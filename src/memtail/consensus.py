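"""Multi-predictor topology consensus.

Merges up to three predictor outputs (CCTOP-style, TMAlphaFold-style,
PolyPhobius-style) into a single consensus topology with a quality label:

* all three present and pairwise agreeing → quality ``high`` (coordinates
  from CCTOP);
* else CCTOP + TMAlphaFold agree → CCTOP coordinates;
* else TMAlphaFold + PolyPhobius agree → TMAlphaFold coordinates;
* otherwise (disagreement or missing data) PolyPhobius is preferred over
  CCTOP over TMAlphaFold and the result is labelled ``low``.

Two topologies *agree* when their TM counts match and, pairing TMs by rank
order, every pair of segment centres falls within a configurable window
(default 14 residues, read as |Δcenter| ≤ 7).  TMAlphaFold predictions that
passed fewer than 5 of its quality tests are discarded up front.
"""

from __future__ import annotations

from dataclasses import dataclass

from .topology_io import PredictorOutput, Topology

QUALITY_HIGH = "high"
QUALITY_MEDIUM = "medium"
QUALITY_LOW = "low"


@dataclass(frozen=True)
class ConsensusParams:
    """Knobs of the agreement and priority rules."""

    center_window: int = 14  # agreement window, residues (|Δcenter| ≤ window/2)
    tmaf_min_tests: int = 5  # TMAlphaFold quality-test filter
    two_way_quality: str = QUALITY_LOW  # label for two-way agreements

    def __post_init__(self) -> None:
        if self.center_window < 0:
            raise ValueError("center_window must be >= 0")
        if self.two_way_quality not in (QUALITY_LOW, QUALITY_MEDIUM):
            raise ValueError("two_way_quality must be 'low' or 'medium'")


@dataclass
class ConsensusTopology:
    """Merged topology with quality label and provenance."""

    topology: Topology
    quality: str
    provenance: str  # which source supplied the coordinates
    agreement: frozenset[frozenset[str]]  # agreeing source pairs


def topologies_agree(a: Topology, b: Topology, params: ConsensusParams) -> bool:
    """True iff TM counts match and all rank-paired centres are within window/2."""
    if a.n_tm != b.n_tm:
        return False
    half = params.center_window / 2.0
    return all(
        abs(sa.center - sb.center) <= half
        for sa, sb in zip(a.segments, b.segments)
    )


def _usable(out: PredictorOutput | None, params: ConsensusParams) -> Topology | None:
    if out is None or out.topology is None:
        return None
    if out.source == "tmalphafold":
        tests = out.meta.get("tests_passed")
        if tests is not None and tests < params.tmaf_min_tests:
            return None
    return out.topology


def merge(
    cctop: PredictorOutput | None = None,
    tmalphafold: PredictorOutput | None = None,
    polyphobius: PredictorOutput | None = None,
    params: ConsensusParams | None = None,
) -> ConsensusTopology:
    """Merge up to three predictor outputs into one consensus topology.

    The output topology is always one of the inputs verbatim — no
    coordinate averaging.  Raises ``ValueError`` when every source is
    absent (or filtered out).
    """
    params = params or ConsensusParams()
    topos = {
        "cctop": _usable(cctop, params),
        "tmalphafold": _usable(tmalphafold, params),
        "polyphobius": _usable(polyphobius, params),
    }
    if all(t is None for t in topos.values()):
        raise ValueError("no usable predictor outputs to merge")

    pairs = [("cctop", "tmalphafold"), ("tmalphafold", "polyphobius"),
             ("cctop", "polyphobius")]
    agreement = frozenset(
        frozenset(p)
        for p in pairs
        if topos[p[0]] is not None
        and topos[p[1]] is not None
        and topologies_agree(topos[p[0]], topos[p[1]], params)
    )

    all_present = all(t is not None for t in topos.values())
    if all_present and len(agreement) == 3:
        return ConsensusTopology(
            topology=topos["cctop"],
            quality=QUALITY_HIGH,
            provenance="cctop",
            agreement=agreement,
        )
    if frozenset(("cctop", "tmalphafold")) in agreement:
        return ConsensusTopology(
            topology=topos["cctop"],
            quality=params.two_way_quality,
            provenance="cctop",
            agreement=agreement,
        )
    if frozenset(("tmalphafold", "polyphobius")) in agreement:
        return ConsensusTopology(
            topology=topos["tmalphafold"],
            quality=params.two_way_quality,
            provenance="tmalphafold",
            agreement=agreement,
        )
    for source in ("polyphobius", "cctop", "tmalphafold"):
        if topos[source] is not None:
            return ConsensusTopology(
                topology=topos[source],
                quality=QUALITY_LOW,
                provenance=source,
                agreement=agreement,
            )
    raise AssertionError("unreachable")
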