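"""Synthetic inputs with known ground truth for every pipeline stage.

The proteome generator emulates the structure of a multispanning membrane
proteome: alternating-side topologies with a controlled TM count, a chosen
fraction of C_ext proteins, and C-tails whose lengths and summed ΔG^app
values are drawn from per-orientation distributions (tail composition is
tuned by greedy residue swaps until the achieved hydrophilicity lies within
a tolerance of the drawn target).  Companion generators derive discordant
predictor outputs (jitter/drop/add/missing), coding sequences carrying
stop-loss variants, and noisy gel-band quantifications — each emitting the
exact formats the corresponding readers consume, alongside the ground
truth, so recovery can be asserted end to end.

All generators are deterministic functions of their spec plus seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .ctail import ORIENT_CCYT, ORIENT_CEXT, ROUTE_COTRANS, ROUTE_POST
from .insertion_assay import GelQuantification
from .scale import STANDARD_AA, HydrophobicityScale
from .topology_io import (
    SIDE_IN,
    SIDE_OUT,
    PredictorOutput,
    ProteinRecord,
    TMSegment,
    Topology,
    flip,
)
from .variant_nonstop import STOP_CODONS, NonstopVariant

logger = logging.getLogger(__name__)

TM_PALETTE = "LIVFAM"
LOOP_PALETTE = "GSTNQDEKRHAP"


# ------------------------------------------------------------------ proteome
@dataclass
class ProteomeSimSpec:
    """Study conditions for the synthetic proteome."""

    n_proteins: int = 200
    tm_count_range: tuple[int, int] = (3, 12)
    frac_c_ext: float = 0.5
    # distribution family + parameters, per orientation
    tail_len_distributions: dict = field(
        default_factory=lambda: {
            ORIENT_CEXT: ("geometric", 0.15),
            ORIENT_CCYT: ("lognormal", 3.0, 0.7),
        }
    )
    # (mean, sd) of the target summed tail ΔG^app, per orientation
    tail_dg_targets: dict = field(
        default_factory=lambda: {
            ORIENT_CEXT: (3.0, 1.5),
            ORIENT_CCYT: (12.0, 4.0),
        }
    )
    loop_len_range: tuple[int, int] = (2, 25)
    tm_len: int = 21
    dg_tolerance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_c_ext <= 1.0:
            raise ValueError("frac_c_ext must be a probability")
        for lo, hi in (self.tm_count_range, self.loop_len_range):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be non-empty and positive")


@dataclass
class PerturbSpec:
    """How predictor outputs deviate from the true topology."""

    center_jitter_sd: float = 0.0  # residues
    p_drop_tm: float = 0.0
    p_add_tm: float = 0.0
    p_missing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_drop_tm, self.p_add_tm, self.p_missing):
            if not 0.0 <= p <= 1.0:
                raise ValueError("perturbation probabilities must be in [0, 1]")


@dataclass
class SimProtein:
    record: ProteinRecord
    topology: Topology
    truth: dict


def _draw_tail_len(dist: tuple, rng: np.random.Generator) -> int:
    family = dist[0]
    if family == "geometric":
        return int(rng.geometric(dist[1]))
    if family == "lognormal":
        return max(1, int(round(rng.lognormal(dist[1], dist[2]))))
    if family == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    raise ValueError(f"unknown tail length distribution family {dist[0]!r}")


def compose_tail(
    length: int,
    target_dg: float,
    rng: np.random.Generator,
    scale: HydrophobicityScale,
    tol: float = 0.5,
    max_iter: int = 200,
) -> str | None:
    """Greedy residue swaps towards a target summed ΔG^app.

    Starts from a random composition and repeatedly applies the single
    letter substitution whose ΔG delta best cancels the residual, until the
    achieved sum is within ``tol`` of the target.  Returns None when the
    target is unreachable for this length.
    """
    dg = scale.per_residue_mid
    letters = sorted(STANDARD_AA)
    seq = [letters[i] for i in rng.integers(0, len(letters), size=length)]
    current = sum(dg[a] for a in seq)
    for _ in range(max_iter):
        residual = target_dg - current
        if abs(residual) <= tol:
            return "".join(seq)
        present = set(seq)
        best = None  # (new_abs_residual, from_aa, to_aa)
        for a in present:
            for b in letters:
                delta = dg[b] - dg[a]
                cand = abs(residual - delta)
                if cand < abs(residual) and (best is None or cand < best[0]):
                    best = (cand, a, b)
        if best is None:
            return None
        _, a, b = best
        positions = [i for i, c in enumerate(seq) if c == a]
        seq[int(rng.choice(positions))] = b
        current += dg[b] - dg[a]
    return "".join(seq) if abs(target_dg - current) <= tol else None


def _random_stretch(palette: str, length: int, rng: np.random.Generator) -> str:
    return "".join(palette[i] for i in rng.integers(0, len(palette), size=length))


def make_proteome(
    spec: ProteomeSimSpec, scale: HydrophobicityScale | None = None
) -> list[SimProtein]:
    """Generate a proteome of multispanning proteins with known ground truth."""
    scale = scale or HydrophobicityScale.default()
    rng = np.random.default_rng(spec.seed)
    lo_dg = min(scale.per_residue_mid.values())
    hi_dg = max(scale.per_residue_mid.values())
    proteins: list[SimProtein] = []
    n_resampled = 0
    for i in range(spec.n_proteins):
        n_tm = int(rng.integers(spec.tm_count_range[0], spec.tm_count_range[1] + 1))
        orientation = ORIENT_CEXT if rng.random() < spec.frac_c_ext else ORIENT_CCYT
        c_side = SIDE_OUT if orientation == ORIENT_CEXT else SIDE_IN
        n_term_side = c_side if n_tm % 2 == 0 else flip(c_side)

        tail_len = _draw_tail_len(spec.tail_len_distributions[orientation], rng)
        mean, sd = spec.tail_dg_targets[orientation]
        tail = None
        target = 0.0
        for _attempt in range(6):
            target = float(rng.normal(mean, sd))
            if not lo_dg * tail_len <= target <= hi_dg * tail_len:
                n_resampled += 1
                continue
            tail = compose_tail(tail_len, target, rng, scale, tol=spec.dg_tolerance)
            if tail is not None:
                break
            n_resampled += 1
        if tail is None:  # fall back to a mid-range reachable target
            target = float(np.clip(target, lo_dg * tail_len, hi_dg * tail_len))
            tail = compose_tail(
                tail_len, target, rng, scale, tol=spec.dg_tolerance, max_iter=2000
            )
            if tail is None:
                raise RuntimeError(
                    f"could not compose a tail of length {tail_len} near "
                    f"dG {target:.2f}"
                )

        parts = [
            _random_stretch(
                LOOP_PALETTE,
                int(rng.integers(spec.loop_len_range[0], spec.loop_len_range[1] + 1)),
                rng,
            )
        ]
        segments: list[TMSegment] = []
        pos = len(parts[0])
        for k in range(n_tm):
            tm_seq = _random_stretch(TM_PALETTE, spec.tm_len, rng)
            segments.append(TMSegment(start=pos + 1, end=pos + spec.tm_len))
            parts.append(tm_seq)
            pos += spec.tm_len
            if k < n_tm - 1:
                loop = _random_stretch(
                    LOOP_PALETTE,
                    int(
                        rng.integers(
                            spec.loop_len_range[0], spec.loop_len_range[1] + 1
                        )
                    ),
                    rng,
                )
                parts.append(loop)
                pos += len(loop)
        parts.append(tail)
        sequence = "".join(parts)

        record = ProteinRecord(id=f"sim{i:05d}", sequence=sequence)
        topology = Topology(segments=segments, n_term_side=n_term_side)
        achieved = scale.tail_hydrophilicity(tail)
        truth = {
            "orientation": orientation,
            "route": ROUTE_POST if tail_len < 45 else ROUTE_COTRANS,
            "tail_len": tail_len,
            "tail_seq": tail,
            "tail_dg_target": target,
            "tail_dg": achieved,
            "n_tm": n_tm,
        }
        proteins.append(SimProtein(record=record, topology=topology, truth=truth))
    if n_resampled:
        logger.info("resampled %d unreachable tail dG targets", n_resampled)
    return proteins


# ------------------------------------------------------------- predictors
def _jitter_segments(
    segments: list[TMSegment],
    sd: float,
    protein_len: int,
    rng: np.random.Generator,
) -> tuple[list[TMSegment], list[int]]:
    shifts = [int(round(rng.normal(0.0, sd))) for _ in segments] if sd > 0 else [
        0
    ] * len(segments)
    new: list[TMSegment] = []
    applied: list[int] = []
    for i, (seg, shift) in enumerate(zip(segments, shifts)):
        lo = (new[-1].end + 2) if new else 1
        hi = (segments[i + 1].start - 2) if i + 1 < len(segments) else protein_len
        ns, ne = seg.start + shift, seg.end + shift
        if ns < lo or ne > hi:  # shift would break the topology; keep in place
            ns, ne, shift = seg.start, seg.end, 0
        new.append(TMSegment(start=ns, end=ne))
        applied.append(shift)
    return new, applied


def make_predictor_outputs(
    truth: Topology,
    spec: PerturbSpec,
    protein_len: int,
    rng: np.random.Generator | None = None,
    protein_id: str | None = None,
    tm_len: int = 21,
) -> tuple[PredictorOutput, PredictorOutput, PredictorOutput]:
    """Derive (cctop, tmalphafold, polyphobius) outputs from a true topology.

    Each source is perturbed independently: Gaussian centre jitter, TM drop,
    spurious TM addition (into the largest loop that can host one), or
    missing data.  The perturbations that fired are recorded in
    ``meta["perturbations"]``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    outputs = []
    for source in ("cctop", "tmalphafold", "polyphobius"):
        meta: dict = {"perturbations": []}
        if source == "tmalphafold":
            meta["tests_passed"] = 10
        if rng.random() < spec.p_missing:
            meta["perturbations"].append("missing")
            outputs.append(
                PredictorOutput(
                    source=source, topology=None, meta=meta, protein_id=protein_id
                )
            )
            continue
        segments = [TMSegment(s.start, s.end) for s in truth.segments]
        if spec.center_jitter_sd > 0:
            segments, shifts = _jitter_segments(
                segments, spec.center_jitter_sd, protein_len, rng
            )
            if any(shifts):
                meta["perturbations"].append(("jitter", shifts))
        if len(segments) > 1 and rng.random() < spec.p_drop_tm:
            k = int(rng.integers(0, len(segments)))
            del segments[k]
            meta["perturbations"].append(("drop", k))
        if rng.random() < spec.p_add_tm:
            added = _add_spurious_tm(segments, protein_len, tm_len, rng)
            if added:
                meta["perturbations"].append("add")
        topo = Topology(segments=segments, n_term_side=truth.n_term_side)
        outputs.append(
            PredictorOutput(
                source=source, topology=topo, meta=meta, protein_id=protein_id
            )
        )
    return tuple(outputs)


def _add_spurious_tm(
    segments: list[TMSegment],
    protein_len: int,
    tm_len: int,
    rng: np.random.Generator,
) -> bool:
    gaps = []  # (gap_start, gap_end) inclusive, free residues
    prev_end = 0
    for seg in segments:
        gaps.append((prev_end + 1, seg.start - 1))
        prev_end = seg.end
    gaps.append((prev_end + 1, protein_len))
    usable = [(s, e) for s, e in gaps if e - s + 1 >= tm_len + 2]
    if not usable:
        return False
    s, e = usable[int(rng.integers(0, len(usable)))]
    mid = (s + e) // 2
    start = mid - tm_len // 2
    segments.append(TMSegment(start=start, end=start + tm_len - 1))
    segments.sort(key=lambda seg: seg.start)
    return True


# ------------------------------------------------------------------- CDSs
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()


def reachable_first_residues() -> frozenset[str]:
    """Amino acids reachable from a stop codon by one nucleotide substitution."""
    reachable = set()
    for stop in STOP_CODONS:
        for i in range(3):
            for base in "ACGT":
                if base == stop[i]:
                    continue
                codon = stop[:i] + base + stop[i + 1 :]
                if codon not in STOP_CODONS:
                    reachable.add(standard_dna_table.forward_table[codon])
    return frozenset(reachable)


def make_cds(
    protein: ProteinRecord | str,
    extension_peptide: str,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    utr_codons: int = 10,
) -> NonstopVariant:
    """Reverse-translate a protein and plant a stop-loss variant.

    The emitted CDS is ``codons(protein) + stop + codons(extension[1:]) +
    stop + random 3' tail`` with uniform codon choice; the variant string
    converts the first stop into a codon for the first extension residue by
    a single nucleotide substitution.  Raises ``ValueError`` when the first
    extension residue is not reachable that way (see
    :func:`reachable_first_residues`).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if isinstance(protein, ProteinRecord):
        protein_id, protein_seq = protein.id, protein.sequence
    else:
        protein_id, protein_seq = "cds", protein
    if not extension_peptide:
        raise ValueError("extension peptide must contain at least one residue")

    first = extension_peptide[0]
    options = [
        (stop, codon, i)
        for stop in sorted(STOP_CODONS)
        for codon in _AA_TO_CODONS.get(first, [])
        for i in range(3)
        if sum(a != b for a, b in zip(stop, codon)) == 1 and stop[i] != codon[i]
    ]
    if not options:
        raise ValueError(
            f"first extension residue {first!r} is not reachable from any stop "
            f"codon by a single substitution; choose from "
            f"{sorted(reachable_first_residues())}"
        )
    stop1, alt_codon, diff_idx = options[int(rng.integers(0, len(options)))]

    def pick_codon(aa: str) -> str:
        codons = _AA_TO_CODONS[aa]
        return codons[int(rng.integers(0, len(codons)))]

    wt_codons = [pick_codon(aa) for aa in protein_seq]
    ext_codons = [pick_codon(aa) for aa in extension_peptide[1:]]
    stop2 = sorted(STOP_CODONS)[int(rng.integers(0, 3))]
    tail = _random_dna(3 * utr_codons, rng)
    cds = "".join(wt_codons) + stop1 + "".join(ext_codons) + stop2 + tail

    wt_len = len(protein_seq)
    pos = 3 * wt_len + diff_idx + 1
    hgvs_c = f"c.{pos}{stop1[diff_idx]}>{alt_codon[diff_idx]}"
    hgvs_p = f"p.Ter{wt_len + 1}{seq3(first)}"
    return NonstopVariant(
        transcript_id=protein_id,
        cds_seq=cds,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        wt_protein_len=wt_len,
    )


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


# -------------------------------------------------------------------- gels
def make_gels(
    true_insertion: float,
    noise_cv: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    sample_id: str = "sim",
    peg_untreated: float = 90.0,
    peg_nem: float = 9.0,
) -> list[GelQuantification]:
    """Invert the %insertion formula into lane values, then add noise.

    With ``noise_cv=0`` the %insertion estimator recovers ``true_insertion``
    exactly.  Noise is multiplicative lognormal per band at the given CV,
    clipped into [0, 100].
    """
    if not 0.0 <= true_insertion <= 100.0:
        raise ValueError("true_insertion must be a percentage in [0, 100]")
    rng = np.random.default_rng(seed)
    p = true_insertion / 100.0
    peg_ams = peg_untreated * (1.0 - p * (1.0 - peg_nem / peg_untreated))
    sigma = float(np.sqrt(np.log1p(noise_cv**2))) if noise_cv > 0 else 0.0
    gels = []
    for rep in range(1, n_replicates + 1):
        lanes = np.array([peg_untreated, peg_nem, peg_ams])
        if sigma > 0:
            noise = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=3)
            lanes = np.clip(lanes * noise, 0.0, 100.0)
        gels.append(
            GelQuantification(
                sample_id=sample_id,
                peg_untreated=float(lanes[0]),
                peg_nem=float(lanes[1]),
                peg_ams=float(lanes[2]),
                replicate=rep,
            )
        )
    return gels
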