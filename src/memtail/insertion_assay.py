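"""Cys-accessibility (PEGylation) quantification of cTM insertion.

The assay probes which side of the membrane a C-terminal cysteine occupies.
AMS is membrane-impermeable and blocks PEGylation only of periplasmic
(inserted) cysteines; NEM is membrane-permeable and blocks both sides;
a mock treatment blocks nothing.  The fraction of correctly inserted
protein is

    %insertion = 100 · (1 − %PEG_AMS / %PEG_untreated)
                     / (1 − %PEG_NEM / %PEG_untreated)

where the NEM term controls for cysteines that are inaccessible in whole
cells.  Band densitometry can be corrected against a two-fold dilution
calibration series before computing %PEGylation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DegenerateDenominatorError(ValueError):
    """NEM blocked no PEGylation relative to mock — the formula is undefined."""


@dataclass
class GelQuantification:
    """Percent PEGylation of one sample under the three treatments."""

    sample_id: str
    peg_untreated: float
    peg_nem: float
    peg_ams: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("peg_untreated", "peg_nem", "peg_ams"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass
class InsertionResult:
    percent_insertion: float  # clamped to [0, 100]
    raw_value: float  # pre-clamp
    sample_id: str = ""
    replicate: int = 1
    flags: list[str] = field(default_factory=list)


@dataclass
class InsertionSummary:
    sample_id: str
    mean: float
    sem: float  # NaN for a single replicate
    n_replicates: int


def percent_insertion(q: GelQuantification) -> InsertionResult:
    """Apply the %insertion formula to one replicate.

    Requires ``peg_untreated > 0`` and ``peg_nem < peg_untreated`` (NEM must
    block some PEGylation, otherwise the denominator is degenerate).  Noise
    can push the raw statistic outside [0, 100]; the reported value is
    clamped and flagged, with the raw value retained.
    """
    if q.peg_untreated <= 0:
        raise ValueError(
            f"{q.sample_id}: peg_untreated must be > 0 (maximal PEGylation)"
        )
    if q.peg_nem >= q.peg_untreated:
        raise DegenerateDenominatorError(
            f"{q.sample_id}: peg_nem ({q.peg_nem}) must be below peg_untreated "
            f"({q.peg_untreated}); NEM blocked no PEGylation"
        )
    raw = (
        100.0
        * (1.0 - q.peg_ams / q.peg_untreated)
        / (1.0 - q.peg_nem / q.peg_untreated)
    )
    flags = []
    value = raw
    if raw < 0.0 or raw > 100.0:
        value = min(max(raw, 0.0), 100.0)
        flags.append("clamped")
    return InsertionResult(
        percent_insertion=value,
        raw_value=raw,
        sample_id=q.sample_id,
        replicate=q.replicate,
        flags=flags,
    )


@dataclass
class Calibration:
    """Linear through-origin densitometry calibration."""

    slope: float
    r_squared: float
    saturation_warning: bool = False

    def correct(self, intensity: float) -> float:
        """Map a band intensity to relative amount."""
        return intensity / self.slope


def calibrate_densitometry(
    dilution_series: Sequence[tuple[float, float]],
    ratio_tol: float = 0.05,
) -> Calibration:
    """Fit a calibration from a (relative_amount, intensity) dilution series.

    Amounts must form a geometric series (e.g. 1, 0.5, 0.25 from two-fold
    dilutions) of at least three points with positive intensities.  The fit
    is least-squares linear through the origin.  A saturation warning fires
    when the residual of the most-concentrated point exceeds twice the RMS
    of the remaining residuals (a capped top band bends the curve).
    """
    if len(dilution_series) < 3:
        raise ValueError("calibration needs at least 3 dilution points")
    pts = sorted(dilution_series, key=lambda p: p[0], reverse=True)
    amounts = np.array([p[0] for p in pts], dtype=float)
    intensities = np.array([p[1] for p in pts], dtype=float)
    if np.any(amounts <= 0) or np.any(intensities <= 0):
        raise ValueError("amounts and intensities must be positive")
    ratios = amounts[:-1] / amounts[1:]
    if np.ptp(ratios) > ratio_tol * ratios.mean():
        raise ValueError(
            "dilution factors do not form a geometric series "
            f"(step ratios {ratios.round(3).tolist()})"
        )
    slope = float(np.dot(amounts, intensities) / np.dot(amounts, amounts))
    residuals = intensities - slope * amounts
    ss_res = float(np.dot(residuals, residuals))
    ss_tot = float(np.sum((intensities - intensities.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # Saturation check against a fit that excludes the most-concentrated
    # point (a through-origin fit including a capped top band would absorb
    # most of its deviation into the slope and mask it).
    slope_rest = float(
        np.dot(amounts[1:], intensities[1:]) / np.dot(amounts[1:], amounts[1:])
    )
    resid_rest = intensities[1:] - slope_rest * amounts[1:]
    rms_rest = float(np.sqrt(np.mean(resid_rest**2)))
    top_resid = float(intensities[0] - slope_rest * amounts[0])
    threshold = max(2.0 * rms_rest, 1e-8 * slope_rest * amounts[0])
    saturated = bool(abs(top_resid) > threshold)
    if saturated:
        warnings.warn(
            "top calibration point deviates from linearity (possible "
            "saturation); its residual exceeds 2x the RMS of the others",
            stacklevel=2,
        )
    return Calibration(slope=slope, r_squared=r_squared, saturation_warning=saturated)


def percent_pegylation(
    band_peg: float, band_unshifted: float, calibration: Calibration | None = None
) -> float:
    """%PEGylation from the PEG-shifted and unshifted band intensities."""
    if band_peg < 0 or band_unshifted < 0:
        raise ValueError("band intensities must be non-negative")
    if calibration is not None:
        band_peg = calibration.correct(band_peg)
        band_unshifted = calibration.correct(band_unshifted)
    total = band_peg + band_unshifted
    if total <= 0:
        raise ValueError("no detectable signal in either band")
    return 100.0 * band_peg / total


def aggregate(replicates: Sequence[InsertionResult]) -> InsertionSummary:
    """Mean ± SEM of %insertion across biological replicates.

    SEM uses the sample standard deviation (ddof=1); it is NaN for a single
    replicate.  Fewer than three replicates triggers a warning.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    sample_id = replicates[0].sample_id
    values = np.array([r.percent_insertion for r in replicates], dtype=float)
    n = values.size
    if n < 3:
        warnings.warn(
            f"{sample_id}: only {n} replicate(s); report at least three",
            stacklevel=2,
        )
    sem = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return InsertionSummary(
        sample_id=sample_id, mean=float(values.mean()), sem=sem, n_replicates=n
    )
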