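"""qPCR absolute quantification: standard curves, copy numbers, species fractions.

A qPCR run reports, for each well, a quantification cycle Cq that is linear
in log10 of the starting template copy number.  A triplicated dilution
series (here spanning 3x10^0 to 3x10^6 copies/reaction) defines the standard
curve Cq = intercept + slope * log10(copies); its slope gives amplification
efficiency E = 10^(-1/slope) - 1 (E = 1 means perfect doubling, slope
-3.3219).  Inverting the curve converts sample Cq values into copies, and
the herring DNA fraction of a sample is herring copies divided by the sum
of herring and sprat copies — the raw observation fed to the calibration
model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: Slope of an ideal standard curve (perfect doubling every cycle).
PERFECT_DOUBLING_SLOPE = -1.0 / math.log10(2.0)  # -3.3219...


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve Cq = intercept + slope * log10(copies).

    Attributes
    ----------
    slope : float
        Cycles per decade of template; negative for a valid curve.
    intercept : float
        Cq at a single copy per reaction (log10(copies) = 0).
    r_squared : float
        Coefficient of determination of the dilution-series regression.
    efficiency : float
        Amplification efficiency 10^(-1/slope) - 1; 1.0 = perfect doubling.
    """

    slope: float
    intercept: float
    r_squared: float = 1.0
    efficiency: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.efficiency is None:
            object.__setattr__(self, "efficiency", curve_efficiency(self.slope))

    @property
    def is_valid(self) -> bool:
        return self.slope < 0


@dataclass(frozen=True)
class QPCRMeasurement:
    """One well: Cq (or None when not detected) for one target in one sample."""

    sample_id: str
    target_species: str  # "herring" or "sprat"
    cq: float | None
    replicate_index: int = 0

    @property
    def detected(self) -> bool:
        return self.cq is not None


@dataclass(frozen=True)
class SpeciesFraction:
    """Per-sample herring fraction of total (herring + sprat) DNA copies.

    ``herring_fraction`` is None when both copy numbers are zero or missing:
    an undetected sample is reported as missing, never as 0.
    """

    sample_id: str
    herring_copies: float
    sprat_copies: float
    herring_fraction: float | None


def curve_efficiency(slope: float) -> float:
    """Amplification efficiency 10^(-1/slope) - 1 from a standard-curve slope."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_standard_curve(dilution_points: list[tuple[float, float]]) -> StandardCurve:
    """Fit a standard curve by OLS of Cq on log10(copies).

    Parameters
    ----------
    dilution_points : list of (copies, cq)
        Dilution-series wells; at least 3 distinct copy levels required.

    Returns
    -------
    StandardCurve
        Fitted curve.  A non-negative slope is permitted in the returned
        object (``is_valid`` is False) so callers can inspect and reject it.
    """
    if len(dilution_points) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    copies = np.asarray([p[0] for p in dilution_points], dtype=float)
    cq = np.asarray([p[1] for p in dilution_points], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    levels = np.unique(copies)
    if levels.size < 3:
        raise ValueError("standard curve needs at least 3 distinct dilution levels")
    res = stats.linregress(np.log10(copies), cq)
    curve = StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
    if not curve.is_valid:
        logger.warning("standard curve has non-negative slope %.4f; flagged invalid", curve.slope)
    return curve


def quantify(cq: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((cq - intercept)/slope)."""
    if not curve.is_valid:
        raise ValueError("cannot quantify against an invalid (slope >= 0) standard curve")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def compute_fraction(
    herring_copies: float, sprat_copies: float, sample_id: str = ""
) -> SpeciesFraction:
    """Herring DNA fraction: herring copies over total (herring + sprat) copies.

    Both copy numbers must be non-negative.  When both are zero the fraction
    is undefined and reported as missing (None).
    """
    if herring_copies < 0 or sprat_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    total = herring_copies + sprat_copies
    fraction = herring_copies / total if total > 0 else None
    return SpeciesFraction(
        sample_id=sample_id,
        herring_copies=herring_copies,
        sprat_copies=sprat_copies,
        herring_fraction=fraction,
    )


def aggregate_technical_replicates(
    measurements: list[QPCRMeasurement], curve: StandardCurve
) -> dict[str, dict[str, float]]:
    """Aggregate duplicate wells to one copy number per sample and target.

    Replicate copy estimates are combined by geometric mean, i.e. the
    arithmetic mean on the Cq scale on which the instrument measures.
    Not-detected wells are treated as missing, not zero; a target with at
    least one detected well keeps the detected value(s), with a warning
    when some of its replicates dropped out.  Targets with no detected
    well are absent from the result.

    Returns
    -------
    dict
        ``{sample_id: {target_species: copies}}``.
    """
    grouped: dict[tuple[str, str], list[QPCRMeasurement]] = {}
    for m in measurements:
        grouped.setdefault((m.sample_id, m.target_species), []).append(m)

    out: dict[str, dict[str, float]] = {}
    any_detected = False
    for (sample_id, target), wells in grouped.items():
        detected = [w for w in wells if w.detected]
        if not detected:
            continue
        any_detected = True
        if len(detected) < len(wells):
            logger.warning(
                "sample %s target %s: %d of %d replicates not detected; using detected only",
                sample_id,
                target,
                len(wells) - len(detected),
                len(wells),
            )
        copies = np.array([quantify(w.cq, curve) for w in detected])
        out.setdefault(sample_id, {})[target] = float(stats.gmean(copies))
    if measurements and not any_detected:
        raise ValueError("no detected replicates for any target")
    return out
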