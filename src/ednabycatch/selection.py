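"""On-site model selection among seasonal calibration models.

At each landing, three 2-4 kg replicates of the catch are mixed with
freshwater (30% water to 70% catch), the water is sampled at 10 min, 2 h
and 4 h, and the replicates are afterwards sorted and weighed so their true
herring weight fraction is known.  Each candidate seasonal calibration
model is scored by inverting the observed eDNA fractions of these test
samples and comparing the predicted weight fractions against the sorted
truth; the model with the smallest mean absolute error is selected for the
landing, with ties broken by seasonal proximity (circular month distance)
to the landing date.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ednabycatch.calibration import CalibrationModel, invert

__all__ = [
    "OnSiteTest",
    "ModelScore",
    "true_fraction_from_sorting",
    "score_model",
    "select_model",
    "month_distance",
]

logger = logging.getLogger(__name__)

STANDARD_TIMEPOINTS_MIN = (10, 120, 240)
WATER_TO_CATCH_RATIO = 0.30

_MONTHS = {
    "january": 1, "february": 2, "march": 3, "april": 4, "may": 5, "june": 6,
    "july": 7, "august": 8, "september": 9, "october": 10, "november": 11,
    "december": 12,
}


@dataclass(frozen=True)
class OnSiteTest:
    """Replicated known-fraction test mixtures with timed water samples.

    ``replicates`` holds (replicate_id, catch weight kg, true herring
    weight fraction); ``observations`` maps timepoint minutes to the
    per-replicate observed eDNA fractions (None = missing).
    """

    landing_id: str
    water_type: str
    replicates: tuple[tuple[str, float, float], ...]
    observations: dict[int, tuple[float | None, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, kg, frac in self.replicates:
            if kg <= 0:
                raise ValueError("replicate catch weight must be positive")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("true fractions must lie in [0, 1]")
        for minutes, obs in self.observations.items():
            if len(obs) != len(self.replicates):
                raise ValueError(f"timepoint {minutes}: need one observation per replicate")

    @property
    def pooled_true_fraction(self) -> float:
        """Weight-weighted true herring fraction of the pooled test sample."""
        kg = np.array([r[1] for r in self.replicates])
        frac = np.array([r[2] for r in self.replicates])
        return float(np.sum(kg * frac) / np.sum(kg))


@dataclass(frozen=True)
class ModelScore:
    model_key: tuple[str, str]  # (season, water_type)
    mean_abs_error: float
    per_timepoint_errors: tuple[tuple[int, float], ...]
    n_used: int
    n_missing: int


def true_fraction_from_sorting(
    sorted_weights: list[tuple[float, float]],
) -> tuple[list[float], float]:
    """Per-replicate and pooled true herring fractions from sorted weights.

    Parameters
    ----------
    sorted_weights : list of (herring_kg, sprat_kg)
        Visually sorted and weighed species totals per replicate.

    Returns
    -------
    (per_replicate_fractions, pooled_fraction)
        The pooled fraction weights replicates by their total weight.
    """
    fractions = []
    totals = []
    for herring_kg, sprat_kg in sorted_weights:
        if herring_kg < 0 or sprat_kg < 0:
            raise ValueError("sorted weights must be non-negative")
        total = herring_kg + sprat_kg
        if total <= 0:
            raise ValueError("replicate total weight must be positive")
        fractions.append(herring_kg / total)
        totals.append(total)
    pooled = float(
        sum(h for h, _ in sorted_weights) / sum(h + s for h, s in sorted_weights)
    )
    return fractions, pooled


def score_model(
    model: CalibrationModel, test: OnSiteTest, compare_pooled: bool = True
) -> ModelScore:
    """Mean absolute error of a model's inverted predictions on an on-site test.

    Every observed eDNA fraction (replicate x timepoint) is inverted to a
    weight fraction; errors are absolute deviations from the pooled true
    fraction (default) or from each replicate's own true fraction.  Missing
    observations are excluded and counted.
    """
    if model.water_type and test.water_type and model.water_type != test.water_type:
        raise ValueError(
            f"model water type {model.water_type!r} does not match test {test.water_type!r}"
        )
    rep_truths = np.array([r[2] for r in test.replicates])
    pooled = test.pooled_true_fraction

    per_tp: list[tuple[int, float]] = []
    all_errors: list[float] = []
    n_missing = 0
    for minutes in sorted(test.observations):
        obs = test.observations[minutes]
        errors = []
        for i, o in enumerate(obs):
            if o is None:
                n_missing += 1
                continue
            predicted, _, _ = invert(model, o)
            truth = pooled if compare_pooled else rep_truths[i]
            errors.append(abs(predicted - truth))
        if errors:
            per_tp.append((minutes, float(np.mean(errors))))
            all_errors.extend(errors)
    if n_missing:
        logger.info("on-site test %s: %d missing observations excluded", test.landing_id, n_missing)
    if not all_errors:
        raise ValueError("no usable observations in on-site test")
    return ModelScore(
        model_key=model.key,
        mean_abs_error=float(np.mean(all_errors)),
        per_timepoint_errors=tuple(per_tp),
        n_used=len(all_errors),
        n_missing=n_missing,
    )


def month_distance(a: str, b: str) -> int:
    """Minimal circular distance in months between two month/season names."""
    try:
        ma, mb = _MONTHS[a.strip().lower()], _MONTHS[b.strip().lower()]
    except KeyError as exc:
        raise ValueError(f"unknown month name: {exc}") from exc
    d = abs(ma - mb)
    return min(d, 12 - d)


def select_model(scores: list[ModelScore], landing_season: str | None = None) -> tuple[str, str]:
    """Select the calibration model for a landing: argmin mean absolute error.

    Ties are broken by circular month distance between the model's season
    and the landing's month; any remaining tie falls to lexicographic
    order of the model key, making selection fully deterministic.
    """
    if not scores:
        raise ValueError("no model scores to select from")

    def sort_key(score: ModelScore):
        proximity = (
            month_distance(score.model_key[0], landing_season)
            if landing_season is not None
            else 0
        )
        return (score.mean_abs_error, proximity, score.model_key)

    return min(scores, key=sort_key).model_key
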