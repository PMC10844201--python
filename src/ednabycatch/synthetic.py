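"""Synthetic data with the statistical structure the pipeline assumes.

Everything downstream — standard curves, read classification, calibration
fits, model selection, landing estimation — can be exercised end to end on
data from this module.  The generators emulate:

* mock-mixture calibration designs at the experimental sprat/herring ratios
  (the March design spans 90/10 to 10/90, the November design adds 95/5 and
  5/95);
* observed eDNA fractions drawn from the mean/precision beta model
  logit(mu) = alpha + beta * logit(w), with seasonal offsets entering
  through alpha (ship water nearly identical across seasons, factory water
  systematically offset);
* qPCR Cq values on a log-linear standard curve over the 3x10^0 to 3x10^6
  copies/reaction dynamic range, with Gaussian cycle noise;
* amplicon read sets with per-species primer bias (herring is
  underrepresented when its multiplier is below 1) and i.i.d. substitution
  errors;
* whole landings whose tanks hold heterogeneous bycatch fractions.

All randomness flows from an explicit per-call seed; identical seed and
configuration give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ednabycatch.calibration import CalibrationSample
from ednabycatch.qpcr import QPCRMeasurement, StandardCurve

__all__ = [
    "GeneratorConfig",
    "SimulatedLanding",
    "MARCH_RATIOS",
    "NOVEMBER_RATIOS",
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "DEFAULT_PHI",
    "SEASON_ALPHA_OFFSETS",
    "DILUTION_SERIES_COPIES",
    "generate_calibration_design",
    "simulate_landing",
    "simulate_qpcr_run",
    "simulate_reads",
    "mutate_sequence",
    "engineer_read",
]

#: Mock-mixture herring weight fractions of the March experiment (90/10 ... 10/90).
MARCH_RATIOS: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)
#: November design adds the 95/5 and 5/95 end points (11 ratios).
NOVEMBER_RATIOS: tuple[float, ...] = (0.05,) + MARCH_RATIOS + (0.95,)

# Default generative calibration parameters.  The experiments show herring
# DNA mildly underrepresented relative to weight (alpha < 0) with a slope
# near 1; phi sets replicate scatter (sd ~ sqrt(mu(1-mu)/(1+phi)), about
# 0.07 at mu = 0.5 for phi = 50).  These are assumptions: the source
# experiments do not report fitted values.
DEFAULT_ALPHA = -0.4
DEFAULT_BETA = 1.0
DEFAULT_PHI = 50.0

# Seasonal intercept offsets on the logit scale, back-computed from the
# reported fraction-scale mean differences between seasons at mid-range
# mixtures (about 0.047 for ship water, 0.121 for factory water) via
# d(fraction) ~ d(alpha) * mu(1-mu) at mu = 0.5.
SEASON_ALPHA_OFFSETS: dict[str, float] = {"ship": 0.19, "factory": 0.50}

#: Seven-decade dilution-series design points, 3x10^0 ... 3x10^6 copies/reaction.
DILUTION_SERIES_COPIES: tuple[float, ...] = tuple(3.0 * 10.0**k for k in range(7))


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the calibration-design generator.

    ``alpha``/``beta`` are the logit-scale intercept and slope of the
    generative eDNA-to-weight relationship and ``phi`` the beta precision;
    ``ratios`` are the true herring weight fractions of the mock mixtures.
    """

    seed: int
    ratios: tuple[float, ...] = NOVEMBER_RATIOS
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    phi: float = DEFAULT_PHI
    n_replicates_per_ratio: int = 9
    season_label: str = "November"
    water_type: str = "ship"

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.n_replicates_per_ratio < 1:
            raise ValueError("n_replicates_per_ratio must be positive")
        if any(not (0.0 < r < 1.0) for r in self.ratios):
            raise ValueError("all ratios must lie strictly in (0, 1)")
        if self.water_type not in ("ship", "factory"):
            raise ValueError("water_type must be 'ship' or 'factory'")
        object.__setattr__(self, "ratios", tuple(self.ratios))


@dataclass(frozen=True)
class SimulatedLanding:
    """A landing as tanks of known weight and true herring fraction."""

    tanks: tuple[tuple[str, float, float], ...]  # (tank_id, tonnes, herring fraction)
    total_weight: float
    mixing_flag: str = "per_tank_mixed"  # or "fully_mixed"

    def __post_init__(self) -> None:
        weights = [t[1] for t in self.tanks]
        if not np.isclose(self.total_weight, sum(weights)):
            raise ValueError("total_weight must equal the sum of tank weights")
        if any(not (0.0 <= t[2] <= 1.0) for t in self.tanks):
            raise ValueError("tank fractions must lie in [0, 1]")

    @property
    def true_fraction(self) -> float:
        """Landing-level true herring fraction: weight-weighted tank mean."""
        w = np.array([t[1] for t in self.tanks])
        f = np.array([t[2] for t in self.tanks])
        return float(np.sum(w * f) / np.sum(w))


def _draw_beta_fraction(
    rng: np.random.Generator, mu: np.ndarray, phi: float
) -> np.ndarray:
    """Beta(mu*phi, (1-mu)*phi) draws, nudged off the closed boundary."""
    draws = rng.beta(mu * phi, (1.0 - mu) * phi)
    tiny = np.finfo(float).tiny
    return np.clip(draws, tiny, 1.0 - 1e-15)


def generate_calibration_design(config: GeneratorConfig) -> list[CalibrationSample]:
    """Generate a mock-mixture calibration dataset.

    For each ratio w, draws ``n_replicates_per_ratio`` observed eDNA
    fractions from Beta(mu*phi, (1-mu)*phi) with
    logit(mu) = alpha + beta*logit(w).  Output order is deterministic:
    ratios in the configured order, replicates within ratio.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[CalibrationSample] = []
    for i, w in enumerate(config.ratios):
        mu = special.expit(config.alpha + config.beta * special.logit(w))
        if not np.isfinite(mu):
            raise ValueError(f"non-finite mean for ratio {w}")
        obs = _draw_beta_fraction(rng, np.full(config.n_replicates_per_ratio, mu), config.phi)
        for rep in range(config.n_replicates_per_ratio):
            samples.append(
                CalibrationSample(
                    sample_id=f"{config.season_label}-{config.water_type}-r{i:02d}-rep{rep}",
                    season=config.season_label,
                    water_type=config.water_type,
                    true_weight_fraction=float(w),
                    edna_fraction=float(obs[rep]),
                    replicate=rep,
                )
            )
    return samples


def simulate_landing(
    n_tanks: int,
    weights: list[float],
    fraction_law,
    seed: int,
    mixing_flag: str = "per_tank_mixed",
) -> SimulatedLanding:
    """Simulate a landing with per-tank true herring fractions.

    Parameters
    ----------
    fraction_law : float or callable
        Either a constant fraction applied to every tank (degenerate law)
        or a callable ``law(rng, n) -> array of n fractions in [0, 1]``.
    """
    if n_tanks < 1:
        raise ValueError("need at least one tank")
    if len(weights) != n_tanks:
        raise ValueError("weights length must match n_tanks")
    if any(w <= 0 for w in weights):
        raise ValueError("tank weights must be positive")
    rng = np.random.default_rng(seed)
    if callable(fraction_law):
        fractions = np.clip(np.asarray(fraction_law(rng, n_tanks), dtype=float), 0.0, 1.0)
    else:
        fractions = np.full(n_tanks, float(fraction_law))
    tanks = tuple(
        (f"tank{i + 1}", float(weights[i]), float(fractions[i])) for i in range(n_tanks)
    )
    return SimulatedLanding(
        tanks=tanks, total_weight=float(sum(weights)), mixing_flag=mixing_flag
    )


def simulate_qpcr_run(
    true_copies: list[float],
    curve: StandardCurve,
    cq_noise_sd: float,
    seed: int,
    sample_ids: list[str] | None = None,
    target_species: str = "herring",
) -> list[QPCRMeasurement]:
    """Simulate Cq values for known template amounts on a given standard curve.

    Cq = intercept + slope*log10(copies) + Normal(0, cq_noise_sd).
    """
    if any(c <= 0 for c in true_copies):
        raise ValueError("template copy numbers must be positive")
    if cq_noise_sd < 0:
        raise ValueError("cq_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    copies = np.asarray(true_copies, dtype=float)
    cq = curve.intercept + curve.slope * np.log10(copies)
    cq = cq + rng.normal(0.0, cq_noise_sd, size=copies.size)
    if sample_ids is None:
        sample_ids = [f"well{i:03d}" for i in range(copies.size)]
    return [
        QPCRMeasurement(
            sample_id=sample_ids[i],
            target_species=target_species,
            cq=float(cq[i]),
            replicate_index=i,
        )
        for i in range(copies.size)
    ]


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def mutate_sequence(
    sequence: str,
    n_substitutions: int,
    rng: np.random.Generator,
    protect_ends: int = 0,
) -> str:
    """Apply exactly n substitutions at distinct positions (never silent).

    ``protect_ends`` keeps the first/last bases untouched: a semi-global
    aligner with free end gaps would otherwise trim terminal mismatches,
    so reads engineered to an exact identity need intact flanks.
    """
    seq = np.frombuffer(sequence.encode(), dtype="S1").copy()
    lo, hi = protect_ends, seq.size - protect_ends
    positions = rng.choice(np.arange(lo, hi), size=n_substitutions, replace=False)
    for pos in positions:
        choices = _BASES[_BASES != seq[pos]]
        seq[pos] = rng.choice(choices)
    return seq.tobytes().decode()


def engineer_read(
    reference: str,
    n_substitutions: int,
    rng: np.random.Generator,
    protect_ends: int = 6,
) -> str:
    """Mutate a reference to an exact target identity under alignment.

    Substitution positions are evenly spaced across the interior of the
    sequence (random only in the replacement base), so a semi-global
    aligner can neither trim terminal mismatches nor convert clustered
    mismatches into gapped realignments: the alignment identity equals
    1 - n_substitutions/len(reference) exactly.
    """
    L = len(reference)
    if n_substitutions == 0:
        return reference
    positions = np.linspace(protect_ends, L - 1 - protect_ends, n_substitutions).astype(int)
    if np.unique(positions).size != n_substitutions:
        raise ValueError("too many substitutions for the sequence length")
    seq = np.frombuffer(reference.encode(), dtype="S1").copy()
    for pos in positions:
        choices = _BASES[_BASES != seq[pos]]
        seq[pos] = rng.choice(choices)
    return seq.tobytes().decode()


def simulate_reads(
    fractions: dict[str, float],
    n_reads: int,
    primer_bias: dict[str, float],
    references: dict[str, str],
    error_rate: float = 0.0,
    length_law=None,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Simulate an amplicon read set with primer bias and substitution errors.

    Reads are assigned to species multinomially with probabilities
    proportional to ``fraction * primer_bias`` (renormalised), then copied
    from the species reference with i.i.d. substitution errors at
    ``error_rate`` per base.  ``length_law(rng, n) -> int array`` optionally
    draws read lengths; a read shorter than the reference is a random
    contiguous substring, a longer one is padded with random bases at the
    3' end.  Indels inside the amplicon are not modelled.

    Returns
    -------
    list of (read_id, true_species, sequence)
    """
    if not references:
        raise ValueError("references must not be empty")
    if any(not ref for ref in references.values()):
        raise ValueError("references must be non-empty sequences")
    species = sorted(fractions)
    if set(species) != set(references):
        raise ValueError("fractions and references must cover the same species")
    frac = np.array([fractions[s] for s in species], dtype=float)
    if not np.isclose(frac.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    bias = np.array([primer_bias.get(s, 1.0) for s in species], dtype=float)
    if np.any(bias <= 0):
        raise ValueError("primer-bias multipliers must be positive")
    probs = frac * bias
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    origin = rng.choice(len(species), size=n_reads, p=probs)
    lengths = None
    if length_law is not None:
        lengths = np.asarray(length_law(rng, n_reads), dtype=int)

    reads: list[tuple[str, str, str]] = []
    for i in range(n_reads):
        sp = species[origin[i]]
        seq = references[sp]
        if lengths is not None:
            target = int(lengths[i])
            if target < 1:
                raise ValueError("length law produced a non-positive length")
            if target < len(seq):
                start = rng.integers(0, len(seq) - target + 1)
                seq = seq[start : start + target]
            elif target > len(seq):
                pad = rng.choice(_BASES, size=target - len(seq)).tobytes().decode()
                seq = seq + pad
        if error_rate > 0.0:
            n_sub = rng.binomial(len(seq), error_rate)
            if n_sub:
                seq = mutate_sequence(seq, n_sub, rng)
        reads.append((f"read{i:06d}", sp, seq))
    return reads
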