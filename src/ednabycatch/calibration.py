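"""Beta-regression calibration of observed eDNA fractions to weight fractions.

The calibration experiments mix sprat and herring at known weight fractions
w and measure the herring eDNA fraction O in the production water.  O lies
strictly in (0, 1) and is modelled with a beta distribution parameterised by
mean and precision,

    O_i ~ Beta(mu_i * phi, (1 - mu_i) * phi),
    logit(mu_i) = alpha + beta * logit(w_i),

so alpha captures systematic over/underrepresentation of herring DNA (e.g.
seasonal release-rate differences) and beta the steepness of the response.
Fitting is by maximum likelihood on (alpha, beta, log phi) with the
covariance taken from the inverse observed information.

For assessment the model is run backwards: an observed eDNA fraction O is
converted to a weight fraction by the closed-form inverse

    w = invlogit((logit(O) - alpha) / beta),

which is the unique inverse making invert(predict(w)) = w exactly.  Note
that writing the inverse as invlogit((O - alpha)/beta), with O left on the
probability scale, is dimensionally inconsistent (alpha lives on the logit
scale); this implementation always applies the logit to O first.

Confidence intervals for both directions use the delta method on the
logit scale and are transformed back through invlogit, so they always stay
inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "CalibrationSample",
    "CalibrationModel",
    "fit_beta_glm",
    "beta_loglik",
    "predict_fraction",
    "invert",
    "shrink_to_open_interval",
    "model_to_text",
    "model_from_text",
]

logit = special.logit
invlogit = special.expit

_MIN_ABS_SLOPE = 1e-8


@dataclass(frozen=True)
class CalibrationSample:
    """One mock-mixture observation: known weight fraction, observed eDNA fraction."""

    sample_id: str
    season: str
    water_type: str  # "ship" or "factory"
    true_weight_fraction: float
    edna_fraction: float
    replicate: int = 0


@dataclass
class CalibrationModel:
    """Fitted eDNA-to-biomass beta regression for one season and water type.

    Attributes
    ----------
    alpha, beta_slope : float
        Intercept and slope on the logit scale.
    phi : float
        Beta precision; larger phi means tighter replicate scatter.
    vcov : (3, 3) ndarray
        Covariance of (alpha, beta_slope, log phi) from the inverse
        observed information.
    loglik : float
        Maximised log-likelihood.
    season, water_type : str
        Labels identifying which calibration experiment the model encodes.
    n : int
        Number of observations fitted.
    converged : bool
        Optimiser convergence flag.
    """

    alpha: float
    beta_slope: float
    phi: float
    vcov: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    loglik: float = np.nan
    season: str = ""
    water_type: str = ""
    n: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        self.vcov = np.asarray(self.vcov, dtype=float)
        if self.vcov.shape != (3, 3):
            raise ValueError("vcov must be 3x3")

    @property
    def key(self) -> tuple[str, str]:
        return (self.season, self.water_type)

    def se(self) -> np.ndarray:
        """Standard errors of (alpha, beta_slope, log phi)."""
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))


def shrink_to_open_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Shrink fractions off the boundary: (y*(n-1) + 0.5)/n.

    The beta distribution has open support, but real qPCR fractions can be
    exactly 0 or 1 (one species undetected).  The standard compression keeps
    interior points nearly unchanged while pulling boundary values inside.
    """
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    n = max(n, 2)
    return (y * (n - 1) + 0.5) / n


def beta_loglik(
    alpha: float, beta_slope: float, phi: float, w: np.ndarray, obs: np.ndarray
) -> float:
    """Beta log-likelihood of observed fractions under the calibration model."""
    if phi <= 0:
        return -np.inf
    mu = invlogit(alpha + beta_slope * logit(w))
    a = mu * phi
    b = (1.0 - mu) * phi
    if np.any(a <= 0) or np.any(b <= 0):
        return -np.inf
    return float(np.sum(stats.beta.logpdf(obs, a, b)))


def _neg_loglik(theta: np.ndarray, x: np.ndarray, obs: np.ndarray) -> float:
    alpha, beta_slope, log_phi = theta
    phi = np.exp(log_phi)
    mu = invlogit(alpha + beta_slope * x)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = np.sum(stats.beta.logpdf(obs, a, b))
    return np.inf if not np.isfinite(ll) else -float(ll)


def _neg_loglik_grad(theta: np.ndarray, x: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Analytic gradient of the negative log-likelihood in (alpha, beta, log phi)."""
    alpha, beta_slope, log_phi = theta
    phi = np.exp(log_phi)
    mu = invlogit(alpha + beta_slope * x)
    z = np.log(obs) - np.log1p(-obs)
    star = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    dmu = mu * (1.0 - mu)
    common = phi * (z - star) * dmu
    d_alpha = np.sum(common)
    d_beta = np.sum(common * x)
    d_phi = np.sum(
        special.digamma(phi)
        - mu * special.digamma(mu * phi)
        - (1.0 - mu) * special.digamma((1.0 - mu) * phi)
        + mu * np.log(obs)
        + (1.0 - mu) * np.log1p(-obs)
    )
    return -np.array([d_alpha, d_beta, phi * d_phi])


def _numeric_hessian(f, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; step relative to parameter magnitude."""
    k = theta.size
    H = np.empty((k, k))
    steps = h * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return H


def fit_beta_glm(
    samples: list[CalibrationSample],
    season: str | None = None,
    water_type: str | None = None,
) -> CalibrationModel:
    """Fit (alpha, beta, phi) by maximum likelihood.

    Starts quasi-Newton iterations from the logit-linear least-squares
    solution plus a small multi-start grid over log phi, and derives the
    parameter covariance from the numerically computed observed information.

    Raises
    ------
    ValueError
        Fewer than 3 distinct true weight fractions, fractions outside
        (0, 1), or degenerate (all-equal) observations.
    """
    if season is None:
        seasons = {s.season for s in samples}
        season = seasons.pop() if len(seasons) == 1 else "mixed"
    if water_type is None:
        waters = {s.water_type for s in samples}
        water_type = waters.pop() if len(waters) == 1 else "mixed"

    w = np.array([s.true_weight_fraction for s in samples], dtype=float)
    obs = np.array([s.edna_fraction for s in samples], dtype=float)
    if np.unique(w).size < 3:
        raise ValueError("need at least 3 distinct true weight fractions")
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("true weight fractions must lie strictly in (0, 1)")
    if np.any((obs < 0) | (obs > 1)):
        raise ValueError("eDNA fractions must lie in [0, 1]")
    if np.any((obs <= 0) | (obs >= 1)):
        obs = shrink_to_open_interval(obs)
    if np.allclose(obs, obs[0]):
        raise ValueError("degenerate data: all observed fractions are equal")

    x = logit(w)
    # logit-linear OLS start for (alpha, beta); moment start for phi
    z = logit(obs)
    beta0, alpha0 = np.polyfit(x, z, 1)
    mu0 = invlogit(alpha0 + beta0 * x)
    resid_var = float(np.mean((obs - mu0) ** 2))
    mu_var = float(np.mean(mu0 * (1.0 - mu0)))
    phi0 = max(mu_var / max(resid_var, 1e-12) - 1.0, 2.0)

    best = None
    for log_phi_start in np.log(phi0) + np.array([-1.0, 0.0, 1.0]):
        res = optimize.minimize(
            _neg_loglik,
            x0=np.array([alpha0, beta0, log_phi_start]),
            args=(x, obs),
            jac=_neg_loglik_grad,
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    # BFGS can stall in the line search with the optimum already reached;
    # accept when the gradient is numerically zero
    grad_norm = float(np.max(np.abs(_neg_loglik_grad(theta, x, obs))))
    converged = bool(best.success) or grad_norm <= 1e-5 * max(1.0, abs(best.fun))
    H = _numeric_hessian(lambda t: _neg_loglik(t, x, obs), theta)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.full((3, 3), np.nan)
    # numerical symmetrisation; information of an interior ML optimum is PSD
    vcov = 0.5 * (vcov + vcov.T)

    return CalibrationModel(
        alpha=float(theta[0]),
        beta_slope=float(theta[1]),
        phi=float(np.exp(theta[2])),
        vcov=vcov,
        loglik=-float(best.fun),
        season=season,
        water_type=water_type,
        n=len(samples),
        converged=converged,
    )


def predict_fraction(
    model: CalibrationModel, w: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Predicted mean eDNA fraction at weight fraction w, with confidence band.

    The band is a Wald interval on the linear predictor
    eta = alpha + beta * logit(w), transformed through invlogit; it is the
    confidence band for the model mean (as drawn on calibration plots),
    not a prediction interval for a new replicate.
    """
    if not (0.0 < w < 1.0):
        raise ValueError("w must lie strictly in (0, 1)")
    x = float(logit(w))
    eta = model.alpha + model.beta_slope * x
    grad = np.array([1.0, x])
    var = float(grad @ model.vcov[:2, :2] @ grad)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lower = float(invlogit(eta - z * se))
    upper = float(invlogit(eta + z * se))
    return float(invlogit(eta)), lower, upper


def invert(
    model: CalibrationModel, observed: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Closed-form inverse: weight fraction from an observed eDNA fraction.

    w = invlogit((logit(observed) - alpha) / beta), strictly increasing in
    the observation when beta > 0.  The interval propagates the (alpha,
    beta) covariance by the delta method on the logit-w scale; observation
    noise is not included (it enters through replicate scatter downstream).
    """
    if not (0.0 < observed < 1.0):
        raise ValueError("observed fraction must lie strictly in (0, 1)")
    if abs(model.beta_slope) < _MIN_ABS_SLOPE:
        raise ValueError("slope too close to zero; inversion refused")
    z_obs = float(logit(observed))
    g = (z_obs - model.alpha) / model.beta_slope
    # gradient of g wrt (alpha, beta)
    grad = np.array([-1.0 / model.beta_slope, -(z_obs - model.alpha) / model.beta_slope**2])
    var = float(grad @ model.vcov[:2, :2] @ grad)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    bounds = sorted((invlogit(g - z * se), invlogit(g + z * se)))
    return float(invlogit(g)), float(bounds[0]), float(bounds[1])


# --- flat-text model serialization (diffable, keyed by season/water type) ---


def model_to_text(model: CalibrationModel) -> str:
    """Serialize a model to a flat key=value text block with covariance rows."""
    lines = [
        f"season={model.season}",
        f"water_type={model.water_type}",
        f"alpha={model.alpha:.17g}",
        f"beta_slope={model.beta_slope:.17g}",
        f"phi={model.phi:.17g}",
        f"loglik={model.loglik:.17g}",
        f"n={model.n}",
        f"converged={model.converged}",
    ]
    for row in model.vcov:
        lines.append("vcov=" + ",".join(f"{v:.17g}" for v in row))
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> CalibrationModel:
    """Parse a model from the flat text format written by :func:`model_to_text`."""
    fields: dict[str, str] = {}
    vcov_rows: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        if key == "vcov":
            vcov_rows.append([float(v) for v in value.split(",")])
        else:
            fields[key] = value
    return CalibrationModel(
        alpha=float(fields["alpha"]),
        beta_slope=float(fields["beta_slope"]),
        phi=float(fields["phi"]),
        vcov=np.array(vcov_rows) if vcov_rows else np.zeros((3, 3)),
        loglik=float(fields.get("loglik", "nan")),
        season=fields.get("season", ""),
        water_type=fields.get("water_type", ""),
        n=int(fields.get("n", "0")),
        converged=fields.get("converged", "True") == "True",
    )
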