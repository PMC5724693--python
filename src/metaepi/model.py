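"""Log-density building blocks for the meta-epidemiological models.

The observation model is binomial at arm level: with ``alpha_im`` the
control-arm log odds and ``theta_im`` the trial-specific log odds ratio,

    r_control ~ Binomial(n_control, expit(alpha_im))
    r_treat   ~ Binomial(n_treat,   expit(alpha_im + theta_im))

Trial effects follow a normal random-effects distribution whose mean and
variance depend on the trial's characteristic indicators ``X_ijm``:

    mean     = d_m + sum_j X_ijm * b_jm
    variance = tau2_m + sum_j X_ijm * kappa2_j          (additive)
    variance = tau2_m * prod_j (1 - X_ijm + X_ijm*lam_j) (label-invariant)

with per-meta-analysis bias terms ``b_jm ~ N(b0_j, phi2_j)`` and a
log-normal(mu, sigma^2) hierarchy on the heterogeneity variances ``tau2_m``.

Variance components ``kappa2`` and ``phi2`` carry zero-atom priors: a point
mass at zero with probability ``p0`` mixed with an inverse-gamma slab.  The
density is taken with respect to the mixture of a point mass at 0 and
Lebesgue measure, so it is a genuine log-density for Metropolis moves that
jump between the atom and the slab.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml
from scipy.special import gammaln, ndtr, ndtri

LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# lambda priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalLambda:
    """log-normal(mean, sd^2) prior on the variance ratio lambda.

    The default (0, 1) has median 1 on the untransformed scale, i.e. it is
    centred on "no difference in heterogeneity".
    """

    mean: float = 0.0
    sd: float = 1.0

    def logpdf(self, lam: float | np.ndarray) -> float | np.ndarray:
        lam = np.asarray(lam, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                lam > 0,
                -np.log(lam)
                - math.log(self.sd)
                - 0.5 * LOG_2PI
                - (np.log(np.where(lam > 0, lam, 1.0)) - self.mean) ** 2 / (2 * self.sd**2),
                -np.inf,
            )
        return out if out.ndim else float(out)

    def ppf(self, q: float) -> float:
        return float(np.exp(self.mean + self.sd * ndtri(q)))

    @property
    def median(self) -> float:
        return float(np.exp(self.mean))


@dataclass(frozen=True)
class UniformLogLambda:
    """Uniform prior on log(lambda) over (low, high)."""

    low: float = -math.log(10.0)
    high: float = math.log(10.0)

    def logpdf(self, lam: float | np.ndarray) -> float | np.ndarray:
        lam = np.asarray(lam, dtype=float)
        inside = (lam > math.exp(self.low)) & (lam < math.exp(self.high))
        with np.errstate(divide="ignore"):
            out = np.where(
                inside,
                -np.log(np.where(lam > 0, lam, 1.0)) - math.log(self.high - self.low),
                -np.inf,
            )
        return out if out.ndim else float(out)

    def ppf(self, q: float) -> float:
        return float(np.exp(self.low + q * (self.high - self.low)))

    @property
    def median(self) -> float:
        return self.ppf(0.5)


@dataclass(frozen=True)
class TruncatedLogNormalLambda:
    """log-normal(mean, sd^2) truncated to lambda > lower (default 1).

    With the defaults this prior gives support only to variance ratios
    strictly greater than 1, mimicking the additive model's constraint; it
    has median ~1.96 and central 95% range ~(1.03, 9.40).
    """

    mean: float = 0.0
    sd: float = 1.0
    lower: float = 1.0

    def _log_tail(self) -> float:
        z = (math.log(self.lower) - self.mean) / self.sd
        return math.log(1.0 - ndtr(z))

    def logpdf(self, lam: float | np.ndarray) -> float | np.ndarray:
        lam = np.asarray(lam, dtype=float)
        base = LogNormalLambda(self.mean, self.sd).logpdf(lam)
        out = np.where(lam > self.lower, np.asarray(base) - self._log_tail(), -np.inf)
        return out if out.ndim else float(out)

    def ppf(self, q: float) -> float:
        z0 = ndtr((math.log(self.lower) - self.mean) / self.sd)
        return float(np.exp(self.mean + self.sd * ndtri(z0 + q * (1.0 - z0))))

    @property
    def median(self) -> float:
        return self.ppf(0.5)


LambdaPrior = Union[LogNormalLambda, UniformLogLambda, TruncatedLogNormalLambda]

#: the configurable family used for prior-sensitivity analyses: three
#: log-normal widths centred on lambda = 1, a flat prior on log(lambda), and
#: the truncated prior that mimics the additive model.
SENSITIVITY_PRIORS: dict[str, LambdaPrior] = {
    "lognormal_half": LogNormalLambda(0.0, 0.5),
    "lognormal_1": LogNormalLambda(0.0, 1.0),
    "lognormal_2": LogNormalLambda(0.0, 2.0),
    "uniform_log": UniformLogLambda(),
    "truncated": TruncatedLogNormalLambda(),
}


def _lambda_prior_to_dict(p: LambdaPrior) -> dict:
    kind = {
        LogNormalLambda: "lognormal",
        UniformLogLambda: "uniform_log",
        TruncatedLogNormalLambda: "truncated_lognormal",
    }[type(p)]
    return {"kind": kind, **asdict(p)}


def _lambda_prior_from_dict(d: dict) -> LambdaPrior:
    d = dict(d)
    kind = d.pop("kind")
    cls = {
        "lognormal": LogNormalLambda,
        "uniform_log": UniformLogLambda,
        "truncated_lognormal": TruncatedLogNormalLambda,
    }[kind]
    return cls(**d)


# ---------------------------------------------------------------------------
# prior and model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Prior choices shared by both variance structures.

    ``location_variance`` is the variance (not precision) of the vague
    normal prior on all location parameters (alpha, d_m, b0, mu).
    """

    location_variance: float = 1000.0
    slab_shape: float = 0.001
    slab_rate: float = 0.001
    p0_beta: tuple[float, float] = (1.0, 1.0)
    lambda_prior: LambdaPrior = LogNormalLambda(0.0, 1.0)
    sigma_upper: float = 2.0


@dataclass
class ModelSpec:
    """Which model to fit: variance structure, characteristics, priors.

    ``structure`` is ``"additive"`` (variance ``tau2 + sum X kappa2``) or
    ``"label_invariant"`` (variance ``tau2 * prod lambda^X``).
    ``characteristics`` lists the characteristic names to model; ``None``
    means all characteristics present in the dataset.
    """

    structure: str = "label_invariant"
    characteristics: list[str] | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.structure not in ("additive", "label_invariant"):
            raise ValueError(f"unknown structure {self.structure!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "structure": self.structure,
            "characteristics": self.characteristics,
            "priors": {
                "location_variance": self.priors.location_variance,
                "slab_shape": self.priors.slab_shape,
                "slab_rate": self.priors.slab_rate,
                "p0_beta": list(self.priors.p0_beta),
                "lambda_prior": _lambda_prior_to_dict(self.priors.lambda_prior),
                "sigma_upper": self.priors.sigma_upper,
            },
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        d = yaml.safe_load(Path(path).read_text())
        pr = d.get("priors", {})
        priors = PriorSpec(
            location_variance=pr.get("location_variance", 1000.0),
            slab_shape=pr.get("slab_shape", 0.001),
            slab_rate=pr.get("slab_rate", 0.001),
            p0_beta=tuple(pr.get("p0_beta", (1.0, 1.0))),
            lambda_prior=_lambda_prior_from_dict(pr["lambda_prior"])
            if "lambda_prior" in pr
            else LogNormalLambda(0.0, 1.0),
            sigma_upper=pr.get("sigma_upper", 2.0),
        )
        return cls(
            structure=d["structure"],
            characteristics=d.get("characteristics"),
            priors=priors,
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """A full parameter point for either variance structure.

    Arrays are indexed by trial (``alpha``, ``theta``), by meta-analysis
    (``d``, ``tau2``), by (meta-analysis, characteristic) (``b``) and by
    characteristic (``b0``, ``phi2``, and ``kappa2`` or ``lam``).  The
    univariable model is the special case p = 1.

    The per-trial bias terms are marginalised out: trial effects are
    modelled directly as ``theta ~ N(d + X b, variance)``, which has the
    same marginal likelihood as sampling each within-trial bias explicitly
    but far fewer latent variables.
    """

    alpha: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    tau2: np.ndarray
    b: np.ndarray  # (M, p)
    b0: np.ndarray  # (p,)
    phi2: np.ndarray  # (p,)
    mu: float
    sigma: float
    kappa2: np.ndarray | None = None  # (p,), additive structure
    lam: np.ndarray | None = None  # (p,), label-invariant structure
    p0_phi: np.ndarray | None = None  # (p,), mixing weight of the phi2 atom
    p0_kappa: np.ndarray | None = None  # (p,), mixing weight of the kappa2 atom


# ---------------------------------------------------------------------------
# density primitives
# ---------------------------------------------------------------------------


def loglik_arm(
    events: int | np.ndarray, n: int | np.ndarray, log_odds: float | np.ndarray
) -> float | np.ndarray:
    """Binomial log-probability of ``events`` successes in ``n`` trials with
    success probability ``expit(log_odds)``.

    Stable for large |log_odds|; the limits log_odds -> +/-inf return 0 when
    the observation is certain and -inf otherwise.
    """
    events = np.asarray(events)
    n = np.asarray(n)
    if np.any(events < 0) or np.any(events > n):
        raise ValueError("events must satisfy 0 <= events <= n")
    x = np.asarray(log_odds, dtype=float)
    coef = gammaln(n + 1) - gammaln(events + 1) - gammaln(n - events + 1)
    # r*x - n*log(1+e^x), with exact handling of infinite log odds
    core = events * np.where(np.isfinite(x), x, 0.0) - n * np.logaddexp(0.0, x)
    out = np.asarray(coef + core, dtype=float)
    pos_inf = np.isposinf(x)
    neg_inf = np.isneginf(x)
    if np.any(pos_inf):
        out = np.where(pos_inf, np.where(events == n, 0.0, -np.inf), out)
    if np.any(neg_inf):
        out = np.where(neg_inf, np.where(events == 0, 0.0, -np.inf), out)
    return out if out.ndim else float(out)


def effect_mean_var(
    X: np.ndarray,
    d_m: float,
    b_jm: np.ndarray,
    tau2_m: float,
    structure: str,
    kappa2_j: np.ndarray | None = None,
    lam_j: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean and variance of a trial's true log odds ratio given its
    characteristic indicators.

    Under both structures the mean is ``d_m + sum_j X_j b_jm``.  The
    variance is ``tau2_m + sum_j X_j kappa2_j`` (additive) or
    ``tau2_m * prod_j lam_j^X_j`` (label-invariant).
    """
    if tau2_m <= 0:
        raise ValueError("tau2_m must be strictly positive")
    X = np.asarray(X, dtype=float)
    b_jm = np.asarray(b_jm, dtype=float)
    if X.shape != b_jm.shape:
        raise ValueError("X and b_jm must have the same length")
    mean = float(d_m + X @ b_jm)
    if structure == "additive":
        kappa2_j = np.asarray(kappa2_j, dtype=float)
        if np.any(kappa2_j < 0):
            raise ValueError("kappa2 must be non-negative")
        var = float(tau2_m + X @ kappa2_j)
    elif structure == "label_invariant":
        lam_j = np.asarray(lam_j, dtype=float)
        if np.any(lam_j <= 0):
            raise ValueError("lambda must be strictly positive")
        var = float(tau2_m * np.prod(1.0 - X + X * lam_j))
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return mean, var


def _invgamma_logpdf(v: np.ndarray, shape: float, rate: float) -> np.ndarray:
    return shape * math.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(v) - rate / v


def logprior_variance_mixture(
    v: float, p0: float, shape: float = 0.001, rate: float = 0.001
) -> float:
    """Log-density of the zero-atom variance prior at ``v``.

    The prior puts mass ``p0`` on exactly zero and mass ``1 - p0`` on an
    inverse-gamma(shape, rate) slab; the density is with respect to the
    mixture of a point mass at 0 and Lebesgue measure.
    """
    if v < 0:
        raise ValueError("variance must be non-negative")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if v == 0.0:
        return math.log(p0) if p0 > 0 else -math.inf
    if p0 == 1.0:
        return -math.inf
    return math.log1p(-p0) + float(_invgamma_logpdf(np.asarray(v, dtype=float), shape, rate))


def logprior_lambda(lam: float | np.ndarray, spec: LambdaPrior) -> float | np.ndarray:
    """Log-density of the chosen lambda prior (see the prior classes)."""
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("lambda must be strictly positive")
    return spec.logpdf(lam)


def logprior_tau2_hierarchy(
    tau2: np.ndarray, mu: float, sigma: float
) -> float:
    """Sum of log-normal(mu, sigma^2) log-densities over heterogeneity
    variances ``tau2_m``."""
    tau2 = np.asarray(tau2, dtype=float)
    if np.any(tau2 <= 0):
        raise ValueError("tau2 must be strictly positive")
    if not 0 < sigma:
        raise ValueError("sigma must be strictly positive")
    log_t = np.log(tau2)
    return float(
        np.sum(
            -log_t - math.log(sigma) - 0.5 * LOG_2PI - (log_t - mu) ** 2 / (2.0 * sigma**2)
        )
    )


def _normal_logpdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (LOG_2PI + np.log(var)) - (x - mean) ** 2 / (2.0 * var)


# ---------------------------------------------------------------------------
# joint posterior
# ---------------------------------------------------------------------------


def trial_variances(
    X: np.ndarray, tau2_trial: np.ndarray, spec: ModelSpec, params: ModelParams
) -> np.ndarray:
    """Per-trial effect variance under the spec's structure."""
    if spec.structure == "additive":
        return tau2_trial + X @ params.kappa2
    return tau2_trial * np.exp(X @ np.log(params.lam))


def logposterior_components(
    dataset, params: ModelParams, spec: ModelSpec
) -> dict[str, float]:
    """Every additive component of the joint log-posterior, by name.

    Components:
      ``arms``       binomial log-likelihood of both arms of every trial
      ``theta``      normal densities of trial effects given (d, b, variances)
      ``b_hier``     N(b0_j, phi2_j) densities of the b_jm (point mass if phi2=0)
      ``locations``  vague normal priors on alpha, d, b0 and mu
      ``tau2_hier``  log-normal hierarchy on the tau2_m
      ``var_priors`` zero-atom priors on phi2 (and kappa2), Beta priors on p0
      ``lambda``     lambda priors (label-invariant only)
      ``sigma``      uniform(0, sigma_upper) prior on sigma
    """
    arr = dataset.arrays()
    names = spec.characteristics or list(dataset.characteristic_names)
    cols = [dataset.characteristic_index(nm) for nm in names]
    X = arr["X"][:, cols]
    mi = arr["meta_index"]
    pr = spec.priors

    arms = float(
        np.sum(loglik_arm(arr["events_control"], arr["n_control"], params.alpha))
        + np.sum(loglik_arm(arr["events_treat"], arr["n_treat"], params.alpha + params.theta))
    )

    mean_t = params.d[mi] + np.einsum("ij,ij->i", X, params.b[mi, :])
    var_t = trial_variances(X, params.tau2[mi], spec, params)
    theta_term = float(np.sum(_normal_logpdf(params.theta, mean_t, var_t)))

    # b hierarchy; phi2 = 0 collapses b_jm to exactly b0_j
    b_hier = 0.0
    for j in range(len(names)):
        if params.phi2[j] > 0:
            b_hier += float(
                np.sum(_normal_logpdf(params.b[:, j], params.b0[j], params.phi2[j]))
            )
        elif not np.allclose(params.b[:, j], params.b0[j]):
            b_hier = -math.inf

    v0 = pr.location_variance
    locations = float(
        np.sum(_normal_logpdf(params.alpha, 0.0, v0))
        + np.sum(_normal_logpdf(params.d, 0.0, v0))
        + np.sum(_normal_logpdf(params.b0, 0.0, v0))
        + _normal_logpdf(np.asarray(params.mu), 0.0, v0)
    )

    tau2_hier = logprior_tau2_hierarchy(params.tau2, params.mu, params.sigma)

    a0, b0_ = pr.p0_beta
    var_priors = 0.0
    for j in range(len(names)):
        p0p = params.p0_phi[j] if params.p0_phi is not None else 0.5
        var_priors += logprior_variance_mixture(
            float(params.phi2[j]), float(p0p), pr.slab_shape, pr.slab_rate
        )
        var_priors += float((a0 - 1) * math.log(p0p) + (b0_ - 1) * math.log1p(-p0p)) if 0 < p0p < 1 else 0.0
        if spec.structure == "additive":
            p0k = params.p0_kappa[j] if params.p0_kappa is not None else 0.5
            var_priors += logprior_variance_mixture(
                float(params.kappa2[j]), float(p0k), pr.slab_shape, pr.slab_rate
            )
            var_priors += float((a0 - 1) * math.log(p0k) + (b0_ - 1) * math.log1p(-p0k)) if 0 < p0k < 1 else 0.0

    lam_term = 0.0
    if spec.structure == "label_invariant":
        lam_term = float(np.sum(logprior_lambda(params.lam, pr.lambda_prior)))

    sigma_term = (
        -math.log(pr.sigma_upper) if 0 < params.sigma < pr.sigma_upper else -math.inf
    )

    return {
        "arms": arms,
        "theta": theta_term,
        "b_hier": b_hier,
        "locations": locations,
        "tau2_hier": tau2_hier,
        "var_priors": var_priors,
        "lambda": lam_term,
        "sigma": sigma_term,
    }


def joint_logposterior(dataset, params: ModelParams, spec: ModelSpec) -> float:
    """Joint log-posterior density (up to a constant) at one parameter point.

    This is the full joint density; the sampler's cut rule is a property of
    the variance-parameter *updates* (feedback blocking), not of the joint
    density itself.
    """
    return float(sum(logposterior_components(dataset, params, spec).values()))
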