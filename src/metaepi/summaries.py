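"""Posterior summaries, predictive heterogeneity, and DIC model fit.

Reporting conventions: posterior medians, standard deviations, and
equal-tailed 95% credible intervals (2.5% and 97.5% quantiles) of the
chain-pooled draws.  Mean-bias parameters are exponentiated to relative
odds ratios (ROR); variance-ratio parameters are also expressed as a
signed percentage change in heterogeneity variance.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MetaEpiDataset
from .mcmc import PosteriorDraws, total_deviance, _saturated_deviance


@dataclass(frozen=True)
class SummaryRow:
    """Posterior median, SD and equal-tailed 95% credible interval."""

    parameter: str
    median: float
    sd: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError(
                f"{self.parameter}: interval ({self.ci_low}, {self.ci_high}) "
                f"does not bracket the median {self.median}"
            )


@dataclass(frozen=True)
class PredictiveTau2Summary:
    """Log-normal summary of the predictive heterogeneity distribution.

    ``log_mean`` and ``log_sd`` are the posterior mean and SD of
    ``log(tau2_new)``; the median and central 95% range are derived from
    the fitted log-normal (1.96 multiplier), so they satisfy
    ``median = exp(log_mean)`` and ``range = exp(log_mean -/+ 1.96*log_sd)``
    exactly.  ``empirical_low``/``empirical_high`` are the raw 2.5%/97.5%
    quantiles of the predictive draws, for comparison with the fitted tail.
    """

    log_mean: float
    log_sd: float
    median: float
    range_low: float
    range_high: float
    empirical_low: float | None = None
    empirical_high: float | None = None

    @classmethod
    def from_log_moments(
        cls,
        log_mean: float,
        log_sd: float,
        empirical_low: float | None = None,
        empirical_high: float | None = None,
    ) -> "PredictiveTau2Summary":
        if log_sd < 0:
            raise ValueError("log_sd must be non-negative")
        return cls(
            log_mean=log_mean,
            log_sd=log_sd,
            median=math.exp(log_mean),
            range_low=math.exp(log_mean - 1.96 * log_sd),
            range_high=math.exp(log_mean + 1.96 * log_sd),
            empirical_low=empirical_low,
            empirical_high=empirical_high,
        )


@dataclass(frozen=True)
class FitDiagnostics:
    """Residual-deviance model-fit statistics.

    ``d_res`` is the posterior mean of the total residual (saturated)
    deviance, ``p_d`` the effective number of parameters computed at the
    posterior mean of the fitted arm probabilities (appropriate when the
    likelihood is non-linear in the parameters), and ``dic = d_res + p_d``.
    """

    d_res: float
    p_d: float
    dic: float

    def __post_init__(self) -> None:
        if not math.isclose(self.dic, self.d_res + self.p_d, rel_tol=1e-12, abs_tol=1e-9):
            raise ValueError("dic must equal d_res + p_d")


def _as_pooled(draws: PosteriorDraws | np.ndarray, param: str | None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if param is None:
            raise KeyError("parameter name required")
        return draws.pooled(param)
    return np.asarray(draws, dtype=float).reshape(-1)


def summarize(draws: PosteriorDraws | np.ndarray, param: str | None = None) -> SummaryRow:
    """Median, SD and 95% credible interval of one parameter's pooled draws."""
    x = _as_pooled(draws, param)
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return SummaryRow(
        parameter=param or "draws",
        median=float(med),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def mcse_median(draws: PosteriorDraws | np.ndarray, param: str | None = None) -> float:
    """Monte-Carlo standard error of the posterior median.

    Uses the asymptotic relation mcse(median) ~ 1.2533 * sd / sqrt(ESS)
    with the effective sample size estimated from the chains.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        chains = draws.get(param)
    else:
        chains = np.atleast_2d(np.asarray(draws, dtype=float))
    ess = float(az.ess(az.convert_to_dataset(chains))["x"].values)
    sd = float(np.std(chains, ddof=1))
    return 1.2533 * sd / math.sqrt(max(ess, 1.0))


def ror(b: float | np.ndarray) -> float | np.ndarray:
    """Relative odds ratio exp(b) for a log-odds-ratio difference b."""
    out = np.exp(np.asarray(b, dtype=float))
    return out if out.ndim else float(out)


def percent_change(lam: float) -> float:
    """Signed percentage change in heterogeneity variance, 100*(lambda - 1)."""
    if lam <= 0:
        raise ValueError("lambda must be strictly positive")
    return 100.0 * (lam - 1.0)


def implied_bias(
    draws: PosteriorDraws, combo
) -> tuple[SummaryRow, SummaryRow]:
    """Implied average bias for a trial with a given combination of
    characteristics: the draw-wise sum of the selected ``b0_j``.

    Summing draw-by-draw preserves the posterior correlations between the
    coefficients, so the interval is a genuine joint-posterior interval.
    Returns (log-scale row, ROR-scale row).
    """
    combo = np.asarray(combo, dtype=float)
    names = draws.characteristics
    if combo.shape != (len(names),):
        raise ValueError(f"combo must have length {len(names)}, got {combo.shape}")
    total = np.zeros_like(draws.pooled(f"b0[{names[0]}]"))
    for j, nm in enumerate(names):
        total = total + combo[j] * draws.pooled(f"b0[{nm}]")
    log_row = summarize(total, None)
    ror_row = summarize(np.exp(total), None)
    return (
        SummaryRow("b0[combined]", log_row.median, log_row.sd, log_row.ci_low, log_row.ci_high),
        SummaryRow("ROR[combined]", ror_row.median, ror_row.sd, ror_row.ci_low, ror_row.ci_high),
    )


def predictive_tau2(draws: PosteriorDraws, seed: int = 0) -> PredictiveTau2Summary:
    """Predictive distribution of the heterogeneity variance in a new
    meta-analysis.

    For every retained iteration one value ``log(tau2_new) ~
    N(mu_draw, sigma_draw^2)`` is simulated; the posterior mean and SD of
    these values parameterise the reported fitted log-normal.
    """
    try:
        mu = draws.pooled("mu")
        sigma = draws.pooled("sigma")
    except KeyError:
        raise SpecError("draws do not include the tau2 hierarchy (mu, sigma)") from None
    rng = np.random.default_rng(seed)
    log_new = mu + sigma * rng.standard_normal(mu.size)
    emp_lo, emp_hi = np.quantile(np.exp(log_new), [0.025, 0.975])
    return PredictiveTau2Summary.from_log_moments(
        log_mean=float(np.mean(log_new)),
        log_sd=float(np.std(log_new, ddof=1)),
        empirical_low=float(emp_lo),
        empirical_high=float(emp_hi),
    )


class SpecError(ValueError):
    pass


def arm_deviance(r: int, n: int, p_hat: float) -> float:
    """Residual (saturated) deviance of one arm:
    ``2[r log(r/(n p)) + (n-r) log((n-r)/(n - n p))]`` with 0*log(0/x) = 0."""
    return float(_saturated_deviance(np.asarray(float(r)), np.asarray(float(n)), np.asarray(p_hat)))


def dic(dataset: MetaEpiDataset, draws: PosteriorDraws) -> FitDiagnostics:
    """Deviance information criterion from the retained deviance trace.

    ``d_res`` averages the total residual deviance over iterations; ``p_d``
    subtracts the deviance evaluated at the posterior mean of the fitted
    arm probabilities (not at the posterior mean of the parameters).
    """
    if draws.fitted_prob_mean is None or draws.deviance is None:
        raise SpecError("draws do not carry fitted arm probabilities")
    arrays = dataset.arrays()
    if draws.fitted_prob_mean.shape[1] != len(arrays["meta_index"]):
        raise SpecError("dataset does not match the fitted draws")
    d_res = float(np.mean(draws.deviance))
    d_at_mean = total_deviance(
        {
            "events_control": arrays["events_control"].astype(float),
            "n_control": arrays["n_control"].astype(float),
            "events_treat": arrays["events_treat"].astype(float),
            "n_treat": arrays["n_treat"].astype(float),
        },
        draws.fitted_prob_mean[0],
        draws.fitted_prob_mean[1],
    )
    p_d = d_res - d_at_mean
    return FitDiagnostics(d_res=d_res, p_d=p_d, dic=d_res + p_d)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class Report:
    """Formatted posterior report: parameter table, predictive
    heterogeneity line and model-fit line."""

    frame: pd.DataFrame
    predictive: PredictiveTau2Summary | None
    fit: FitDiagnostics | None
    text: str

    def save(self, csv_path, text_path=None) -> None:
        self.frame.to_csv(csv_path, index=False)
        if text_path is not None:
            with open(text_path, "w") as fh:
                fh.write(self.text)


def report_table(
    draws: PosteriorDraws,
    dataset: MetaEpiDataset | None = None,
    predictive_seed: int = 0,
) -> Report:
    """Assemble the standard posterior report for a fitted model.

    Per characteristic: ``b0`` (log scale), its ROR transform, the variance
    parameter (``lambda``, or ``kappa = sqrt(kappa2)`` for the additive
    structure) and ``phi = sqrt(phi2)``.  For multivariable fits an
    implied-combined-bias block (all characteristics present) is appended.
    The model-fit line requires the dataset to recompute the deviance at
    the posterior-mean fitted values.
    """
    rows: list[SummaryRow] = []
    for nm in draws.characteristics:
        b0 = draws.pooled(f"b0[{nm}]")
        rows.append(SummaryRow(f"b0[{nm}]", *_stats(b0)))
        rows.append(SummaryRow(f"ROR[{nm}]", *_stats(np.exp(b0))))
        if draws.structure == "label_invariant":
            rows.append(SummaryRow(f"lambda[{nm}]", *_stats(draws.pooled(f"lam[{nm}]"))))
        else:
            rows.append(
                SummaryRow(f"kappa[{nm}]", *_stats(np.sqrt(draws.pooled(f"kappa2[{nm}]"))))
            )
        rows.append(SummaryRow(f"phi[{nm}]", *_stats(np.sqrt(draws.pooled(f"phi2[{nm}]")))))
    if len(draws.characteristics) > 1:
        log_row, ror_row = implied_bias(draws, np.ones(len(draws.characteristics)))
        rows.append(log_row)
        rows.append(ror_row)

    pred = None
    if "mu" in draws.params and "sigma" in draws.params:
        pred = predictive_tau2(draws, seed=predictive_seed)
    fit_line = dic(dataset, draws) if dataset is not None else None

    frame = pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "median": r.median,
                "sd": r.sd,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in rows
        ]
    )
    buf = io.StringIO()
    buf.write(f"Model: {draws.structure}\n")
    buf.write(f"{'Parameter':<22}{'Median':>8}{'SD':>8}{'95% CI':>20}\n")
    for r in rows:
        buf.write(
            f"{r.parameter:<22}{r.median:>8.2f}{r.sd:>8.2f}"
            f"{r.ci_low:>9.2f} to {r.ci_high:<7.2f}\n"
        )
    if pred is not None:
        buf.write(
            f"Predictive tau2_new: log-normal({pred.log_mean:.2f}, {pred.log_sd:.2f}^2), "
            f"median = {pred.median:.2f}, 95% range {pred.range_low:.3f}-{pred.range_high:.2f}\n"
        )
    if fit_line is not None:
        buf.write(
            f"D_res = {fit_line.d_res:.0f}, p_D = {fit_line.p_d:.0f}, DIC = {fit_line.dic:.0f}\n"
        )
    return Report(frame=frame, predictive=pred, fit=fit_line, text=buf.getvalue())


def _stats(x: np.ndarray) -> tuple[float, float, float, float]:
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return float(med), float(np.std(x, ddof=1)), float(lo), float(hi)
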