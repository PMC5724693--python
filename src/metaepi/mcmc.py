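"""Posterior sampling for the meta-epidemiological models.

The sampler is Metropolis-within-Gibbs.  Gaussian full conditionals
(``d_m``, ``b0_j``, ``b_jm``, ``mu``) are sampled exactly; strictly positive
parameters (``tau2_m``, ``lambda_j``) use random-walk proposals on the log
scale; ``sigma`` uses a reflected random walk on (0, sigma_upper).  Proposal
scales adapt towards a 44% acceptance rate during burn-in and are frozen
afterwards.

Zero-atom variance components (``phi2_j``, ``kappa2_j``) are sampled with a
mixture kernel that jumps between the point mass at zero and the
inverse-gamma slab, so posterior draws can be *exactly* zero with positive
frequency.  Because ``phi2_j = 0`` collapses every ``b_jm`` onto ``b0_j``,
the ``(phi2_j, b0_j, b_jm)`` block is updated in collapsed form: ``phi2_j``
and ``b0_j`` are sampled with the ``b_jm`` integrated out analytically
(Sherman-Morrison on the one-factor covariance), after which the ``b_jm``
are re-drawn from their exact conditionals.

Cut rule: meta-analyses with fewer than two trials in either category of a
characteristic cannot separate ``tau2_m`` from the variance inflation.
Their trial-effect variances still *use* the current ``kappa2``/``lambda``
value, but their likelihood terms are excluded from the acceptance ratio of
the ``kappa2``/``lambda`` update, blocking feedback from those
meta-analyses — the same directed behaviour as the BUGS "cut" device.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MetaEpiDataset, classify_informative
from .model import (
    LambdaPrior,
    ModelSpec,
    TruncatedLogNormalLambda,
    logprior_lambda,
)


class SpecificationError(ValueError):
    """Raised when a model cannot be fitted to the given dataset."""


class DiagnosticUnavailableError(ValueError):
    """Raised when a convergence diagnostic cannot be computed."""


@dataclass
class McmcConfig:
    """Sampler settings.

    Defaults are a scaled-down run suitable for simulation studies; the
    long-run analogue (500 000 iterations, 25 000 burn-in, 3 chains) can be
    requested explicitly.
    """

    n_iter: int = 20000
    n_burnin: int = 5000
    n_chains: int = 3
    seed: int = 0
    init_dispersion: float = 2.0
    target_params: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class PosteriorDraws:
    """Retained posterior draws plus the accumulators needed for DIC.

    ``params`` maps a parameter name to an array of shape
    ``(n_chains, n_kept)``.  ``deviance`` holds the total residual deviance
    of the fitted arm probabilities at every retained iteration, and
    ``fitted_prob_mean`` the posterior mean fitted event probability per arm
    (control row 0, treatment row 1) — together these are exactly the
    per-iteration fitted-probability information DIC requires, kept in
    accumulated form so memory does not scale with chain length.
    """

    params: dict[str, np.ndarray]
    deviance: np.ndarray
    fitted_prob_mean: np.ndarray
    structure: str
    characteristics: list[str]
    meta_ids: list[str]
    config: McmcConfig
    diagnostics: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.params)

    def get(self, param: str) -> np.ndarray:
        """Draws for one parameter, shape (n_chains, n_kept)."""
        try:
            return self.params[param]
        except KeyError:
            raise KeyError(
                f"parameter {param!r} not retained; available: {sorted(self.params)[:20]}..."
            ) from None

    def pooled(self, param: str) -> np.ndarray:
        """Draws pooled across chains (1-D)."""
        return self.get(param).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: chain id, iteration, one column per parameter."""
        n_chains, n_kept = self.deviance.shape
        cols = {
            "chain": np.repeat(np.arange(n_chains), n_kept),
            "iteration": np.tile(np.arange(n_kept), n_chains),
        }
        for name, arr in self.params.items():
            cols[name] = arr.reshape(-1)
        cols["deviance"] = self.deviance.reshape(-1)
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def bgr(draws: PosteriorDraws | np.ndarray, param: str | None = None) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor.

    Computed from the between- and within-chain variances of the retained
    draws.  Values near 1 indicate the chains have mixed; values above
    ~1.05 suggest non-convergence.  Sampling noise can push the raw
    estimate slightly below 1, in which case 1 is returned.
    """
    if isinstance(draws, PosteriorDraws):
        if param is None:
            raise ValueError("param name required")
        chains = draws.get(param)
    else:
        chains = np.asarray(draws, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected array of shape (n_chains, n_iterations)")
    c, t = chains.shape
    if c < 2:
        raise DiagnosticUnavailableError("BGR diagnostic requires at least 2 chains")
    within = float(np.mean(np.var(chains, axis=1, ddof=1)))
    between = float(t * np.var(np.mean(chains, axis=1), ddof=1))
    if within == 0.0:
        return 1.0 if between == 0.0 else math.inf
    v_hat = (t - 1) / t * within + between / t
    return max(1.0, math.sqrt(v_hat / within))


def apply_cut_mask(
    dataset: MetaEpiDataset, flags, spec: ModelSpec
) -> np.ndarray:
    """Boolean mask, shape (n_meta, p), of which meta-analyses contribute
    likelihood terms to each variance-inflation parameter's update.

    ``flags`` is a sequence of :class:`InformativenessFlags`, one per
    modelled characteristic in spec order.  All meta-analyses always
    contribute to ``b_m``, ``b0``, ``phi2``, ``d_m`` and ``tau2_m``; the
    mask only gates the ``kappa2``/``lambda`` updates.
    """
    names = spec.characteristics or list(dataset.characteristic_names)
    meta_ids = dataset.meta_ids
    mask = np.zeros((len(meta_ids), len(names)), dtype=bool)
    for j, fl in enumerate(flags):
        if fl.characteristic != names[j]:
            raise SpecificationError(
                f"flags for {fl.characteristic!r} do not match modelled "
                f"characteristic {names[j]!r}"
            )
        for k, mid in enumerate(meta_ids):
            mask[k, j] = fl.informative_for_variance[mid]
    return mask


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

_TARGET_ACC = 0.44  # optimal scalar random-walk acceptance rate


def _adapt(log_scale: np.ndarray, accepted, t: int) -> None:
    gamma = 2.0 / (t + 20.0) ** 0.6
    log_scale += gamma * (np.asarray(accepted, dtype=float) - _TARGET_ACC)


def _binom_core(r, n, x):
    # binomial log-likelihood without the constant binomial coefficient
    return r * x - n * np.logaddexp(0.0, x)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _saturated_deviance(r, n, p_hat):
    p_hat = np.clip(p_hat, 1e-12, 1.0 - 1e-12)
    fitted = n * p_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0) / fitted), 0.0)
        t2 = np.where(
            n - r > 0,
            (n - r) * np.log(np.where(n - r > 0, n - r, 1.0) / (n - fitted)),
            0.0,
        )
    return 2.0 * (t1 + t2)


def total_deviance(arrays: dict, p_control: np.ndarray, p_treat: np.ndarray) -> float:
    """Total residual (saturated) deviance of fitted arm probabilities."""
    return float(
        np.sum(_saturated_deviance(arrays["events_control"], arrays["n_control"], p_control))
        + np.sum(_saturated_deviance(arrays["events_treat"], arrays["n_treat"], p_treat))
    )


def _invgamma_logpdf(v, shape, rate):
    from scipy.special import gammaln

    return shape * math.log(rate) - gammaln(shape) - (shape + 1.0) * np.log(v) - rate / v


class _SlabProposal:
    """Adaptive log-normal proposal used to jump from the zero atom into the
    slab; location/scale track accepted positive values during burn-in."""

    def __init__(self, loc: float = math.log(0.04), scale: float = 1.5):
        self.loc = loc
        self.scale = scale
        self._n = 0
        self.frozen = False

    def logpdf(self, v: float) -> float:
        z = (math.log(v) - self.loc) / self.scale
        return -math.log(v) - math.log(self.scale) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z

    def draw(self, rng) -> float:
        return float(np.exp(self.loc + self.scale * rng.standard_normal()))

    def observe(self, v: float) -> None:
        if self.frozen or v <= 0:
            return
        self._n += 1
        w = 1.0 / min(self._n, 200)
        self.loc = (1 - w) * self.loc + w * math.log(v)


class _ChainState:
    """Mutable state of one chain."""

    def __init__(self, data, spec, chain_idx, init_dispersion, rng):
        r_c, n_c = data["events_control"], data["n_control"]
        r_t, n_t = data["events_treat"], data["n_treat"]
        M = data["n_meta"]
        p = data["p"]
        mi = data["meta_index"]
        off = init_dispersion * ((chain_idx + 1) // 2) * (1 if chain_idx % 2 else -1)

        logit_c = np.log((r_c + 0.5) / (n_c - r_c + 0.5))
        logit_t = np.log((r_t + 0.5) / (n_t - r_t + 0.5))
        self.alpha = logit_c + off
        self.theta = (logit_t - logit_c) + off
        self.d = np.bincount(mi, self.theta, minlength=M) / np.bincount(mi, minlength=M)
        self.b = np.zeros((M, p))
        self.b0 = np.zeros(p) + 0.25 * off
        var_levels = [0.1, 0.01, 1.0]
        self.tau2 = np.full(M, var_levels[chain_idx % 3])
        self.phi2 = np.full(p, var_levels[chain_idx % 3])
        self.mu = math.log(self.tau2[0])
        self.sigma = [1.0, 0.5, 1.8][chain_idx % 3]
        self.p0_phi = np.full(p, 0.5)
        if spec.structure == "additive":
            self.kappa2 = np.full(p, var_levels[chain_idx % 3])
            self.p0_kappa = np.full(p, 0.5)
            self.lam = None
        else:
            # dispersed but always inside the prior's support
            q = [0.5, 0.25, 0.75][chain_idx % 3]
            self.lam = np.full(p, spec.priors.lambda_prior.ppf(q))
            self.kappa2 = None
            self.p0_kappa = None

    def trial_var(self, data) -> np.ndarray:
        mi = data["meta_index"]
        X = data["X"]
        if self.lam is not None:
            return self.tau2[mi] * np.exp(X @ np.log(self.lam))
        return self.tau2[mi] + X @ self.kappa2

    def trial_mean(self, data) -> np.ndarray:
        mi = data["meta_index"]
        return self.d[mi] + np.einsum("ij,ij->i", data["X"], self.b[mi, :])


def _prepare(dataset: MetaEpiDataset, spec: ModelSpec) -> dict:
    arr = dataset.arrays()
    names = spec.characteristics or list(dataset.characteristic_names)
    cols = [dataset.characteristic_index(nm) for nm in names]
    X = arr["X"][:, cols] if cols else np.zeros((len(dataset), 0))
    meta_ids = dataset.meta_ids
    flags = [classify_informative(dataset, nm) for nm in names]
    for nm, fl in zip(names, flags):
        if not any(fl.informative_for_mean.values()):
            raise SpecificationError(
                f"no meta-analysis is informative for the mean difference of "
                f"characteristic {nm!r}"
            )
        if not any(fl.informative_for_variance.values()):
            raise SpecificationError(
                f"no meta-analysis is variance-informative for characteristic "
                f"{nm!r}; the variance-inflation posterior would equal its prior"
            )
    cut = apply_cut_mask(dataset, flags, spec)
    data = {
        "events_control": arr["events_control"].astype(float),
        "n_control": arr["n_control"].astype(float),
        "events_treat": arr["events_treat"].astype(float),
        "n_treat": arr["n_treat"].astype(float),
        "meta_index": arr["meta_index"],
        "X": X,
        "n_meta": len(meta_ids),
        "p": len(names),
        "names": names,
        "meta_ids": meta_ids,
        "cut_mask": cut,
    }
    # per-characteristic trial index sets
    sel, sel_cut = [], []
    for j in range(len(names)):
        idx = np.where(X[:, j] == 1.0)[0]
        sel.append(idx)
        sel_cut.append(idx[cut[arr["meta_index"][idx], j]])
    data["sel"] = sel
    data["sel_cut"] = sel_cut
    return data


def _run_chain(data, spec, config, chain_idx, rng, keep, store_names):
    M, p = data["n_meta"], data["p"]
    N = len(data["meta_index"])
    mi = data["meta_index"]
    X = data["X"]
    r_c, n_c = data["events_control"], data["n_control"]
    r_t, n_t = data["events_treat"], data["n_treat"]
    pr = spec.priors
    v0 = pr.location_variance
    a_beta, b_beta = pr.p0_beta
    additive = spec.structure == "additive"

    st = _ChainState(data, spec, chain_idx, config.init_dispersion, rng)

    ls_alpha = np.full(N, math.log(0.5))
    ls_theta = np.full(N, math.log(0.5))
    ls_tau = np.full(M, math.log(0.8))
    ls_lam = np.full(p, math.log(0.6))
    ls_kap = np.full(p, math.log(1.2))
    ls_phi = np.full(p, math.log(1.2))
    ls_sigma = math.log(0.3)
    slab_phi = [_SlabProposal() for _ in range(p)]
    slab_kap = [_SlabProposal() for _ in range(p)]

    n_keep = config.n_iter - config.n_burnin
    out = {nm: np.empty(n_keep) for nm in store_names}
    dev_out = np.empty(n_keep)
    fit_sum = np.zeros((2, N))
    acc_lam = np.zeros(p)

    def mixture_mh(v, ls, slab, p0, f, j_acc=None):
        """One mixture atom/slab MH move for a variance component.

        ``f(v)`` is the log-likelihood contribution (f(0) finite); the
        mixture prior and Hastings terms are handled here.  Returns the new
        value and whether the move was accepted.
        """
        sh, ra = pr.slab_shape, pr.slab_rate
        if v > 0.0:
            if rng.random() < 0.5:  # propose the atom
                if p0 <= 0.0:
                    return v, False
                loga = (
                    f(0.0)
                    + math.log(p0)
                    + slab.logpdf(v)
                    - f(v)
                    - math.log1p(-p0)
                    - float(_invgamma_logpdf(v, sh, ra))
                    - math.log(0.5)
                )
                if math.log(rng.random()) < loga:
                    return 0.0, True
                return v, False
            step = math.exp(ls)
            v_new = v * math.exp(step * rng.standard_normal())
            loga = (
                f(v_new)
                - f(v)
                + float(_invgamma_logpdf(v_new, sh, ra))
                - float(_invgamma_logpdf(v, sh, ra))
                + math.log(v_new / v)
            )
            if math.log(rng.random()) < loga:
                slab.observe(v_new)
                return v_new, True
            return v, False
        # at the atom: propose a slab value from the pseudo-proposal
        if p0 >= 1.0:
            return v, False
        v_new = slab.draw(rng)
        loga = (
            f(v_new)
            + math.log1p(-p0)
            + float(_invgamma_logpdf(v_new, sh, ra))
            + math.log(0.5)
            - f(0.0)
            - (math.log(p0) if p0 > 0 else -math.inf)
            - slab.logpdf(v_new)
        )
        if math.log(rng.random()) < loga:
            slab.observe(v_new)
            return v_new, True
        return v, False

    for t in range(config.n_iter):
        adapting = t < config.n_burnin

        # --- alpha: vectorised random-walk Metropolis --------------------
        prop = st.alpha + np.exp(ls_alpha) * rng.standard_normal(N)
        xt_cur = st.alpha + st.theta
        xt_prop = prop + st.theta
        delta = (
            _binom_core(r_c, n_c, prop)
            - _binom_core(r_c, n_c, st.alpha)
            + _binom_core(r_t, n_t, xt_prop)
            - _binom_core(r_t, n_t, xt_cur)
            + (st.alpha**2 - prop**2) / (2.0 * v0)
        )
        acc = np.log(rng.random(N)) < delta
        st.alpha = np.where(acc, prop, st.alpha)
        if adapting:
            _adapt(ls_alpha, acc, t)

        # --- theta: vectorised random-walk Metropolis --------------------
        mean_t = st.trial_mean(data)
        var_t = st.trial_var(data)
        prop = st.theta + np.exp(ls_theta) * rng.standard_normal(N)
        delta = (
            _binom_core(r_t, n_t, st.alpha + prop)
            - _binom_core(r_t, n_t, st.alpha + st.theta)
            + ((st.theta - mean_t) ** 2 - (prop - mean_t) ** 2) / (2.0 * var_t)
        )
        acc = np.log(rng.random(N)) < delta
        st.theta = np.where(acc, prop, st.theta)
        if adapting:
            _adapt(ls_theta, acc, t)

        # --- d: exact Gaussian conditional -------------------------------
        var_t = st.trial_var(data)
        resid = st.theta - np.einsum("ij,ij->i", X, st.b[mi, :])
        prec = np.bincount(mi, 1.0 / var_t, minlength=M) + 1.0 / v0
        mean = np.bincount(mi, resid / var_t, minlength=M) / prec
        st.d = mean + rng.standard_normal(M) / np.sqrt(prec)

        # --- per characteristic: collapsed (phi2, b0, b) block -----------
        for j in range(p):
            idx = data["sel"][j]
            mj = mi[idx]
            var_t = st.trial_var(data)
            e = (
                st.theta[idx]
                - st.d[mj]
                - np.einsum("ij,ij->i", X[idx], st.b[mj, :])
                + st.b[mj, j]
            )
            w = 1.0 / var_t[idx]
            A = np.bincount(mj, w, minlength=M)
            B = np.bincount(mj, e * w, minlength=M)
            has = A > 0
            b0j = st.b0[j]

            def f_phi(v, A=A[has], C=None, b0j=b0j, Bh=B[has]):
                c = Bh - b0j * A
                den = 1.0 + v * A
                return float(-0.5 * np.sum(np.log(den)) + 0.5 * v * np.sum(c * c / den))

            st.phi2[j], _ = mixture_mh(
                float(st.phi2[j]), ls_phi[j], slab_phi[j], float(st.p0_phi[j]), f_phi
            )

            # b0_j | phi2_j with b_jm integrated out
            den = 1.0 + st.phi2[j] * A[has]
            prec0 = np.sum(A[has] / den) + 1.0 / v0
            mean0 = np.sum(B[has] / den) / prec0
            st.b0[j] = mean0 + rng.standard_normal() / math.sqrt(prec0)

            # b_jm | b0_j, phi2_j
            if st.phi2[j] > 0.0:
                precb = A + 1.0 / st.phi2[j]
                meanb = (B + st.b0[j] / st.phi2[j]) / precb
                st.b[:, j] = meanb + rng.standard_normal(M) / np.sqrt(precb)
            else:
                st.b[:, j] = st.b0[j]

            # p0 | atom indicator (Beta-Bernoulli conjugacy)
            z0 = 1.0 if st.phi2[j] == 0.0 else 0.0
            st.p0_phi[j] = rng.beta(a_beta + z0, b_beta + 1.0 - z0)

        # --- variance inflation (cut: informative meta-analyses only) ----
        mean_t = st.trial_mean(data)
        for j in range(p):
            idx = data["sel_cut"][j]
            res2 = (st.theta[idx] - mean_t[idx]) ** 2
            var_cur = st.trial_var(data)[idx]
            if additive:
                k_cur = float(st.kappa2[j])

                def f_kap(v, base=var_cur - k_cur, res2=res2):
                    vv = base + v
                    return float(-0.5 * np.sum(np.log(vv) + res2 / vv))

                st.kappa2[j], _ = mixture_mh(
                    k_cur, ls_kap[j], slab_kap[j], float(st.p0_kappa[j]), f_kap
                )
                z0 = 1.0 if st.kappa2[j] == 0.0 else 0.0
                st.p0_kappa[j] = rng.beta(a_beta + z0, b_beta + 1.0 - z0)
            else:
                lam_cur = float(st.lam[j])
                lam_new = lam_cur * math.exp(
                    math.exp(ls_lam[j]) * rng.standard_normal()
                )
                lp_new = logprior_lambda(lam_new, pr.lambda_prior)
                if np.isfinite(lp_new):
                    var_new = var_cur * (lam_new / lam_cur)
                    loga = (
                        float(-0.5 * np.sum(np.log(var_new) + res2 / var_new))
                        - float(-0.5 * np.sum(np.log(var_cur) + res2 / var_cur))
                        + float(lp_new)
                        - float(logprior_lambda(lam_cur, pr.lambda_prior))
                        + math.log(lam_new / lam_cur)
                    )
                    ok = math.log(rng.random()) < loga
                else:
                    ok = False
                if ok:
                    st.lam[j] = lam_new
                    acc_lam[j] += 0.0 if adapting else 1.0
                if adapting:
                    ls_lam[j] += (2.0 / (t + 20.0) ** 0.6) * ((1.0 if ok else 0.0) - _TARGET_ACC)

        # --- tau2: vectorised log-scale random walk per meta-analysis ----
        mean_t = st.trial_mean(data)
        eta = np.log(st.tau2)
        eta_new = eta + np.exp(ls_tau) * rng.standard_normal(M)
        tau2_new = np.exp(eta_new)
        var_cur = st.trial_var(data)
        if additive:
            var_new = var_cur - st.tau2[mi] + tau2_new[mi]
        else:
            var_new = var_cur * (tau2_new / st.tau2)[mi]
        res2 = (st.theta - mean_t) ** 2
        per_trial = -0.5 * (np.log(var_new) - np.log(var_cur)) - 0.5 * res2 * (
            1.0 / var_new - 1.0 / var_cur
        )
        delta = np.bincount(mi, per_trial, minlength=M) + (
            (eta - st.mu) ** 2 - (eta_new - st.mu) ** 2
        ) / (2.0 * st.sigma**2)
        acc = np.log(rng.random(M)) < delta
        st.tau2 = np.where(acc, tau2_new, st.tau2)
        if adapting:
            _adapt(ls_tau, acc, t)

        # --- (mu, sigma) hierarchy ---------------------------------------
        eta = np.log(st.tau2)
        prec = M / st.sigma**2 + 1.0 / v0
        st.mu = float(np.sum(eta) / st.sigma**2 / prec + rng.standard_normal() / math.sqrt(prec))

        s_new = st.sigma + math.exp(ls_sigma) * rng.standard_normal()
        ok = False
        if 0.0 < s_new < pr.sigma_upper:
            ss = float(np.sum((eta - st.mu) ** 2))
            loga = -M * math.log(s_new) - ss / (2 * s_new**2) + M * math.log(st.sigma) + ss / (
                2 * st.sigma**2
            )
            ok = math.log(rng.random()) < loga
        if ok:
            st.sigma = s_new
        if adapting:
            ls_sigma += (2.0 / (t + 20.0) ** 0.6) * ((1.0 if ok else 0.0) - _TARGET_ACC)

        # --- record -------------------------------------------------------
        if t >= config.n_burnin:
            k = t - config.n_burnin
            p_ctrl = _expit(st.alpha)
            p_trt = _expit(st.alpha + st.theta)
            dev_out[k] = total_deviance(data, p_ctrl, p_trt)
            fit_sum[0] += p_ctrl
            fit_sum[1] += p_trt
            for nm in store_names:
                out[nm][k] = keep[nm](st)

    return out, dev_out, fit_sum


def _default_store(data, spec, config):
    """Names and extractor closures for the retained parameters."""
    names = data["names"]
    meta_ids = data["meta_ids"]
    additive = spec.structure == "additive"
    keep: dict = {}
    for j, nm in enumerate(names):
        keep[f"b0[{nm}]"] = lambda st, j=j: st.b0[j]
        keep[f"phi2[{nm}]"] = lambda st, j=j: st.phi2[j]
        if additive:
            keep[f"kappa2[{nm}]"] = lambda st, j=j: st.kappa2[j]
        else:
            keep[f"lam[{nm}]"] = lambda st, j=j: st.lam[j]
    keep["mu"] = lambda st: st.mu
    keep["sigma"] = lambda st: st.sigma
    for k, mid in enumerate(meta_ids):
        keep[f"d[{mid}]"] = lambda st, k=k: st.d[k]
        keep[f"tau2[{mid}]"] = lambda st, k=k: st.tau2[k]
    if config.target_params is not None:
        wanted = set(config.target_params)

        def match(name: str) -> bool:
            return name in wanted or name.split("[")[0] in wanted

        keep = {nm: fn for nm, fn in keep.items() if match(nm)}
        if not keep:
            raise SpecificationError(f"target_params matched nothing: {config.target_params}")
    return keep


def fit(dataset: MetaEpiDataset, spec: ModelSpec, config: McmcConfig) -> PosteriorDraws:
    """Sample the posterior of the chosen model on a dataset.

    Runs ``config.n_chains`` independent chains from dispersed starting
    values.  Identical (dataset, spec, config) including the seed yields
    bitwise-identical draws.  If the BGR statistic of any retained
    parameter exceeds 1.05 a warning is attached to the result (and issued
    via :mod:`warnings`) — non-convergence is reported, never raised.
    """
    data = _prepare(dataset, spec)
    keep = _default_store(data, spec, config)
    store_names = list(keep)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_keep = config.n_iter - config.n_burnin
    params = {nm: np.empty((config.n_chains, n_keep)) for nm in store_names}
    deviance = np.empty((config.n_chains, n_keep))
    fit_sum = np.zeros((2, len(data["meta_index"])))
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        out, dev, fs = _run_chain(data, spec, config, c, rng, keep, store_names)
        for nm in store_names:
            params[nm][c] = out[nm]
        deviance[c] = dev
        fit_sum += fs

    draws = PosteriorDraws(
        params=params,
        deviance=deviance,
        fitted_prob_mean=fit_sum / (config.n_chains * n_keep),
        structure=spec.structure,
        characteristics=list(data["names"]),
        meta_ids=list(data["meta_ids"]),
        config=config,
    )
    if config.n_chains >= 2:
        for nm in store_names:
            draws.diagnostics[nm] = bgr(params[nm])
        bad = {nm: v for nm, v in draws.diagnostics.items() if v > 1.05}
        if bad:
            worst = max(bad, key=bad.get)
            msg = (
                f"BGR statistic exceeds 1.05 for {len(bad)} parameter(s); "
                f"worst: {worst} = {bad[worst]:.3f}"
            )
            draws.warnings.append(msg)
            _warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return draws


# ---------------------------------------------------------------------------
# prior-only sampling (no likelihood contribution)
# ---------------------------------------------------------------------------


def sample_lambda_prior(
    prior: LambdaPrior,
    n_draws: int,
    seed: int,
    n_walkers: int = 1000,
    n_warm: int = 300,
    step: float = 2.4,
) -> np.ndarray:
    """Draws from a lambda prior using the sampler's Metropolis kernel with
    the likelihood removed.

    Runs ``n_walkers`` parallel log-scale random-walk chains and pools
    their post-warm-up states; used to verify that the kernel reproduces
    the specified prior when the data carry no information.
    """
    rng = np.random.default_rng(seed)
    lower = prior.lower if isinstance(prior, TruncatedLogNormalLambda) else 0.0
    lam = np.exp(rng.normal(0.5, 1.0, n_walkers))
    if lower > 0.0:
        lam = lower + np.abs(lam)
    n_per = -(-n_draws // n_walkers)  # ceil
    out = np.empty((n_per, n_walkers))
    for t in range(n_warm + n_per):
        prop = lam * np.exp(step * rng.standard_normal(n_walkers))
        lp_new = np.asarray(logprior_lambda(np.maximum(prop, 1e-300), prior))
        lp_cur = np.asarray(logprior_lambda(lam, prior))
        loga = lp_new - lp_cur + np.log(prop) - np.log(lam)
        acc = np.log(rng.random(n_walkers)) < loga
        lam = np.where(acc, prop, lam)
        if t >= n_warm:
            out[t - n_warm] = lam
    return out.reshape(-1)[:n_draws]
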