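"""Bayesian estimation of fitness functions and bias coefficients.

Priors (weakly informative, neutrality-centred): every fitness segment
value c ~ Exp(1), so the prior mean of each f_i is 1 (no selection); every
bias coefficient beta ~ N(0, 1) on the standardized covariate scale.

Sampling runs in an unconstrained space — c on the log scale with the
Jacobian correction — with the package's NUTS sampler and analytic
gradients: the derivative of the Dirichlet-multinomial log-likelihood with
respect to alpha is a difference of digamma terms, and alpha is an
explicit product of the parameters, so the full gradient is closed-form.

Effects are declared significant when the middle 98% of the posterior
(the 1%–99% quantile interval) excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from . import hmc
from .dm import ContractError, ModelParams, quartile_breakpoints

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)
FEATURE_COEFS = ("beta_win", "beta_top50_win", "beta_top50_freq")


@dataclass
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.9
    max_depth: int = 10
    seed: int = 0
    init_jitter: float = 0.2
    rhat_max: float = 1.01
    ess_min: float = 400.0


class ModelData:
    """Precomputed inference inputs for one position.

    Fixes the quartile breakpoints from the observed frequency series (over
    the modelling years), precomputes the active fitness segment of every
    move in every transition year, and caches the count-dependent constant
    of the DM log-pmf.
    """

    def __init__(self, table, features, plus_one: bool = True, breakpoints=None):
        X = np.asarray(table.counts, dtype=float)
        N = np.asarray(table.totals, dtype=float)
        if X.shape[0] < 2:
            raise ContractError("need at least 2 years (1 transition) to fit")
        self.k = X.shape[1]
        self.moves = list(table.moves)
        self.years = np.asarray(table.years)
        self.plus_one = plus_one
        freqs = table.frequencies()
        if breakpoints is None:
            breakpoints = [quartile_breakpoints(freqs[N > 0, i]) for i in range(self.k)]
        self.breakpoints = [tuple(b) for b in breakpoints]
        ok = (N[:-1] > 0) & (N[1:] > 0)
        if not ok.any():
            raise ContractError("no usable transitions (zero-game years)")
        self.trans_idx = np.nonzero(ok)[0]  # year index t of each transition
        self.Xc = X[:-1][ok]
        self.Nc = N[:-1][ok]
        self.Xn = X[1:][ok]
        self.Nn = N[1:][ok]
        self.Y = np.asarray(features.standardized, dtype=float)[:-1][ok]  # (Tr, k, 3)
        P = self.Xc / self.Nc[:, None]
        bp = np.asarray(self.breakpoints)  # (k, 3)
        self.seg = np.stack(
            [np.searchsorted(bp[i], P[:, i], side="right") for i in range(self.k)], axis=1
        )  # (Tr, k) active segment of each move at each transition
        self.logpmf_const = float(
            np.sum(gammaln(self.Nn + 1)) - np.sum(gammaln(self.Xn + 1))
        )
        self.n_params = 7 * self.k

    def param_names(self) -> list[str]:
        names = [f"c[{m},{j + 1}]" for m in self.moves for j in range(4)]
        names += [f"{coef}[{m}]" for m in self.moves for coef in FEATURE_COEFS]
        return names

    # -- log posterior and gradient in the unconstrained space ----------

    def _alpha_parts(self, C, B):
        c_active = C[np.arange(self.k)[None, :], self.seg]  # (Tr, k)
        expfac = np.exp(np.einsum("tim,im->ti", self.Y, B))
        a_raw = expfac * c_active * self.Xc
        a = a_raw + 1.0 if self.plus_one else a_raw
        return a_raw, a

    def unconstrained_logpost_grad(self, theta: np.ndarray):
        """(log posterior + Jacobian, gradient) at theta = (log c, beta)."""
        k = self.k
        u = theta[: 4 * k].reshape(k, 4)
        B = theta[4 * k :].reshape(k, 3)
        if np.any(np.abs(theta) > 300):  # far outside any posterior mass; exp would overflow
            return -np.inf, np.zeros_like(theta)
        with np.errstate(over="raise"):
            try:
                C = np.exp(u)
                a_raw, a = self._alpha_parts(C, B)
            except FloatingPointError:
                return -np.inf, np.zeros_like(theta)
        if (not self.plus_one and np.any(a <= 0)) or not np.all(np.isfinite(a)):
            return -np.inf, np.zeros_like(theta)
        A = a.sum(axis=1)
        loglik = self.logpmf_const + float(
            np.sum(gammaln(A) - gammaln(self.Nn + A))
            + np.sum(gammaln(self.Xn + a) - gammaln(a))
        )
        # d loglik / d alpha
        g = (
            digamma(A)[:, None]
            - digamma(self.Nn + A)[:, None]
            + digamma(self.Xn + a)
            - digamma(a)
        )
        w = g * a_raw  # chain through alpha_raw (the +1 shift has zero gradient)
        grad_u = np.empty((k, 4))
        for j in range(4):
            grad_u[:, j] = np.sum(w * (self.seg == j), axis=0)
        grad_B = np.einsum("ti,tim->im", w, self.Y)
        # priors: Exp(1) on c (+ log Jacobian u), N(0,1) on beta
        logprior = float(np.sum(u - C)) + float(np.sum(-0.5 * B * B - _HALF_LOG_2PI))
        grad_u += 1.0 - C
        grad_B += -B
        logpost = loglik + logprior
        return logpost, np.concatenate([grad_u.ravel(), grad_B.ravel()])

    def params_from_vector(self, theta: np.ndarray, log_scale: bool = False) -> ModelParams:
        k = self.k
        c = theta[: 4 * k].reshape(k, 4)
        if log_scale:
            c = np.exp(c)
        return ModelParams.from_matrices(c, theta[4 * k :].reshape(k, 3), self.breakpoints)


def log_posterior(params, table, features, plus_one: bool = True) -> float:
    """Log posterior density at a natural-scale parameter point.

    ``params`` is a :class:`ModelParams`, or a raw ``(c, beta, breakpoints)``
    triple so that points outside the support can be queried: any fitness
    value c <= 0 returns -inf (outside the Exp(1) support), not an exception.
    """
    from .dm import model_log_likelihood

    if not isinstance(params, ModelParams):
        c, beta, bps = params
        if np.any(np.asarray(c) <= 0):
            return -np.inf
        params = ModelParams.from_matrices(np.asarray(c), np.asarray(beta), bps)
    c = params.c_matrix()
    if np.any(c <= 0):
        return -np.inf
    beta = params.beta_matrix()
    loglik = model_log_likelihood(table, features, params, plus_one=plus_one)
    return float(loglik - c.sum() + np.sum(-0.5 * beta**2 - _HALF_LOG_2PI))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    draws: np.ndarray  # (chains, draws, 7k) on the natural scale (c, beta)
    param_names: list[str]
    data: ModelData
    config: SamplerConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def flagged(self) -> bool:
        """True when convergence diagnostics failed their gates."""
        return bool(self.diagnostics.get("flagged", False))

    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def c_draws(self) -> np.ndarray:
        """(n_draws_total, k, 4) fitness segment values."""
        k = self.data.k
        return self.flat_draws()[:, : 4 * k].reshape(-1, k, 4)

    def beta_draws(self) -> np.ndarray:
        k = self.data.k
        return self.flat_draws()[:, 4 * k :].reshape(-1, k, 3)


def sample_posterior(table, features, config: SamplerConfig | None = None, plus_one: bool = True, data: ModelData | None = None) -> FitResult:
    """Fit the model by NUTS; reproducible given ``config.seed``.

    Runs ``config.chains`` independent chains from jittered neutral starts
    (c = 1, beta = 0).  Convergence is gated on split-R-hat and bulk ESS;
    a failing run is returned with ``flagged=True``, never silently.
    """
    config = config or SamplerConfig()
    if data is None:
        data = ModelData(table, features, plus_one=plus_one)
    d = data.n_params
    chains = []
    stats = []
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        theta0 = rng.normal(0.0, config.init_jitter, size=d)
        draws_u, st = hmc.nuts(
            data.unconstrained_logpost_grad,
            theta0,
            config.warmup,
            config.draws,
            rng,
            target_accept=config.target_accept,
            max_depth=config.max_depth,
        )
        chains.append(draws_u)
        stats.append(st)
    draws_u = np.stack(chains)  # (chains, draws, d)
    draws = draws_u.copy()
    draws[:, :, : 4 * data.k] = np.exp(draws_u[:, :, : 4 * data.k])
    diagnostics = _diagnose(draws_u, config)
    diagnostics["n_divergent"] = int(sum(s.n_divergent for s in stats))
    diagnostics["step_sizes"] = [s.step_size for s in stats]
    diagnostics["flagged"] = bool(
        diagnostics["max_rhat"] > config.rhat_max
        or diagnostics["min_ess"] < config.ess_min
        or diagnostics["n_divergent"] > 0
    )
    return FitResult(
        draws=draws,
        param_names=data.param_names(),
        data=data,
        config=config,
        diagnostics=diagnostics,
    )


def _diagnose(draws_u: np.ndarray, config: SamplerConfig) -> dict:
    import arviz as az

    ds = az.convert_to_dataset(draws_u)
    rhat = az.rhat(ds)["x"].values
    ess = az.ess(ds)["x"].values
    # split-R-hat is undefined for a single chain
    max_rhat = float(np.nanmax(rhat)) if np.any(np.isfinite(rhat)) else float("nan")
    return {
        "rhat": rhat,
        "ess_bulk": ess,
        "max_rhat": max_rhat,
        "min_ess": float(np.nanmin(ess)),
    }


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Medians, 98% intervals, significance flags, derived trajectories."""

    params: pd.DataFrame  # name, median, q01, q99, rhat, ess, significant
    years: np.ndarray  # transition years (all modelling years but the last)
    mean_fitness: pd.DataFrame  # year, median, q01, q99
    normalized_fitness: pd.DataFrame  # year, move, median, q01, q99
    game_sample_size: pd.DataFrame  # year, median, q01, q99
    plus_one: bool = True

    def significant_betas(self) -> pd.DataFrame:
        mask = self.params.name.str.startswith("beta") & self.params.significant
        return self.params[mask]


def summarize(fit: FitResult, table=None, features=None) -> PosteriorSummary:
    """Posterior medians, 1%/99% quantiles, and derived fitness trajectories.

    Derived quantities (fbar_t, f'_i, N_s) are evaluated per posterior draw
    and then summarized — not computed from summarized parameters.
    """
    data = fit.data
    flat = fit.flat_draws()
    if flat.size == 0:
        raise ValueError("no posterior draws to summarize")
    med = np.median(flat, axis=0)
    q01 = np.quantile(flat, 0.01, axis=0)
    q99 = np.quantile(flat, 0.99, axis=0)
    names = fit.param_names
    signif = np.array(
        [n.startswith("beta") and (lo > 0 or hi < 0) for n, lo, hi in zip(names, q01, q99)]
    )
    params = pd.DataFrame(
        {
            "name": names,
            "median": med,
            "q01": q01,
            "q99": q99,
            "rhat": fit.diagnostics.get("rhat", np.full(len(names), np.nan)),
            "ess": fit.diagnostics.get("ess_bulk", np.full(len(names), np.nan)),
            "significant": signif,
        }
    )

    c_draws = fit.c_draws()  # (nd, k, 4)
    P = data.Xc / data.Nc[:, None]
    years = data.years[data.trans_idx]
    rows_f, rows_fp, rows_ns = [], [], []
    for t in range(P.shape[0]):
        act = c_draws[:, np.arange(data.k), data.seg[t]]  # (nd, k)
        fbar = act @ P[t]
        fprime = act / fbar[:, None]
        ns = fbar * data.Nc[t]
        y = int(years[t])
        rows_f.append(
            {"year": y, "median": float(np.median(fbar)),
             "q01": float(np.quantile(fbar, 0.01)), "q99": float(np.quantile(fbar, 0.99))}
        )
        rows_ns.append(
            {"year": y, "median": float(np.median(ns)),
             "q01": float(np.quantile(ns, 0.01)), "q99": float(np.quantile(ns, 0.99))}
        )
        for i, m in enumerate(data.moves):
            rows_fp.append(
                {"year": y, "move": m, "median": float(np.median(fprime[:, i])),
                 "q01": float(np.quantile(fprime[:, i], 0.01)),
                 "q99": float(np.quantile(fprime[:, i], 0.99))}
            )
    return PosteriorSummary(
        params=params,
        years=years,
        mean_fitness=pd.DataFrame(rows_f),
        normalized_fitness=pd.DataFrame(rows_fp),
        game_sample_size=pd.DataFrame(rows_ns),
        plus_one=data.plus_one,
    )
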