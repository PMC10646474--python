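"""Dirichlet-multinomial model of year-to-year move-choice transmission.

The model treats the yearly counts of the k moves played from a fixed
chess position as an overdispersed Wright–Fisher-like process.  Counts in
year t+1 are Dirichlet-multinomial,

    x_{t+1} ~ DM(N_{t+1}, alpha_t),
    alpha_ti = exp(beta_i . y_ti) * f_i(x_ti / N_t) * x_ti   (+1 optionally),

where f_i is a piecewise-constant frequency-dependent fitness function
(4 segments split at quartiles of the move's observed frequencies) and
beta_i are success/prestige bias coefficients multiplying standardized
covariates y_ti (population win rate, top-50 win rate, top-50 frequency).

With all f_i = 1, beta = 0 and no +1 correction the process reduces to the
neutral model x_{t+1} ~ DM(N_{t+1}, x_t): moves are transmitted in
proportion to their current frequencies, and all dynamics is drift.

The f_i play two roles.  Their relative values f'_i = f_i / fbar_t are
growth rates (f'_i > 1 means expected frequency increase), while the mean
fitness fbar_t = sum_j f_j(p_tj) p_tj sets the overdispersion of next-year
counts: the "game sample size" N_s(t) = fbar_t * N_t is the multinomial-
equivalent number of games players effectively observe, the cultural
analogue of a variance effective population size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


class ContractError(ValueError):
    """An argument violates a model-contract precondition."""


# ---------------------------------------------------------------------------
# Dirichlet-multinomial primitives
# ---------------------------------------------------------------------------


def _check_counts(y, n, alpha):
    y = np.asarray(y, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if y.shape != alpha.shape:
        raise ContractError(f"length mismatch: counts {y.shape} vs alpha {alpha.shape}")
    if np.any(y < 0):
        raise ContractError("counts must be non-negative")
    if not np.isclose(y.sum(), n):
        raise ContractError(f"counts sum to {y.sum()}, expected n={n}")
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ContractError("alpha must be strictly positive and finite")
    return y, alpha


def dm_log_pmf(y, n, alpha) -> float:
    """Log-probability of counts ``y`` (summing to ``n``) under DM(n, alpha).

    Computed entirely with log-gamma so large counts never overflow.
    """
    y, alpha = _check_counts(y, n, alpha)
    a0 = alpha.sum()
    return float(
        gammaln(n + 1)
        - gammaln(y + 1).sum()
        + gammaln(a0)
        - gammaln(n + a0)
        + (gammaln(y + alpha) - gammaln(alpha)).sum()
    )


def dm_expectation(n, alpha) -> np.ndarray:
    """E[y] = n * alpha / sum(alpha) for y ~ DM(n, alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ContractError("alpha must be strictly positive")
    return n * alpha / alpha.sum()


def dm_variance(n_next, n_curr, p, mean_fitness) -> np.ndarray:
    """Variance of next-year counts given bias-free frequencies ``p``.

    Var[x_{t+1,i}] = N_{t+1} p_i (1-p_i) (N_{t+1} + N_t fbar) / (1 + N_t fbar).
    The last factor is the overdispersion relative to multinomial sampling:
    it tends to 1 as fbar grows and to N_{t+1} as N_t fbar -> 0.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ContractError("p must be a probability vector")
    if mean_fitness <= 0:
        raise ContractError("mean fitness must be positive")
    a0 = n_curr * mean_fitness
    return n_next * p * (1.0 - p) * (n_next + a0) / (1.0 + a0)


def dm_sample(rng, n, alpha, size=None) -> np.ndarray:
    """Two-stage draw: theta ~ Dirichlet(alpha), y ~ Multinomial(n, theta)."""
    alpha = np.asarray(alpha, dtype=float)
    if size is None:
        theta = rng.dirichlet(alpha)
        return rng.multinomial(n, theta)
    theta = rng.dirichlet(alpha, size=size)
    return np.vstack([rng.multinomial(n, th) for th in theta])


# ---------------------------------------------------------------------------
# Piecewise-constant frequency-dependent fitness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseFitness:
    """A 4-segment step function on [0, 1].

    Segments are [0, b1), [b1, b2), [b2, b3), [b3, 1] — left-closed,
    right-open, with the last segment closed at 1.  Breakpoints are fixed
    data-derived constants (frequency quartiles), not estimated.
    """

    breakpoints: tuple[float, float, float]
    values: tuple[float, float, float, float]

    def __post_init__(self):
        b = np.asarray(self.breakpoints, dtype=float)
        c = np.asarray(self.values, dtype=float)
        if b.shape != (3,) or not np.all(np.diff(b) > 0) or b[0] <= 0 or b[-1] >= 1:
            raise ContractError("breakpoints must be 3 strictly increasing values in (0,1)")
        if c.shape != (4,) or np.any(c <= 0):
            raise ContractError("segment values must be 4 strictly positive reals")

    def __call__(self, x):
        return piecewise_eval(self, x)


def piecewise_eval(f: PiecewiseFitness, x):
    """Evaluate the step function; scalar in, scalar out."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > 1):
        raise ContractError("frequency must lie in [0, 1]")
    idx = np.searchsorted(np.asarray(f.breakpoints), xa, side="right")
    out = np.asarray(f.values, dtype=float)[idx]
    return float(out) if np.isscalar(x) or xa.ndim == 0 else out


def quartile_breakpoints(freqs, interpolation: str = "linear") -> tuple[float, float, float]:
    """25/50/75% empirical quantiles of a move's yearly frequency series.

    These become the fixed breakpoints of its fitness function, so each
    constant segment is estimated from the same number of year-transitions.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size < 4:
        raise ContractError("need at least 4 observed years to place quartiles")
    b = np.quantile(freqs, [0.25, 0.5, 0.75], method=interpolation)
    if not np.all(np.diff(b) > 0):
        raise ContractError(
            "frequency quartiles coincide (series too concentrated); "
            "supply breakpoints manually or pool years"
        )
    return (float(b[0]), float(b[1]), float(b[2]))


# ---------------------------------------------------------------------------
# Full parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasCoefficients:
    """Multiplicative transmission-bias coefficients on the standardized scale."""

    beta_win: float = 0.0
    beta_top50_win: float = 0.0
    beta_top50_freq: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.beta_win, self.beta_top50_win, self.beta_top50_freq])


@dataclass(frozen=True)
class ModelParams:
    """Per-move fitness functions and bias coefficients; 7k free parameters."""

    fitness: tuple[PiecewiseFitness, ...]
    biases: tuple[BiasCoefficients, ...]

    def __post_init__(self):
        if len(self.fitness) != len(self.biases):
            raise ContractError("one fitness function and one bias triple per move")

    @property
    def k(self) -> int:
        return len(self.fitness)

    def c_matrix(self) -> np.ndarray:
        """(k, 4) array of segment values."""
        return np.array([f.values for f in self.fitness])

    def beta_matrix(self) -> np.ndarray:
        """(k, 3) array of bias coefficients."""
        return np.array([b.as_array() for b in self.biases])

    def breakpoint_matrix(self) -> np.ndarray:
        """(k, 3) array of fixed breakpoints."""
        return np.array([f.breakpoints for f in self.fitness])

    @staticmethod
    def neutral(k: int, breakpoints=None) -> "ModelParams":
        """All fitness values 1, all biases 0 (drift only)."""
        if breakpoints is None:
            breakpoints = [(0.25, 0.5, 0.75)] * k
        return ModelParams(
            fitness=tuple(PiecewiseFitness(tuple(b), (1.0, 1.0, 1.0, 1.0)) for b in breakpoints),
            biases=tuple(BiasCoefficients() for _ in range(k)),
        )

    @staticmethod
    def from_matrices(c, beta, breakpoints) -> "ModelParams":
        c = np.asarray(c, dtype=float)
        beta = np.asarray(beta, dtype=float)
        return ModelParams(
            fitness=tuple(
                PiecewiseFitness(tuple(np.asarray(b, dtype=float)), tuple(ci))
                for ci, b in zip(c, breakpoints)
            ),
            biases=tuple(BiasCoefficients(*row) for row in beta),
        )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def mean_fitness(params: ModelParams, p) -> float:
    """fbar = sum_j f_j(p_j) p_j, the frequency-weighted mean fitness."""
    p = np.asarray(p, dtype=float)
    if p.shape != (params.k,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ContractError("p must be a length-k probability vector")
    return float(sum(piecewise_eval(f, pi) * pi for f, pi in zip(params.fitness, p)))


def normalized_fitness(params: ModelParams, p) -> np.ndarray:
    """Growth rates f'_i = f_i(p_i) / fbar; f'_i = 1 means no expected change."""
    p = np.asarray(p, dtype=float)
    fbar = mean_fitness(params, p)
    return np.array([piecewise_eval(f, pi) for f, pi in zip(params.fitness, p)]) / fbar


def game_sample_size(mean_fitness_t: float, n_t) -> float:
    """N_s(t) = fbar_t * N_t, the multinomial-equivalent observation count."""
    if mean_fitness_t <= 0:
        raise ContractError("mean fitness must be positive")
    if n_t < 0:
        raise ContractError("N_t must be non-negative")
    return float(mean_fitness_t * n_t)


def build_alpha(x_t, n_t, y_t, params: ModelParams, plus_one: bool = True) -> np.ndarray:
    """Dirichlet allocation vector for the transition out of year t.

    alpha_i = exp(beta_i . y_ti) * f_i(x_ti / N_t) * x_ti, plus 1 when
    ``plus_one`` so that zero-count moves keep positive transmission
    probability.  The fitness argument is the raw (uncorrected) frequency.
    """
    x_t = np.asarray(x_t, dtype=float)
    if np.any(x_t < 0):
        raise ContractError("counts must be non-negative")
    if n_t <= 0:
        raise ContractError("N_t must be positive for a transition")
    if not np.isclose(x_t.sum(), n_t):
        raise ContractError("counts must sum to N_t")
    y_t = np.asarray(y_t, dtype=float)
    if y_t.shape != (params.k, 3) or not np.all(np.isfinite(y_t)):
        raise ContractError("y_t must be a finite (k, 3) covariate array")
    freq = x_t / n_t
    fvals = np.array([piecewise_eval(f, q) for f, q in zip(params.fitness, freq)])
    expfac = np.exp(np.sum(params.beta_matrix() * y_t, axis=1))
    alpha = expfac * fvals * x_t
    if plus_one:
        alpha = alpha + 1.0
    return alpha


def model_log_likelihood(table, features, params: ModelParams, plus_one: bool = True) -> float:
    """Sum of DM transition log-probabilities over consecutive year pairs.

    Year t's counts and covariates parameterize the distribution of year
    t+1's counts; the final year appears only as an outcome.  Transitions
    through a year with zero games are dropped with a warning.
    """
    import warnings

    counts = np.asarray(table.counts, dtype=float)
    totals = np.asarray(table.totals, dtype=float)
    if counts.shape[0] < 2:
        raise ContractError("need at least 2 modelling years for a transition")
    y = features.standardized  # (T, k, 3)
    total = 0.0
    for t in range(counts.shape[0] - 1):
        if totals[t] == 0 or totals[t + 1] == 0:
            warnings.warn(f"zero-game year at transition {t}; dropped", stacklevel=2)
            continue
        alpha = build_alpha(counts[t], totals[t], y[t], params, plus_one=plus_one)
        total += dm_log_pmf(counts[t + 1], totals[t + 1], alpha)
    return total
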