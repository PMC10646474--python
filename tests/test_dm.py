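"""Oracle tests for the Dirichlet-multinomial core.

Brute-force enumeration and two-stage sampling serve as independent
references for the closed-form pmf, moments, and the alpha construction.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from openingdrift.dm import (
    BiasCoefficients,
    ContractError,
    ModelParams,
    PiecewiseFitness,
    build_alpha,
    dm_expectation,
    dm_log_pmf,
    dm_sample,
    dm_variance,
    game_sample_size,
    mean_fitness,
    model_log_likelihood,
    normalized_fitness,
    piecewise_eval,
    quartile_breakpoints,
)


def compositions(n, k):
    """All non-negative integer k-vectors summing to n (enumeration oracle)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in compositions(n - first, k - 1):
            yield (first,) + rest


# ---------------------------------------------------------------------------
# pmf
# ---------------------------------------------------------------------------


def test_pmf_normalizes_over_all_compositions(rng):
    for _ in range(20):
        n = int(rng.integers(1, 7))
        k = int(rng.integers(2, 5))
        alpha = rng.gamma(1.0, 2.0, size=k) + 0.05
        total = sum(
            math.exp(dm_log_pmf(np.array(y), n, alpha)) for y in compositions(n, k)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


def test_uniform_predictive_closed_form():
    # alpha = (1, 1): the predictive is uniform over the n+1 compositions
    for n in (1, 2, 5, 20):
        for y0 in (0, n // 2, n):
            lp = dm_log_pmf(np.array([y0, n - y0]), n, np.array([1.0, 1.0]))
            assert lp == pytest.approx(math.log(1.0 / (n + 1)), abs=1e-12)


def test_pmf_matches_numerical_integration_of_two_stage_density():
    # integrate Multinomial(y; n, (t, 1-t)) * Beta(t; a1, a2) dt numerically
    y, n, alpha = np.array([2, 1]), 3, np.array([0.7, 1.9])

    def integrand(t):
        binom = math.comb(n, int(y[0])) * t ** y[0] * (1 - t) ** y[1]
        beta = (
            t ** (alpha[0] - 1)
            * (1 - t) ** (alpha[1] - 1)
            / math.exp(gammaln(alpha[0]) + gammaln(alpha[1]) - gammaln(alpha.sum()))
        )
        return binom * beta

    expected, _ = integrate.quad(integrand, 0, 1)
    assert math.exp(dm_log_pmf(y, n, alpha)) == pytest.approx(expected, rel=1e-9)


def test_pmf_degenerate_single_category():
    assert dm_log_pmf(np.array([7]), 7, np.array([2.3])) == pytest.approx(0.0, abs=1e-12)


def test_pmf_contract_errors():
    with pytest.raises(ContractError):
        dm_log_pmf(np.array([1, 1]), 3, np.array([1.0, 1.0]))  # sum != n
    with pytest.raises(ContractError):
        dm_log_pmf(np.array([1, 2]), 3, np.array([1.0, -1.0]))  # alpha <= 0
    with pytest.raises(ContractError):
        dm_log_pmf(np.array([1, 2]), 3, np.array([1.0]))  # length mismatch


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def test_expectation_closed_form_and_null_transmission():
    assert np.allclose(dm_expectation(10, np.array([1.0, 3.0])), [2.5, 7.5])
    # neutral transmission scales counts by N_{t+1}/N_t
    assert np.allclose(dm_expectation(200, np.array([60.0, 40.0])), [120.0, 80.0])


def test_moments_match_two_stage_sampler(rng):
    n, alpha = 50, np.array([2.0, 3.0, 5.0])
    draws = dm_sample(rng, n, alpha, size=100_000)
    expect = dm_expectation(n, alpha)
    # DM variance: n p (1-p) (n + a0) / (1 + a0)
    a0 = alpha.sum()
    p = alpha / a0
    var = n * p * (1 - p) * (n + a0) / (1 + a0)
    m = draws.shape[0]
    se_mean = draws.std(axis=0, ddof=1) / math.sqrt(m)
    assert np.all(np.abs(draws.mean(axis=0) - expect) < 3 * se_mean)
    # SE of the sample variance from the empirical fourth central moment
    centered = draws - draws.mean(axis=0)
    m4 = (centered**4).mean(axis=0)
    se_var = np.sqrt((m4 - var**2) / m)
    assert np.all(np.abs(draws.var(axis=0, ddof=1) - var) < 3 * se_var)


def test_variance_formula_limits():
    p = np.array([0.3, 0.7])
    # huge mean fitness: multinomial limit n p (1-p)
    v = dm_variance(100, 1000, p, 1e9)
    assert np.allclose(v, 100 * p * (1 - p), rtol=1e-5)
    # vanishing N_t * fbar: maximal overdispersion n^2 p (1-p)
    v0 = dm_variance(100, 1000, p, 1e-12)
    assert np.allclose(v0, 100**2 * p * (1 - p), rtol=1e-6)


def test_variance_identity_with_game_sample_size(rng):
    # substituting N_s = fbar * N into the variance reproduces it exactly
    for _ in range(25):
        n_next = float(rng.integers(10, 10_000))
        n_curr = float(rng.integers(10, 10_000))
        fbar = float(rng.uniform(0.05, 3.0))
        p = rng.dirichlet(np.ones(3))
        ns = game_sample_size(fbar, n_curr)
        direct = dm_variance(n_next, n_curr, p, fbar)
        via_ns = n_next * p * (1 - p) * (n_next + ns) / (1 + ns)
        assert np.allclose(direct, via_ns)
    assert game_sample_size(0.5, 1000) == 500.0
    assert game_sample_size(1.0, 777) == 777.0


# ---------------------------------------------------------------------------
# piecewise fitness
# ---------------------------------------------------------------------------


def test_piecewise_interval_conventions():
    f = PiecewiseFitness((0.25, 0.5, 0.75), (2.0, 1.0, 1.0, 0.5))
    assert piecewise_eval(f, 0.1) == 2.0
    assert piecewise_eval(f, 0.25) == 1.0  # boundary belongs to the right segment
    assert piecewise_eval(f, 0.0) == 2.0
    assert piecewise_eval(f, 1.0) == 0.5  # last segment closed at 1
    with pytest.raises(ContractError):
        piecewise_eval(f, 1.2)


def test_piecewise_validation():
    with pytest.raises(ContractError):
        PiecewiseFitness((0.5, 0.5, 0.75), (1, 1, 1, 1))
    with pytest.raises(ContractError):
        PiecewiseFitness((0.25, 0.5, 0.75), (1, 1, -1, 1))


def test_quartile_breakpoints_linear_interpolation():
    assert quartile_breakpoints([0.1, 0.2, 0.3, 0.4]) == pytest.approx(
        (0.175, 0.25, 0.325)
    )
    with pytest.raises(ContractError):
        quartile_breakpoints([0.3, 0.3, 0.3, 0.3])
    with pytest.raises(ContractError):
        quartile_breakpoints([0.1, 0.2])


def test_quartile_breakpoints_inside_range(rng):
    for _ in range(20):
        series = rng.uniform(0.05, 0.95, size=12)
        b = quartile_breakpoints(series)
        assert series.min() < b[0] < b[1] < b[2] < series.max()


# ---------------------------------------------------------------------------
# fitness summaries
# ---------------------------------------------------------------------------


def _two_move_params():
    return ModelParams(
        fitness=(
            PiecewiseFitness((0.25, 0.5, 0.75), (2.0, 2.0, 2.0, 2.0)),
            PiecewiseFitness((0.25, 0.5, 0.75), (1.0, 1.0, 1.0, 1.0)),
        ),
        biases=(BiasCoefficients(), BiasCoefficients()),
    )


def test_mean_and_normalized_fitness_arithmetic():
    params = _two_move_params()
    p = np.array([0.5, 0.5])
    assert mean_fitness(params, p) == pytest.approx(1.5)
    assert np.allclose(normalized_fitness(params, p), [4 / 3, 2 / 3])
    neutral = ModelParams.neutral(3)
    pn = np.array([0.2, 0.3, 0.5])
    assert mean_fitness(neutral, pn) == pytest.approx(1.0)
    assert np.allclose(normalized_fitness(neutral, pn), 1.0)


def test_normalized_fitness_weighted_sum_is_one(rng):
    for _ in range(20):
        k = int(rng.integers(2, 6))
        c = rng.gamma(2.0, 1.0, size=(k, 4)) + 0.05
        params = ModelParams.from_matrices(c, np.zeros((k, 3)), [(0.25, 0.5, 0.75)] * k)
        p = rng.dirichlet(np.ones(k))
        assert np.dot(normalized_fitness(params, p), p) == pytest.approx(1.0)


def test_mean_fitness_invariant_to_move_reordering(rng):
    c = rng.gamma(2.0, 1.0, size=(3, 4)) + 0.05
    params = ModelParams.from_matrices(c, np.zeros((3, 3)), [(0.25, 0.5, 0.75)] * 3)
    p = np.array([0.2, 0.3, 0.5])
    perm = [2, 0, 1]
    params_p = ModelParams.from_matrices(c[perm], np.zeros((3, 3)), [(0.25, 0.5, 0.75)] * 3)
    assert mean_fitness(params, p) == pytest.approx(mean_fitness(params_p, p[perm]))


def test_scale_splitting_identity(rng):
    # c -> gamma * c leaves f' unchanged and scales fbar and N_s by gamma
    c = rng.gamma(2.0, 1.0, size=(4, 4)) + 0.05
    params = ModelParams.from_matrices(c, np.zeros((4, 3)), [(0.25, 0.5, 0.75)] * 4)
    gamma = 3.7
    scaled = ModelParams.from_matrices(gamma * c, np.zeros((4, 3)), [(0.25, 0.5, 0.75)] * 4)
    p = rng.dirichlet(np.ones(4))
    assert np.allclose(normalized_fitness(params, p), normalized_fitness(scaled, p))
    assert mean_fitness(scaled, p) == pytest.approx(gamma * mean_fitness(params, p))
    n_t = 1234.0
    assert game_sample_size(mean_fitness(scaled, p), n_t) == pytest.approx(
        gamma * game_sample_size(mean_fitness(params, p), n_t)
    )


# ---------------------------------------------------------------------------
# alpha construction and likelihood
# ---------------------------------------------------------------------------


def test_build_alpha_reduces_to_null_model():
    params = ModelParams.neutral(2)
    x = np.array([30.0, 70.0])
    y = np.zeros((2, 3))
    assert np.allclose(build_alpha(x, 100, y, params, plus_one=False), x)
    assert np.allclose(build_alpha(np.array([0.0, 5.0]), 5, y, params, plus_one=True), [1.0, 6.0])


def test_plus_one_biases_expectation_toward_pseudocounts():
    params = ModelParams.neutral(3)
    x = np.array([10.0, 30.0, 60.0])
    alpha = build_alpha(x, 100, np.zeros((3, 3)), params, plus_one=True)
    expect = dm_expectation(100, alpha)
    assert np.allclose(expect / 100, (x + 1) / (100 + 3))


def test_build_alpha_bias_factor_is_exponential():
    params = ModelParams.from_matrices(
        np.ones((2, 4)), np.array([[0.5, 0.0, 0.0], [0.0, 0.0, 0.0]]), [(0.25, 0.5, 0.75)] * 2
    )
    y = np.zeros((2, 3))
    y[0, 0] = 2.0
    alpha = build_alpha(np.array([10.0, 10.0]), 20, y, params, plus_one=False)
    assert alpha[0] == pytest.approx(10.0 * math.exp(1.0))
    assert alpha[1] == pytest.approx(10.0)


def test_full_model_equals_null_on_neutral_params(rng):
    # with f=1, beta=0, plus_one=False the transition law is exactly DM(N, x_t)
    for _ in range(100):
        k = int(rng.integers(2, 5))
        x_t = rng.integers(1, 50, size=k).astype(float)
        n_next = int(rng.integers(5, 60))
        x_next = rng.multinomial(n_next, rng.dirichlet(np.ones(k))).astype(float)
        params = ModelParams.neutral(k)
        alpha = build_alpha(x_t, x_t.sum(), np.zeros((k, 3)), params, plus_one=False)
        assert dm_log_pmf(x_next, n_next, alpha) == pytest.approx(
            dm_log_pmf(x_next, n_next, x_t), abs=1e-12
        )


def test_model_log_likelihood_transitions_and_permutation(rng):
    from openingdrift.synthetic import SimulationConfig, simulate_trajectory

    ds = simulate_trajectory(SimulationConfig(k=3, years=6, n_per_year=200, seed=1))
    params = ModelParams.neutral(3)
    ll = model_log_likelihood(ds.table, ds.features, params)
    # permuting move labels jointly leaves the likelihood unchanged
    perm = [2, 0, 1]
    table = ds.table
    feats = ds.features
    table_p = type(table)(
        years=table.years,
        moves=[table.moves[i] for i in perm],
        counts=table.counts[:, perm],
        totals=table.totals,
    )
    feats_p = type(feats)(
        years=feats.years,
        moves=[feats.moves[i] for i in perm],
        win_rate=feats.win_rate[:, perm],
        top50_win_rate=feats.top50_win_rate[:, perm],
        top50_freq=feats.top50_freq[:, perm],
        standardized=feats.standardized[:, perm, :],
    )
    assert model_log_likelihood(table_p, feats_p, params) == pytest.approx(ll)


def test_two_years_give_single_transition_term():
    from openingdrift.synthetic import SimulationConfig, simulate_trajectory

    ds = simulate_trajectory(SimulationConfig(k=2, years=2, n_per_year=100, seed=3))
    params = ModelParams.neutral(2)
    ll = model_log_likelihood(ds.table, ds.features, params)
    alpha = build_alpha(
        ds.table.counts[0].astype(float),
        ds.table.totals[0],
        ds.features.standardized[0],
        params,
    )
    assert ll == pytest.approx(dm_log_pmf(ds.table.counts[1], ds.table.totals[1], alpha))


def test_neutral_likelihood_beats_selective_on_null_data(rng):
    from openingdrift.synthetic import SimulationConfig, simulate_trajectory

    neutral = ModelParams.neutral(3)
    strong = ModelParams.from_matrices(
        np.tile([5.0, 2.0, 0.3, 0.05], (3, 1)), np.zeros((3, 3)), [(0.25, 0.5, 0.75)] * 3
    )
    wins = 0
    n_rep = 20
    for rep in range(n_rep):
        ds = simulate_trajectory(SimulationConfig(k=3, years=10, n_per_year=500, seed=100 + rep))
        if model_log_likelihood(ds.table, ds.features, neutral) > model_log_likelihood(
            ds.table, ds.features, strong
        ):
            wins += 1
    assert wins > n_rep / 2
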