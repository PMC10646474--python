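"""Rare-move pooling, covariate construction, standardization, year windows."""

import numpy as np
import pandas as pd
import pytest

from openingdrift.features import (
    OTHER_LABEL,
    FeatureTable,
    aggregate_rare,
    compute_features,
    restrict_years,
    standardize,
)
from openingdrift.ingest import YearlyCountTable


def _table(counts, years=None, moves=None):
    counts = np.asarray(counts)
    years = np.asarray(years if years is not None else np.arange(2000, 2000 + len(counts)))
    moves = moves or [f"m{i}" for i in range(counts.shape[1])]
    return YearlyCountTable(
        years=years, moves=moves, counts=counts, totals=counts.sum(axis=1)
    )


# -- aggregation -------------------------------------------------------------


def test_aggregate_rare_pools_below_threshold():
    # avg freqs: b = (3% + 0%)/2 = 1.5%, c = (0% + 2%)/2 = 1% (rare);
    # d = (3% + 1%)/2 = 2% sits exactly at the threshold and is kept
    t = _table([[94, 3, 0, 3], [97, 0, 2, 1]], moves=["a", "b", "c", "d"])
    out, _ = aggregate_rare(t, threshold=0.02)
    assert out.moves == ["a", "d", OTHER_LABEL]
    i = out.moves.index(OTHER_LABEL)
    # pooled counts are the yearly sums of the rare columns: (3,0) + (0,2)
    assert out.counts[:, i].tolist() == [3, 2]
    assert np.array_equal(out.totals, t.totals)  # conservation


def test_aggregate_rare_no_op_and_all_rare_error():
    t = _table([[50, 50], [40, 60]])
    out, _ = aggregate_rare(t, threshold=0.02)
    assert out.moves == t.moves
    tiny = _table([[1, 1], [1, 1]])
    # both moves at 50% are not rare; force the error with a silly threshold
    with pytest.raises(ValueError):
        aggregate_rare(tiny, threshold=0.9)


def test_aggregate_pools_outcome_tallies():
    t = _table([[90, 6, 4]], moves=["a", "b", "c"])
    tallies = pd.DataFrame(
        [
            {"year": 2000, "move": "a", "games": 90, "wins": 40, "losses": 30, "draws": 20,
             "top50_games": 0, "top50_wins": 0, "top50_losses": 0, "top50_draws": 0},
            {"year": 2000, "move": "b", "games": 6, "wins": 3, "losses": 1, "draws": 2,
             "top50_games": 0, "top50_wins": 0, "top50_losses": 0, "top50_draws": 0},
            {"year": 2000, "move": "c", "games": 4, "wins": 0, "losses": 2, "draws": 2,
             "top50_games": 0, "top50_wins": 0, "top50_losses": 0, "top50_draws": 0},
        ]
    )
    out, pooled = aggregate_rare(t, tallies, threshold=0.07)
    other = pooled[pooled.move == OTHER_LABEL].iloc[0]
    assert (other.games, other.wins, other.losses, other.draws) == (10, 3, 3, 4)
    # pooled win rate equals the pooled (wins - losses) / games of constituents
    ft = compute_features(out, pooled)
    i = out.moves.index(OTHER_LABEL)
    assert ft.win_rate[0, i] == pytest.approx((3 - 3) / 10)


# -- covariates --------------------------------------------------------------


def _tally_row(year, move, games, wins, losses, draws, t50=(0, 0, 0, 0)):
    return {
        "year": year, "move": move, "games": games, "wins": wins,
        "losses": losses, "draws": draws, "top50_games": t50[0],
        "top50_wins": t50[1], "top50_losses": t50[2], "top50_draws": t50[3],
    }


def test_win_rate_encoding():
    t = _table([[10, 5]], moves=["a", "b"])
    tallies = pd.DataFrame(
        [
            _tally_row(2000, "a", 10, 6, 2, 2),  # (6-2)/10 = 0.4
            _tally_row(2000, "b", 5, 0, 0, 5),  # all draws -> 0
        ]
    )
    ft = compute_features(t, tallies)
    assert ft.win_rate[0, 0] == pytest.approx(0.4)
    assert ft.win_rate[0, 1] == 0.0


def test_top50_features_and_zero_top50_convention():
    t = _table([[10, 10], [10, 10]], moves=["a", "b"])
    tallies = pd.DataFrame(
        [
            _tally_row(2000, "a", 10, 5, 5, 0, t50=(4, 3, 1, 0)),
            _tally_row(2000, "b", 10, 5, 5, 0, t50=(1, 0, 1, 0)),
            _tally_row(2001, "a", 10, 5, 5, 0),  # no top-50 games at all
            _tally_row(2001, "b", 10, 5, 5, 0),
        ]
    )
    ft = compute_features(t, tallies)
    assert ft.top50_win_rate[0, 0] == pytest.approx((3 - 1) / 4)
    assert ft.top50_freq[0, 0] == pytest.approx(4 / 5)
    assert ft.top50_freq[1, 0] == 0.0  # neutral fill, flagged upstream


# -- standardization ---------------------------------------------------------


def test_standardize_zero_mean_unit_variance():
    rng = np.random.default_rng(0)
    ft = FeatureTable(
        years=np.arange(2000, 2010),
        moves=["a", "b"],
        win_rate=rng.uniform(-0.5, 0.5, (10, 2)),
        top50_win_rate=rng.uniform(-0.5, 0.5, (10, 2)),
        top50_freq=rng.uniform(0, 1, (10, 2)),
    )
    standardize(ft)
    z = ft.standardized
    assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
    assert np.allclose(z.std(axis=0), 1.0)


def test_standardize_constant_series_flagged_as_zero():
    ft = FeatureTable(
        years=np.arange(2000, 2004),
        moves=["a"],
        win_rate=np.full((4, 1), 0.25),
        top50_win_rate=np.linspace(-0.2, 0.2, 4).reshape(4, 1),
        top50_freq=np.linspace(0.1, 0.4, 4).reshape(4, 1),
    )
    standardize(ft)
    assert np.all(ft.standardized[:, 0, 0] == 0.0)
    assert ("a", "win_rate") in ft.flags["constant_series"]


def test_standardize_idempotent_up_to_tolerance():
    rng = np.random.default_rng(1)
    ft = FeatureTable(
        years=np.arange(2000, 2008),
        moves=["a"],
        win_rate=rng.uniform(-0.5, 0.5, (8, 1)),
        top50_win_rate=rng.uniform(-0.5, 0.5, (8, 1)),
        top50_freq=rng.uniform(0, 1, (8, 1)),
    )
    z1 = standardize(ft).standardized.copy()
    # re-running is deterministic, and z-scoring a z-scored series is identity
    assert np.array_equal(standardize(ft).standardized, z1)
    rezscored = (z1 - z1.mean(axis=0)) / z1.std(axis=0)
    assert np.allclose(rezscored, z1, atol=1e-12)


# -- year restriction --------------------------------------------------------


def test_restrict_years_window_and_restandardization():
    rng = np.random.default_rng(2)
    T = 49
    counts = rng.integers(1, 100, (T, 2))
    t = _table(counts, years=np.arange(1971, 2020))
    ft = FeatureTable(
        years=t.years, moves=["m0", "m1"],
        win_rate=rng.uniform(-0.5, 0.5, (T, 2)),
        top50_win_rate=rng.uniform(-0.5, 0.5, (T, 2)),
        top50_freq=rng.uniform(0, 1, (T, 2)),
    )
    standardize(ft)
    t2, ft2 = restrict_years(t, ft, 1980, 2019)
    assert len(t2.years) == 40 and t2.years[0] == 1980 and t2.years[-1] == 2019
    # standardization is recomputed over the modelling window only
    assert np.all(np.abs(ft2.standardized.mean(axis=0)) < 1e-12)


def test_restrict_years_errors():
    t = _table([[10, 10], [10, 10]], years=[2000, 2001])
    with pytest.raises(ValueError):
        restrict_years(t, None, 2010, 2000)
    with pytest.raises(ValueError):
        restrict_years(t, None, 1900, 1950)
    single, _ = restrict_years(t, None, 2001, 2001)
    assert len(single.years) == 1  # usable downstream only as an error case
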