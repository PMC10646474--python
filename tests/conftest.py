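import numpy as np
import pytest

from openingdrift.dm import BiasCoefficients, ModelParams, PiecewiseFitness


@pytest.fixture
def fixture_games():
    """Hand-countable games: two 1.d4 starts, one 1.e4 start, a transposition
    into the open Sicilian, and metadata edge cases for the filters."""
    return [
        {"plys": ["d4", "d5", "c4"], "result": "1-0", "white_elo": 2500,
         "black_elo": 2400, "year": 1995, "white_name": "Alpha", "black_name": "Beta"},
        {"plys": ["d4", "Nf6", "c4"], "result": "1/2-1/2", "white_elo": 2600,
         "black_elo": 2650, "year": 1995, "white_name": "Gamma", "black_name": "Alpha"},
        {"plys": ["e4", "c5", "Nf3", "d6"], "result": "0-1", "white_elo": 2450,
         "black_elo": 2700, "year": 1996, "white_name": "Beta", "black_name": "Delta"},
        # transposition: reaches the position after 1. e4 c5 2. Nf3 via 1. Nf3 c5 2. e4
        {"plys": ["Nf3", "c5", "e4", "d6"], "result": "1-0", "white_elo": 2480,
         "black_elo": 2520, "year": 1996, "white_name": "Delta", "black_name": "Gamma"},
    ]


@pytest.fixture
def selective_params():
    """k=4: one move with declining step fitness and a success bias, rest neutral."""
    k = 4
    fitness = [PiecewiseFitness((0.25, 0.5, 0.75), (1.0,) * 4) for _ in range(k)]
    fitness[0] = PiecewiseFitness((0.25, 0.5, 0.75), (1.6, 1.2, 0.9, 0.7))
    biases = [BiasCoefficients() for _ in range(k)]
    biases[0] = BiasCoefficients(beta_win=0.5)
    return ModelParams(fitness=tuple(fitness), biases=tuple(biases))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
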