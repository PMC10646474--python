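"""From raw games to yearly move-count tables.

Pipeline: parse PGN -> filter (legality, metadata completeness, Elo floor,
year window) -> tabulate, per calendar year, how often each response move
was played from a fixed focal position, together with outcome tallies and
the same tallies restricted to games in which the mover is one of that
year's top-50 players by mean Elo.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _chess, pgn

log = logging.getLogger(__name__)

DEFAULT_MIN_ELO = 2000
DEFAULT_YEAR_RANGE = (1971, 2019)

_RESULT_MAP = {"1-0": "white_win", "0-1": "black_win", "1/2-1/2": "draw"}


@dataclass(frozen=True)
class GameRecord:
    """One validated game."""

    white_name: str
    black_name: str
    white_elo: int
    black_elo: int
    year: int
    result: str  # "white_win" | "black_win" | "draw"
    plys: tuple[str, ...]  # canonical SAN


@dataclass(frozen=True)
class PositionSpec:
    """The focal position: a SAN prefix; responses at ply depth len+1.

    ``match_mode="board_state"`` (default) counts every game that reaches
    the same board state — placement, side to move, castling and usable
    en-passant rights — regardless of move order, so transpositions are
    included.  ``"prefix"`` requires the exact move order.
    """

    ply_prefix: tuple[str, ...]
    match_mode: str = "board_state"

    def __post_init__(self):
        if self.match_mode not in ("prefix", "board_state"):
            raise ValueError("match_mode must be 'prefix' or 'board_state'")
        _chess.replay(list(self.ply_prefix))  # raises if illegal

    @property
    def depth(self) -> int:
        return len(self.ply_prefix) + 1

    @property
    def mover_color(self) -> str:
        """Side making the response move at the focal position."""
        return _chess.WHITE if len(self.ply_prefix) % 2 == 0 else _chess.BLACK

    def canonical_prefix(self) -> tuple[str, ...]:
        return tuple(_chess.canonicalize(list(self.ply_prefix)))

    def position_key(self) -> str:
        return _chess.replay(list(self.ply_prefix)).position_key()


@dataclass
class YearlyCountTable:
    """Counts x_ti of k response moves per year, with totals N_t."""

    years: np.ndarray  # (T,) strictly increasing ints
    moves: list[str]  # k unique labels
    counts: np.ndarray  # (T, k) non-negative ints
    totals: np.ndarray  # (T,)
    position: PositionSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts)
        self.totals = np.asarray(self.totals)
        if len(self.moves) != len(set(self.moves)):
            raise ValueError("move labels must be unique")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.counts.shape != (self.years.size, len(self.moves)):
            raise ValueError("counts shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.counts.sum(axis=1), self.totals):
            raise ValueError("row sums of counts must equal totals")

    @property
    def k(self) -> int:
        return len(self.moves)

    def frequencies(self) -> np.ndarray:
        """x_ti / N_t with zero-game years giving zero rows."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.counts / self.totals[:, None]
        return np.nan_to_num(f)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": int(y), "move": m, "count": int(self.counts[t, i]), "total": int(self.totals[t])}
            for t, y in enumerate(self.years)
            for i, m in enumerate(self.moves)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parse + filter
# ---------------------------------------------------------------------------


def parse_pgn(stream) -> tuple[list[pgn.RawGame], pgn.ParseReport]:
    """Read a PGN stream; malformed games are skipped and counted."""
    return pgn.read_pgn(stream)


def _year_of(tags: dict) -> int | None:
    date = tags.get("Date", "")
    m = re.match(r"^(\d{4})", date)
    return int(m.group(1)) if m else None


def filter_games(
    raw_games,
    min_elo: int = DEFAULT_MIN_ELO,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> tuple[list[GameRecord], dict]:
    """Apply the dataset filters; returns records plus per-criterion drop counts.

    A game survives only if its movetext replays legally from the starting
    position, it has a decisive-or-draw result, both player names, both
    Elos at or above ``min_elo``, and a year inside ``year_range``.
    """
    lo, hi = year_range
    drops = {
        "no_result": 0,
        "missing_names": 0,
        "missing_elo": 0,
        "low_elo": 0,
        "bad_year": 0,
        "illegal_moves": 0,
    }
    kept: list[GameRecord] = []
    for g in raw_games:
        result = _RESULT_MAP.get(g.result_token or g.tags.get("Result", ""))
        if result is None:
            drops["no_result"] += 1
            continue
        white, black = g.tags.get("White", ""), g.tags.get("Black", "")
        if not white or not black:
            drops["missing_names"] += 1
            continue
        try:
            welo, belo = int(g.tags["WhiteElo"]), int(g.tags["BlackElo"])
        except (KeyError, ValueError):
            drops["missing_elo"] += 1
            continue
        if welo < min_elo or belo < min_elo:
            drops["low_elo"] += 1
            continue
        year = _year_of(g.tags)
        if year is None or not (lo <= year <= hi):
            drops["bad_year"] += 1
            continue
        try:
            plys = tuple(_chess.canonicalize(g.moves))
        except (_chess.IllegalMoveError, ValueError):
            drops["illegal_moves"] += 1
            continue
        kept.append(
            GameRecord(
                white_name=white,
                black_name=black,
                white_elo=welo,
                black_elo=belo,
                year=year,
                result=result,
                plys=plys,
            )
        )
    log.info("filter_games kept %d, dropped %s", len(kept), drops)
    return kept, drops


def encode_outcome(record: GameRecord, mover_side: str) -> int:
    """Game outcome from the mover's perspective: win 1, loss -1, draw 0."""
    if record.result == "draw":
        return 0
    won_white = record.result == "white_win"
    mover_white = mover_side == _chess.WHITE
    return 1 if won_white == mover_white else -1


# ---------------------------------------------------------------------------
# top-50 prestige lists
# ---------------------------------------------------------------------------


def top50_by_year(records, n_top: int = 50) -> dict[int, set[str]]:
    """Per year, the ``n_top`` players with highest mean Elo over their games.

    A player's Elo observations come from both colours.  Ties at the
    cutoff are broken by lexicographic name order; years with fewer than
    ``n_top`` players return everyone.
    """
    elos: dict[int, dict[str, list[int]]] = {}
    for r in records:
        yr = elos.setdefault(r.year, {})
        yr.setdefault(r.white_name, []).append(r.white_elo)
        yr.setdefault(r.black_name, []).append(r.black_elo)
    out = {}
    for year, players in elos.items():
        ranked = sorted(players, key=lambda nm: (-float(np.mean(players[nm])), nm))
        out[year] = set(ranked[:n_top])
    return out


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def _response_at_position(record: GameRecord, position: PositionSpec) -> str | None:
    """Canonical SAN of the move this game played from the focal position.

    Board-state mode replays the game and matches position keys (first
    occurrence only, so repetitions cannot double-count a game); prefix
    mode compares canonical SAN prefixes.
    """
    d = len(position.ply_prefix)
    if position.match_mode == "prefix":
        if len(record.plys) <= d:
            return None
        return record.plys[d] if record.plys[:d] == position.canonical_prefix() else None
    target = position.position_key()
    board = _chess.Board()
    for san in record.plys:
        if board.position_key() == target:
            return san
        board.push_san(san)
    return None  # position never reached, or reached only after the final ply


def tabulate_position(
    records,
    position: PositionSpec,
    top50: dict[int, set[str]] | None = None,
) -> tuple[YearlyCountTable, pd.DataFrame]:
    """Count response moves per year at the focal position.

    Returns the :class:`YearlyCountTable` and a tally frame with one row
    per year x move: games, wins/losses/draws (mover's perspective) and
    the same restricted to games whose mover is a top-50 player that year.
    """
    if top50 is None:
        top50 = top50_by_year(records)
    mover = position.mover_color
    tally: dict[tuple[int, str], np.ndarray] = {}
    years_seen: set[int] = set()
    n_hits = 0
    for r in records:
        years_seen.add(r.year)
        san = _response_at_position(r, position)
        if san is None:
            continue
        n_hits += 1
        key = (r.year, san)
        row = tally.setdefault(key, np.zeros(8, dtype=int))
        o = encode_outcome(r, mover)
        row[0] += 1
        row[1 + (0 if o == 1 else 1 if o == -1 else 2)] += 1
        mover_name = r.white_name if mover == _chess.WHITE else r.black_name
        if mover_name in top50.get(r.year, set()):
            row[4] += 1
            row[5 + (0 if o == 1 else 1 if o == -1 else 2)] += 1
    if n_hits == 0:
        log.warning("no game reaches the focal position; table is all zeros")
    years = np.array(sorted(years_seen), dtype=int)
    moves = sorted({m for _, m in tally})
    counts = np.zeros((years.size, max(len(moves), 1)), dtype=int)
    cols = [
        "games", "wins", "losses", "draws",
        "top50_games", "top50_wins", "top50_losses", "top50_draws",
    ]
    rows = []
    for t, y in enumerate(years):
        for i, m in enumerate(moves or ["<none>"]):
            row = tally.get((int(y), m), np.zeros(8, dtype=int))
            counts[t, i] = row[0]
            rows.append({"year": int(y), "move": m, **dict(zip(cols, row.tolist()))})
    table = YearlyCountTable(
        years=years,
        moves=moves or ["<none>"],
        counts=counts,
        totals=counts.sum(axis=1),
        position=position,
        meta={"match_mode": position.match_mode, "n_games_at_position": n_hits},
    )
    return table, pd.DataFrame(rows)


def count_moves(records, position: PositionSpec) -> YearlyCountTable:
    """Yearly response-move counts at the focal position (counts only)."""
    table, _ = tabulate_position(records, position)
    return table
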