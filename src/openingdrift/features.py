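"""Modelling inputs: rare-move pooling, covariates, standardization.

Order of operations matters and is fixed here: rare moves are pooled into
an "other" category *before* covariates are computed, so that "other" has
its own pooled win rates and top-50 frequency (every modelled category
needs a covariate row).  Features for year t enter the model as predictors
of counts in year t+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import YearlyCountTable

OTHER_LABEL = "other"
FEATURE_NAMES = ("win_rate", "top50_win_rate", "top50_freq")


@dataclass
class FeatureTable:
    """Per-year, per-move covariates, raw and z-scored.

    ``standardized`` is a (T, k, 3) array in feature order
    (win_rate, top50_win_rate, top50_freq); each (move, feature) series is
    z-scored across the modelling years.  Zero-variance series are set to
    all zeros and recorded in ``flags`` (their coefficient is then
    unidentifiable and should not be interpreted).
    """

    years: np.ndarray
    moves: list[str]
    win_rate: np.ndarray  # (T, k) in [-1, 1]
    top50_win_rate: np.ndarray  # (T, k) in [-1, 1]
    top50_freq: np.ndarray  # (T, k) in [0, 1]
    standardized: np.ndarray | None = None  # (T, k, 3)
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        for name in ("win_rate", "top50_win_rate"):
            a = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.abs(a) > 1 + 1e-12):
                raise ValueError(f"{name} must lie in [-1, 1]")
            setattr(self, name, a)
        self.top50_freq = np.asarray(self.top50_freq, dtype=float)
        if np.any(self.top50_freq < -1e-12) or np.any(self.top50_freq > 1 + 1e-12):
            raise ValueError("top50_freq must lie in [0, 1]")

    def raw_stack(self) -> np.ndarray:
        return np.stack([self.win_rate, self.top50_win_rate, self.top50_freq], axis=-1)

    def to_frame(self) -> pd.DataFrame:
        std = self.standardized
        rows = []
        for fi, fname in enumerate(FEATURE_NAMES):
            raw = self.raw_stack()[:, :, fi]
            for t, y in enumerate(self.years):
                for i, m in enumerate(self.moves):
                    rows.append(
                        {
                            "year": int(y),
                            "move": m,
                            "feature": fname,
                            "raw": raw[t, i],
                            "standardized": float(std[t, i, fi]) if std is not None else np.nan,
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rare-move aggregation
# ---------------------------------------------------------------------------


def aggregate_rare(
    table: YearlyCountTable,
    tallies: pd.DataFrame | None = None,
    threshold: float = 0.02,
) -> tuple[YearlyCountTable, pd.DataFrame | None]:
    """Pool moves with average frequency below ``threshold`` into "other".

    The average is of the yearly frequencies x_ti / N_t over years with at
    least one game.  Outcome tallies, when given, are pooled the same way
    so "other" carries the summed wins/losses/draws of its constituents.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    freqs = table.frequencies()
    nonzero = table.totals > 0
    if not nonzero.any():
        raise ValueError("table has no games at all")
    avg = freqs[nonzero].mean(axis=0)
    rare = avg < threshold
    if rare.all():
        raise ValueError("every move is below the rarity threshold; nothing to model")
    if not rare.any():
        return table, tallies
    keep = [m for m, r in zip(table.moves, rare) if not r]
    rare_moves = [m for m, r in zip(table.moves, rare) if r]
    counts = np.column_stack([table.counts[:, ~rare], table.counts[:, rare].sum(axis=1)])
    out = YearlyCountTable(
        years=table.years,
        moves=keep + [OTHER_LABEL],
        counts=counts,
        totals=table.totals,
        position=table.position,
        meta={**table.meta, "aggregated": rare_moves, "threshold": threshold},
    )
    pooled = None
    if tallies is not None:
        t = tallies.copy()
        t["move"] = np.where(t["move"].isin(rare_moves), OTHER_LABEL, t["move"])
        pooled = t.groupby(["year", "move"], as_index=False).sum(numeric_only=True)
    return out, pooled


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def compute_features(table: YearlyCountTable, tallies: pd.DataFrame) -> FeatureTable:
    """Build the three bias covariates from outcome tallies.

    win_rate = (wins - losses) / games on the {-1, 0, 1} outcome encoding;
    the top-50 variants use only games whose mover is a top-50 player that
    year; top50_freq is the move's share of top-50 games at the position.
    Cells with zero games get the neutral value 0 and are flagged.
    """
    T, k = table.counts.shape
    win = np.zeros((T, k))
    t50win = np.zeros((T, k))
    t50freq = np.zeros((T, k))
    idx = {(int(r.year), r.move): r for r in tallies.itertuples()}
    empty_cells = 0
    for t, y in enumerate(table.years):
        t50_total = sum(
            idx[(int(y), m)].top50_games for m in table.moves if (int(y), m) in idx
        )
        for i, m in enumerate(table.moves):
            r = idx.get((int(y), m))
            if r is None or r.games == 0:
                empty_cells += 1
                continue
            win[t, i] = (r.wins - r.losses) / r.games
            if r.top50_games > 0:
                t50win[t, i] = (r.top50_wins - r.top50_losses) / r.top50_games
            if t50_total > 0:
                t50freq[t, i] = r.top50_games / t50_total
    ft = FeatureTable(
        years=table.years,
        moves=list(table.moves),
        win_rate=win,
        top50_win_rate=t50win,
        top50_freq=t50freq,
    )
    ft.flags["empty_cells"] = empty_cells
    return ft


def standardize(features: FeatureTable) -> FeatureTable:
    """Z-score each (move, feature) series across the modelling years.

    Writes the (T, k, 3) ``standardized`` array in place and returns the
    table.  Constant series become all zeros and are flagged.
    """
    raw = features.raw_stack()
    mean = raw.mean(axis=0, keepdims=True)
    sd = raw.std(axis=0, ddof=0, keepdims=True)
    degenerate = sd[0] < 1e-12
    sd = np.where(sd < 1e-12, 1.0, sd)
    z = (raw - mean) / sd
    z[:, degenerate] = 0.0
    features.standardized = z
    if degenerate.any():
        features.flags["constant_series"] = [
            (features.moves[i], FEATURE_NAMES[f])
            for i, f in zip(*np.nonzero(degenerate))
        ]
    return features


def restrict_years(
    table: YearlyCountTable,
    features: FeatureTable | None = None,
    lo: int = 1980,
    hi: int = 2019,
) -> tuple[YearlyCountTable, FeatureTable | None]:
    """Cut both objects to the modelling window [lo, hi]."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    mask = (table.years >= lo) & (table.years <= hi)
    if not mask.any():
        raise ValueError(f"no years left in [{lo}, {hi}]")
    out = YearlyCountTable(
        years=table.years[mask],
        moves=list(table.moves),
        counts=table.counts[mask],
        totals=table.totals[mask],
        position=table.position,
        meta={**table.meta, "year_range": (lo, hi)},
    )
    fout = None
    if features is not None:
        fout = FeatureTable(
            years=features.years[mask],
            moves=list(features.moves),
            win_rate=features.win_rate[mask],
            top50_win_rate=features.top50_win_rate[mask],
            top50_freq=features.top50_freq[mask],
            standardized=None,
            flags=dict(features.flags),
        )
        fout = standardize(fout)  # re-standardize over the window actually modelled
    return out, fout
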