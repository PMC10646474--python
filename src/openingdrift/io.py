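"""Delimited-text round trips for every pipeline artifact.

All outputs are TSV (or YAML for parameters/config) so that runs are
diffable and a synthetic dataset is indistinguishable on disk from a real
one.  Writers are deterministic: fixed column orders, fixed float format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .features import FEATURE_NAMES, FeatureTable
from .dm import ModelParams
from .ingest import YearlyCountTable

_FLOAT_FMT = "%.10g"


def write_count_table(table: YearlyCountTable, path, tallies: pd.DataFrame | None = None) -> None:
    df = table.to_frame()
    if tallies is not None:
        df = df.merge(tallies, on=["year", "move"], how="left")
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_count_table(path) -> YearlyCountTable:
    df = pd.read_csv(path, sep="\t")
    years = np.array(sorted(df["year"].unique()))
    moves = list(dict.fromkeys(df["move"]))
    counts = (
        df.pivot_table(index="year", columns="move", values="count", fill_value=0)
        .reindex(index=years, columns=moves)
        .to_numpy()
        .astype(int)
    )
    return YearlyCountTable(
        years=years, moves=moves, counts=counts, totals=counts.sum(axis=1)
    )


def write_feature_table(features: FeatureTable, path) -> None:
    features.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    years = np.array(sorted(df["year"].unique()))
    moves = list(dict.fromkeys(df["move"]))
    mats = {}
    for name in FEATURE_NAMES:
        sub = df[df["feature"] == name]
        mats[name] = (
            sub.pivot_table(index="year", columns="move", values="raw")
            .reindex(index=years, columns=moves)
            .to_numpy()
        )
    ft = FeatureTable(years=years, moves=moves, **mats)
    if df["standardized"].notna().all():
        std = np.stack(
            [
                df[df["feature"] == name]
                .pivot_table(index="year", columns="move", values="standardized")
                .reindex(index=years, columns=moves)
                .to_numpy()
                for name in FEATURE_NAMES
            ],
            axis=-1,
        )
        ft.standardized = std
    return ft


def write_params(params: ModelParams, path, meta: dict | None = None) -> None:
    doc = {
        "k": params.k,
        "moves": [
            {
                "breakpoints": [float(b) for b in f.breakpoints],
                "values": [float(c) for c in f.values],
                "beta_win": float(bi.beta_win),
                "beta_top50_win": float(bi.beta_top50_win),
                "beta_top50_freq": float(bi.beta_top50_freq),
            }
            for f, bi in zip(params.fitness, params.biases)
        ],
    }
    if meta:
        doc["meta"] = meta
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_params(path) -> ModelParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    c = [m["values"] for m in doc["moves"]]
    beta = [[m["beta_win"], m["beta_top50_win"], m["beta_top50_freq"]] for m in doc["moves"]]
    bps = [m["breakpoints"] for m in doc["moves"]]
    return ModelParams.from_matrices(np.array(c), np.array(beta), bps)


def write_draws(fit, path) -> None:
    """Persist posterior draws as (chain, iteration, parameter, value) TSV."""
    chains, n, d = fit.draws.shape
    rows = {
        "chain": np.repeat(np.arange(chains), n * d),
        "iteration": np.tile(np.repeat(np.arange(n), d), chains),
        "parameter": np.tile(fit.param_names, chains * n),
        "value": fit.draws.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_draws(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    names = list(dict.fromkeys(df["parameter"]))
    chains = df["chain"].nunique()
    n = df["iteration"].nunique()
    draws = df["value"].to_numpy().reshape(chains, n, len(names))
    return draws, names


def write_summary(summary, prefix) -> None:
    summary.params.to_csv(f"{prefix}_params.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    summary.mean_fitness.to_csv(
        f"{prefix}_mean_fitness.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    summary.normalized_fitness.to_csv(
        f"{prefix}_normalized_fitness.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    summary.game_sample_size.to_csv(
        f"{prefix}_game_sample_size.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
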