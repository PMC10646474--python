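"""Vector-graphics panels: move frequencies, fitness trajectories, deviation curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def frequency_panel(table, path) -> None:
    freqs = table.frequencies()
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, m in enumerate(table.moves):
        ax.plot(table.years, freqs[:, i], label=m)
    ax.set_xlabel("year")
    ax.set_ylabel("move frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def fitness_panel(summary_prefix, path) -> None:
    fp = pd.read_csv(f"{summary_prefix}_normalized_fitness.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(6, 4))
    for m, sub in fp.groupby("move"):
        ax.plot(sub["year"], sub["median"], label=m)
        ax.fill_between(sub["year"], sub["q01"], sub["q99"], alpha=0.15)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("year")
    ax.set_ylabel("normalized fitness $f_i/\\bar{f}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def deviation_panel(curves_path, path) -> None:
    df = pd.read_csv(curves_path, sep="\t")
    fig, ax = plt.subplots(figsize=(6, 4))
    for m, sub in df.groupby("move"):
        ax.plot(sub["frequency"], sub["deviation"], label=m)
        ax.fill_between(sub["frequency"], sub["lo"], sub["hi"], alpha=0.15)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("current-year frequency")
    ax.set_ylabel("deviation from random choice")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
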