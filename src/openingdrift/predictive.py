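"""Posterior-predictive analyses.

Two outputs: (1) the model's fitted move-choice probabilities over time
(alpha / sum(alpha) per posterior draw, summarized as a mean with a middle
98% band), and (2) frequency-dependence deviation curves — how far the
expected next-year choice probability of a move departs from random
choice as its current frequency is swept over a grid, everything else
held fixed.  Negative frequency dependence (anti-conformity) shows up as
a curve that is positive at low frequency and negative at high frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DeviationCurve:
    move: str
    grid: np.ndarray  # frequencies 0, 0.02, ..., 1
    deviation: np.ndarray  # E[p_{t+1}] - p at each grid point
    lo: np.ndarray  # bootstrap band for the mean
    hi: np.ndarray
    degenerate: np.ndarray  # grid points where the counterfactual collapses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "move": self.move,
                "frequency": self.grid,
                "deviation": self.deviation,
                "lo": self.lo,
                "hi": self.hi,
                "degenerate": self.degenerate,
            }
        )


def _alpha_draws(fit, t):
    """(n_draws, k) alpha vectors for transition t under each posterior draw."""
    data = fit.data
    c_act = fit.c_draws()[:, np.arange(data.k), data.seg[t]]
    expfac = np.exp(np.einsum("dim,im->di", fit.beta_draws(), data.Y[t]))
    a = expfac * c_act * data.Xc[t]
    if data.plus_one:
        a = a + 1.0
    return a


def choice_probability_timeseries(fit) -> pd.DataFrame:
    """Posterior mean move-choice probability per year, with 98% bands.

    The probability in year t+1 implied by year t is alpha / sum(alpha);
    with neutral parameters and no +1 correction this is exactly the
    observed frequency x_t / N_t.
    """
    data = fit.data
    years = data.years[data.trans_idx]
    rows = []
    for t in range(len(years)):
        a = _alpha_draws(fit, t)
        p = a / a.sum(axis=1, keepdims=True)
        for i, m in enumerate(data.moves):
            rows.append(
                {
                    "year": int(years[t]),
                    "move": m,
                    "mean": float(p[:, i].mean()),
                    "q01": float(np.quantile(p[:, i], 0.01)),
                    "q99": float(np.quantile(p[:, i], 0.99)),
                }
            )
    return pd.DataFrame(rows)


def deviation_curves(
    fit,
    n_samples: int = 1000,
    grid_step: float = 0.02,
    boot_conf: float = 0.98,
    n_boot: int = 2000,
    seed: int = 0,
    reference_n: float | None = None,
    counterfactual: str = "rescale",
) -> list[DeviationCurve]:
    """Deviation of expected next-year choice probability from random choice.

    For each focal move and grid frequency p, a counterfactual count vector
    is built with the focal move at p*N and — under the default
    ``counterfactual="rescale"`` — the competitors scaled proportionally
    (from the reference year's counts) to fill (1-p)*N; ``"observed"``
    keeps competitors at their reference counts.  Covariates are held at
    their standardized mean (0).  For ``n_samples`` posterior draws the
    expected choice probability alpha_i / sum(alpha) is computed; the curve
    is the mean deviation from p with a percentile bootstrap band for the
    mean.
    """
    data = fit.data
    k = data.k
    if k < 2:
        raise ValueError("need at least 2 move categories for a counterfactual")
    if counterfactual not in ("rescale", "observed"):
        raise ValueError("counterfactual must be 'rescale' or 'observed'")
    rng = np.random.default_rng(seed)
    flat_c = fit.c_draws()
    flat_b = fit.beta_draws()
    nd = flat_c.shape[0]
    take = rng.choice(nd, size=min(n_samples, nd), replace=n_samples > nd)
    Cs, Bs = flat_c[take], flat_b[take]
    exp0 = np.exp(np.zeros((Cs.shape[0], k)))  # covariates at standardized mean
    N = float(reference_n if reference_n is not None else data.Nc[-1])
    x_ref = data.Xc[-1].astype(float)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    bp = np.asarray(data.breakpoints)
    qlo, qhi = (1 - boot_conf) / 2, 1 - (1 - boot_conf) / 2

    curves = []
    for i, move in enumerate(data.moves):
        others = np.delete(np.arange(k), i)
        ref_others = x_ref[others]
        dev = np.empty_like(grid)
        lo = np.empty_like(grid)
        hi = np.empty_like(grid)
        degen = np.zeros(grid.size, dtype=bool)
        for gi, p in enumerate(grid):
            x = np.zeros(k)
            x[i] = p * N
            if counterfactual == "rescale":
                if ref_others.sum() > 0:
                    x[others] = (1 - p) * N * ref_others / ref_others.sum()
                else:
                    degen[gi] = True
                    x[others] = (1 - p) * N / len(others)
            else:
                x[others] = ref_others
            n_tot = x.sum()
            if p >= 1.0 or n_tot <= 0:
                degen[gi] = degen[gi] or p >= 1.0
            freq = x / n_tot
            seg = np.array([np.searchsorted(bp[j], freq[j], side="right") for j in range(k)])
            c_act = Cs[:, np.arange(k), seg]
            a = exp0 * c_act * x
            if data.plus_one:
                a = a + 1.0
            probs = a[:, i] / a.sum(axis=1)
            d = probs - p
            dev[gi] = d.mean()
            boot = rng.choice(d, size=(n_boot, d.size), replace=True).mean(axis=1)
            lo[gi] = np.quantile(boot, qlo)
            hi[gi] = np.quantile(boot, qhi)
        curves.append(
            DeviationCurve(move=move, grid=grid, deviation=dev, lo=lo, hi=hi, degenerate=degen)
        )
    return curves
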