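# Methods

## The model

Fix a chess position and let `x_t = (x_t1, …, x_tk)` be the number of
games in year `t` in which each of the `k` candidate response moves was
played, with `N_t = Σ_i x_ti`. The package models the next year's counts
as Dirichlet-multinomial:

    x_{t+1} ~ DM(N_{t+1}, α_t),
    α_ti = exp(β_i · y_ti) · f_i(x_ti / N_t) · x_ti            (+1, see below)

This is a cultural analogue of a many-allele Wright–Fisher model. The
baseline (`f ≡ 1`, `β = 0`, no +1) is neutral transmission: players
"sample" a move in proportion to last year's counts, `E[x_{t+1}] =
(N_{t+1}/N_t) x_t`, and all frequency change is drift. Departures are
carried by two kinds of parameters, per move:

- **Frequency-dependent fitness** `f_i`: a positive step function of the
  move's current frequency, with 4 segments split at 3 fixed breakpoints.
  Breakpoints are the 25/50/75% empirical quantiles of the move's own
  yearly frequency series (linear-interpolation quantiles over the
  modelling years; both the rule and window are configurable and recorded),
  so each segment value is informed by roughly the same number of year
  transitions. Segments are left-closed/right-open, the last closed at 1.
- **Bias coefficients** `β_i = (β_win, β_top50-win, β_top50-freq)`:
  multiplicative (exponential-link) effects of three standardized
  covariates from year `t` — the move's population win rate on the
  {−1, 0, +1} outcome encoding from the mover's side, the same win rate
  among the year's top-50 players by mean Elo, and the move's frequency
  among those players. They operationalize success bias and prestige bias.

The fitness values play two roles at once. Ratios `f′_i = f_i / f̄_t`,
with mean fitness `f̄_t = Σ_j f_j(p_tj) p_tj`, are growth rates (`f′_i > 1`
means expected frequency increase; `Σ_i f′_i p_i = 1` identically). The
overall scale of the `f_i` sets the overdispersion of next-year counts:

    Var[x_{t+1,i}] = N_{t+1} p_i (1−p_i) (N_{t+1} + N_t f̄_t) / (1 + N_t f̄_t),

where `p` are the bias-free frequencies `f_i x_i / Σ f_j x_j`. Defining
the **game sample size** `N_s(t) = f̄_t N_t` — the multinomial-equivalent
number of games players effectively observe, i.e. a variance effective
population size — makes the variance formula depend on the data only
through `N_s`. Multiplying every `f` value by a constant γ leaves every
`f′` unchanged and scales `f̄` and `N_s` by γ exactly (tested).

**Zero counts.** The baseline model assumes positive counts. For real
data the Dirichlet parameter is shifted to `α + 1` ("+1 correction"),
which keeps zero-count moves transmissible and biases expectations from
`x_i/N` to `(x_i+1)/(N+k)` — negligible once counts reach the hundreds.
The shift is applied outside `f_i`, whose argument is always the raw
frequency. `plus_one` defaults to on for inference and off in the theory
utilities; every output records which was used.

## Data preparation

PGN games are parsed with an in-package chess rules engine (move
legality, SAN disambiguation, and FEN-style position keys). Filters:
legal move sequence, recorded result and both player names, both Elos
at/above 2000, years 1971–2019; all defaults configurable and drop counts
logged. A position is matched by **board state** by default — placement,
side to move, castling rights, and en-passant rights recorded only when
actually usable — so transpositions count; exact move-order prefix
matching is available, and a game contributes at most its first arrival
at the position. Moves below 2% average yearly frequency are pooled into
"other" *before* covariates are computed, so the pooled category carries
its own pooled win rates and top-50 share. Covariates are z-scored per
move and feature over the modelling years (1980–2019 by default; the
window is re-standardized after restriction). Cells with no games get the
neutral value 0 before standardization and are flagged; constant series
become zeros and their coefficient is reported as unidentifiable.

## Inference

Priors: each segment value `c ~ Exp(1)` (prior mean fitness 1 =
neutrality), each `β ~ N(0,1)` on the standardized scale. Sampling uses
the package's No-U-Turn sampler — multinomial trajectory sampling,
dual-averaging step size (target acceptance 0.9), diagonal mass matrix
adapted in expanding windows — with `c` sampled on the log scale
(Jacobian included) and analytic gradients: ∂logDM/∂α is a difference of
digamma functions and α is an explicit product of the parameters.
Defaults: 4 chains, 1000 warmup + 1000 draws, jittered neutral starts.
Convergence gates (split-R̂ < 1.01, bulk ESS > 400, no divergences) flag
the result rather than hiding it; all thresholds are configurable and
logged. Runs are reproducible from the seed.

Point estimates are posterior medians; uncertainty is the 1%–99% quantile
interval, and a coefficient is "significant" when that middle-98%
interval excludes zero. Derived trajectories (`f̄_t`, `f′_i(t)`, `N_s(t)`)
are computed per posterior draw and then summarized — never by plugging
summarized parameters into the formulas. Fitnesses are reported for all
modelling years except the last, which enters only as an outcome.

## Posterior predictive

Fitted move-choice probabilities are `α/Σα` per draw and year (posterior
mean with middle-98% band); with neutral parameters and no +1 correction
they reproduce the observed frequencies exactly. Frequency-dependence
curves sweep a focal move's frequency over 0, 0.02, …, 1: a counterfactual
count vector puts the focal move at `p·N` with competitors rescaled
proportionally from a reference year (the last modelling year's counts
and total by default) and covariates held at their standardized mean 0;
for 1000 posterior draws the expected next-year choice probability is
computed and the curve reports the mean deviation from `p` with a
percentile-bootstrap band for the mean (2000 resamples, 98% by default).
The counterfactual construction sits behind one function with an
"observed competitors" alternative as a config switch, and degenerate
grid points (`p = 1`, or no competitor games to rescale) are flagged, not
fabricated. Negative frequency dependence (anti-conformity) appears as a
curve positive at low and negative at high frequency.

## Synthetic data

The simulator draws the exact generative process: `θ_t ~ Dirichlet(α_t)`,
`x_{t+1} ~ Multinomial(N_{t+1}, θ_t)`. Default conditions emulate a
mid-depth opening position: 40 years, k = 4 moves, 5000 games per year.
Covariates are exogenous stationary AR(1) series (autocorrelation 0.5)
mapped to the natural scales and z-scored exactly as the pipeline would,
which isolates bias-coefficient recovery from outcome-model error; an
end-to-end mode instead derives win rates from simulated per-game
outcomes (with a causal running z-score, so β scales differ slightly from
the truth there). A move going extinct with `plus_one` off halts the
simulation with a diagnostic; with the correction on it continues. One
seeded generator drives everything; the seed is echoed in every output.

What the simulator does *not* emulate: real games, Elo dynamics, player
identity, feature-outcome feedback, and non-stationarity in N_t beyond a
supplied series. Passing recovery tests therefore validates the
estimation machinery under the model's own assumptions, not the model's
adequacy for real chess data.

## Verification studies and problem sizes

- Exact identities (likelihood normalization by enumeration at n ≤ 6,
  k ≤ 4; uniform predictive at α = (1,1); reduction of the full model to
  the neutral one; the γ scale-splitting identity) hold to ≤ 1e-10.
- Monte-Carlo moments: 1e5 two-stage draws agree with the closed-form
  mean and variance within 3 standard errors.
- Parameter recovery: 40 years, k = 4, N = 5000, one move with declining
  fitness steps (1.6, 1.2, 0.9, 0.7) and β_win = 0.5; 4 chains × (800
  warmup + 800 draws). The fit uses the truth's breakpoints (they are
  fixed constants of the generative process; re-derived quartiles would
  define a different binning and make raw `c` values incomparable). True
  values fall inside the middle-98% intervals and the selective move's
  deviation curve is positive at low and negative at high frequency. At
  this chain length the slowest mode — the common log-scale of all `c`,
  i.e. `f̄` — sits slightly above the production R̂ gate; longer runs
  clear it without changing the conclusions.
- Null calibration: 50 neutral replicates at k = 3, 30 years, N = 2000,
  2 chains × (200 + 300) per fit; the middle-98% rule flags coefficients
  at roughly the nominal 2% rate (accepted band 0.3%–5%, a ~99.7%
  binomial interval widened for quantile-estimation noise at 600 draws).

## Known limitations

- The overdispersion scale (`f̄`, hence `N_s`) is weakly identified when
  it is close to 1 and the number of transitions is small; the Exp(1)
  prior then shrinks it below 1. It is well identified when counts are
  genuinely overdispersed (`f̄` well below 1), the regime reported for
  real positions.
- Breakpoint placement from observed quartiles means fitted step
  functions from different datasets are not directly comparable segment
  by segment; compare `f_i(x)` as functions, or `f′` trajectories.
- Name variants of one player are not merged (PGN offers no reliable
  key); top-50 lists may split such a player's games.
- The sampler's diagonal mass matrix leaves the global fitness-scale
  direction the slowest to mix; budget draws accordingly when `N_s` is
  the quantity of interest.
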