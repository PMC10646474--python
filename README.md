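# openingdrift

Inference of cultural transmission biases in chess opening move choice.

Professional chess leaves an unusually clean record of a cultural
practice: for a fixed board position, every year yields counts of how
often each candidate move was played. `openingdrift` models these yearly
count vectors as an overdispersed Wright–Fisher-like process and asks
*why* move frequencies change: drift alone, frequency-dependent bias
(anti-conformity — playing a move *because* it is rare), success bias
(copying moves with high win rates), or prestige bias (copying the top
players). It is intended for quantitative cultural-evolution researchers
and chess analysts working from PGN game collections.

## Model

For a position with `k` candidate moves, counts `x_t` in year `t` and
totals `N_t`, next-year counts are Dirichlet-multinomial:

    x_{t+1} ~ DM(N_{t+1}, α_t),     α_ti = exp(β_i · y_ti) · f_i(x_ti/N_t) · x_ti

- `f_i`: a 4-segment step function of the move's current frequency
  (breakpoints at the quartiles of its observed frequencies). Ratios
  `f′_i = f_i/f̄_t` are growth rates; the mean fitness
  `f̄_t = Σ_j f_j(p_tj) p_tj` sets the overdispersion, giving the *game
  sample size* `N_s(t) = f̄_t N_t` — the multinomial-equivalent number of
  games players effectively observe (a variance effective population
  size).
- `β_i`: coefficients on three standardized per-year covariates — the
  move's population win rate, its win rate among the year's top-50
  players by mean Elo, and its frequency among those players.
- With `f ≡ 1` and `β = 0` the process reduces to neutral transmission,
  `E[x_{t+1}] = (N_{t+1}/N_t) x_t`.
- In inference `α` is shifted to `α + 1` so zero-count moves remain
  transmissible.

Priors are `c ~ Exp(1)` per fitness segment (neutrality-centred) and
`β ~ N(0,1)`; the posterior is sampled with the package's No-U-Turn
sampler using analytic gradients. Effects are called significant when the
middle 98% of the posterior excludes zero. See `docs/methods.md` for the
full account.

## Worked example

Simulate 40 years of a position with four candidate moves where one move
has declining frequency-dependent fitness and a success bias, then fit
and summarize (this is the library layer; the `openingdrift` CLI wraps
the same calls):

```python
import openingdrift as od

truth = od.ModelParams(
    fitness=(
        od.PiecewiseFitness((0.25, 0.5, 0.75), (1.6, 1.2, 0.9, 0.7)),
        od.PiecewiseFitness((0.25, 0.5, 0.75), (1.0, 1.0, 1.0, 1.0)),
    ),
    biases=(od.BiasCoefficients(beta_win=0.5), od.BiasCoefficients()),
)
data = od.simulate_trajectory(
    od.SimulationConfig(k=2, years=40, n_per_year=3000, params=truth, seed=7)
)
fit = od.sample_posterior(
    data.table, data.features,
    od.SamplerConfig(chains=2, warmup=300, draws=300, seed=1),
)
summary = od.summarize(fit)
betas = summary.params[summary.params.name.str.startswith("beta")]
print(betas[["name", "median", "q01", "q99", "significant"]].round(3).to_string(index=False))

curves = od.deviation_curves(fit, n_samples=300, seed=2)
sel = curves[0]
print("deviation of m1 from random choice at frequency 0.10:", round(sel.deviation[5], 4))
print("deviation of m1 from random choice at frequency 0.90:", round(sel.deviation[45], 4))
```

Output (your numbers will match at these seeds):

```
               name  median    q01   q99  significant
       beta_win[m1]   0.483  0.450 0.519         True
 beta_top50_win[m1]   0.003 -0.027 0.034        False
beta_top50_freq[m1]   0.206 -0.871 1.246        False
       beta_win[m2]  -0.008 -0.034 0.021        False
 beta_top50_win[m2]   0.006 -0.033 0.035        False
beta_top50_freq[m2]  -0.183 -1.224 0.879        False
deviation of m1 from random choice at frequency 0.10: 0.025
deviation of m1 from random choice at frequency 0.90: -0.0363
```

The simulated success bias 0.5 is recovered as `beta_win[m1]` = 0.483
with a middle-98% interval excluding zero, so the significance rule
flags it; the other five coefficients, truly zero, are not flagged. The
deviation curve shows move m1 chosen *above* random-copying expectation
when rare (+2.5 percentage points at frequency 0.10) and below it when
common (−3.6 points at 0.90) — the signature of anti-conformity built
into its declining fitness steps. `summary.params` also holds the step
heights `c[m,j]`, and `summary.mean_fitness` / `summary.game_sample_size`
give `f̄_t` and `N_s(t)` per year with 98% bands.

For real data the pipeline starts from PGN:

```
openingdrift features games.pgn --position "e4 c5" --out run/
openingdrift fit --counts run/counts.tsv --features run/features.tsv --out run/
openingdrift predict --counts run/counts.tsv --features run/features.tsv \
    --draws-file run/draws.tsv --out run/
```

Positions are matched by board state (transpositions count), games are
filtered to Elo ≥ 2000 and years 1971–2019, rare moves (< 2% average
frequency) are pooled into "other", and the model is fitted on 1980–2019
— all configurable.

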