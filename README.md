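# habmod

Probabilistic models of infant habituation looking times.

## The problem

In a habituation experiment an infant sees the same stimulus for a number of
trials and then a novel *test* stimulus; the looking time (LT) per trial is
the measurement. LTs are strictly positive durations, so the routine practice
of analyzing them with additive-normal tools (ANOVA, linear regression)
embeds a substantive assumption — that experimental factors shift looking by
fixed *amounts* of time rather than by *percentages*. `habmod` is for
researchers who want to take that choice seriously: it implements a grid of
candidate trial-level models — five positive-support likelihoods (truncated
normal **N**, truncated normal with exponential mean **E**, lognormal **L**,
Weibull **W**, gamma **G**) crossed with three time structures (trend,
quadratic, autoregressive) and two pooling schemes (independent per-infant
fits vs hierarchical partial pooling) — and the machinery to compare them.

## The model

Each infant `i` has a latent habituation state on trial `t`; for the trend
structure

    z_{i,t} = alpha_i + beta_i * t + gamma_i * [t > d_i],

where `d_i` is the number of habituation trials, `alpha_i` the initial
level, `beta_i` the per-trial habituation change and `gamma_i` the
dishabituation shift on test trials. The LT is drawn from the chosen family
at `(z_{i,t}, sigma_i)`; for the multiplicative families (`E`, `L`, `W`,
`G`) the state acts on the log scale and parameters are reported as percent
change `100*(exp(z) - 1)`. Partial pooling places group-level normals over
the infant parameters, e.g. `alpha_i ~ N(mu^alpha_{b_i} + mu^alpha_{c_i},
sigma^alpha)` for stimulus contrast `b` and age cohort `c`. Models are named
by three-letter codes — `GTP` is gamma/trend/partial-pooling.

Fitting is by the package's built-in No-U-Turn sampler with analytic
gradients; convergence is gated by split R-hat < 1.1 per variable. Model
comparison uses data log-likelihood at posterior medians,
posterior-predictive mean absolute error, and the predictive score of a
censored fifth trial. Population analyses (omnibus ANOVA over per-infant
estimates, parameter-correlation tables with Fisher intervals, main-effect
summaries, the early-vs-late dishabituation contrast) live in
`habmod.popstats`. See `docs/methods.md` for the full model account.

## Worked example

```python
from habmod import HabituationModel, GeneratorConfig, generate_dataset, apply_exclusion
from habmod import families, popstats

# a synthetic study: 3 contrasts x 3 cohorts x 4 habituation-trial counts,
# the study's unbalanced cell sizes, ~7%-per-trial decrease, dropout
data = generate_dataset(GeneratorConfig(), seed=1)
data, report = apply_exclusion(data)        # drop sessions with < 3 test trials
print(data.n_infants, round(report["exclusion_rate"], 3))

model = HabituationModel(family="G", structure="trend", pooling="partial",
                         sampler="test", seed=1).fit(data)
print(model.model_code_, model.converged_, round(model.score(), 1))

effects = popstats.main_effects_summary(model.posterior_, "G")
slope = effects[(effects.parameter == "beta") & (effects.factor == "contrast")]
print(slope[["level", "median", "q2.5", "q97.5"]].round(1))

# analytic orthogonality anchors
print(round(families.parameter_correlation("G", 2.1), 2),
      round(families.parameter_correlation("W", 1.0), 2))
print(popstats.trials_to_criterion(0.07, 0.5))
```

Output (the hierarchical fit takes a few minutes at this scale):

```
260 0.136
GTP True -3751.1
         level  median  q2.5  q97.5
6    luminance    -4.8  -8.3   -0.9
7        color    -9.1 -12.6   -5.6
8  orientation    -4.5  -9.2    0.2
0.89 0.31
10
```

260 of 301 simulated sessions survive the exclusion rule (13.6% excluded);
the gamma-trend partial-pooling fit converges (split R-hat < 1.1 on every
variable), and the slope main effects bracket the generating 7% per-trial
decrease in every contrast group — the percent-scale medians scatter around
−7% with 95% intervals a few points wide, as expected for one simulated
study. The two constants are the asymptotic correlations between the two
parameter estimates implied by the inverse Fisher information — 0.89 for the
gamma family at shape 2.1 and 0.31 for the Weibull family (any shape) — and
a 7% per-trial decrease needs 10 trials to halve looking time.

A command-line pipeline wraps the same steps:

```bash
habmod simulate --seed 1 --preset study-like --out dataset.csv
habmod fit --data dataset.csv --model GTP --model GTN --seed 1
habmod evaluate --data dataset.csv --model GTP --model GTN
habmod analyze --data dataset.csv
habmod report
```

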