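# bridgevar

Dynamic mental-state networks and **bridge effects** for ecological
momentary assessment (EMA) panels.

When depression and anxiety co-occur, network accounts of comorbidity
propose that specific *bridge* symptoms carry activation from one symptom
cluster into the other. At the daily-life timescale this is a dynamic
question: does a momentary state such as worrying transmit yesterday's
anxious activation into today's low mood? `bridgevar` is a toolkit for
researchers in network psychometrics and clinical epidemiology who want
to answer it from intensive longitudinal self-report data:

- a **synthetic panel generator** with the multilevel VAR(1) structure,
  fixed daily sampling scheme (5 prompts/day at 3-h intervals for 14
  days), night gaps, jitter and missed prompts of a three-group clinical
  EMA design (comorbid / depression-only / anxiety-only);
- **preprocessing**: reverse coding, alignment of unequally spaced
  prompts onto an equally spaced 180-min lattice with explicit missing
  cells, group descriptives, KPSS stationarity and collinearity screens;
- a **hierarchical Bayesian multilevel VAR(1)** — latent person-mean
  centering, all 49 lag coefficients and 7 means as person-level random
  effects, group-dummy regression at the between level, full innovation
  covariance, missing-data augmentation by forward-filter
  backward-sampling inside a Gibbs sampler (numba-compiled), split-chain
  PSR convergence diagnostics;
- the **bridge effect**: for a candidate bridge node *b*, the sum over
  all qualifying ordered pairs (i, j) of `phi[b<-i] * phi[j<-b]` —
  lag-2 indirect effects funnelling through *b* — evaluated at every
  MCMC draw, with credible intervals, one-tailed posterior p values,
  group differences and per-group rankings on the per-path *mean* bridge
  effect.

## The statistic

With seven items — three pure depression states, two pure anxiety
states, two overlapping states (worrying, irritated) — a path
`i -> b -> j` qualifies when i ≠ j, neither is the bridge, and the pair
crosses clusters under at least one reading of the overlapping items.
That yields **22** indirect effects when an overlapping state is the
bridge, **24** for a pure anxiety bridge and **26** for a pure
depression bridge. The bridge effect of node *b* in group *g* is

```
B_g(b) = Σ_{(i,j)} φ_g[b←i] · φ_g[j←b]
```

computed drawwise on the group-average lag matrices, so the full
posterior of the statistic — and of its between-group differences —
comes for free. The mean bridge effect `B_g(b)/|pairs|` makes nodes with
different path counts comparable in rankings.

## Worked example

```python
from bridgevar import (default_config, simulate_panel, reverse_code,
                       align_to_grid, fit_mlvar, group_phi_draws,
                       enumerate_bridge_paths, bridge_effect_draws,
                       summarize_effect, compare_groups, edge_summaries,
                       edge_density, default_catalog)

cfg = default_config(seed=1, n_persons={"comorbid": 20,
                                        "depression_only": 12,
                                        "anxiety_only": 12})
panel = simulate_panel(cfg)                       # raw questionnaire scale
gridded = align_to_grid(reverse_code(panel), delta_min=180.0)
draws = fit_mlvar(gridded, chains=2, iterations=1500, seed=2)

catalog = default_catalog()
for group in draws.groups:
    phi = group_phi_draws(draws, group)
    ps = enumerate_bridge_paths("WOR", catalog)
    s = summarize_effect(bridge_effect_draws(phi, ps, catalog), ps.count,
                         bridge="WOR", group=group)
    lo, hi = s.ci95
    print(f"bridge effect WOR, {group}: {s.mean:.4f} [{lo:.4f}, {hi:.4f}] "
          f"p={s.p_one_tailed:.3f} ({ps.count} paths)")
```

prints (44 persons, 2835 answered records; 13,678 latent cells imputed
per MCMC iteration):

```
bridge effect WOR, comorbid: 0.0699 [0.0183, 0.1318] p=0.006 (22 paths)
bridge effect WOR, depression_only: 0.0375 [-0.0123, 0.1049] p=0.078 (22 paths)
bridge effect WOR, anxiety_only: 0.0828 [0.0129, 0.1635] p=0.008 (22 paths)
```

Each line is the posterior mean of the summed indirect effect through
worrying, its central 95% credible interval, and the one-tailed posterior
probability of the opposite sign: in this simulated cohort worrying acts
as a credible bridge in the comorbid and anxiety-only groups (intervals
exclude zero) but not in the depression-only group. Group contrasts come
from `compare_groups` (drawwise differences on aligned draws), network
density from `edge_density(edge_summaries(draws))`, and rankings with
comparison-to-best flags from `rank_bridges`.

The same chain is available from the shell:

```
bridgevar run --seed 1 --out results/run1       # simulate → ... → report
bridgevar report --out results/run1
```

with staged verbs (`simulate`, `preprocess`, `fit`, `bridges`) for
custom pipelines, YAML configs via `--config`, and `--subgroup NAME` for
sensitivity refits on severity-tertile or diagnosis-recency subsets.

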