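# Methods

## The scientific problem

When depression and anxiety co-occur, network theories of psychopathology
propose that specific "bridge" symptoms transmit activation from one
symptom cluster to the other. At the timescale of daily life, momentary
mental states (measured by ecological momentary assessment, EMA — brief
self-reports several times a day) stand in for clinical symptoms, and the
bridging question becomes dynamic: does yesterday-afternoon's worrying
carry anxious activation into this evening's feeling down?

`bridgevar` implements the full analysis chain for this question on
long-format EMA panels: a hierarchical Bayesian multilevel VAR(1) that
estimates group-average lagged networks from unequally spaced prompts,
and a posterior functional — the *bridge effect* — that quantifies
cross-cluster funnelling through any candidate node, with group
comparisons and node rankings.

## Item catalog

Seven 1–7 Likert items: three pure depression states (listless, down,
not-cheerful), two pure anxiety states (nervous, not-relaxed), and two
*overlapping* states that belong to both clusters (worrying, irritated).
"Cheerful" and "relaxed" are asked positively and reverse coded
(`8 − x`) so high always means symptomatic. The panel object carries a
`coded` flag so reverse coding is applied exactly once; applying
`reverse_code` twice restores the raw scores.

A note on naming: published accounts of this design are not fully
consistent about which two items are the a-priori bridge candidates (one
passage pairs "worrying" with "feeling down"). We follow the reading
consistent with the path-count arithmetic below: the overlapping items
are worrying and irritated.

## Lattice alignment (unequal spacing)

A VAR(1) coefficient is only interpretable at a fixed lag. Prompts are
nominally 180 min apart but jittered, with long night gaps and missed
beeps. `align_to_grid` places each person's answered records on a
`delta_min` lattice (default 180): the person-local origin is their first
answered prompt, each record goes to its nearest slot (`round((t −
t0)/Δ)`, ties away from zero), and unfilled interior slots become
explicit missing cells that the sampler later treats as latent data. When
two records fall in one slot the earlier is kept and the later dropped
and counted. The exact binning dialect used by commercial DSEM software
is not public; nearest-slot rounding preserves the median spacing and is
simple to reason about, and the per-person collision counts let users
audit the choice.

## Stationarity and collinearity screens

Per person × item, a level-stationarity KPSS test (statsmodels, constant
regression, automatic Newey–West bandwidth) is run on the observed
subsequence; series shorter than 20 observed points are marked untestable
and excluded from the per-item stationary fraction. A constant series has
zero partial-sum variance and is defined stationary with statistic 0.
No detrending is applied downstream. Collinearity is screened on pooled
person-mean-centred Pearson correlations with a 0.9 flag threshold.

## The multilevel VAR(1)

For person *i* with latent means `mu_i` and lag matrix `Phi_i`
(`phi[to, from]`):

    y_t − mu_i = Phi_i (y_{t−1} − mu_i) + eps_t,   eps_t ~ N(0, Sigma)

All 49 lag entries and 7 means are person-level random effects. Each has
mean `gamma0 + gamma_g` (reference group mean plus a dummy offset per
non-reference group; reference defaults to the comorbid group) and its
own variance `tau^2` — a diagonal random-effects covariance. A full
56×56 covariance is not estimable at these sample sizes and published
applications do not report one; the diagonal structure is a deliberate
simplification. `Sigma` is a full 7×7 innovation covariance shared
across persons and groups.

Centering is *latent*: `mu_i` is a parameter sampled inside the model,
not the person's observed average, which avoids the small-T bias induced
by observed-mean centering.

### Priors

Normal(0, 10²) on all fixed effects, Inverse-Gamma(0.001, 0.001) on each
`tau^2`, and Inverse-Wishart(df = 9, scale = I) on `Sigma`. With
thousands of person-transitions these are data-dominated stand-ins for
the "non-informative defaults" of standard DSEM software, whose exact
priors are not published; all are configurable via `MlvarSpec`.

### Gibbs sampler

Each iteration cycles:

1. **Missing cells** — per person, forward-filter backward-sample on the
   state `z_t = y_t − mu_i`. Observations enter as exact (noise-free)
   conditioning on the observed components; the slot-0 prior is the
   person's stationary distribution (falling back to an inflated `Sigma`
   near the unit root). Missing cells interior to the observed span are
   imputed every iteration; boundary slots outside the span are trimmed,
   not extrapolated.
2. **Person lag matrix** — conjugate normal draw of `vec(Phi_i)` (49-dim)
   given the imputed series, `Sigma`, and the person's group-specific
   prior mean and `tau^2`.
3. **Person means** — conjugate 7-dim normal draw given `Phi_i`.
4. **Group regression and variances** — per parameter, Bayesian linear
   regression of the person values on the group-dummy design
   (vectorised over all 56 parameters via an eigendecomposition of
   `X'X`), then the conjugate Inverse-Gamma update for `tau^2`.
5. **Innovation covariance** — Inverse-Wishart update from pooled
   residuals.

Person-level likelihoods condition on each person's first observed slot
(transitions only); the imputation step uses the stationary prior for
slot 0. The compiled kernels (numba) take pre-generated standard-normal
arrays, so all randomness flows from a single numpy `SeedSequence` and
identical seeds give identical draws. Defaults: 2 chains × 4000
iterations, 50% burn-in, no thinning. Convergence is monitored by
split-chain potential scale reduction (threshold 1.1) on all fixed
effects and innovation variances; failures warn and list the worst
parameters rather than aborting.

An edge is reported "significant" when its central 95% credible interval
(equal-tailed quantiles, not HPD — matching standard DSEM output)
excludes zero; per-group density is the count of significant edges out
of 49.

## The bridge effect

For candidate bridge *b*, qualifying paths are ordered pairs (i, j) with
i ≠ j, neither equal to *b*, whose endpoints admit two different cluster
readings — equivalently, every pair except those whose endpoints are
single-cluster items of the *same* cluster. An ordered pair counts once
even when both of its endpoints are overlapping items (two cluster
readings support it, but it is one path). This is the only convention
that reproduces all three path counts implied by the 3 + 2 + 2 design:
22 paths for an overlapping bridge, 24 for a pure-anxiety bridge, 26 for
a pure-depression bridge.

The bridge effect is

    B(b) = sum over pairs (i, j) of phi[b <- i] * phi[j <- b]

evaluated at *every retained draw* of the group-average lag matrix — a
full posterior for the functional, never a plug-in of posterior means.
Summaries: posterior mean, central 95% CI, one-tailed posterior p
(`min(Pr(B <= 0), Pr(B >= 0))`, the convention of Bayesian SEM output;
a two-tailed doubling is also emitted since reporting conventions vary),
and the *mean bridge effect* `B(b)/count` for ranking nodes with unequal
path counts. Group differences are drawwise (reference − group) on
aligned (chain, iteration) indices — automatic here because all group
matrices compose from shared fixed-effect draws. Rankings flag nodes
whose drawwise difference from the top-ranked node has a 95% CI
excluding zero; ties at the top break by catalog order with a warning.

## Synthetic data generator

No public dataset carries this design, so the generator is a first-class
module emulating it: three diagnostic groups (143 comorbid, 40
depression-only, 37 anxiety-only by default), 5 prompts/day at 3-h
intervals for 14 days (max 70 prompts), prompt-time jitter (SD 10 min,
clipped to ±45% of the interval so prompts keep their lattice slot),
8% missed prompts, and person-level random effects (SD 0.05 on lag
entries, 0.6 on means) around group-average dynamics.

The group lag matrices are **illustrative, not estimates**: all-positive
effects with autoregressions 0.2–0.36, a denser comorbid network (26
nonzero entries) than the single-disorder networks (14 and 20), and
cross-cluster paths routed through the overlapping items — the
qualitative shape reported for such cohorts. Item means follow published
group descriptives; innovation SDs (0.78–1.0 with a shared 0.3
correlation) are chosen so within-person SDs land near 0.6–1.1 on the
coded scale. The mapping from printed within-person SDs to innovation
scale is underdetermined, which is one reason the defaults are labelled
illustrative.

The latent process evolves *through* the night on the lattice
(unobserved slots are latent, not a restart), matching the equal-interval
model the estimator assumes. Likert rounding is off by default — the
analysis model treats items as continuous, and continuous emission keeps
parameter-recovery tests well-specified; rounding is available for
robustness checks. Severity metadata is a noisy monotone function of the
person's latent symptom level (scaled to an IDS-like 0–84 range) and a
binary recency class is drawn with group-specific rates; both exist to
exercise subgroup filters, not as a joint model. Person draws whose lag
matrix is non-stationary are redrawn (up to 100 times, then an error
naming the group).

What the generator does *not* emulate: ordinal measurement (by default),
response latency within the answering window, time-of-day or weekend
effects, non-random missingness, and trends — so passing recovery tests
show the estimator is correct under its own assumptions, not that real
EMA data satisfy them.

## Sensitivity subgroups and pipeline

`filter_subgroup` restricts one group by metadata — severity tertile
(sample quantiles at 1/3 and 2/3 within the target group, ties to the
lower tertile) or recency class — leaving other groups untouched;
sensitivity analyses *refit* the model on the filtered panel rather than
reweighting draws. The pipeline (`run_pipeline` / the `bridgevar` CLI)
chains generate/load → preprocess → fit → bridges → report, seeds every
stochastic stage from one manifest seed, and writes a manifest with a
config hash, per-stage row counts, a PSR summary and a checksum of every
output file.

## Numerical choices and problem sizes

- Tie-break in slot assignment: half away from zero; collision keeps the
  earlier record.
- FFBS adds 1e-9 jitter to conditioning blocks; filtered covariances are
  symmetrised and observed rows/columns clamped to exactly zero.
- Degenerate inputs: persons with no answered records are dropped with a
  warning; persons below the minimum observed-slot count (default 10)
  are excluded from fitting; a single-record person grids to one slot.
- The test suite exercises the estimator at reduced problem sizes chosen
  to keep full runs on one CPU short while leaving the statistical
  checks well-powered: the least-squares agreement study uses 50 persons
  × 56 complete slots (2 × 2000 iterations), the recovery study 3 × 30
  persons × 70 prompts (2 × 2000), the null calibration 3 × 20 persons
  (2 × 1000), and the CI-coverage study 100 replicates of 10 persons ×
  32 slots (2 × 400).

## Known limitations

- Diagonal random-effects covariance; no correlation between a person's
  lag entries and means is modelled.
- One shared innovation covariance across persons and groups; no
  person-specific residual variances.
- No continuous-time model: coefficients refer to the lattice interval,
  and alignment discretises true spacing to the nearest slot.
- No ordinal measurement model for Likert responses.
- No model comparison machinery (DIC/WAIC) and no time-varying dynamics.
- Coefficients are not standardised before bridging; bridge effects are
  on the model's raw scale, so cross-study comparisons require matched
  scales.
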