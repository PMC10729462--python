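# Methods

This note documents the models and procedures implemented in `crossbench`,
the synthetic data they are exercised on, and the numerical and design
choices that were genuinely open.

## Design and data model

A 2×2 cross-over trial: each subject is randomized to sequence PV
(placebo then verum) or VP, with four visits per treatment period —
t1 baseline, t2 on-treatment, t3 post-treatment, t4 follow-up. The data
model (`trial_data`) is strict long format, one row per
(subject, period, time), complete cases only: missing values are rejected
at read time so that the permutation engine stays exact. Treatment is a
deterministic function of (sequence, period) and is validated as such.

Outcomes:

- **count** — blister count, non-negative integer;
- **ordinal** — VAS severity score on the half-point grid {0, 0.5, …, 10};
- **binary** — derived responder indicator: 1 iff the count at a
  post-baseline visit is *strictly* below (1 − 0.4) × that period's
  baseline count. A zero baseline yields 0 at every visit (no reduction is
  definable), and baseline rows are always 0. Each period uses its own t1
  as baseline; the headline responder status is read at t3.

The **period block** — one subject-period's ordered 4-vector — is the unit
of resampling throughout.

## Synthetic generator

`synthetic.generate_trial` produces *null* datasets (no treatment, period,
or carry-over effect) with the three features that make this design hard:
overdispersion, between-subject heterogeneity, and within-block serial
correlation.

Per subject: a log-normal frailty u with E[u] = 1 and log-scale SD σᵤ
(default 0.5), shared by both periods. Per block: a latent standard-normal
AR(1) path z₁…z₄ with lag-1 correlation ρ (default 0.6). Counts arise by a
Gaussian copula — the negative-binomial quantile function (mean λ₀·u with
λ₀ = 7, size r = 4) evaluated at Φ(z_t) — so the NB marginal is exact and
`dispersion=None` degenerates to an exact Poisson(λ₀·u) marginal; with
σᵤ = 0 and ρ = 0 the counts are i.i.d. Poisson(λ₀), which the tests verify
against closed-form moments. VAS scores use an independent AR(1) path
mapped affinely (mean 5, SD 2), rounded to the half-point grid and clamped
to [0, 10]; rounding ties are intentional — they exercise the tie terms of
every rank-based statistic.

Defaults (15 subjects, 8/7 sequence split, λ₀ = 7, σᵤ = 0.5, ρ = 0.6,
r = 4) were fixed once as a plausible emulation of a small dermatology
trial with moderate counts; no real-data moments were fit. What the
generator does *not* emulate: missing data, floor/ceiling pile-ups in the
VAS, outcome-specific tie intensity of any particular real dataset, or
carry-over. Consequently, passing benchmarks show correct operating
characteristics *under this dependence structure*, not under any
particular trial's.

All randomness flows through a single `numpy` SeedSequence per dataset;
identical seeds give bit-identical datasets.

## Block permutation and effect injection

`permutation.block_permute` reassigns the 2n blocks uniformly at random to
the 2n (subject, period) slots, all outcome columns travelling together
and design columns untouched. This preserves the within-block dependence
and every block-level marginal while destroying treatment, period, and
subject effects simultaneously — an exact simulated null; the multiset of
blocks (hence every outcome total) is conserved, which the tests check
exactly.

Power scenarios add independent draws to the **placebo** arm (larger
counts/VAS are worse): S1 adds mean-δ draws at t3 only; S2 additionally
adds mean-δ/2 draws at t4. Count injections are Poisson(δ) (or a point
mass); ordinal injections are N(δ, (δ/2)²) rounded to the grid and
clamped. Binary power is induced by injecting on the counts and
re-deriving the responder indicator, mirroring how the endpoint is defined.
The default effect grid (δ ∈ {1, 2, 4} blisters, {1, 2} VAS points) is a
configuration choice, not an estimate.

## Generalized pairwise comparisons

Pair scores are ±1/0 per the sign of the comparison; because the outcomes
here are harms, the default orientation scores *lower* verum values as
wins, so Δ > 0 reads as verum benefit; the raw "+1 if V₁ > V₂" convention
is available as `higher_is_better`. Ties are never broken.

- *Univariate*: blocks are collapsed by a summary (default: change from
  baseline at t3; also mean of post-baseline visits, or block total).
- *Prioritized*: default ladder t3 → t4 → t2 → t1 (clinical relevance
  order); the first non-tied visit decides.
- *Non-prioritized*: the mean of the four per-time scores. The pooling
  rule is not canonical; per-pair averaging was chosen because it keeps
  Δ ∈ [−1, 1], reduces to the univariate score when all visits agree, and
  equals pooled per-time counting. Win/loss/tie counts for this variant
  are by the sign of the (fractional) per-pair score; for integer-scored
  variants Δ = (wins − losses)/n_pairs exactly.

Unmatched Δ averages all n² cross-arm pairs (a subject's own two periods
included); with no missing data and a univariate score it is the linear
transform 2U/n² − 1 of the tie-adjusted Mann–Whitney statistic, verified
against an independent rank implementation. Inference swaps, independently
per subject with probability ½, which of the subject's blocks is labelled
verum — a group of 2ⁿ permutations that preserves within-subject
dependence and is exact under within-subject period exchangeability. The
p-value uses the add-one estimator (1 + #{|Δ*| ≥ |Δ|})/(B + 1) to avoid
p = 0; exhaustive enumeration replaces sampling on request (and is
compared against brute force in the tests). Matched variants use the exact
conditional sign test on the non-tied within-subject scores,
p = min(1, 2·min(P(B ≤ b), P(B ≥ b))), B ~ Binomial(m, ½); results carry a
warning below 15 pairs, where the test cannot be meaningful.

## Nonparametric marginal model

Within one period the data are a 2 (group, whole-plot) × 4 (time,
sub-plot) factorial. Midranks over all observations of the period give
normalized rank means per cell; the interaction contrast is
T = (I₂ − J₂/2) ⊗ (I₄ − J₄/4), and the ANOVA-type statistic is
ATS = p̂ᵀT p̂ / tr(T V̂) with V̂ the block-diagonal estimated covariance of
the cell means and box-type numerator df f̂ = tr(T V̂)²/tr(T V̂ T V̂),
referred to F(f̂, ∞) (equivalently χ²(f̂)/f̂). A finite-denominator
variant (denominator df from the group-wise diagonal blocks of T V̂, each
scaled by 1/(n_g − 1)) is available and is never less conservative. The
implementation is verified against a from-scratch matrix evaluation on
tiny instances, is invariant under joint strictly monotone transforms, and
its null p-values are uniform within a KS-style band (with a 0.03
allowance for the small-sample F approximation). Cross-over data are
tested per period — the rank scale does not pool periods cleanly — with
optional Bonferroni or liberal min-p combination rules; per-period
reporting is the default.

## GEE-type marginal regression

Mean model on the link scale: β₀ + β₁G + β₂P + ΣⱼβⱼTⱼ plus the G·P, G·T
and P·T interactions (13 columns; reference cell placebo/period 1/t1) —
Poisson-log
for counts, binomial-logit for the responder indicator, with subject-period
blocks as independent clusters (between- and within-period covariance
assumed separable; a subject-fixed-effects variant sits behind a flag, off
by default). Estimation and the sandwich covariance come from statsmodels'
GEE; `correction="bias_corrected"` selects the Mancl–DeRouen leverage
adjustment and is the default for counts (for the binary outcome the
responder variance is closer to homoscedastic and no correction is the
default). Non-convergence and apparent separation are flagged, never
silently dropped.

Two small-sample facts shaped defaults:

- The derived responder outcome is identically 0 at baseline, so the full
  design is separated in the t1 cell; binomial models are therefore fit
  over t2–t4 (10 columns, 4-df overall treatment contrast).
- With 30 clusters of 4, the χ²₅ reference for the overall Wald test is
  markedly liberal (empirical size ≈ 0.15 at n = 15 even bias-corrected).
  `wald_test` defaults to χ² but exposes an F reference; the benchmark
  uses F(r, n_subjects − 1), which restores size ≈ 0.06.

The fit is verified against ordinary least squares in the
Gaussian-identity degenerate mode, against HC0 with singleton clusters,
and by parameter recovery (300 simulated trials at 200 subjects, ≥ 93%
coverage of every coefficient at ±3 robust SEs).

## Model averaging

Default candidate pools: counts — {Poisson, negative binomial} × {time
categorical with group×time, time linear with group×time, time categorical
main effects only}, all with a period main effect (Q = 6); binary — the
three binomial counterparts. Failed fits receive weight exactly 0 with a
warning. Akaike weights are computed after subtracting the minimum AIC
(identical by shift invariance, numerically safe). Effects are computed
from model predictions averaged over the observed rows of each
(treatment, time) cell: the log rate ratio at t3 (counts, weighted
geometric mean) or the ΔΔ difference-in-differences of response
proportions, t3 versus baseline — with the baseline term structurally 0
for the derived responder outcome.

Inference is a within-subject label-swap permutation test of the averaged
effect, refitting the entire pool per permutation. This is a deliberate
design choice: analytic post-averaging variances are fragile at these
sample sizes and have produced mis-calibrated tests for counts, whereas the
permutation construction is exact under within-subject exchangeability
regardless of how well any candidate fits. Results are flagged when more
than 10% of permutation refits fail.

## Benchmark

`benchmark.estimate_type1` / `estimate_power` run
generate → block-permute (→ inject) → analyze, with nested seeding:
master seed → per-replicate streams → per-method streams. Every method
sees the identical dataset within a replicate (common random numbers), so
paired power comparisons are valid. Failures are counted and reported per
method, never dropped; rates are rejections over non-failed replicates
with binomial MC standard errors. Reports are tidy CSVs; wall-clock
timings go to the run log so that re-runs with one seed are byte-identical.

Problem sizes used by the shipped checks: n_sim = 1000 replicates with
1000 permutations per test for type-I error and the power-ordering
comparisons; 300 replicates at 200 subjects for parameter recovery; the
`smoke` configuration (n_sim = 50, n_perm = 200) exercises every stage in
well under a minute.

## Known limitations

- Only 2 treatments × 2 periods × 4 equally spaced visits; no missing
  data, no multiple imputation, no carry-over *estimation* beyond the
  period and interaction terms already in the regression model.
- The non-prioritized pooling rule and the univariate summary are
  configurable conventions; power orderings between GPC variants are
  sensitive to both and to the generator's tie structure. In particular,
  with the default generator the baseline-differenced univariate summary
  is very well adapted to an effect injected at t3 and can outperform the
  prioritized ladder there, and per-pair averaging dilutes multi-visit
  effects relative to prioritization.
- MA inference is permutation-based only; no weighted-Wald or Bayesian
  averaging is provided.
- The ATS denominator-df convention and the GEE working-covariance /
  bias-correction pairing are defaults among several reasonable choices;
  both are exposed in configuration.
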