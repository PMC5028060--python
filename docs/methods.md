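# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical conventions, and the design decisions behind
`esmnet`.  It is written for a reader who wants to know exactly what the
package computes and what its validation does and does not show.

## Data model

One row per scheduled beep: monitored-day index, calendar day (days since
study start), beep index (1–10), scheduled time (minutes since midnight,
450–1350), answered flag, five symptom ratings (integers 1–7, individually
missing-able even on answered beeps), and the daily medication dose in mg.
All validation is strict: ratings outside 1–7, beeps outside the sampling
window, within-day gaps outside [10, 180] minutes, ratings on unanswered
beeps, or a dose/state change within a calendar day are reported as errors
with row numbers rather than silently repaired.

The daily dose maps deterministically to a clinical state
(350 → stable, 400 → impending relapse, 450 → full relapse by default; any
other dose is a hard error unless an override map is supplied).  An
*episode* is a maximal run of consecutive **monitored** days sharing one
state.  Because monitoring covers only ~4 days per week, monitored days are
not consecutive calendar days; episode durations therefore count monitored
days (so durations always partition the monitored days), while episode
start/end are reported as calendar days.  Generator state plans use the
same monitored-day axis.

## Lag pairs

The regression unit is the pair (previous answered beep, current answered
beep) **within one calendar day**.  The lag is the immediately preceding
*answered* beep regardless of how many scheduled beeps were missed in
between: at ~47% completion, requiring adjacent beep indices would discard
most of the data, while overnight gaps (≥ 9 h) are qualitatively different
from the 10 min–3 h design frame and are never bridged.  An optional
`max_lag_minutes` cutoff can drop long same-day gaps (default: keep all);
dropping a pair does not break the chain — the current beep still serves as
the lag of the next one.  An outcome row enters a given regression only if
the outcome rating and all five lagged ratings are present (per-model
casewise deletion), so the five models of one network can use slightly
different row counts.

## Network estimation

Per state (stratification = fitting on that state's pairs only), five OLS
models regress each current symptom on all five lagged symptoms plus
calendar day.  The time covariate is *calendar day*, linear, one per model:
its role is de-trending — slow drift over the study otherwise masquerades
as lagged dependence.  The beep-within-day index is not a covariate.
Coefficients are unstandardized (raw Likert units) by default; a
`standardize` option z-scores outcome and predictors within the stratum.
Matrix orientation is fixed everywhere: `W[i][j]` is the coefficient of
lagged symptom *j* in the model of symptom *i* (column = source at t−1,
row = target at t); the diagonal holds the autoregressive self-loops.
Per-coefficient p-values are the usual OLS t-tests, uncorrected.  Estimation
requires at least 8 complete rows (one more than the 7 parameters);
rank-deficient designs fail with the offending column named; a constant
outcome returns exact zero slopes with an undefined R², flagged degenerate.

The sensitivity method replaces each coefficient with the Spearman partial
correlation between the current symptom and the lagged source, conditioning
on the other four lagged symptoms and calendar day — the same adjustment
set as the regression.  All columns are rank-transformed, the pair is
residualized on the conditioning set by least squares, and the residual
Pearson correlation is the partial correlation; p-values use the t
reference with n − 2 − k degrees of freedom (k = 5).  This equals the
standard recursive/partial-inverse definition and is pinned in a unit test
against an independent implementation (pingouin).  Whether a published
sensitivity analysis of this kind also conditioned on current-time symptoms
is generally unknowable from methods sections; mirroring the regression's
adjustment set is this package's documented choice.

## Centrality

Strengths sum absolute weights (networks legitimately contain negative
coefficients; magnitude-based strength and distance is the convention of the
graphing tools used in this literature, and signs are preserved in all
exports).  Inward strength of *v* is Σ_u |W[v][u]|, outward Σ_u |W[u][v]|,
both including the self-loop, so node strength counts it twice — with a
5×5 lag matrix the self-loop is the single most informative edge and
dropping it would understate a symptom's inertia.

Path indices use edge distance 1/|w| with self-loops excluded; a weight of
exactly 0 (or below an optional threshold) means "no edge".  Closeness of
*v* is 1/Σ_u d(v,u) over **outgoing** shortest distances, 0 when any node is
unreachable (the inverse of an infinite sum).  Betweenness is the Brandes
accumulation of σ_st(v)/σ_st over ordered pairs s ≠ t ≠ v, endpoints
excluded; equal-length path ties are detected to 1e−12.  With continuously
estimated weights exact ties have measure zero, so integer betweenness
values emerge in practice.  Implementation is an in-package Dijkstra/Brandes
(n = 5 makes efficiency irrelevant; correctness is what matters), tested
against an exhaustive simple-path enumeration oracle and against networkx.

## Synthetic generator

Latent dynamics per state s, beep k, calendar day d:

```
x_k = c_s + A_s x_{k−1} + τ·d + ε,   ε ~ N(0, diag(σ_s²))
```

with the first beep of each day drawn from the state's stationary
distribution ("reset", default) or carried across the night ("carry").
Reset is the default because the estimator never uses cross-night lags, so
cross-night dependence is unidentifiable from the fitted networks; reset
keeps days exchangeable.  Observed ratings are `clamp(round(x), 1, 7)` —
chosen over latent-normal thresholding because it keeps a transparent link
whose attenuation the recovery experiments can quantify.  Beeps are
answered i.i.d. Bernoulli(completion), answered items go missing i.i.d.
Bernoulli(item-missing); the defaults 943/2010 ≈ 0.469 and 0.004 reproduce
a frame of 2010 scheduled beeps with ~943 answered and ~939 complete values
per variable.  Beep times are sampled sequentially: each gap is uniform on
[min-gap, min(max-gap, slack)] where the slack guarantees the remaining
beeps fit before the window closes — always feasible, full support.
Relapse episodes are placed either explicitly or automatically (4 full
episodes of 4–25 days and 2 impending episodes of 7–31 days by default,
separated by at least one stable day).

The default dynamics are **test scaffolding, not claims about any real
patient**: a chronic-psychosis-like profile (voices ~5, paranoia ~2.8,
loss of control ~1.6 on the 1–7 scale) with a positive down↔paranoia loop,
a negative relaxed↔paranoia loop, relaxed damping voices (−0.16), down
feeding loss of control (0.21), and denser, stronger coupling during
relapse.  Stationarity (spectral radius < 1) is enforced at validation.

What the generator does *not* emulate: context/appraisal items, event
sampling, reactivity (answering affecting later symptoms), time-of-day
effects, non-Gaussian latent noise, and informative missingness.  Passing
recovery tests therefore show that the estimator recovers the assumed class
of dynamics through the real sampling frame and measurement coarseness —
not that real symptom dynamics belong to that class.

## Validation experiments (`esmnet.simstudy`)

**Attenuation oracle.** Likert rounding/clamping and missed-beep thinning
shrink the estimator's population target below the latent A_s.  The oracle
estimates that target by running the same generator + estimator on ~30 000
single-state days (~10⁵ pairs; Monte-Carlo error ~0.004 per coefficient).

**Parameter recovery.** 50 replicates at study scale (201 days × 10 beeps,
completion 0.469) with the default state-dependent matrices on a balanced
plan (three 67-day blocks, one per state — the naturalistic episode plan
leaves too few relapse pairs to say anything about estimator correctness)
and mid-scale means (keeping all symptoms away from the 1/7 boundaries
separates "does the estimator recover the lag structure" from floor/ceiling
censoring, which the oracle quantifies separately).  Checks: every true
edge with |A| ≥ 0.2 keeps its sign in ≥ 95% of replicates, and the mean
estimate across replicates stays within ±0.06 of the oracle.

**De-trending.** Two series share one seed; one adds a latent drift of
0.0015/day (~2 scale units over 1400 daily-monitored days, ~5000 pairs —
large against the dynamics yet small enough not to saturate the scale,
which would alter the measurement process itself).  Including calendar day
moves lag estimates by < 0.02; omitting it biases them several-fold more.

**Null calibration.** With purely autoregressive truth (no cross edges,
mid-scale means), the fraction of off-diagonal edges with p < 0.05 over 200
study-scale replicates sits at the nominal level for both the regression
and the Spearman-partial networks.

**Relapse-hub signature.** A configuration with a full-relapse connectivity
boost, paranoia as hub (out-edges ±0.35 to all symptoms, in-edges ±0.25),
mood shifted down and relaxation reduced, and a long full-relapse block
(~100 monitored days, so the full-state network rests on ~350 pairs) yields
a pipeline report in which paranoia ranks first on node strength and
betweenness in the full-relapse network and the Welch contrasts flag the
configured down↑ / relaxed↓ shifts.  Edge strengths and block length were
chosen so the signature is identified with high probability at this scale;
with ~70 relapse days and hub edges of 0.30 the betweenness ranking
occasionally ties.

## Numerical conventions and degenerate inputs

Sample (n−1) standard deviations throughout; Welch t for pairwise state
contrasts (α = 0.05, two-sided, no multiplicity correction — group sizes
are very unequal by design); one-way ANOVA for beeps-per-day and
within-day-sd comparisons, with groups of fewer than two observations
dropped and the F statistic undefined (missing, never 0) below two groups.
Summary cells without data are missing, never 0.  Day-level means use
answered, non-missing ratings only.  Completion fraction is answered over
scheduled rows.  All randomness flows through `numpy.random.default_rng`
seeds; derived child seeds stay below 2³¹.  Pipeline exports are
byte-deterministic given config + seed, and the manifest records a SHA-256
content hash for golden-file comparison.

## Known limitations

- Lag-1 linearity on the rating scale; no regularization, no multilevel or
  contemporaneous structure (out of scope by design: n = 1, five symptoms).
- Betweenness on 5-node weighted digraphs is fragile: near-ties in path
  length flip integer betweenness between otherwise similar networks.  Both
  the regression and the rank-based networks' centralities are reported so
  the discrepancy is visible rather than hidden.
- Closeness values scale inversely with coefficient magnitude, so they are
  comparable across states within one analysis but not across differently
  scaled analyses.
- The dose→state mapping treats dose as an exact state proxy; washout and
  transition days are labeled by dose alone.
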