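# Methods

This note documents the models implemented in `modeval`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## The comparative interrupted time series

The target estimand is the change in a community-level daily outcome
attributable to a platform policy that switches on at a known date.  Two
reference points discipline the comparison: (i) a *counterfactual forecast*
of the community's own pre-policy trajectory, and (ii) a *non-equivalent
control* — a thematically matched community the policy did not target, which
absorbs contemporaneous shocks (news cycles, world events) that plausibly hit
both communities alike.  Unlike difference-in-differences, the design needs
no parallel-path assumption: each series is forecast from its own history.

**Pre-period model.**  Each series is fit with a SARIMAX model on the days
strictly before the evaluated policy's start date.  Known earlier enforcement
phases enter as 0/1 exogenous dummies; because the phase table partitions the
calendar, the first phase serves as the reference level against the
intercept.  Orders can be fixed or chosen by a small stepwise AIC search
(differencing order from a KPSS test, (p, q) hill-climbing from four standard
starting models, seasonal (P, Q) over {0, 1} at period S).  The search caps
orders at p, q ≤ 5 and P, Q ≤ 2 to bound runtime.  S defaults to 7 for daily
data (weekly rhythm); S = 1 disables seasonality.  Non-convergence triggers a
retry ladder — more optimizer iterations with a derivative-free polish, then
the differencing order incremented, then a fixed (1,0,0) fallback — with all
fallbacks recorded on the returned fit.

**Simulated counterfactual.**  `B` forecast paths of length `k` (default
B = 1000) are drawn from the fitted model via the state-space simulator,
anchored at the end of the sample, with the evaluated policy's dummy held at
zero.  Parameters are held at their point estimates; parameter uncertainty is
deliberately not propagated — the Z statistic below is defined against the
forecast distribution under the fitted model.  Each path is reduced to its
mean `M_k`; the Monte-Carlo mean `m̂_k` and standard deviation `ŝ_k` of the
`M_k` draws summarise the counterfactual.

**Inference.**  With observed post-period mean `ȳ`,

    Z  = (ȳ − m̂_k) / ŝ_k,
    CI = (ȳ − m̂_k) ± z_crit · ŝ_k,     z_crit = Φ⁻¹(1 − α/2),

so the CI excludes zero exactly when |Z| > z_crit — the two are the same
statement.  The comparative statistic subtracts the comparator's deviation
and pools the forecast spreads.  Because the two communities' forecasts are
independent Monte-Carlo estimates, the variance of the difference is the
*sum* of variances, and `pooling="sum"` is the default.  A `pooling=
"as_printed"` mode computes `sqrt(ŝ²_treated − ŝ²_comparator)` instead — a
form that appears in some applied write-ups — and raises a
degenerate-denominator error whenever the difference is non-positive; it is
provided for reproduction purposes, not recommended.

**Effect scales.**  Average daily differences on the logit scale exponentiate
to odds ratios; on the log-virality scale to relative risks; domain-quality
differences are already on an interpretable additive [0, 1] scale and pass
through untransformed.  CI endpoints transform monotonically.

**Known property: mild anticonservatism at long horizons.**  Holding
parameters at their estimates means the intercept-estimation error
(variance ∝ 1/n) is not reflected in `ŝ_k` (variance ∝ 1/k), so under the
null Var(Z) ≈ 1 + k/n.  At the calibration-study sizes used here
(n = 540 pre-period days, k = 30-day horizon) this inflates the nominal 5%
rejection rate to ≈5.7% and is visible but harmless; at k comparable to n
the inflation grows, which is worth keeping in mind when evaluating very
long policy phases.  The null-calibration and coverage numbers computed by
`scripts/acceptance.py` quantify this directly.

**Multiple comparisons.**  An optional Bonferroni correction widens `z_crit`
across pairs within a measure (`correction="bonferroni"`); default off, and
the choice is recorded in the effect table's metadata.

## Outcome measures

- **Content share** — each community's share of all tweets that day,
  retweets and quote tweets included, Laplace-smoothed
  (`(count + 1) / (total + C)` with C communities) so exact 0/1 proportions
  never reach the logit.  With two communities the logit reduces to
  `log(count_A / count_B)`, which makes a multiplicative volume intervention
  an exact log-odds shift.
- **Virality** — per user-authored tweet,
  `log((retweets + 1) / (followers + 1))`; the add-one smoothing covers
  never-retweeted tweets and zero-follower accounts; the daily value is the
  mean over that community-day's user-authored tweets.  Retweet counts are a
  single at-export snapshot column.
- **Domain quality** — every URL is reduced to its registered domain
  (public-suffix rule; `www.example.com/...` → `example.com`), looked up in a
  [0, 1] quality table; a tweet with several rated URLs gets its *minimum*
  rating; unrated tweets leave the denominator.  Natural logarithms are used
  everywhere; quality stays untransformed.
- **Topic shares** — tweets carry a category label (retweets inherit the
  original's).  Five-rater label tuples collapse to a group by: skepticism
  iff all raters chose skepticism categories; promotion iff all chose
  promotion categories; commentary iff at least one chose commentary and none
  chose the other two sets; other otherwise.  Daily group shares use add-one
  smoothing over the four groups, then the logit.

Monthly aggregation recomputes proportions from monthly counts (then logit),
and averages virality/quality with tweet-count weights — equivalent to
averaging the month's tweet-level values.  Partial calendar months are
included and flagged.

## Missing data

A day is an outage iff it has zero user-authored tweets across all
communities.  Because an outage can straddle day boundaries and leave partial
counts, the days immediately before and after each outage run are dropped
too.  Dropped values are replaced by linear interpolation between nearest
retained neighbours, on the transformed (logit/log) scale, independently per
(community, measure).  Gaps touching the span's edge have only one anchor and
carry the nearest retained value; such days are flagged in the report.
Imputation is idempotent and restores any linear series exactly.  Daily
binning is UTC.  A `--known-outages` override lets users supply an external
dropped-date list instead of detection.

## The fixed-effects (LSDV) model

Monthly outcomes `y_{c,t}` are regressed on platform-wide moderation counts
(content removed, accounts suspended) lagged one month — the lag blunts the
endogeneity of enforcement intensity reacting to misinformation levels — plus
a first-order lagged dependent variable, a dummy per community (one reference
community dropped to avoid the dummy trap; recorded in the fit), and
dummy-by-predictor interactions.  Standard errors are Newey–West HAC with the
automatic truncation `floor(4 (T/100)^{2/9})` and a small-sample `n/(n−k)`
correction.  Transparency counts enter in raw units; a per-thousand scaling
flag is available for conditioning.

Residual stationarity is checked per community with augmented Dickey–Fuller
tests.  On short monthly panels the default long-lag search wastes degrees of
freedom, so the AIC lag search is capped at one tenth of the series length;
the pooled verdict is a majority rule over conclusive per-community tests.
Two properties worth knowing: without interactions and lagged DV, the LSDV
predictor estimates equal the within (demeaned) estimator exactly; and the
lagged-DV coefficient carries Nickell bias of order 1/T (≈0.05 at T = 27
months), which the test suite shows shrinking by an order of magnitude at
T = 270.

## Retweet network

Accounts are nodes; arcs run retweeter → original author (credit flows to the
author; the direction is recorded in graph metadata) with weight equal to the
retweet count for the ordered pair.  The k-core keeps the maximal subgraph in
which every node has at least k *distinct* neighbours, judged on the
undirected adjacency (a weighted-degree variant is available by flag).
Community extraction is Louvain modularity maximization on the weighted
undirected projection, deterministic given a seed; community ids are
stabilized by ordering communities by their smallest member, so node
relabeling permutes but never re-partitions.  Community counts on synthetic
graphs are data-dependent and are not asserted anywhere.

## The synthetic ecosystem

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is validated.

Daily user-authored volume per community follows
`Poisson(baseline · exp(A sin(2πt/7) + u_t) · V_t)` with `u_t` a stationary
AR(1) (φ = 0.5, innovation sd 0.15), weekly amplitude A = 0.10, and `V_t` the
product of active interventions' volume factors.  This log-linear AR-plus-
sinusoid form was chosen to be the kind of process a weekly-seasonal SARIMAX
can fit well, making parameter recovery a fair test of the inference rather
than of model misspecification.  Follower counts are log-normal (median
≈1100, σ = 0.8); retweet snapshot counts are Poisson with mean
`0.05 · followers`, modulated by a per-day log-normal engagement multiplier
(AR(1), sd 0.2) that gives the virality series genuine day-level variance; a
negative-binomial dispersion knob fattens the tails on demand.  Engagement
defaults are set high enough that a multiplicative shift of the retweet rate
passes through the Laplace-smoothed log transform almost losslessly — at low
per-tweet retweet intensities the `+1` smoothing would attenuate the
recovered relative risk below its nominal value (Jensen-type gap), which
would make ground-truth recovery tests ambiguous.

Interventions are step functions.  Volume and virality effects multiply the
respective intensities from the start date; the quality effect reweights the
community's domain mixture toward its extreme-quality domain with the mixing
weight solved in closed form, so the induced additive shift of the mean is
exact in expectation; topic effects shift mixture log-odds.  Every injected
effect is written to a YAML ground-truth ledger so recovery studies never
re-derive truth from the stream.

Retweet *records* (the stream rows with `is_retweet = true`) are generated at
a fixed fraction (0.3) of user-authored volume, sharing the volume
intervention factor, and reference same-day originals with
follower-proportional attachment.  They are deliberately decoupled from the
snapshot `retweet_count_final` column: records drive content counts and the
retweet graph, the snapshot drives virality.  This keeps each injected effect
confined to its own measure and mirrors the real-world distinction between
in-window retweet events and counts-at-export.  Outage days contain no
records at all, while snapshot counts on neighbouring days are unaffected.

All randomness flows from one root seed through `numpy` `SeedSequence`
substreams (one per community, plus streams for the transparency table and
the standalone graph generator), so regenerating one community is stable.
The standalone `generate_retweet_graph` uses preferential attachment
(probability ∝ in-strength + 1) with planted within-community preference
(0.9), producing hub-dominated, approximately scale-free in-degree profiles.

**What the generator does not emulate:** real platform data have burstier
volume dynamics (news shocks), heavier-than-log-normal follower tails,
content-dependent engagement, coordinated/bot behaviour, and topic drift.
Passing recovery tests here therefore shows the *inference machinery* is
correct and calibrated under its stated assumptions — not that those
assumptions hold on any particular platform corpus.

## Validation study sizes

Chosen once, documented here, and reused by both the test suite and
`scripts/acceptance.py`:

- Null calibration and CI coverage: AR(1) pairs with n = 540 pre days,
  k = 30 horizon, B = 200 paths, 300 replicates (150 in the acceptance
  script); expected rejection ≈5.7% (see the anticonservatism note above).
- Ground-truth recovery: two-community ecosystems, 462 days, intervention at
  day 420 (n = 420, k = 42), baseline 120 tweets/day, 100 seeds (40 in the
  script); fixed (1,0,0) orders — the weekly sinusoid cancels in the
  two-community logit and elsewhere inflates the innovation variance
  slightly, which widens CIs conservatively.
- LSDV recovery: 6 communities × 27 months (the transparency-window length),
  β_content = −0.5, β_suspended = 0.3, ρ = 0.3, one interaction 0.4,
  noise sd 0.3, 100 seeds; each structural coefficient is judged against a
  2-HAC-SE band per seed.
- k-core oracle: 200 random directed graphs, ≤50 nodes, against a naive
  repeated-removal loop.

## Numerical details and degenerate inputs

- `ŝ_k = 0` (e.g. a deterministic fit) raises an undefined-statistic error
  rather than returning infinite Z.
- Smoothed proportions keep per-day community shares summing to 1 before the
  transform; the smoothing constant is configurable.
- Malformed URLs are skipped with a warning; tweets with only unrated URLs
  leave the quality denominator.
- Constant exogenous columns are dropped before fitting (they are collinear
  with the intercept on the fit span).
- ADF on constant or too-short residual series reports "inconclusive", never
  an exception.
- Ties in activity ranking break lexicographically by account id, making the
  top-25 lists deterministic.

## Limitations

The CITS machinery validates against synthetic data generated by the model
family it fits; real-data applications must still argue comparator validity
(the non-equivalent control absorbing shared shocks) and watch the k/n
anticonservatism on long horizons.  The LSDV design identifies associations
between enforcement intensity and outcomes under a one-month-lag endogeneity
defence, not causal effects.  The order search emulates common stepwise
practice but is not a bit-for-bit reproduction of any particular library's
search path.
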