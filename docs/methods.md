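# Model and methods

## The belief-revision model

Voters are Bayesian agents with a single binary hypothesis
*h* = "the micro-targeting (MTC) candidate is the right choice". A
campaign message is a *report*: the MTC candidate endorses *h*, the
stochastic candidate opposes it. After a contact the voter replaces
*P(h)* with the posterior

P(h|rep) = P(h)·P(rep|h) / [P(h)·P(rep|h) + P(¬h)·P(rep|¬h)].

The report likelihoods integrate source credibility. Credibility has two
independent components — trustworthiness *P(T)* (intention to report
accurately) and expertise *P(E)* (capability) — and an 8-entry conditional
table *p(rep | h/¬h, T/¬T, E/¬E)* fixed for all voters:

|      | T,E  | T,¬E | ¬T,E | ¬T,¬E |
|------|------|------|------|-------|
| h    | 0.80 | 0.58 | 0.34 | 0.18  |
| ¬h   | 0.22 | 0.42 | 0.59 | 0.71  |

Marginalising over the voter's *P(T)* and *P(E)* (treated as independent)
gives P(rep|h) = Σ p(rep|h,t,e)·w(t)·w(e) with w(T)=P(T), w(¬T)=1−P(T),
etc. An **opposing** message is treated as the negated report: each
likelihood ℓ is replaced by 1−ℓ. (An alternative convention — relabelling
the hypothesis so the opposer "endorses ¬h", giving posterior
P·ℓ_¬h/(P·ℓ_¬h+(1−P)·ℓ_h) — differs from the negated-report form by less
than 3% in likelihood ratio anywhere in the perception space; we use the
negated-report form throughout.)

Properties that follow, and that the test suite asserts: the posterior
stays in [0,1]; an endorsement raises belief iff P(rep|h) > P(rep|¬h)
(the reverse inequality is the **backfire region** — with this table a
voter who rates a source at trust = expertise = 0.5 or below backfires,
at 0.6 does not); the posterior is strictly increasing in the prior; and
certainty (P(h) ∈ {0,1}) is absorbing. A zero denominator (possible only
with degenerate likelihoods) returns the prior unchanged and logs a
warning rather than producing a NaN.

Trust and expertise are **fixed for the whole simulation**; only *P(h)*
updates. Joint posterior updating of source perceptions is deliberately
out of scope.

## The electorate

Each of the 10,000 voters draws, in this fixed order from one seeded
generator: belief P(h) ~ N(0.5, 0.25) clamped to [0.01, 1]; turnout
propensity P(vote) ~ N(0.5, 0.25) clamped to [0.01, 1]; then trust and
expertise for each candidate, independently N(μ_cred, 0.25) clamped to
[0.01, 0.99]. Conventions worth noting:

- **Clamping, not rejection-resampling.** Out-of-bound draws are set to
  the bound. This leaves point masses at the bounds (≈2.3% of voters at
  belief exactly 1.0, which is absorbing under both message types).
- The belief bound is asymmetric ([0.01, 1], not [0.01, 0.99]) by
  convention; source perceptions are kept off 0 and 1 to exclude
  degenerate certainty about sources.
- The per-voter **credibility score** for a candidate is
  (trust + expertise)/2; the MTC screens on it.

P(vote) never changes after initialization.

## Campaigns and the daily cycle

Per tick (day), each campaign contacts up to `reach` voters (MTC default
20). The MTC samples uniformly without replacement from the *eligible
pool*: voters with 0.25 < P(h) < 0.75 (strict), credibility score ≥ 0.5
(inclusive), and P(vote) > 0.5 (strict), recomputed every tick from
start-of-tick beliefs, so the campaign adapts as beliefs move. The
stochastic campaign samples uniformly without replacement from the whole
electorate. A voter can be contacted at most once per campaign per day,
but by both campaigns on the same day, and repeatedly across days.

Within a tick both contact lists are drawn from start-of-tick state, then
belief updates are applied in a fixed order: all MTC contacts, then all
stochastic contacts. The order is a reproducibility convention; a
sensitivity test (swapped order across 40 seeds) confirms the aggregate
effect is negligible because double contacts are rare.

After the final tick each voter casts a ballot with probability P(vote):
for the MTC candidate if P(h) > 0.5, the stochastic candidate if < 0.5,
by fair coin at exactly 0.5 (reachable only through degenerate
configurations, but defined for completeness).

## Randomness and reproducibility

One `numpy` PCG64 generator per run, seeded from the run seed, consumed
in a documented order: six population vectors, then per tick the MTC
sample followed by the stochastic sample, then one turnout vector and one
tie-break vector at the election. Sweep runs derive per-run seeds from
`SeedSequence([base_seed, cell indices, rep])`, so results are
independent of execution order and identical configs give bit-identical
results. The test suite checks the vectorised engine against a naive
per-agent loop implementation for exact tally equality at n = 200.

## Experiments

The headline sweep crosses μ_cred ∈ {0.4, 0.5, 0.6} for each candidate
with ten reach ratios (0.5–5.0 in steps of 0.5, i.e. stochastic reach
10–100 against the MTC's fixed 20; non-integer scaled reaches round to
nearest) and 100 repetitions per cell: 9,000 runs. Per cell we report the
mean MTC share of cast votes; the **break-even ratio** is the smallest
ratio at which the linearly interpolated mean-share curve crosses 0.5
(`none in range` when it does not). Linear interpolation between adjacent
grid means is the simplest defensible estimator; because the share-vs-
ratio curves are shallow (≈0.005–0.007 share per unit ratio), the
crossing location is sensitive to small vertical shifts — a ±0.002 shift
in mean share moves it by ±0.3 — so break-even estimates should always be
read together with the repetition count.

The reproduction script sweeps a finer grid (step 0.25) bracketing each
expected crossing with 50 repetitions per ratio. Where a check leaves the
repetition count open we use 30 (reach-liability rank correlation) or 50
(dominance across the grid) repetitions, balancing Monte-Carlo error
against runtime at full scale.

## What the generator does and does not emulate

The synthetic electorate reproduces the study conditions exactly:
population size, distributional means/sds, bounds, and the two-candidate
zero-sum belief structure. It does not emulate features of real
electorates such as correlated perceptions across voters (e.g. partisan
media environments), social influence between voters, policy-based
preferences, turnout responsive to the campaign, or noisy voter data on
the MTC's side. Passing tests therefore demonstrate properties of the
idealised model — with a *perfect* voter model the MTC's measured
advantage is an upper bound on what noisy targeting data could deliver —
not claims about any actual election.

## Known limitations

- Break-even locations, unlike the qualitative strategy findings, are
  sensitive to implementation conventions that the model description
  leaves open (out-of-bound draw handling, the opposing-message formula,
  within-tick scheduling). Under the conventions above, the equally-liked
  cell (0.6 vs 0.6) breaks even near ratio 3.9–4.1 and the
  disadvantaged-MTC cell (0.5 vs 0.6) near 2.9–3.1 at 50 repetitions per
  ratio.
- The election is a single national popular vote; no districts,
  abstention dynamics, or multi-candidate races.
- Campaign reach is exogenous; there is no budget, cost per contact, or
  diminishing returns.
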