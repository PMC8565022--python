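# Methods

## Elicitation protocol

The interview administers, per health state, a rating-scale question
followed by a standard-gamble titration seeded from the rating.

**Rating scale.** A rating r ∈ [0, 100] maps to the coefficient r/100.
Out-of-range ratings are rejected rather than clamped: a rating outside the
anchors indicates a protocol error, not a preference.

**Standard-gamble titration.** The published protocol specifies the first
proposed risk (1 − UC_RS) and that the risk is then raised or lowered
according to the answers until the respondent cannot decide, but not the
adjustment schedule. We use bisection on the bracketing interval
[p_low, p_high], initialised to [0, 1]:

- *accept* at risk p ⇒ the indifference risk is ≥ p ⇒ p_low ← p;
- *reject* at p ⇒ p_high ← p;
- next proposal = midpoint of the bracket.

Bisection is deterministic, never widens the bracket, and converges in
⌈log₂(1/tol)⌉ midpoint steps. Stopping: an explicit *indifferent* answer
(UC = 1 − p at that risk), bracket width ≤ `tolerance` (UC = 1 − bracket
midpoint), or `max_steps`. Defaults: tolerance 0.01 — one point on the
0–100 rating scale, so both instruments resolve preferences equally — and
max_steps 30 (bisection needs ≤ 7 for tolerance 0.01; the cap only guards
degenerate answerers). A refusal of any risk is accepted only at the first
question, per protocol, and yields UC = 1 exactly. A degenerate first risk
of 0 or 1 (rating at an anchor) is clamped into [tol, 1 − tol]: a zero-risk
gamble is vacuous and a certain-death gamble uninformative. Proposed risks
are kept at full floating precision; elicited extremes such as 0.005 or
0.075 in the reference statistics indicate sub-percent resolution was used
in practice, so no presentation rounding is applied in the engine (a CLI
may format as it likes).

**Time trade-off** is implemented (UC = t₂/t₁ with 0 ≤ t₂ ≤ t₁) for
completeness but is not part of the default pipeline, which mirrors the
two-question RS+SG design.

## Synthetic respondents

The generator emulates the statistical structure of the 47-interviewee
study so the full pipeline can be exercised without the raw data.

- **Latent RS utility** per state: Beta distribution parameterised by mean
  μ_s and sd σ_s, with (α, β) matched by moments (feasibility σ_s² <
  μ_s(1 − μ_s) is validated). Defaults anchor μ_s, σ_s to the bundled
  published per-state RS mean and sd.
- **Latent SG utility**: the deterministic distortion
  u_SG = 1 − (1 − u_RS)^(1/γ), γ ∈ (0, 1]; γ < 1 pushes valuations toward
  1, reproducing the strong skew of SG relative to RS. Default γ = 0.35,
  chosen so that for mid-range states the simulated SG median clears the RS
  upper quartile, as observed.
- **Refusals**: with probability `refusal_prob` (default 0.25) a respondent
  whose latent SG utility for a state is ≥ `refusal_threshold` (default
  0.90) declines any risk outright, producing the exact-1 valuations that
  dominate the upper tail of published SG distributions.
- **Rating noise**: ratings are clamp(round(100·u + ε), 0, 100) with
  ε ~ N(0, rs_noise_sd²), default sd 5 points — a plausible re-test spread
  on a 101-point scale.
- **Indifference band** δ (default 0.01): the respondent answers
  "indifferent" when the gamble's certainty equivalent is within δ of the
  latent utility.
- **Demographics**: categorical fields drawn from the bundled study
  composition (sex 33 F / 14 M; education 7/4/36; family situation 7/2/38);
  ages from a truncated normal on [21, 68] whose *truncated* mean is
  calibrated (by root-finding on the location parameter) to the observed
  mean 40.8 with scale 14.79. The study does not publish profession or
  marital-status compositions (only "unemployed", "commercial activities"
  and "married" are mentioned); the bundled defaults are plausible,
  clearly-replaceable category lists, and both fields are free-text in the
  profile type.

All randomness derives from one integer seed; each (respondent, state,
purpose) triple gets an independent substream via a CRC32-keyed
`SeedSequence`, so results are independent of evaluation order and
reproducible record-for-record.

What the simulator does *not* emulate: within-respondent correlation across
states beyond the shared demographic profile (latent draws are independent
across states); interview duration and learning effects; the exact
incidence of SG medians equal to 1.0 for every mid-range state (the default
refusal rate reproduces the upper-tail mass only partially); and any causal
dependence of utilities on demographics — simulated age/sex correlation
tests should therefore come out null on average, which is precisely what
makes them useful as a calibration of test size, not of effect estimates.
Passing tests show the machinery recovers known ground truth under this
model, not that the model captures every feature of real interviews.

## Analysis conventions

- **Quantiles**: linear interpolation between order statistics (the common
  default of mainstream statistical environments); sd is the sample (n − 1)
  estimate. The source tables do not state a convention; this choice only
  affects synthetic-data summaries, not the bundled reference values.
- **Confidence intervals**: normal approximation mean ± z·sd/√n with
  z(0.95) = 1.959964. Validated against the published per-state bounds at
  n = 47: 53 of the 54 printed numbers are reproduced after 2-decimal
  rounding. The single exception (state 4's upper bound, printed 0.89,
  computed 0.885 → 0.88 — all 54 match only if the denominator uses n − 1)
  appears to be an off-by-one in the original analysis; we keep the
  standard formula and the documented n. t-based intervals are ~3% wider
  at this n and reproduce fewer of the printed bounds.
- **Rounding for reporting**: half-up decimal rounding (3 decimals for
  summary tables, 2 for CI tables), matching the reference tables; internal
  computation is at full precision.
- **Ranking**: states ordered ascending by mean; ties broken by state id
  (no ties occur in the reference data). Concordance reports matched
  positions and the longest shared worst-prefix/best-suffix runs.
- **Spearman**: midrank ties, p-value from the t-approximation
  (`scipy.stats.spearmanr`); undefined (NaN) when a margin is constant.
- **Rank-sum**: two-sided Mann–Whitney; exact enumeration when both groups
  have ≤ 25 observations, continuity-corrected normal approximation
  otherwise. The overall male-vs-female comparison pools each respondent's
  18-state mean UC into one observation per respondent — the pooling behind
  the published test is unstated, and this unpaired per-respondent-mean
  variant is our documented assumption.
- **LOWESS**: local linear fits, tricube weights over a span of 2/3, three
  bisquare robustness iterations (`statsmodels`), evaluated at the observed
  abscissae.
- **Sample size**: smallest n ≥ 2 with t(1 − α/2, n − 1)·sd/√n ≤ margin,
  found by forward iteration (the half-width is monotone decreasing in n).
  The published computation (n = 38 for margin 0.05, sd 0.15, 95%) is
  reproduced by this t-based rule; the closed-form z rule gives 35 and is
  exposed behind `method="z"` for comparison.
- **QALY discounting**: optional continuous discounting; a segment entered
  at elapsed time a contributes UC·(e^(−ra) − e^(−r(a+T)))/r. Default rate
  0, so the plain weighted sum Σ Tᵢ·UCᵢ holds exactly.

## Data and formats

UC repositories are CSV with fixed header
`respondent_id,state_id,method,value,n_steps,refused_gamble`; values are
serialised with full precision so write∘read is the identity. State
catalogs and respondent profiles are JSON. SNOMED CT validation is
syntactic only — each token must match `code|term|` with an all-digit
code — because the codes serve as labels here, not as a reasoning
substrate; no terminology server is consulted. The bundled comparator file
carries the prior North-American study's published means/CIs, with state 11
(post-operative hemorrhages) missing there and kept as NA. The single
bundled scenario factsheet is an explicitly synthetic stand-in (the study's
French factsheets are not redistributable); factsheet content is opaque
data, never interpreted.

## Problem sizes in the test suite

Deterministic checks run at the study's own sizes (18 states, 47
respondents, 1692 records). Monte-Carlo checks use: 10⁴ draws for
distribution anchors, 10³ replicates for oracle agreement and test size,
200 respondents for parameter recovery (±3 Monte-Carlo standard errors),
and a 101-point exhaustive grid for titration recovery. These sizes give
standard errors well inside the asserted tolerances while keeping the suite
fast.
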