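# Methods

This note documents the models, conventions and numerical choices behind
`sharktrace`, and what the synthetic-data tests do and do not demonstrate.

## Data model and conventions

Detections are `(tag_id, station_id, timestamp)` triples. Timestamps are
stored in UTC; *behavioural* quantities (days at the island, diel angles)
are computed in local time via a configurable offset (default −6 h,
Cocos Island). All intervals — receiver deployment windows, residence
events, calendar days — are half-open `[start, end)`, so adjacent
intervals never double-count an instant; a detection at the exact end of a
deployment window is outside it. Detection sorting is total:
`(tag, timestamp, station)`, making same-instant detections at two
receivers (overlapping ranges) deterministic. Exact duplicate rows are
collapsed rather than rejected, because receiver downloads can overlap.

## Residence-event segmentation

Events follow the V-track criteria for VEMCO arrays: `min_pings = 2`
successive detections at one receiver with inter-detection gaps
≤ `timeout_s = 900` open an event (start = first of those detections);
the event ends at its last own-station detection and closes on (a) a gap
> 900 s (*timeout*), (b) ≥ 2 detections at a *single* other receiver since
the last own-station detection (*other_station*), or (c) stream end.
Choices the criteria leave open, fixed here:

- Cross-station termination counts detections at a single other station,
  not pooled across stations, and those detections must themselves satisfy
  the 900 s gap rule — they seed the candidate event at the new station
  under exactly the opening rule. An own-station detection resets all
  other-station accumulators.
- The timeout check runs before anything else at each detection, so a
  late other-station ping first times the open event out and then counts
  toward a new candidate.
- The transit threshold is strict: an event of exactly 15 min is a visit.
  Duration is last-minus-first detection time, a lower bound on true
  occupancy (one-ping margins at each end).

Gap arithmetic is done in integer nanoseconds: at epoch magnitudes,
float64 seconds cannot represent microsecond timestamps exactly and
boundary comparisons (gap == timeout) would become unstable.

## Residency index

`RI = |detected days| / monitoring days`, with monitoring days counted
from the tagging date through the last detection date *inclusive* — an
animal tagged and detected only that day has RI = 1/1, matching the
convention that RI = 1 means daily presence. Days are local-time days. RI
is invariant to detection multiplicity within a day. Cohort summaries use
the sample SD (n−1); a single-animal cohort reports SD 0 with n = 1 so
callers can flag it. The monitoring-duration/RI association is reported as
a Pearson correlation with df = n−2.

## Tagging-bias correction

Because animals are necessarily at the tagging receiver when tagged, the
initial portion of each track would inflate apparent preference for that
site. The analysis window starts at the earlier of (a) the first visit at
any other receiver and (b) the first visit at the tagging receiver that
follows ≥ 24 h of absence from it; earlier visits are dropped, and tracks
where neither rule fires are dropped whole. Literal re-application of
these rules to an already-corrected track would truncate it again (a
rule-(b) track again starts at the tagging receiver), so the corrected
state is made explicit: the operation returns a `CorrectedTrack`, and
passing a `CorrectedTrack` back in is the identity. That makes the
correction idempotent at the API level without altering the rules.

## Site-preference mixed model

Log visit duration in hours is modelled as a one-way random-intercept
linear mixed model: `y = Xβ + Zb + ε`, `b ~ N(0, σ²_g I)` per shark,
`ε ~ N(0, σ²_r I)`, with site a reference-coded fixed effect (reference
"Alcyone" when present). The log transform is the package default because
dwell processes are multiplicative and heavy-tailed; an identity-response
option exists.

Fitting profiles β and σ²_r analytically given the variance ratio
λ = σ²_g/σ²_r — per-group algebra uses the rank-one structure
`(I + λJ)⁻¹ = I − λ/(1+λn_i) J` and `|I + λJ| = 1 + λn_i` — and maximises
the profiled (restricted) log-likelihood over log λ ∈ [−12, 12] by bounded
scalar search (tolerance 1e−10), with the boundary λ = 0 (OLS) checked
explicitly. REML is the default for variance components; likelihood-ratio
tests of the site effect refit both models with ML, since REML
log-likelihoods are not comparable across fixed-effect structures.

Coefficient and contrast p-values use Satterthwaite degrees of freedom:
`df = 2 f² / Var(f)` with `f = cᵀ C(θ) c`, the variance-component
covariance taken as the inverse observed information of the REML
log-likelihood (central finite differences). If the information matrix is
not usable (boundary fits), the residual df is used and the fit is flagged
(`df_normal_fallback`). Pairwise contrasts cover all 15 unordered site
pairs with Holm adjustment — conservative and assumption-free, chosen
because no particular dependence structure can be assumed among the
contrasts. For each contrast the df is the minimum Satterthwaite df of the
coefficients involved, a conservative shortcut.

## Diel statistics

The periodogram operates on mean-removed hourly counts (by default
*distinct sharks per hour*, since a single resident animal contributes
thousands of pings; raw detection counts are available) via
`scipy.signal.periodogram`; the dominant period is the reciprocal of the
maximal-power frequency, and a constant series yields a no-peak sentinel.
At least 48 hourly bins are required to resolve a 24 h cycle.

Circular statistics treat each *detection* as an angle on the 24 h clock
(hour + minute/60 + second/3600, × 15°; no binning loss). The mean
resultant length r and mean angle come from the resultant vector;
Rayleigh Z = n·r² with the standard second-order large-n p approximation.
Rao's spacing statistic U = ½ Σ|Tᵢ − 360°/n| over sorted circular gaps is
calibrated by seeded Monte-Carlo (default 10,000 uniform samples;
p = (1 + #{U* ≥ U})/(reps + 1)), chunked to bound memory at large n —
printed critical-value tables are quantized, whereas the Monte-Carlo null
is exact up to sampling error and itself testable for uniformity.

## Movement networks and inter-island transfers

Each consecutive pair of residence events of one animal at distinct
receivers increments one directed edge; same-station pairs are ignored
unless self-loops are requested, and an optional maximum-gap flag can
suppress transitions across long absences (default: all pairs count,
regardless of elapsed time). Degree is the number of distinct partner
nodes. An island-aggregation mapping collapses stations to islands for
regional networks.

Transfers are island change points in each tag's detection sequence;
travel time (last detection at origin → first at destination) is a lower
bound on time at sea, so the derived straight-line speed
`distance/time` is a lower bound too. Route distances default to the
published great-circle values (Cocos–Galapagos 710 km, Cocos–Malpelo
627 km), with a haversine fallback from station coordinates for unlisted
routes. The median of an even trip count is the midpoint of the central
pair. Very long "travel times" can include undetected interludes (an
animal may go unseen for years between arrays); they are reported as-is.

## Synthetic generator

Defaults encode the focal study conditions: 17 sharks on the six-station
Cocos array (14 tagged at Alcyone, 2 at Roca Sucia, 1 at Manuelita; sexes
drawn 62% F / 1% M / 37% undetermined), daily presence probability 0.52,
diel window 06:00–18:00 local with a 2% chance a visit runs past dusk,
site dwell times lognormal on log-hours with site means equal to the
fitted site effects (intercept 1.22804, offsets −1.46012 … −0.46899) and
variance components σ²_g = 0.2912 (per-shark) and σ²_r = 1.0636
(per-visit), a stay-biased Markov chain over sites (stay probability 0.5,
uniform otherwise), 60–90 s uniform ping delays, detection probability 1
within 150 m decaying linearly to 0 at 300 m with a per-visit uniform
distance draw (the range test gives only the two radii; this is the
simplest model consistent with a steep fall-off), 1350-day tag battery,
and a 0.001/shark-day migration rate with lognormal travel times (median
≈ 33 d) to single-station Galapagos/Malpelo arrays. `study_days` defaults
to 120 — a realistic multi-month deployment chosen to keep default
datasets a few hundred thousand detections; the longer windows of real
campaigns are a config field away.

Randomness uses one substream per shark (`SeedSequence(seed, spawn_key)`),
so adding sharks never perturbs existing tracks, and output is
byte-reproducible given the seed.

What the generator does *not* emulate: continuous-space movement (distance
to the receiver is redrawn per visit, not per ping), acoustic propagation
physics, tide/current or seasonal effects, clock drift, tag shedding or
mortality, and collisions between co-located tags. Passing recovery tests
therefore show that the pipeline correctly inverts *this* observation
model — e.g. that RI and visits are recovered exactly under full
detection — not that real-array detection efficiency is unbiased. Indeed
the generator makes one real-data pathology visible: with range-dependent
detection, long true visits fragment into shorter events and the fitted
site effects and between-shark variance attenuate relative to the dwell
model that generated them.

## Problem sizes and numerical checks

The test suite validates against independent oracles: a separately coded
brute-force replay of the segmentation rules (1,000 fuzzed streams plus
property-based cases), brute-force evaluation of the bias-correction
rules (400 randomized sequences), dense-likelihood Nelder-Mead
maximisation and statsmodels `MixedLM` for the mixed model (agreement to
1e−4), and closed forms for the circular statistics (r = 1/Z = n for
identical angles, r = 0 and U = 0 for perfect uniformity, the Bessel
ratio I₁(κ)/I₀(κ) for von Mises samples). Calibration studies use 1,000
null likelihood-ratio simulations (size within [0.03, 0.07] at α = 0.05)
and 200 replicates of the 17-shark × 6-site design (95% CI coverage, the
near-identical Dos Amigos/Roca Sucia pair least often rejected). The
acceptance script repeats these at moderately reduced replicate counts so
the whole report recomputes in well under a minute.

## Known limitations

- The mixed model supports a single random intercept only — no crossed or
  nested effects, random slopes, or non-Gaussian responses.
- Event segmentation does not correct for detection efficiency; transit
  classification depends on a fixed swim-speed assumption.
- The RI denominator convention (inclusive local days) and the response
  transform of the duration model (log hours) are defensible but not
  unique; both are configurable.
- Rao's Monte-Carlo p-value is exact only up to `1/(reps+1)` granularity.
- Transfer travel times are bounds, not estimates, and can be inflated by
  detection gaps.
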