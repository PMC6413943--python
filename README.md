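# sharktrace

Residency analysis for passive acoustic telemetry of reef-associated
sharks. The package implements the full analysis chain used to quantify
how strongly scalloped hammerhead sharks (*Sphyrna lewini*) associate with
an oceanic island monitored by a small array of fixed acoustic receivers —
and ships a seeded simulator of the observation process so every stage can
be validated against known ground truth.

## What it computes

Given detection logs (tag ID, receiver, timestamp), receiver metadata and
tagging metadata, the pipeline produces:

- **Residence events** — per-tag detection streams are segmented with the
  V-track criteria: an event at a receiver opens after ≥ 2 successive
  pings with gaps ≤ 900 s, extends while pings continue, and terminates on
  a 900 s timeout, on ≥ 2 pings at a single other receiver, or at stream
  end. Events shorter than 15 min (the time to cross a receiver's
  detection range at ~0.5 m s⁻¹) are flagged as transits.
- **Residency index** — RI = (days detected at the island) / (days from
  tagging through last detection, inclusive), so RI = 1 is daily presence.
  Cohort summaries (mean ± SD, long-monitoring subsets, duration–RI
  correlation) and tag × date presence matrices.
- **Tagging-bias correction** — each track is truncated to start when the
  animal is first seen away from its tagging receiver, or after ≥ 24 h of
  absence from it, whichever comes first.
- **Site-preference mixed model** — log visit duration (hours) modelled as
  `y = β_site + b_tag + ε`, with `b_tag ~ N(0, σ²_g)` a per-shark random
  intercept and `ε ~ N(0, σ²_r)`. Fitting profiles β and σ²_r given the
  variance ratio and maximises the (restricted) likelihood in one
  dimension; a likelihood-ratio test (ML) compares against the
  intercept-only null, and all 15 site pairs get Wald contrasts with
  Satterthwaite df and Holm adjustment.
- **Diel statistics** — hourly binning (detections or distinct sharks per
  hour), an FFT periodogram of the presence series with its dominant
  period, and circular statistics on the 24 h clock (15°/hour): mean
  resultant length r, Rayleigh Z = n·r², and Rao's spacing test with a
  seeded Monte-Carlo p-value.
- **Movement networks** — directed counts of consecutive-event transitions
  between receivers (networkx graph, edge-list CSV and GraphML exports),
  node degree as distinct partners.
- **Inter-island transfers** — change points in island-labelled detection
  sequences; travel times (last detection at origin → first at
  destination) and straight-line speeds over great-circle route distances
  (Cocos–Galapagos 710 km, Cocos–Malpelo 627 km by default).
- **Synthetic data** — a generator emulating 60–90 s pseudorandom ping
  delays, detection probability decaying linearly from 150 m to 300 m,
  diurnal (06:00–18:00) island presence with Markov-chain site hops and
  lognormal dwell times, receiver downtime, and rare inter-island
  migrations, with full ground truth for recovery scoring.

## Worked example

```python
from sharktrace import (SimulationConfig, simulate, segment_all, classify_visits,
                        track_summaries, summarize_ri, fit_lmm, lrt_site_effect)
from sharktrace.residency import correct_cohort
from sharktrace.site_model import visits_to_records

result = simulate(SimulationConfig(n_sharks=17, study_days=120, rng_seed=1))
events = segment_all(result.detections)
visits = classify_visits(events)
summ = track_summaries(result.detections, result.tags, -6.0,
                       stations=result.stations, island_id="Cocos")
ri = summarize_ri(summ)

corrected, _ = correct_cohort(visits, result.tags)
records = visits_to_records(corrected)
fit = fit_lmm(records, criterion="REML")
lrt = lrt_site_effect(fit_lmm(records, "ML", intercept_only=True),
                      fit_lmm(records, "ML"))
```

This prints (via the obvious `print` calls):

```
267586 detections from 17 sharks
4282 residence events, 903 transits (<15 min)
residency index 0.51 +/- 0.05 SD (n=17)
visit-duration model: sigma2_tag=0.0583, sigma2_resid=1.5654
site effect: chi2(5) = 413.49, p = 3.67e-87
```

Reading: 17 simulated sharks monitored for 120 days were detected on about
half of their tracked days (the generator's daily presence probability is
0.52; conditioning on detection nudges the estimate up slightly). Site is
an overwhelmingly significant predictor of log visit duration — the
generator gives each site a different mean dwell — while the observation
process (range-dependent detection, diel clipping, event fragmentation)
attenuates the recovered between-shark variance relative to the dwell
model's inputs, which is exactly the kind of bias the simulator exists to
expose. The same stages are available from the shell:

```sh
sharktrace simulate --seed 1 --out sim/
sharktrace run --detections sim/detections.csv --stations sim/stations.csv \
    --tags sim/tags.csv --deployments sim/deployments.csv --out out/
```

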