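# Methods

This note records the models, conventions and numerical choices behind
herdscope, in the order the pipeline runs.

## The synthetic herd generator

The simulator exists so that every analysis stage has a recoverable ground
truth. It is a movement model plus three observation models, all driven by
one seeded RNG (`rng_seed`); identical configs give identical output.

### Movement

Positions live in a planar metre frame with the night camp at the origin;
GPS output converts to latitude/longitude by a small-area equirectangular
approximation around a configurable reference point (default 28.72299 N,
83.97360 E). Working in metres keeps all distance logic unambiguous; the
conversion error over a few kilometres is negligible against GPS noise.

Each animal follows a correlated random walk updated every `step_seconds`
(default 60 s): velocity persistence 0.8, per-axis innovation
`wander_speed_sd` = 0.15 m/s (grazing-scale wandering). Three steering
terms are added, each scaled by the animal's *sociability* 1 − independence:

- **Shepherd schedule** — during the day window (default 06:00–17:00 local)
  a drift of up to `travel_speed` = 0.5 m/s toward the pasture centre, and
  toward camp in the last `return_lead_minutes` = 60 of the day. The drift
  tapers linearly inside 50 m of the target so animals graze around it
  rather than collapsing onto it.
- **Herd centroid attraction** — a fractional pull of
  `attraction_strength × (1 − independence) × 0.05` per minute toward the
  current centroid. This is the knob the cohesion-recovery tests turn.
- **Night camp pull** — at night animals relax toward camp at
  `night_home_rate` = 0.05/min with innovation `night_noise_sd` = 2 m/min,
  giving a stationary bedding spread of about 6 m per axis: animals rest
  scattered over the camp area rather than in a single heap, so the 3 m
  proximity radius is informative at night.

`independence ∈ [0, 1]` discounts **every** steering term: a fully
independent animal is a pure random walker day and night (this is what the
unconstrained-diffusion test exploits). In the study-conditions factory
(`study_config`) independence rises linearly with age from 0.05 (juveniles)
to 0.45 (a 13-year-old female), encoding the field observation that older
animals drift on their own while juveniles stick to the herd; this is what
makes the per-individual signal mean fall with age.

Untethered night movement gets a noise burst (×6) within ±1 h of
`night_activity_peak_hour` (default midnight), producing the nocturnal
activity peak. Tethered animals — the juveniles, when `tether_enabled` and
the day index has reached `tether_start_day` — are held within 2 m of their
assigned tether spot (default: a line of spots 1.5 m apart near camp).
The tether is physical, so it overrides independence.

### Observation models

- **Activity** (0.1 Hz): per 10-s epoch, magnitude = 30 × step speed (m/s)
  + half-normal sensor noise (σ = 2 counts). Activity is therefore a pure
  function of movement plus noise, so diel activity structure in the output
  is exactly the movement schedule.
- **Proximity** (1-min cadence): a dyad emits a record in a minute iff its
  true distance is ≤ `rssi_cutoff_m` = 3 m. RSSI is piecewise linear in
  distance through the two calibration anchors (−45 dBm at 1 m, −90 dBm at
  2.5 m), clamped at −45 below 1 m, plus Gaussian jitter (σ = 3 dBm). A
  linear interpolant is the simplest curve through two anchors; nothing
  downstream uses the RSSI value itself, only record existence.
- **GPS**: true position + isotropic Gaussian noise (σ = 5 m), sampled
  every 60 s during the day and every 600 s at night.

Logger battery death truncates all three streams of an animal at the same
instant — unequal recording arises from battery life, not sensor dropouts.
The `study_config` factory kills ~1 in 5 loggers 50–95 % of the way through.

### What the generator does not emulate

No behavioural states (grazing/resting/travelling HMM), no terrain or
forage gradients, no predator encounters, no dyadic preferences beyond the
tether, no GPS multipath autocorrelation, no RSSI dependence on body
orientation or vegetation. Passing recovery tests therefore shows the
*pipeline* is correct under known conditions; it does not validate any
ecological claim about real herds.

## Association matrices

Time is discretised into minute bins; a bin belongs to a logger's
on-window, and to day or night, according to the bin's start. For each dyad,
`raw_count` is the number of bins with ≥ 1 record and `effort` the number of
bins with both loggers on; `rate = raw_count/effort`, undefined (NaN,
flagged) where effort is zero. Effort is the *intersection* of the two
on-windows: when all loggers start together — the deployment practice the
data model assumes — this equals the shorter of the two recording times,
which is the classic minimum-recorded-time correction.

"Mean signals" per individual averages `rate × window-minutes-per-24 h`
over partners with positive effort (day rates scale by the day-window
length, 660 min by default; night by its complement). Averaging over
partners is the default; summing is available (`how="sum"`) since either
reading of a per-individual mean is defensible — the choice affects
magnitudes, not signs or orderings.

Day/night split is half-open local time: [06:00, 17:00) is day, so a
record at exactly 17:00 is night. A night window is labelled with the date
its evening starts (pre-dawn minutes belong to the previous date's night).

## Modularity

Community search is Louvain (networkx) with 25 seeded restarts; the best-Q
partition is kept and relabelled canonically by lowest member id, which
makes the output deterministic and restart-order independent. Q is
recomputed in-repo from the weight matrix (Newman–Girvan, weighted), so the
reported value is always self-consistent with the returned partition. The
test suite checks the search attains the exhaustive-enumeration optimum on
all graphs up to 8 nodes. Resolution defaults to 1.0.

## Trajectories

Speed filtering is a greedy forward pass: keep the first fix, then keep
each fix iff its haversine speed from the last *kept* fix is ≤ `vmax`
(default 6 km/h — faster than a grazing yak moves). Greedy forward removal
is deterministic, idempotent, and the common practice in trajectory
cleaning. Distances are spherical haversine (mean Earth radius); sub-metre
error at herd scale.

Regularisation places slots every 2 min (configurable) from a grid origin
(shared across animals when scan clustering will follow). A slot takes the
nearest fix within half an interval; otherwise it is linearly interpolated
iff the raw fixes bracketing it are ≤ `max_fill_gap` = 20 min apart, else
flagged as a gap with no position. The 20-min default lets the night
10-min GPS cadence interpolate while refusing to fabricate positions
across multi-hour dropouts.

## Cohesion scans

Scans default to every 30 min. Two animals are linked when their
separation is below the threshold — `degrees` mode uses the either-axis
(Chebyshev) rule max(|Δlon|, |Δlat|) < t, `metres` mode geodesic distance —
and subgroups are connected components (union-find), so chains merge
transitively. Scans with fewer than two present animals are flagged
low-coverage and excluded from fractions and tests.

The degree-mode default threshold is 0.5°. At this latitude 0.5° is tens of
kilometres, so on a single pasture it yields one subgroup almost always;
it is retained as the literal convention, while metre mode (the recovery
tests and the acceptance run use 50 m) is the physically meaningful rule.
The calibration recipe for real data: choose the smallest threshold at
which the herd is a single subgroup in a clear majority of scans and the
subgroup count stabilises.

Diel periods: hourly bins by local clock hour, and six 4-h periods
anchored at 01:00 (01–04, 05–08, …, 21–00). The omnibus test is
Kruskal–Wallis over period groups of the per-scan subgroup count; pairwise
Mann–Whitney tests are reported with Benjamini–Hochberg adjustment at 0.05
alongside the unadjusted p.

## Statistics conventions

All tests are rank-based with midrank ties. Degenerate inputs carry no
evidence and return statistic 0 with p = 1: a Kruskal–Wallis where every
value is identical, or a paired Wilcoxon whose differences are all zero.
Constant vectors in a Spearman correlation raise instead (the correlation
is undefined, not null). Activity comparisons are offered both pooled over
epochs (maximal power, pseudo-replicates individuals) and per-individual
means (the individual as the unit); pooled is the default, but with ~10⁵
epochs per group the pooled test rejects on trivially small differences,
so the per-individual variant is reported alongside it everywhere.

Timezone: all timestamps are stored UTC and converted to the configured
local zone (default Asia/Kathmandu) only for diel binning and day/night
windows, since the shepherd schedule anchors every diel claim.

Juvenile/adult cutoff: 4 years (configurable) — herd cohesion drops in
males around that age in this husbandry system.

## Problem sizes

The test suite runs small simulations (5–8 animals, one day) so the whole
suite completes in well under a minute; recovery properties are asserted
over 10 paired seeds. The acceptance script simulates the full study
geometry — two herds of 17 over five days, GPS on 11 — which is enough for
stable window-level contrasts while keeping the run to seconds.

## Known limitations

- The movement model is a stand-in: its parameters are plausible for a
  shepherded herd on open pasture but are not calibrated to any terrain.
- Tether nights are applied from local midnight of the tether start day,
  not from the evening; the few pre-dawn hours of that day are a
  simplification.
- Effort is computed at minute resolution from bin starts; partial minutes
  at window edges are attributed wholesale to one side.
- The day-window boundary treats the return-to-camp hour as day; real
  transitions are gradual.
- Contact records are presence/absence; RSSI magnitude is never used to
  grade distance within 3 m.
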