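# herdscope

Biologging analysis of social behaviour in shepherded herds. The package
targets the data a field team collects on a high-altitude livestock herd —
collar accelerometers, Bluetooth proximity loggers, and GPS — and turns the
three streams into the standard social-structure summaries of behavioural
ecology: diel activity profiles, effort-corrected association networks with
community structure, and scan-sampled spatial cohesion. A synthetic herd
simulator with a known ground truth makes every stage verifiable end to end.

It is written for behavioural ecologists and anyone managing proximity-logger
or GPS deployments on group-living animals (yaks, cattle, sheep, ungulates
generally).

## The quantities at the core

**Association rate.** Proximity loggers record an RSSI between two collars
once a minute while the animals are within ~3 m, but loggers die at
different times, so raw contact counts are incomparable. For a dyad *(i, j)*
the package computes

&nbsp;&nbsp;&nbsp;&nbsp;rate(i, j) = x(i, j) / e(i, j),

where *x* is the number of distinct contact minutes and *e* the number of
minutes during which **both** loggers were recording (inside the day, night,
or whole window). The rate is the fraction of jointly observed time the pair
spent in proximity, in [0, 1]; it is re-expressed as expected contact
minutes per 24 h window for the per-individual "mean signals" summary.

**Modularity.** The weighted association network is scored with
Newman–Girvan modularity

&nbsp;&nbsp;&nbsp;&nbsp;Q = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − k<sub>i</sub>k<sub>j</sub>/2m] δ(c<sub>i</sub>, c<sub>j</sub>),

maximised over partitions with a seeded multi-restart Louvain search. Q = 0
for a single community; higher Q means better-separated subgroups (for
instance, juveniles tethered together at night).

**Cohesion scans.** From speed-filtered (default 6 km/h), 2-min-regularised
GPS tracks, every 30 min the animals present are partitioned into spatial
subgroups: connected components of the graph linking animals closer than a
separation threshold (either-axis degrees, or geodesic metres). The per-scan
subgroup count is summarised as fractions (1, 2, 3, 4+ subgroups) and
compared across hours and six 4-hour diel periods with Kruskal–Wallis and
rank post-hoc tests.

All group comparisons are rank-based (Kruskal–Wallis, Wilcoxon signed-rank,
Mann–Whitney, Spearman), as is standard for skewed activity and count data.

## Worked example

```python
import herdscope as hs

cfg = hs.SimulationConfig(
    n_individuals=6, n_juveniles=3, duration_days=1, rng_seed=7,
    tether_enabled=True,
    tether_positions=tuple(hs.sim.default_tether_line(3)))
res = hs.simulate_herd(cfg)

night = hs.build_association(res.contacts, res.logger_windows, window="night")
per_id, mean, sd = hs.mean_signals(night)
print(f"night signals per individual: {mean:.1f} +/- {sd:.1f}")

nm = hs.max_modularity(night)
print(f"night modularity Q = {nm.modularity_q:.3f}")
print("communities:", nm.partition)

counts = res.truth.cluster_counts()
print(f"mean subgroups per scan: {counts.mean():.2f}")
```

Output:

```
night signals per individual: 146.3 +/- 134.4
night modularity Q = 0.047
communities: {'herd1_y00': 0, 'herd1_y01': 0, 'herd1_y02': 0, 'herd1_y03': 1, 'herd1_y04': 1, 'herd1_y05': 1}
mean subgroups per scan: 1.04
```

The six animals exchange on average 146 expected contact minutes per night
(the large spread reflects the tethered/untethered split); the night network
divides into exactly the tethered juveniles (`y00`–`y02`) versus the adults,
and the herd is almost always a single spatial group (1.04 subgroups per
scan).

The same analyses run from the shell: `herdscope simulate`, `herdscope
activity`, `herdscope tracks`, `herdscope network`, `herdscope cohesion`,
and `herdscope run` for the end-to-end pipeline on CSV inputs (see
`herdscope --help`).

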