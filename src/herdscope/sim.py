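"""Synthetic herd generator with a known ground truth.

Emulates the full biologging setup of a shepherded high-altitude herd —
accelerometer activity at 0.1 Hz, minute-cadence proximity (RSSI) records,
and GPS fixes at 1 min (day) / 10 min (night) — on top of a movement model
whose truth is fully known, so every downstream analysis stage can be
checked for recovery.

Movement is a correlated random walk in a planar metre frame around the
camp, with three drift terms reproducing the shepherd schedule: toward the
pasture after the morning departure, toward camp in the hour before the
evening return, and a social pull toward the herd centroid whose strength
is ``attraction_strength * (1 - independence_i)``. At night, untethered
animals wander near camp with a burst of movement around
``night_activity_peak_hour``; tethered juveniles are held within 2 m of
their tether position.

The observation models follow the hardware: activity is scaled step speed
plus non-negative sensor noise; a proximity record is emitted for a dyad
in a given minute iff its true distance is within the RSSI cutoff (3 m),
with RSSI linear in distance through the two calibration anchors
(−45 dBm at 1 m, −90 dBm at 2.5 m) plus Gaussian jitter; GPS adds Gaussian
position noise and converts to lat/lon around the configured reference
point. Logger battery death truncates all three streams of an animal at
once.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._geo import DEFAULT_REF_LAT, DEFAULT_REF_LON, planar_to_latlon
from .actigraphy import ActivitySeries
from .proximity import ContactLog

__all__ = ["SimulationConfig", "GroundTruth", "SimResult", "simulate_herd",
           "default_tether_line", "study_config"]


def default_tether_line(n: int, spacing_m: float = 1.5,
                        origin: tuple[float, float] = (6.0, 0.0)) -> list[tuple[float, float]]:
    """Tether spots in a line near camp, adjacent animals ``spacing_m`` apart."""
    x0, y0 = origin
    return [(x0 + k * spacing_m, y0) for k in range(n)]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic herd; defaults match the study conditions
    (17 animals per herd, 0.1 Hz activity, 1-min contacts, 1/10-min GPS,
    day 06:00–17:00 local)."""

    n_individuals: int = 17
    n_juveniles: int = 8
    duration_days: int = 2
    step_seconds: int = 60

    # social movement
    attraction_strength: float = 1.0
    independence: float | tuple = 0.2          # scalar or per-individual, in [0, 1]
    heading_persistence: float = 0.8
    wander_speed_sd: float = 0.15              # m/s, per-axis CRW innovation (day)
    travel_speed: float = 0.5                  # m/s drift toward schedule target
    attraction_rate_per_min: float = 0.05      # fractional pull to centroid at strength 1
    init_spread_m: float = 5.0

    # schedule / places (planar metres, camp at origin)
    day_window: tuple[dt.time, dt.time] = (dt.time(6, 0), dt.time(17, 0))
    camp_position: tuple[float, float] = (0.0, 0.0)
    pasture_center: tuple[float, float] = (600.0, 400.0)
    return_lead_minutes: int = 60
    timezone: str = "Asia/Kathmandu"
    start_date: str = "2022-03-10"

    # night behaviour: the untethered stationary spread around camp is
    # night_noise_sd / sqrt(2 * night_home_rate) per axis (~6 m with the
    # defaults) — animals bed scattered over the camp area, not in a heap
    night_activity_peak_hour: int = 0
    night_noise_sd: float = 2.0                # m per step, untethered wander
    night_burst_factor: float = 6.0            # noise multiplier within ±1 h of peak
    night_home_rate: float = 0.05              # per-step pull back to camp
    tether_enabled: bool = False
    tether_positions: tuple | None = None      # planar coords, one per tethered juvenile
    tether_start_day: int = 0                  # first day index whose night is tethered
    tether_jitter_sd: float = 0.5              # m, within-tether shuffling

    # proximity observation model
    rssi_at_1m: float = -45.0
    rssi_at_2_5m: float = -90.0
    rssi_cutoff_m: float = 3.0
    rssi_jitter_sd: float = 3.0

    # activity observation model
    activity_epoch_seconds: int = 10
    activity_scale: float = 30.0               # counts per m/s of step speed
    activity_noise_sd: float = 2.0             # half-normal sensor noise, counts

    # GPS observation model
    gps_day_interval: int = 60                 # s
    gps_night_interval: int = 600              # s
    gps_noise_sd: float = 5.0                  # m
    gps_ids: tuple | None = None               # subset with GPS collars (default: all)
    ref_lat: float = DEFAULT_REF_LAT
    ref_lon: float = DEFAULT_REF_LON

    # logger battery
    battery_death: dict | None = None          # id -> hours from start

    # ground-truth clustering rule
    truth_cluster_sep_m: float = 50.0
    truth_scan_minutes: int = 30

    herd_label: str = "herd1"
    ages: tuple | None = None                  # per-individual years (else drawn)
    rng_seed: int = 0

    def independence_vector(self) -> np.ndarray:
        v = np.asarray(self.independence, dtype=float)
        if v.ndim == 0:
            v = np.full(self.n_individuals, float(v))
        if v.shape != (self.n_individuals,):
            raise ValueError("independence must be scalar or length n_individuals")
        return v

    def validate(self) -> None:
        if self.n_individuals < 1 or not (0 <= self.n_juveniles <= self.n_individuals):
            raise ValueError("invalid individual counts")
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        ind = self.independence_vector()
        if (ind < 0).any() or (ind > 1).any():
            raise ValueError("independence values must lie in [0, 1]")
        if not self.rssi_at_1m > self.rssi_at_2_5m:
            raise ValueError("rssi_at_1m must be stronger (less negative) than rssi_at_2_5m")
        if self.gps_day_interval > self.gps_night_interval:
            raise ValueError("gps_day_interval must be <= gps_night_interval")
        for name in ("camp_position", "pasture_center"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite coordinates in {name}")
        if self.tether_enabled:
            if not self.tether_positions:
                raise ValueError("tether_enabled requires non-empty tether_positions")
            if len(self.tether_positions) < self.n_juveniles:
                raise ValueError("need a tether position for every juvenile")
            if not np.isfinite(np.asarray(self.tether_positions)).all():
                raise ValueError("non-finite coordinates in tether_positions")
        if self.step_seconds <= 0 or (60 % self.step_seconds != 0
                                      and self.step_seconds % 60 != 0):
            raise ValueError("step_seconds must divide or be a multiple of 60")
        if self.step_seconds % self.activity_epoch_seconds:
            raise ValueError("activity_epoch_seconds must divide step_seconds")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f"{self.herd_label}_y{i:02d}" for i in range(self.n_individuals))

    @property
    def juvenile_ids(self) -> tuple[str, ...]:
        return self.ids[: self.n_juveniles]


@dataclass
class GroundTruth:
    """The simulator's truth channel: exact positions and derived quantities."""

    times: pd.DatetimeIndex          # UTC, step resolution
    ids: tuple[str, ...]
    positions: np.ndarray            # (T, n, 2) planar metres
    tether_group: frozenset
    config: SimulationConfig

    def pairwise_distance(self, t_slice=slice(None)) -> np.ndarray:
        """(T, n, n) true inter-individual distances; symmetric, zero diagonal."""
        p = self.positions[t_slice]
        d = np.linalg.norm(p[:, :, None, :] - p[:, None, :, :], axis=-1)
        return d

    def nearest_neighbour_distance(self) -> np.ndarray:
        """(T, n) distance to nearest herd mate (inf for a lone animal)."""
        d = self.pairwise_distance()
        T, n, _ = d.shape
        d[:, np.arange(n), np.arange(n)] = np.inf
        return d.min(axis=2)

    def centroid_distance(self) -> np.ndarray:
        """(T, n) distance of each animal to the herd centroid."""
        c = self.positions.mean(axis=1, keepdims=True)
        return np.linalg.norm(self.positions - c, axis=-1)

    def cluster_counts(self) -> pd.Series:
        """True subgroup count at each scan under the generator's own rule:
        connected components of the { distance < truth_cluster_sep_m } graph,
        evaluated every truth_scan_minutes."""
        step = self.config.step_seconds
        stride = max(1, (self.config.truth_scan_minutes * 60) // step)
        idxs = range(0, len(self.times), stride)
        out = {}
        for t in idxs:
            d = np.linalg.norm(self.positions[t][:, None] - self.positions[t][None, :], axis=-1)
            out[self.times[t]] = _n_components(d < self.config.truth_cluster_sep_m)
        return pd.Series(out, name="true_n_clusters")


def _n_components(adj: np.ndarray) -> int:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    count = 0
    for s in range(n):
        if seen[s]:
            continue
        count += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return count


@dataclass
class SimResult:
    config: SimulationConfig
    truth: GroundTruth
    activity: list[ActivitySeries]
    contacts: ContactLog
    gps: pd.DataFrame                 # individual_id, timestamp, lat, lon
    meta: pd.DataFrame                # individual_id, herd, sex, age, class, tethered
    logger_windows: dict              # id -> (on, off) UTC timestamps


def _rssi_of_distance(d: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    # linear through (1 m, rssi_at_1m) and (2.5 m, rssi_at_2_5m); clamped below 1 m
    slope = (cfg.rssi_at_2_5m - cfg.rssi_at_1m) / 1.5
    return np.minimum(cfg.rssi_at_1m + slope * np.maximum(d - 1.0, 0.0), cfg.rssi_at_1m)


def simulate_herd(config: SimulationConfig) -> SimResult:
    """Run the generator; identical config (incl. seed) gives identical output."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_individuals
    step = cfg.step_seconds
    T = cfg.duration_days * 86400 // step

    start_local = pd.Timestamp(f"{cfg.start_date} 00:00", tz=cfg.timezone)
    times_local = start_local + pd.to_timedelta(np.arange(T) * step, unit="s")
    times = pd.DatetimeIndex(times_local).tz_convert("UTC")
    local = pd.DatetimeIndex(times_local)
    secs_of_day = np.asarray(local.hour * 3600 + local.minute * 60 + local.second)
    day_start_s = cfg.day_window[0].hour * 3600 + cfg.day_window[0].minute * 60
    day_end_s = cfg.day_window[1].hour * 3600 + cfg.day_window[1].minute * 60
    is_day = (secs_of_day >= day_start_s) & (secs_of_day < day_end_s)
    is_return = is_day & (secs_of_day >= day_end_s - cfg.return_lead_minutes * 60)
    day_index = np.asarray((local - local[0]).days, dtype=int)
    hour_frac = secs_of_day / 3600.0
    dh = np.abs((hour_frac - cfg.night_activity_peak_hour + 12.0) % 24.0 - 12.0)
    in_burst = dh <= 1.0

    camp = np.asarray(cfg.camp_position, dtype=float)
    pasture = np.asarray(cfg.pasture_center, dtype=float)
    indep = cfg.independence_vector()
    # an animal's independence discounts every steering influence on it:
    # the shepherd schedule, the pull back to camp at night, and the herd
    # centroid; a fully independent animal is a pure random walker
    soc = 1.0 - indep
    attract = cfg.attraction_strength * soc  # per-individual centroid weight
    kappa = cfg.attraction_rate_per_min * step / 60.0
    dtm = step / 60.0  # steps expressed in minutes, for per-minute rates

    tethered_mask = np.zeros(n, dtype=bool)
    tether_xy = None
    if cfg.tether_enabled:
        tethered_mask[: cfg.n_juveniles] = True
        tether_xy = np.asarray(cfg.tether_positions, dtype=float)[: cfg.n_juveniles]

    pos = camp + rng.normal(0.0, cfg.init_spread_m, size=(n, 2))
    vel = np.zeros((n, 2))
    rho = cfg.heading_persistence
    sig = cfg.wander_speed_sd * step  # m per step

    P = np.empty((T, n, 2))
    for t in range(T):
        if is_day[t]:
            target = camp if is_return[t] else pasture
            vel = rho * vel + math.sqrt(1 - rho * rho) * rng.normal(0.0, sig, size=(n, 2))
            to_target = target - pos
            dist = np.linalg.norm(to_target, axis=1, keepdims=True)
            drift = np.where(dist > 1e-9,
                             to_target / np.maximum(dist, 1e-9)
                             * np.minimum(1.0, dist / 50.0) * cfg.travel_speed * step,
                             0.0) * soc[:, None]
            centroid = pos.mean(axis=0)
            pos = pos + vel + drift + (kappa * attract)[:, None] * (centroid - pos)
        else:
            tether_now = cfg.tether_enabled and day_index[t] >= cfg.tether_start_day
            noise_sd = cfg.night_noise_sd * (cfg.night_burst_factor if in_burst[t] else 1.0)
            wander = (pos + (cfg.night_home_rate * dtm * soc)[:, None] * (camp - pos)
                      + rng.normal(0.0, noise_sd * dtm, size=(n, 2)))
            if tether_now and tethered_mask.any():
                jit = rng.normal(0.0, cfg.tether_jitter_sd, size=(tethered_mask.sum(), 2))
                r = np.linalg.norm(jit, axis=1, keepdims=True)
                jit = np.where(r > 2.0, jit * (2.0 / r), jit)  # hold within 2 m of the spot
                wander[tethered_mask] = tether_xy + jit
            pos = wander
        P[t] = pos

    if not np.isfinite(P).all():
        raise FloatingPointError("simulation produced non-finite coordinates")

    ids = cfg.ids
    sim_end = times[0] + pd.Timedelta(seconds=T * step)
    death = {}
    for i in ids:
        if cfg.battery_death and i in cfg.battery_death:
            death[i] = min(sim_end, times[0] + pd.Timedelta(hours=float(cfg.battery_death[i])))
        else:
            death[i] = sim_end
    logger_windows = {i: (times[0], death[i]) for i in ids}
    alive = np.stack([(times < death[i]) for i in ids], axis=1)  # (T, n)

    # --- activity: scaled step speed + non-negative sensor noise ------------
    speed = np.zeros((T, n))
    speed[1:] = np.linalg.norm(P[1:] - P[:-1], axis=-1) / step
    per_step = step // cfg.activity_epoch_seconds
    activity_series = []
    epoch_offsets = np.arange(per_step) * cfg.activity_epoch_seconds
    base_epochs = (times.values[:, None] + epoch_offsets.astype("timedelta64[s]")).ravel()
    for k, i in enumerate(ids):
        mag = (cfg.activity_scale * np.repeat(speed[:, k], per_step)
               + np.abs(rng.normal(0.0, cfg.activity_noise_sd, size=T * per_step)))
        keep = base_epochs < np.datetime64(death[i].tz_convert("UTC").tz_localize(None))
        idx = pd.DatetimeIndex(base_epochs[keep], tz="UTC")
        s = pd.Series(mag[keep], index=idx)
        activity_series.append(ActivitySeries(
            individual_id=i, data=s, herd=cfg.herd_label,
            logger_window=(times[0], death[i])))

    # --- proximity: minute-cadence contact emission -------------------------
    minute_steps = np.nonzero(secs_of_day % 60 == 0)[0]
    rec_a, rec_b, rec_t, rec_rssi = [], [], [], []
    iu, ju = np.triu_indices(n, k=1)
    for t in minute_steps:
        d = np.linalg.norm(P[t][:, None] - P[t][None, :], axis=-1)
        dv = d[iu, ju]
        close = dv <= cfg.rssi_cutoff_m
        both_on = alive[t, iu] & alive[t, ju]
        hit = close & both_on
        if hit.any():
            rssi = (_rssi_of_distance(dv[hit], cfg)
                    + rng.normal(0.0, cfg.rssi_jitter_sd, size=int(hit.sum())))
            rec_a.append(iu[hit])
            rec_b.append(ju[hit])
            rec_t.append(np.full(int(hit.sum()), t))
            rec_rssi.append(rssi)
    if rec_a:
        aa = np.concatenate(rec_a)
        bb = np.concatenate(rec_b)
        tt = np.concatenate(rec_t)
        rr = np.minimum(np.concatenate(rec_rssi), 0.0)
        contacts = ContactLog(pd.DataFrame({
            "id_a": [ids[x] for x in aa],
            "id_b": [ids[x] for x in bb],
            "timestamp": times[tt],
            "rssi": rr,
        }))
    else:
        contacts = ContactLog(pd.DataFrame(
            {"id_a": pd.Series(dtype=str), "id_b": pd.Series(dtype=str),
             "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
             "rssi": pd.Series(dtype=float)}))

    # --- GPS: day/night cadence, position noise, lat/lon --------------------
    gps_ids = cfg.gps_ids if cfg.gps_ids is not None else ids
    secs_from_start = np.arange(T) * step
    on_day_grid = (secs_from_start % cfg.gps_day_interval == 0) & is_day
    on_night_grid = (secs_from_start % cfg.gps_night_interval == 0) & ~is_day
    gps_steps = np.nonzero(on_day_grid | on_night_grid)[0]
    rows = []
    for i in gps_ids:
        k = ids.index(i)
        keep = gps_steps[alive[gps_steps, k]]
        noisy = P[keep, k, :] + rng.normal(0.0, cfg.gps_noise_sd, size=(len(keep), 2))
        lat, lon = planar_to_latlon(noisy, cfg.ref_lat, cfg.ref_lon)
        rows.append(pd.DataFrame({"individual_id": i, "timestamp": times[keep],
                                  "lat": lat, "lon": lon}))
    gps = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["individual_id", "timestamp", "lat", "lon"]))

    # --- metadata ------------------------------------------------------------
    juv = np.arange(n) < cfg.n_juveniles
    if cfg.ages is not None:
        if len(cfg.ages) != n:
            raise ValueError("ages must have one entry per individual")
        ages = np.asarray(cfg.ages)
    else:
        ages = np.where(juv, rng.integers(1, 4, size=n), rng.integers(5, 14, size=n))
    meta = pd.DataFrame({
        "individual_id": list(ids),
        "herd": cfg.herd_label,
        "sex": np.where(juv, "male", "female"),
        "age": ages,
        "class": np.where(juv, "juvenile", "adult"),
        "tethered": juv & cfg.tether_enabled,
    })

    truth = GroundTruth(times=times, ids=ids, positions=P,
                        tether_group=frozenset(cfg.juvenile_ids) if cfg.tether_enabled
                        else frozenset(), config=cfg)
    return SimResult(config=cfg, truth=truth, activity=activity_series,
                     contacts=contacts, gps=gps, meta=meta,
                     logger_windows=logger_windows)


def study_config(herd: str, seed: int, tether: bool, duration_days: int = 5,
                 gps_count: int | None = None, **overrides) -> SimulationConfig:
    """Config for one herd under study-like conditions: 17 animals (male
    juveniles, adult females), tether herd tied from day 3, staggered
    battery death, GPS on a subset, and independence rising with age —
    older females drift on their own more, juveniles stick to the herd."""
    n = overrides.pop("n_individuals", 17)
    n_juv = overrides.pop("n_juveniles", 8 if not tether else 4)
    overrides.setdefault("tether_start_day", min(3, duration_days - 1) if tether else 0)
    rng = np.random.default_rng(seed + 10_007)
    if "ages" not in overrides:
        overrides["ages"] = tuple(
            int(a) for a in np.concatenate([rng.integers(1, 4, size=n_juv),
                                            rng.integers(5, 14, size=n - n_juv)]))
    if "independence" not in overrides:
        ages = np.asarray(overrides["ages"], dtype=float)
        overrides["independence"] = tuple(
            np.clip(0.05 + 0.40 * (ages - 4.0) / 9.0, 0.05, 0.45))
    cfg = SimulationConfig(
        n_individuals=n, n_juveniles=n_juv, duration_days=duration_days,
        herd_label=herd, rng_seed=seed,
        tether_enabled=tether,
        tether_positions=tuple(default_tether_line(n_juv)) if tether else None,
        **overrides,
    )
    if gps_count is not None:
        cfg = replace(cfg, gps_ids=cfg.ids[:gps_count])
    # staggered battery death: a few loggers die 50-95% of the way through
    short = rng.choice(n, size=max(1, n // 5), replace=False)
    death = {cfg.ids[k]: float(24 * duration_days * rng.uniform(0.5, 0.95))
             for k in short}
    return replace(cfg, battery_death=death)
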