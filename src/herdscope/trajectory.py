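"""GPS track cleaning and regularisation.

Raw collar fixes arrive at 1-min cadence during the day and 10-min at
night, with occasional aberrant positions (multipath, cold-start). The
cleaning chain is: (1) a greedy forward speed filter that drops any fix
implying a speed above a threshold (default 6 km/h — faster than a
grazing yak moves) from the previously retained fix; (2) regularisation
onto a fixed-interval grid (default 2 min), taking the nearest fix within
half an interval of each slot, linearly interpolating across short gaps,
and flagging anything longer as missing rather than inventing positions.

Distances are spherical (haversine); at herd scale the error versus an
ellipsoid is far below GPS noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import haversine_m, initial_bearing_deg

__all__ = ["Trajectory", "speed_filter", "regularise", "step_metrics"]


@dataclass
class Trajectory:
    """One individual's GPS track.

    ``fixes`` is a DataFrame with columns ``lat``, ``lon`` (degrees) and,
    once regularised, a boolean ``gap`` column, indexed by strictly
    increasing tz-aware timestamps. ``regular_interval`` is None for raw
    tracks and the slot spacing once regularised; with it set, consecutive
    index entries are exactly one interval apart and missing slots carry
    ``gap=True`` with NaN coordinates.
    """

    individual_id: str
    fixes: pd.DataFrame
    regular_interval: pd.Timedelta | None = None

    def __post_init__(self):
        df = self.fixes
        if not isinstance(df.index, pd.DatetimeIndex) or df.index.tz is None:
            raise ValueError("fixes must be indexed by tz-aware timestamps")
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise ValueError("fix timestamps must be strictly increasing")
        ok = df[["lat", "lon"]].dropna()
        if (ok["lat"].abs() > 90).any() or (ok["lon"].abs() > 180).any():
            raise ValueError("lat/lon out of range")
        if self.regular_interval is not None:
            self.regular_interval = pd.Timedelta(self.regular_interval)
            if "gap" not in df.columns:
                raise ValueError("regularised track needs a gap column")
            if len(df) > 1:
                deltas = np.unique(np.diff(df.index.values))
                if len(deltas) != 1 or pd.Timedelta(deltas[0]) != self.regular_interval:
                    raise ValueError("slot spacing must equal regular_interval exactly")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def present(self) -> pd.DataFrame:
        """Non-gap fixes only."""
        if "gap" in self.fixes.columns:
            return self.fixes[~self.fixes["gap"]]
        return self.fixes

    @classmethod
    def from_frame(cls, individual_id: str, df: pd.DataFrame) -> "Trajectory":
        df = df.sort_values("timestamp").drop_duplicates("timestamp")
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        out = pd.DataFrame({"lat": df["lat"].to_numpy(float),
                            "lon": df["lon"].to_numpy(float)},
                           index=pd.DatetimeIndex(ts))
        return cls(individual_id=str(individual_id), fixes=out)


def speed_filter(track: Trajectory, vmax_kmh: float = 6.0
                 ) -> tuple[Trajectory, pd.DatetimeIndex]:
    """Remove fixes implying speed above ``vmax_kmh`` from the last kept fix.

    Greedy forward pass: the first fix is always retained; each later fix
    is kept iff its speed from the previously *retained* fix is within the
    threshold. Deterministic and idempotent. Returns the filtered track and
    the timestamps removed; raises if nothing would survive.
    """
    if vmax_kmh <= 0:
        raise ValueError("vmax must be positive")
    df = track.present
    if len(df) < 2:
        return track, pd.DatetimeIndex([], tz="UTC")
    t = df.index.view("int64") / 1e9
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    keep = [0]
    removed = []
    for k in range(1, len(df)):
        j = keep[-1]
        dt_s = t[k] - t[j]
        d_m = float(haversine_m(lat[j], lon[j], lat[k], lon[k]))
        if dt_s > 0 and (d_m / dt_s) * 3.6 <= vmax_kmh:
            keep.append(k)
        else:
            removed.append(k)
    if not keep:
        raise ValueError("speed filter removed every fix")
    out = df.iloc[keep][["lat", "lon"]]
    return (Trajectory(track.individual_id, out),
            df.index[removed])


def regularise(track: Trajectory, interval="2min", max_fill_gap="20min",
               origin: pd.Timestamp | None = None) -> Trajectory:
    """Resample a cleaned track onto a fixed grid with explicit gaps.

    Slots run at ``t0 + k*interval`` from the first to the last fix. Each
    slot takes the nearest fix within ``interval/2``; otherwise, if the raw
    fixes bracketing the slot are at most ``max_fill_gap`` apart, the slot
    is linearly interpolated between them; otherwise it is flagged as a
    gap (NaN position). No position is ever fabricated across a long
    dropout.

    ``origin`` anchors the grid phase: slots fall on ``origin +
    k*interval``. Pass one shared origin when several animals' tracks must
    land on a common grid (scan clustering requires it); default is the
    track's own first fix.
    """
    interval = pd.Timedelta(interval)
    max_fill_gap = pd.Timedelta(max_fill_gap)
    if interval <= pd.Timedelta(0):
        raise ValueError("interval must be positive")
    df = track.present
    if df.empty:
        raise ValueError("cannot regularise an empty track")
    t0, t1 = df.index[0], df.index[-1]
    if origin is not None:
        origin = pd.Timestamp(origin)
        k0 = int(np.ceil((t0 - origin) / interval))
        t0 = origin + k0 * interval
        if t0 > t1:
            raise ValueError("no grid slot falls inside the track span")
    slots = pd.date_range(t0, t1, freq=interval)
    ts = df.index.view("int64")
    slot_ns = slots.view("int64")
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()

    out_lat = np.full(len(slots), np.nan)
    out_lon = np.full(len(slots), np.nan)
    gap = np.ones(len(slots), dtype=bool)

    # nearest fix per slot
    right = np.searchsorted(ts, slot_ns)
    left = np.clip(right - 1, 0, len(ts) - 1)
    right = np.clip(right, 0, len(ts) - 1)
    d_left = np.abs(slot_ns - ts[left])
    d_right = np.abs(ts[right] - slot_ns)
    nearest = np.where(d_right < d_left, right, left)
    d_near = np.minimum(d_left, d_right)
    half = interval.value / 2
    snap = d_near <= half
    out_lat[snap] = lat[nearest[snap]]
    out_lon[snap] = lon[nearest[snap]]
    gap[snap] = False

    # interpolate remaining slots across short raw gaps
    for k in np.nonzero(~snap)[0]:
        r = np.searchsorted(ts, slot_ns[k])
        if r == 0 or r >= len(ts):
            continue
        l = r - 1
        if ts[r] - ts[l] <= max_fill_gap.value:
            w = (slot_ns[k] - ts[l]) / (ts[r] - ts[l])
            out_lat[k] = lat[l] + w * (lat[r] - lat[l])
            out_lon[k] = lon[l] + w * (lon[r] - lon[l])
            gap[k] = False

    out = pd.DataFrame({"lat": out_lat, "lon": out_lon, "gap": gap}, index=slots)
    return Trajectory(track.individual_id, out, regular_interval=interval)


def step_metrics(track: Trajectory) -> pd.DataFrame:
    """Per-step distance (m), speed (km/h) and heading (degrees).

    Steps connect consecutive present fixes; each row is indexed by the
    step's end time. Heading is NaN for a zero-length step.
    """
    df = track.present
    if len(df) < 2:
        raise ValueError("need at least two fixes")
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    t = df.index.view("int64") / 1e9
    d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    dt_s = np.diff(t)
    speed = np.where(dt_s > 0, d / dt_s * 3.6, np.nan)
    heading = initial_bearing_deg(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return pd.DataFrame({"distance_m": d, "speed_kmh": speed, "heading_deg": heading},
                        index=df.index[1:])
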