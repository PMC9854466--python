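"""Accelerometer activity: loading, diel profiles, group comparisons.

Collar-mounted accelerometers record a single-axis activity magnitude at
0.1 Hz (one epoch every 10 s). The module builds hour-of-day (diel)
profiles and compares activity distributions between herds or between
juveniles and adults with rank-based tests.

Hour-of-day is always computed in local clock time (default
Asia/Kathmandu): the shepherd schedule — leaving camp around 06:00,
returning around 17:00 — anchors every diel claim, so UTC binning would
smear the pattern.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .stats import StatResult, kruskal_groups

logger = logging.getLogger(__name__)

DEFAULT_TZ = "Asia/Kathmandu"

__all__ = [
    "ActivitySeries",
    "DielProfile",
    "load_activity",
    "diel_profile",
    "group_activity",
    "compare_distributions",
    "DEFAULT_TZ",
]


@dataclass
class ActivitySeries:
    """One individual's activity magnitudes over its logger's on-window.

    ``data`` is a float Series indexed by tz-aware epoch-start timestamps
    (UTC internally), strictly increasing, nominally 10 s apart. Magnitudes
    are non-negative activity counts; the unit is the device's arbitrary
    count scale.
    """

    individual_id: str
    data: pd.Series
    herd: str | None = None
    logger_window: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self):
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise TypeError("data must be indexed by timestamps")
        if self.data.index.tz is None:
            raise ValueError("timestamps must be timezone-aware (UTC internally)")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("epoch timestamps must be strictly increasing")
        if (self.data < 0).any():
            raise ValueError("activity magnitudes must be non-negative")
        if self.logger_window is None:
            self.logger_window = (self.data.index[0], self.data.index[-1])
        lo, hi = self.logger_window
        if len(self.data) and (self.data.index[0] < lo or self.data.index[-1] > hi):
            raise ValueError("epochs fall outside the logger on-window")

    @property
    def n_epochs(self) -> int:
        return len(self.data)


@dataclass
class DielProfile:
    """Hourly activity summary for one group.

    ``table`` has exactly 24 rows (hour 0..23) with columns ``mean``,
    ``sd``, ``n_epochs``. Hours with no data keep NaN mean/sd and
    ``n_epochs = 0`` — they are flagged empty, never zero-filled.
    """

    group: str
    table: pd.DataFrame

    def __post_init__(self):
        if list(self.table.index) != list(range(24)):
            raise ValueError("diel table must cover hours 0..23 exactly")


def load_activity(source, meta: pd.DataFrame | None = None) -> tuple[list[ActivitySeries], int]:
    """Read an activity table into per-individual series.

    ``source`` is a CSV path or a DataFrame with columns
    ``individual_id,timestamp,magnitude`` (ISO-8601 timestamps; naive
    timestamps are taken as UTC). Rows with negative magnitude violate the
    device's count scale and are rejected; the rejected count is returned
    and logged. Returns ``(series_list, n_rejected)``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    for col in ("individual_id", "timestamp", "magnitude"):
        if col not in df.columns:
            raise ValueError(f"activity table is missing required column {col!r}")
    if df.empty:
        logger.warning("activity table is empty")
        return [], 0
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    bad = df["magnitude"] < 0
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.warning("rejected %d rows with negative magnitude", n_rejected)
        df = df[~bad]
    herd_of = {}
    if meta is not None:
        herd_of = dict(zip(meta["individual_id"].astype(str), meta["herd"].astype(str)))
    out = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("timestamp").drop_duplicates("timestamp")
        s = pd.Series(sub["magnitude"].to_numpy(float), index=pd.DatetimeIndex(sub["timestamp"]))
        out.append(ActivitySeries(individual_id=str(ind), data=s, herd=herd_of.get(str(ind))))
    return out, n_rejected


def _group_key(series: ActivitySeries, group_by: str, meta: Mapping | None) -> str:
    if group_by == "herd":
        if series.herd is not None:
            return series.herd
        if meta is not None and series.individual_id in meta:
            return str(meta[series.individual_id])
        raise ValueError(f"no herd label for individual {series.individual_id!r}")
    if group_by == "age_class":
        if meta is None or series.individual_id not in meta:
            raise ValueError(
                f"age_class grouping needs a meta mapping with id {series.individual_id!r}")
        return str(meta[series.individual_id])
    raise ValueError(f"unknown group key {group_by!r} (use 'herd' or 'age_class')")


def diel_profile(series: Iterable[ActivitySeries], group_by: str = "herd",
                 meta: Mapping | None = None, tz: str = DEFAULT_TZ) -> dict[str, DielProfile]:
    """Hour-of-day mean activity per group.

    ``meta`` maps individual_id -> group label and is required for
    ``group_by='age_class'`` (and for 'herd' when series carry no herd).
    Hours are local clock hours in ``tz``.
    """
    series = list(series)
    if not series:
        raise ValueError("need at least one activity series")
    buckets: dict[str, list[pd.Series]] = {}
    for s in series:
        key = _group_key(s, group_by, meta)
        local = s.data.copy()
        local.index = local.index.tz_convert(tz)
        buckets.setdefault(key, []).append(local)
    out = {}
    for key, parts in sorted(buckets.items()):
        allv = pd.concat(parts)
        hour = allv.index.hour
        tab = pd.DataFrame(index=pd.RangeIndex(24, name="hour"),
                           columns=["mean", "sd", "n_epochs"], dtype=float)
        grouped = allv.groupby(hour)
        tab["mean"] = grouped.mean()
        tab["sd"] = grouped.std()
        tab["n_epochs"] = grouped.size().reindex(tab.index, fill_value=0)
        tab["n_epochs"] = tab["n_epochs"].astype(int)
        out[key] = DielProfile(group=key, table=tab)
    return out


def group_activity(series: Iterable[ActivitySeries], group_by: str = "herd",
                   meta: Mapping | None = None, level: str = "pooled") -> dict[str, np.ndarray]:
    """Collect activity values per group for distribution comparison.

    ``level='pooled'`` pools every epoch of every member (treats epochs as
    the unit, which pseudo-replicates individuals but maximises power);
    ``level='individual'`` reduces each animal to its mean first, making
    the individual the unit. Both views are offered because they answer
    subtly different questions.
    """
    if level not in ("pooled", "individual"):
        raise ValueError("level must be 'pooled' or 'individual'")
    groups: dict[str, list] = {}
    for s in series:
        if s.n_epochs == 0:
            continue  # a logger that recorded nothing contributes no values
        key = _group_key(s, group_by, meta)
        if level == "pooled":
            groups.setdefault(key, []).append(s.data.to_numpy(float))
        else:
            groups.setdefault(key, []).append(np.array([s.data.mean()]))
    return {k: np.concatenate(v) for k, v in sorted(groups.items())}


def compare_distributions(groups) -> StatResult:
    """Rank-based k-sample test (Kruskal–Wallis; valid for 2 groups too)."""
    return kruskal_groups(groups)
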