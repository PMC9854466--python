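"""Herd-cohesion scan sampling from regularised GPS tracks.

At regular scan times (default every 30 min) the tracked animals present
at the scan are partitioned into spatial subgroups: two animals are linked
when their separation falls below a threshold, and subgroups are the
connected components of that graph (so a chain A–B–C is one subgroup even
if A and C are far apart). The separation rule has two modes: ``degrees``
applies the threshold to either coordinate axis (Chebyshev rule — linked
iff max(|Δlon|, |Δlat|) < threshold), ``metres`` uses geodesic distance.

The per-scan subgroup counts form a cohesion series analysed by local
clock time: hourly bins, and six 4-hour periods (01–04, 05–08, 09–12,
13–16, 17–20, 21–00) compared with rank tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from ._geo import haversine_m
from .stats import StatResult, kruskal_groups, rank_test_2sample
from .trajectory import Trajectory

DEFAULT_TZ = "Asia/Kathmandu"

PERIOD_LABELS = ("01-04", "05-08", "09-12", "13-16", "17-20", "21-00")

__all__ = ["ScanPartition", "CohesionSeries", "scan_clusters", "period_summary",
           "cohesion_fraction", "PERIOD_LABELS"]


@dataclass
class ScanPartition:
    """Subgroup assignment of the animals present at one scan."""

    scan_time: pd.Timestamp
    present_ids: tuple[str, ...]
    cluster_of: dict[str, int]
    low_coverage: bool  # fewer than 2 individuals present

    def __post_init__(self):
        if set(self.cluster_of) != set(self.present_ids):
            raise ValueError("cluster_of must cover exactly the present ids")

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_of.values()))


@dataclass
class CohesionSeries:
    """Per-scan subgroup counts with local-time period labels.

    ``table`` is indexed by scan time (UTC) with columns ``n_clusters``,
    ``n_present``, ``low_coverage``, ``hour`` (local 0–23) and ``period4h``
    (one of :data:`PERIOD_LABELS`).
    """

    table: pd.DataFrame
    tz: str = DEFAULT_TZ

    @classmethod
    def from_partitions(cls, partitions: list[ScanPartition], tz: str = DEFAULT_TZ
                        ) -> "CohesionSeries":
        if not partitions:
            raise ValueError("no scans")
        idx = pd.DatetimeIndex([p.scan_time for p in partitions])
        local_hour = idx.tz_convert(tz).hour
        period = [(int(h) - 1) % 24 // 4 for h in local_hour]
        tab = pd.DataFrame({
            "n_clusters": [p.n_clusters for p in partitions],
            "n_present": [len(p.present_ids) for p in partitions],
            "low_coverage": [p.low_coverage for p in partitions],
            "hour": np.asarray(local_hour, dtype=int),
            "period4h": [PERIOD_LABELS[k] for k in period],
        }, index=idx)
        return cls(table=tab, tz=tz)

    @property
    def valid(self) -> pd.DataFrame:
        """Scans with enough coverage to say anything about subgrouping."""
        return self.table[~self.table["low_coverage"]]


def _components(adj: np.ndarray) -> np.ndarray:
    """Connected-component labels of a boolean adjacency matrix (union-find)."""
    n = adj.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    roots = [find(i) for i in range(n)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return np.array([relabel[r] for r in roots])


def scan_clusters(tracks: list[Trajectory], scan_interval="30min",
                  sep_threshold: float = 0.5, sep_unit: str = "degrees"
                  ) -> list[ScanPartition]:
    """Partition the herd into spatial subgroups at each scan time.

    Tracks must be regularised on a common grid (same interval and phase).
    Scan times step by ``scan_interval`` from the earliest slot; an animal
    is present at a scan iff it has a non-gap slot exactly there. Scans
    with fewer than two present animals are flagged low-coverage (their
    single- or zero-animal "subgroup count" says nothing about cohesion).
    """
    if sep_threshold <= 0:
        raise ValueError("sep_threshold must be positive")
    if sep_unit not in ("degrees", "metres"):
        raise ValueError("sep_unit must be 'degrees' or 'metres'")
    scan_interval = pd.Timedelta(scan_interval)
    if not tracks:
        raise ValueError("no tracks")
    intervals = {t.regular_interval for t in tracks}
    if None in intervals or len(intervals) != 1:
        raise ValueError("tracks must share one regular interval")
    interval = intervals.pop()
    phases = {t.fixes.index[0].value % interval.value for t in tracks}
    if len(phases) != 1:
        raise ValueError("tracks are not on a common grid (different phase)")
    if scan_interval.value % interval.value:
        raise ValueError("scan_interval must be a multiple of the track interval")

    t0 = min(t.fixes.index[0] for t in tracks)
    t1 = max(t.fixes.index[-1] for t in tracks)
    scans = pd.date_range(t0, t1, freq=scan_interval)

    # slot lookup per track
    frames = {t.individual_id: t.present[["lat", "lon"]] for t in tracks}
    partitions = []
    any_present = False
    for ts in scans:
        ids, lats, lons = [], [], []
        for ind in sorted(frames):
            df = frames[ind]
            if ts in df.index:
                row = df.loc[ts]
                ids.append(ind)
                lats.append(float(row["lat"]))
                lons.append(float(row["lon"]))
        if not ids:
            continue
        any_present = True
        lats = np.asarray(lats)
        lons = np.asarray(lons)
        if sep_unit == "degrees":
            sep = np.maximum(np.abs(lons[:, None] - lons[None, :]),
                             np.abs(lats[:, None] - lats[None, :]))
        else:
            sep = haversine_m(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
        labels = _components(sep < sep_threshold)
        partitions.append(ScanPartition(
            scan_time=ts,
            present_ids=tuple(ids),
            cluster_of={i: int(c) for i, c in zip(ids, labels)},
            low_coverage=len(ids) < 2,
        ))
    if not any_present:
        raise ValueError("no individuals present at any scan")
    return partitions


def period_summary(series: CohesionSeries, by: str = "period4h") -> dict:
    """Summaries plus omnibus and pairwise rank tests across diel periods.

    ``by`` is ``'period4h'`` (six 4-h periods) or ``'hour'`` (24 bins).
    Returns a dict with ``summary`` (per-period mean/sd/n over valid
    scans), ``omnibus`` (Kruskal–Wallis over period groups) and
    ``pairwise`` (Mann–Whitney per pair with Benjamini–Hochberg adjusted
    p-values; the unadjusted p is reported alongside). Periods with zero
    scans are dropped with a warning, never imputed.
    """
    if by not in ("period4h", "hour"):
        raise ValueError("by must be 'period4h' or 'hour'")
    tab = series.valid
    groups = {str(k): g["n_clusters"].to_numpy(float)
              for k, g in tab.groupby(by, sort=True) if len(g)}
    if len(groups) < 2:
        raise ValueError("need at least two populated periods")
    summary = pd.DataFrame({
        "mean": {k: v.mean() for k, v in groups.items()},
        "sd": {k: v.std(ddof=1) if len(v) > 1 else 0.0 for k, v in groups.items()},
        "n": {k: len(v) for k, v in groups.items()},
    })
    omnibus = kruskal_groups(groups)
    keys = list(groups)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            res = rank_test_2sample(groups[keys[i]], groups[keys[j]], paired=False)
            rows.append({"a": keys[i], "b": keys[j],
                         "statistic": res.statistic, "p": res.p_value})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = false_discovery_control(pairwise["p"], method="bh")
    return {"summary": summary, "omnibus": omnibus, "pairwise": pairwise}


def cohesion_fraction(series: CohesionSeries) -> dict:
    """Distribution of subgroup counts over valid scans.

    Returns fractions of scans with 1, 2, 3 and >=4 subgroups (summing to
    1 over valid scans), the overall mean ± sd of the count, and how many
    low-coverage scans were set aside.
    """
    tab = series.valid
    if tab.empty:
        raise ValueError("no valid scans")
    n = tab["n_clusters"].to_numpy()
    total = len(n)
    return {
        "fraction": {
            "1": float((n == 1).sum() / total),
            "2": float((n == 2).sum() / total),
            "3": float((n == 3).sum() / total),
            "4+": float((n >= 4).sum() / total),
        },
        "mean": float(n.mean()),
        "sd": float(n.std(ddof=1)) if total > 1 else 0.0,
        "n_valid_scans": int(total),
        "n_low_coverage": int(series.table["low_coverage"].sum()),
    }
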