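"""Proximity-logger contact networks.

Bluetooth proximity loggers record a received signal strength indicator
(RSSI, dBm) between two collars once a minute whenever the animals are
within roughly 3 m — the range the hardware can bridge and the distance
class conventionally read as an affiliative association in cattle. Loggers
die at different times (battery life in extreme cold is uneven), so raw
contact counts are not comparable across dyads: each dyad's count is
corrected by the time both of its loggers were actually recording, giving
a dyadic contact *rate* in [0, 1] — the fraction of jointly observed
minutes the pair spent in proximity.

From the corrected association matrices the module derives per-individual
signal means, weighted Newman–Girvan modularity with a Louvain search, the
signal-vs-age rank correlation, and day/night or tether on/off contrasts.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import louvain_communities

from .stats import StatResult, rank_test_2sample, spearman_corr

DEFAULT_DAY_WINDOW = (dt.time(6, 0), dt.time(17, 0))
DEFAULT_TZ = "Asia/Kathmandu"

__all__ = [
    "ContactLog",
    "AssociationMatrix",
    "NetworkMetrics",
    "split_day_night",
    "build_association",
    "mean_signals",
    "modularity_q",
    "max_modularity",
    "centrality_vs_age",
    "contrast_windows",
    "write_edgelist_csv",
    "write_graphml",
]


@dataclass
class ContactLog:
    """Timestamped dyadic RSSI records with a canonical dyad orientation.

    Construction canonicalises each record so that ``id_a < id_b``,
    rejects self-contacts, requires RSSI <= 0 dBm, and collapses duplicate
    (dyad, timestamp) records to the strongest signal.
    """

    records: pd.DataFrame  # columns: id_a, id_b, timestamp, rssi

    def __post_init__(self):
        df = self.records.copy()
        for col in ("id_a", "id_b", "timestamp", "rssi"):
            if col not in df.columns:
                raise ValueError(f"contact log is missing required column {col!r}")
        df["id_a"] = df["id_a"].astype(str)
        df["id_b"] = df["id_b"].astype(str)
        if (df["id_a"] == df["id_b"]).any():
            raise ValueError("self-contacts are not allowed (id_a == id_b)")
        if (df["rssi"] > 0).any():
            raise ValueError("RSSI must be <= 0 dBm")
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        df["timestamp"] = ts
        swap = df["id_a"] > df["id_b"]
        df.loc[swap, ["id_a", "id_b"]] = df.loc[swap, ["id_b", "id_a"]].to_numpy()
        df = (df.sort_values(["timestamp", "id_a", "id_b", "rssi"])
                .drop_duplicates(["id_a", "id_b", "timestamp"], keep="last")
                .reset_index(drop=True))
        self.records = df[["id_a", "id_b", "timestamp", "rssi"]]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return sorted(set(self.records["id_a"]) | set(self.records["id_b"]))

    @classmethod
    def from_csv(cls, path) -> "ContactLog":
        return cls(pd.read_csv(path, sep=None, engine="python"))

    def to_csv(self, path) -> None:
        out = self.records.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
        out.to_csv(path, index=False)


@dataclass
class AssociationMatrix:
    """Symmetric dyadic contact counts, joint observation effort, and rates.

    ``raw_count[i, j]`` — distinct contact minutes of the dyad inside the
    window; ``effort[i, j]`` — minutes of the window during which both
    loggers were on. ``rate = raw_count / effort`` is NaN (flagged
    undefined) where effort is zero.
    """

    ids: tuple[str, ...]
    raw_count: np.ndarray
    effort: np.ndarray
    window_label: str  # 'day' | 'night' | 'all'
    window_minutes_per_day: float
    date: dt.date | None = None

    def __post_init__(self):
        n = len(self.ids)
        for name in ("raw_count", "effort"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.diagonal(m).any():
                raise ValueError(f"{name} must have a zero diagonal")
        if (self.raw_count > self.effort).any():
            raise ValueError("contact minutes exceed joint observation minutes")

    @property
    def rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.effort > 0, self.raw_count / np.maximum(self.effort, 1e-300), np.nan)
        np.fill_diagonal(r, 0.0)
        return r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rate, index=list(self.ids), columns=list(self.ids))


@dataclass
class NetworkMetrics:
    modularity_q: float
    partition: dict[str, int]
    mean_signals_per_individual: pd.Series
    matrix_ref: str

    def __post_init__(self):
        if not (-0.5 <= self.modularity_q <= 1.0):
            raise ValueError(f"modularity out of range: {self.modularity_q}")


# ---------------------------------------------------------------------------
# windows

def _local_times(ts: pd.Series | pd.DatetimeIndex, tz: str):
    if isinstance(ts, pd.Series):
        ts = pd.DatetimeIndex(ts)
    return ts.tz_convert(tz)


def _is_day(local: pd.DatetimeIndex, day_window) -> np.ndarray:
    start, end = day_window
    secs = local.hour * 3600 + local.minute * 60 + local.second
    s0 = start.hour * 3600 + start.minute * 60
    s1 = end.hour * 3600 + end.minute * 60
    if s0 <= s1:
        return (secs >= s0) & (secs < s1)  # half-open [start, end)
    return (secs >= s0) | (secs < s1)


def split_day_night(log: ContactLog, day_window=DEFAULT_DAY_WINDOW,
                    tz: str = DEFAULT_TZ) -> tuple[ContactLog, ContactLog]:
    """Partition records by local clock time into day [start, end) and night.

    The union of the two parts restores the input exactly.
    """
    local = _local_times(log.records["timestamp"], tz)
    day_mask = _is_day(local, day_window)
    day = ContactLog(log.records[day_mask].reset_index(drop=True))
    night = ContactLog(log.records[~day_mask].reset_index(drop=True))
    return day, night


def _day_window_minutes(day_window) -> float:
    s0 = day_window[0].hour * 60 + day_window[0].minute
    s1 = day_window[1].hour * 60 + day_window[1].minute
    return float((s1 - s0) % 1440 or 1440)


# ---------------------------------------------------------------------------
# association matrices

def build_association(log: ContactLog, logger_windows: Mapping[str, tuple],
                      window: str = "all", day_window=DEFAULT_DAY_WINDOW,
                      tz: str = DEFAULT_TZ, per_date: bool = False):
    """Build corrected association matrices from a contact log.

    ``logger_windows`` maps every id to its (on, off) timestamps — the
    interval its logger recorded; ids present in the log but absent here
    raise. Time is discretised into minute bins (a bin belongs to a logger's
    on-window, and to day or night, according to the bin start); effort is
    the number of bins in the window with both loggers on, raw_count the
    number of bins with at least one record for the dyad.

    Returns one :class:`AssociationMatrix` for ``window`` in
    ``{'day','night','all'}``, or, with ``per_date=True``, a dict keyed by
    local date (day windows by their own date; a night window carries the
    date its evening part starts, i.e. minutes before the day start belong
    to the previous date's night).
    """
    if window not in ("day", "night", "all"):
        raise ValueError("window must be 'day', 'night' or 'all'")
    missing = [i for i in log.ids if i not in logger_windows]
    if missing:
        raise ValueError(f"ids present in log but missing a logger window: {missing}")
    ids = tuple(sorted(logger_windows))
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)

    starts = [pd.Timestamp(logger_windows[i][0]).tz_convert("UTC") for i in ids]
    ends = [pd.Timestamp(logger_windows[i][1]).tz_convert("UTC") for i in ids]
    t0 = min(starts).floor("min")
    t1 = max(ends).ceil("min")
    grid = pd.date_range(t0, t1, freq="min", inclusive="left")
    m = len(grid)

    on = np.zeros((n, m), dtype=bool)
    for k, i in enumerate(ids):
        on[k] = (grid >= starts[k]) & (grid < ends[k])

    local = grid.tz_convert(tz)
    day_mask = _is_day(local, day_window)
    if window == "day":
        class_mask = day_mask
    elif window == "night":
        class_mask = ~day_mask
    else:
        class_mask = np.ones(m, dtype=bool)
    wmpd = {"day": _day_window_minutes(day_window),
            "night": 1440.0 - _day_window_minutes(day_window),
            "all": 1440.0}[window]

    # night minutes before the day start belong to the previous evening's night
    date_label = pd.Series(local.date, index=grid)
    if window == "night":
        before_daystart = _is_day(local, (dt.time(0, 0), day_window[0]))
        date_label[before_daystart] = (local[before_daystart] - pd.Timedelta(days=1)).date

    rec = log.records
    minute = rec["timestamp"].dt.floor("min")
    pos = ((minute - t0).dt.total_seconds() // 60).astype(int).to_numpy()
    a = rec["id_a"].map(idx).to_numpy()
    b = rec["id_b"].map(idx).to_numpy()
    valid = (pos >= 0) & (pos < m)
    pos, a, b = pos[valid], a[valid], b[valid]

    def _one(mask: np.ndarray, label: str, date=None) -> AssociationMatrix:
        onw = on[:, mask].astype(np.int64)
        effort = onw @ onw.T
        np.fill_diagonal(effort, 0)
        keep = mask[pos]
        raw = np.zeros((n, n), dtype=np.int64)
        if keep.any():
            dyad_min = np.unique(np.stack([a[keep], b[keep], pos[keep]], axis=1), axis=0)
            np.add.at(raw, (dyad_min[:, 0], dyad_min[:, 1]), 1)
            raw = raw + raw.T
        return AssociationMatrix(ids=ids, raw_count=raw, effort=effort,
                                 window_label=label, window_minutes_per_day=wmpd, date=date)

    if not per_date:
        return _one(class_mask, window)
    out = {}
    for d in sorted(set(date_label[class_mask])):
        mask = class_mask & (date_label == d).to_numpy()
        out[d] = _one(mask, window, date=d)
    return out


def mean_signals(matrix: AssociationMatrix, how: str = "mean",
                 reference_minutes: float | None = None):
    """Per-individual corrected signal level, plus the group mean ± sd.

    Each dyadic rate is re-expressed as expected contact minutes per 24 h
    of its window class (day rates scale by the day-window length, night
    rates by its complement), so animals with unequal battery life are
    comparable. Per individual, dyads with zero joint effort are excluded;
    ``how='mean'`` averages over the remaining partners, ``how='sum'``
    totals them (both offered because either reading of a per-individual
    "mean number of signals" is defensible; 'mean' is the default).

    Returns ``(per_id: pd.Series, group_mean: float, group_sd: float)``.
    """
    if len(matrix.ids) < 2:
        raise ValueError("need at least two individuals")
    if how not in ("mean", "sum"):
        raise ValueError("how must be 'mean' or 'sum'")
    ref = matrix.window_minutes_per_day if reference_minutes is None else reference_minutes
    if not (matrix.effort > 0).any():
        raise ValueError("all dyadic efforts are zero; nothing was jointly observed")
    signals = matrix.rate * ref
    per_id = {}
    for k, i in enumerate(matrix.ids):
        row = np.delete(signals[k], k)
        row = row[~np.isnan(row)]
        if row.size == 0:
            per_id[i] = np.nan
        else:
            per_id[i] = float(row.mean() if how == "mean" else row.sum())
    s = pd.Series(per_id, name="mean_signals")
    valid = s.dropna()
    return s, float(valid.mean()), float(valid.std(ddof=1)) if len(valid) > 1 else 0.0


# ---------------------------------------------------------------------------
# modularity

def modularity_q(weights: np.ndarray, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Newman–Girvan modularity of a weighted undirected graph.

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / 2m] * delta(c_i, c_j),
    with A the (symmetric, zero-diagonal) weight matrix, k the weighted
    degrees and 2m the total weight. Q = 0 for the all-in-one partition.
    """
    w = np.asarray(weights, dtype=float)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        raise ValueError("graph has no positive edge weight")
    same = labels[:, None] == labels[None, :]
    return float(((w - resolution * np.outer(k, k) / two_m) * same).sum() / two_m)


def _canonical_partition(ids, labels) -> dict[str, int]:
    # relabel communities by their lowest member id
    by_comm: dict[int, list[str]] = {}
    for i, c in zip(ids, labels):
        by_comm.setdefault(c, []).append(i)
    order = sorted(by_comm.values(), key=lambda members: min(members))
    return {i: new for new, members in enumerate(order) for i in members}


def max_modularity(matrix: AssociationMatrix, resolution: float = 1.0,
                   n_restarts: int = 25, seed: int = 0,
                   signal_how: str = "mean") -> NetworkMetrics:
    """Community search maximising weighted modularity.

    Louvain optimisation with ``n_restarts`` seeded restarts; the best-Q
    partition is kept (ties: first found) and relabelled canonically by
    lowest member id. Only ids with at least one positive-rate edge enter
    the graph.
    """
    rate = matrix.rate
    g = nx.Graph()
    for i_k, i in enumerate(matrix.ids):
        for j_k in range(i_k + 1, len(matrix.ids)):
            w = rate[i_k, j_k]
            if np.isfinite(w) and w > 0:
                g.add_edge(i, matrix.ids[j_k], weight=float(w))
    if g.number_of_edges() == 0:
        raise ValueError("graph has no positive edge; modularity undefined")
    nodes = sorted(g.nodes)
    w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")

    best_q, best_labels = -np.inf, None
    for r in range(n_restarts):
        comms = louvain_communities(g, weight="weight", resolution=resolution,
                                    seed=seed + r)
        lab = np.empty(len(nodes), dtype=int)
        for c, members in enumerate(comms):
            for node in members:
                lab[nodes.index(node)] = c
        q = modularity_q(w, lab, resolution=resolution)
        if q > best_q:
            best_q, best_labels = q, lab

    partition = _canonical_partition(nodes, best_labels)
    per_id, _, _ = mean_signals(matrix, how=signal_how)
    ref = f"{matrix.window_label}" + (f":{matrix.date}" if matrix.date else "")
    return NetworkMetrics(modularity_q=best_q, partition=partition,
                          mean_signals_per_individual=per_id, matrix_ref=ref)


# ---------------------------------------------------------------------------
# comparisons

def centrality_vs_age(per_id_means: Mapping[str, float] | pd.Series,
                      ages: Mapping[str, float] | pd.Series) -> StatResult:
    """Spearman correlation of per-individual signal level with age (years)."""
    m = pd.Series(per_id_means).dropna()
    a = pd.Series(ages).astype(float)
    common = sorted(set(m.index) & set(a.index))
    if len(common) < 3:
        raise ValueError("need at least 3 individuals with both signal mean and age")
    return spearman_corr(m[common].to_numpy(), a[common].to_numpy())


def contrast_windows(x, y, paired: bool, alternative: str = "two-sided") -> StatResult:
    """Rank test between two sets of window-level metrics.

    ``x`` and ``y`` are e.g. per-window mean signal levels or modularities
    for day vs night (paired by date) or tether on vs off (unpaired).
    """
    return rank_test_2sample(x, y, paired=paired, alternative=alternative)


# ---------------------------------------------------------------------------
# export

def write_edgelist_csv(matrix: AssociationMatrix, path) -> None:
    rate = matrix.rate
    rows = []
    for i_k, i in enumerate(matrix.ids):
        for j_k in range(i_k + 1, len(matrix.ids)):
            w = rate[i_k, j_k]
            if np.isfinite(w) and w > 0:
                rows.append((i, matrix.ids[j_k], w))
    pd.DataFrame(rows, columns=["id_a", "id_b", "rate"]).to_csv(path, index=False)


def write_graphml(matrix: AssociationMatrix, path) -> None:
    g = nx.Graph()
    rate = matrix.rate
    g.add_nodes_from(matrix.ids)
    for i_k, i in enumerate(matrix.ids):
        for j_k in range(i_k + 1, len(matrix.ids)):
            w = rate[i_k, j_k]
            if np.isfinite(w) and w > 0:
                g.add_edge(i, matrix.ids[j_k], weight=float(w))
    nx.write_graphml(g, path)
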