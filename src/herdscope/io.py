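"""File formats, metadata, configuration and the end-to-end pipeline.

The pipeline ties the stages together: activity profiles and herd/class
comparisons, day- and night-wise association networks with mean-signal and
modularity contrasts (herd, day/night, tether on/off), the signal-vs-age
correlation, and the GPS cohesion analysis. Every number in the report is
a pure aggregation of the module operations — nothing is computed here
that cannot be recomputed by calling the modules directly.

All timestamps are stored UTC internally and converted to the configured
timezone only where the local clock matters (diel binning, day/night
windows).
"""
from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import actigraphy, cohesion, proximity, trajectory
from .actigraphy import ActivitySeries
from .proximity import ContactLog
from .stats import StatResult
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_meta", "load_gps", "validate_ids",
           "run_pipeline", "write_report"]

_COLUMN_SYNONYMS = {
    "id": "individual_id", "animal_id": "individual_id", "individual": "individual_id",
    "time": "timestamp", "datetime": "timestamp", "date_time": "timestamp",
    "latitude": "lat", "longitude": "lon", "long": "lon",
    "activity": "magnitude", "counts": "magnitude",
    "id1": "id_a", "id2": "id_b", "logger_a": "id_a", "logger_b": "id_b",
}


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read a delimited table, tolerating delimiter and column-name variants."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [_COLUMN_SYNONYMS.get(c.strip().lower(), c.strip().lower())
                  for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    return df


@dataclass
class PipelineConfig:
    """Analysis constants for one end-to-end run."""

    timezone: str = actigraphy.DEFAULT_TZ
    day_window: tuple[dt.time, dt.time] = proximity.DEFAULT_DAY_WINDOW
    vmax_kmh: float = 6.0
    regular_interval: str = "2min"
    max_fill_gap: str = "20min"
    scan_interval: str = "30min"
    sep_threshold: float = 0.5
    sep_unit: str = "degrees"
    modularity_resolution: float = 1.0
    modularity_restarts: int = 25
    seed: int = 0
    juvenile_age_cutoff: float = 4.0
    signal_how: str = "mean"

    def __post_init__(self):
        if isinstance(self.day_window[0], str):
            self.day_window = tuple(dt.time.fromisoformat(t) for t in self.day_window)
        for name in ("vmax_kmh", "sep_threshold", "juvenile_age_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["day_window"] = [t.isoformat(timespec="minutes") for t in self.day_window]
        return d


def load_meta(source, juvenile_age_cutoff: float = 4.0) -> pd.DataFrame:
    """Load the individual metadata table and derive the age class.

    Requires columns ``individual_id, herd, sex, age``; ``class`` is
    derived (juvenile below the cutoff, adult at or above it) and checked
    for consistency if already present. Duplicate ids are an error.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = [_COLUMN_SYNONYMS.get(c.strip().lower(), c.strip().lower())
                      for c in df.columns]
    else:
        df = _read_table(source, ("individual_id", "herd", "sex", "age"))
    df["individual_id"] = df["individual_id"].astype(str)
    if df["individual_id"].duplicated().any():
        dupes = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise ValueError(f"duplicate individual ids in metadata: {dupes}")
    df["age"] = df["age"].astype(float)
    if (df["age"] < 0).any():
        raise ValueError("ages must be non-negative")
    derived = np.where(df["age"] < juvenile_age_cutoff, "juvenile", "adult")
    if "class" in df.columns:
        if not (df["class"].to_numpy() == derived).all():
            raise ValueError("metadata 'class' column inconsistent with age and cutoff")
    df["class"] = derived
    return df


def load_gps(source) -> dict[str, Trajectory]:
    """Read a GPS fix table into raw per-individual trajectories."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = [_COLUMN_SYNONYMS.get(str(c).strip().lower(), str(c).strip().lower())
                      for c in df.columns]
    else:
        df = _read_table(source, ("individual_id", "timestamp", "lat", "lon"))
    out = {}
    for ind, sub in df.groupby("individual_id", sort=True):
        out[str(ind)] = Trajectory.from_frame(str(ind), sub)
    return out


def validate_ids(streams: dict[str, set], meta: pd.DataFrame) -> dict:
    """Classify every stream id as matched or unmatched against the metadata."""
    known = set(meta["individual_id"].astype(str))
    report = {}
    for name, ids in streams.items():
        ids = set(map(str, ids))
        report[name] = {
            "matched": sorted(ids & known),
            "unmatched": sorted(ids - known),
        }
    report["meta_only"] = sorted(known - set().union(*map(set, (
        set(map(str, s)) for s in streams.values()))) if streams else known)
    return report


def _stat(res: StatResult) -> dict:
    return {"test": res.name, "statistic": res.statistic, "p_value": res.p_value,
            "n": res.n, **res.extra}


def _profile_dict(profile: actigraphy.DielProfile) -> dict:
    t = profile.table
    return {
        "mean_by_hour": [None if pd.isna(v) else round(float(v), 6) for v in t["mean"]],
        "n_by_hour": [int(v) for v in t["n_epochs"]],
    }


# ---------------------------------------------------------------------------
# pipeline blocks

def _activity_block(series: list[ActivitySeries], meta: pd.DataFrame,
                    cfg: PipelineConfig) -> dict:
    herd_of = dict(zip(meta["individual_id"], meta["herd"]))
    class_of = dict(zip(meta["individual_id"], meta["class"]))
    series = [s for s in series if s.individual_id in herd_of]
    for s in series:
        s.herd = herd_of[s.individual_id]
    out = {"diel_profile_by_herd": {}, "diel_profile_by_class": {}}
    profiles = actigraphy.diel_profile(series, "herd", tz=cfg.timezone)
    for k, p in profiles.items():
        out["diel_profile_by_herd"][k] = _profile_dict(p)
    for k, p in actigraphy.diel_profile(series, "age_class", meta=class_of,
                                        tz=cfg.timezone).items():
        out["diel_profile_by_class"][k] = _profile_dict(p)

    herds = sorted(set(herd_of[s.individual_id] for s in series))
    if len(herds) >= 2:
        out["herd_comparison"] = {
            level: _stat(actigraphy.compare_distributions(
                actigraphy.group_activity(series, "herd", level=level)))
            for level in ("pooled", "individual")
        }
    out["class_comparison_by_herd"] = {}
    for h in herds:
        sub = [s for s in series if s.herd == h]
        classes = {class_of[s.individual_id] for s in sub}
        if len(classes) >= 2:
            out["class_comparison_by_herd"][h] = {
                level: _stat(actigraphy.compare_distributions(
                    actigraphy.group_activity(sub, "age_class", meta=class_of,
                                              level=level)))
                for level in ("pooled", "individual")
            }
    return out


def _window_metrics(matrices: dict, cfg: PipelineConfig) -> pd.DataFrame:
    """Per window instance (one date, day or night): group mean signal and Q."""
    rows = []
    for d, m in sorted(matrices.items()):
        try:
            _, gmean, gsd = proximity.mean_signals(m, how=cfg.signal_how)
        except ValueError:
            continue
        try:
            q = proximity.max_modularity(
                m, resolution=cfg.modularity_resolution,
                n_restarts=cfg.modularity_restarts, seed=cfg.seed,
                signal_how=cfg.signal_how).modularity_q
        except ValueError:
            q = np.nan
        rows.append({"date": d, "window": m.window_label,
                     "mean_signal": gmean, "sd_signal": gsd, "modularity_q": q})
    return pd.DataFrame(rows)


def _network_block(contacts: ContactLog, meta: pd.DataFrame,
                   logger_windows: dict, cfg: PipelineConfig,
                   tether_calendar: dict | None) -> dict:
    out = {}
    herd_of = dict(zip(meta["individual_id"], meta["herd"]))
    herds = sorted(meta["herd"].unique())
    per_id_all: dict[str, float] = {}
    per_herd_tables = {}
    for h in herds:
        ids = set(meta.loc[meta["herd"] == h, "individual_id"])
        rec = contacts.records
        sub = rec[rec["id_a"].isin(ids) & rec["id_b"].isin(ids)]
        if sub.empty:
            out[h] = {"skipped": "no contacts for this herd"}
            continue
        log = ContactLog(sub.reset_index(drop=True))
        lw = {i: logger_windows[i] for i in ids if i in logger_windows}
        kw = dict(day_window=cfg.day_window, tz=cfg.timezone)
        day_mats = proximity.build_association(log, lw, "day", per_date=True, **kw)
        night_mats = proximity.build_association(log, lw, "night", per_date=True, **kw)
        all_mat = proximity.build_association(log, lw, "all", **kw)

        tab_day = _window_metrics(day_mats, cfg)
        tab_night = _window_metrics(night_mats, cfg)
        per_herd_tables[h] = (tab_day, tab_night)
        hblock = {
            "windows_day": tab_day.assign(date=tab_day["date"].astype(str))
                                   .to_dict("records") if len(tab_day) else [],
            "windows_night": tab_night.assign(date=tab_night["date"].astype(str))
                                      .to_dict("records") if len(tab_night) else [],
        }

        per_id, gmean, gsd = proximity.mean_signals(all_mat, how=cfg.signal_how)
        per_id_all.update({i: v for i, v in per_id.items()})
        hblock["overall_mean_signal"] = {"mean": gmean, "sd": gsd}

        # day vs night, paired by date
        common = sorted(set(tab_day["date"]) & set(tab_night["date"])) \
            if len(tab_day) and len(tab_night) else []
        if len(common) >= 2:
            d_ = tab_day.set_index("date").loc[common]
            n_ = tab_night.set_index("date").loc[common]
            hblock["day_vs_night"] = {
                "mean_signal": _stat(proximity.contrast_windows(
                    d_["mean_signal"], n_["mean_signal"], paired=True)),
            }
            both_q = d_["modularity_q"].notna() & n_["modularity_q"].notna()
            if both_q.sum() >= 2:
                hblock["day_vs_night"]["modularity"] = _stat(
                    proximity.contrast_windows(d_.loc[both_q, "modularity_q"],
                                               n_.loc[both_q, "modularity_q"],
                                               paired=True))

        # tether on/off over night windows
        if tether_calendar and h in tether_calendar and len(tab_night):
            tether_dates = {pd.Timestamp(d).date() for d in tether_calendar[h]}
            on = tab_night[tab_night["date"].isin(tether_dates)]
            off = tab_night[~tab_night["date"].isin(tether_dates)]
            if len(on) and len(off):
                hblock["tether_on_vs_off"] = {
                    "mean_signal": _stat(proximity.contrast_windows(
                        on["mean_signal"], off["mean_signal"], paired=False)),
                }
                if on["modularity_q"].notna().all() and off["modularity_q"].notna().all():
                    hblock["tether_on_vs_off"]["modularity"] = _stat(
                        proximity.contrast_windows(on["modularity_q"],
                                                   off["modularity_q"], paired=False))
        out[h] = hblock

    if len(herds) >= 2:
        sig_by_herd = {h: [v for i, v in per_id_all.items() if herd_of.get(i) == h
                           and not pd.isna(v)] for h in herds}
        if all(len(v) >= 2 for v in sig_by_herd.values()):
            h0, h1 = herds[:2]
            out["herd_comparison_mean_signal"] = _stat(
                proximity.contrast_windows(sig_by_herd[h0], sig_by_herd[h1],
                                           paired=False))

    ages = dict(zip(meta["individual_id"], meta["age"]))
    if len(per_id_all) >= 3:
        try:
            out["age_correlation"] = _stat(
                proximity.centrality_vs_age(per_id_all, ages))
        except ValueError as exc:
            out["age_correlation"] = {"skipped": str(exc)}
    out["_per_id_mean_signal"] = {i: (None if pd.isna(v) else float(v))
                                  for i, v in sorted(per_id_all.items())}
    return out


def _cohesion_block(tracks: dict[str, Trajectory], cfg: PipelineConfig) -> dict:
    cleaned = {}
    removed = {}
    origin = min(t.fixes.index[0] for t in tracks.values()).floor(cfg.regular_interval)
    for ind, tr in tracks.items():
        if len(tr) < 2:
            continue
        filt, rem = trajectory.speed_filter(tr, cfg.vmax_kmh)
        removed[ind] = len(rem)
        cleaned[ind] = trajectory.regularise(filt, cfg.regular_interval,
                                             cfg.max_fill_gap, origin=origin)
    if len(cleaned) < 2:
        return {"skipped": "fewer than two usable tracks"}
    partitions = cohesion.scan_clusters(list(cleaned.values()), cfg.scan_interval,
                                        cfg.sep_threshold, cfg.sep_unit)
    series = cohesion.CohesionSeries.from_partitions(partitions, tz=cfg.timezone)
    out = {"n_fixes_removed_by_speed_filter": removed,
           "fractions": cohesion.cohesion_fraction(series)}
    try:
        hourly = cohesion.period_summary(series, by="hour")
        out["hourly"] = {"omnibus": _stat(hourly["omnibus"])}
    except ValueError as exc:
        out["hourly"] = {"skipped": str(exc)}
    try:
        p4 = cohesion.period_summary(series, by="period4h")
        out["period4h"] = {
            "omnibus": _stat(p4["omnibus"]),
            "summary": {k: {"mean": float(r["mean"]), "sd": float(r["sd"]),
                            "n": int(r["n"])}
                        for k, r in p4["summary"].iterrows()},
            "pairwise": p4["pairwise"].to_dict("records"),
        }
    except ValueError as exc:
        out["period4h"] = {"skipped": str(exc)}
    return out


def run_pipeline(meta, config: PipelineConfig | None = None, *,
                 activity: list[ActivitySeries] | None = None,
                 contacts: ContactLog | None = None,
                 gps: dict[str, Trajectory] | None = None,
                 logger_windows: dict | None = None,
                 tether_calendar: dict | None = None) -> dict:
    """Run every analysis the supplied streams allow; skip the rest.

    ``meta`` is the individual table (path or DataFrame); streams are
    in-memory objects (use the loaders for files). ``logger_windows``
    (id -> (on, off)) defaults to each logger's observed activity window,
    falling back to its contact span. ``tether_calendar`` maps a herd
    label to the local dates whose nights were tethered. Deterministic for
    a fixed config.
    """
    cfg = config or PipelineConfig()
    if not isinstance(meta, pd.DataFrame):
        meta = load_meta(meta, cfg.juvenile_age_cutoff)
    else:
        meta = load_meta(meta, cfg.juvenile_age_cutoff)
    report: dict = {"config": cfg.to_dict(), "skipped": []}

    streams = {}
    if activity is not None:
        streams["activity"] = {s.individual_id for s in activity}
    if contacts is not None:
        streams["contacts"] = set(contacts.ids)
    if gps is not None:
        streams["gps"] = set(gps)
    report["id_validation"] = validate_ids(streams, meta)

    known = set(meta["individual_id"])
    if activity is not None:
        usable = [s for s in activity if s.individual_id in known]
        if usable:
            report["activity"] = _activity_block(usable, meta, cfg)
        else:
            report["skipped"].append("activity: no ids matched metadata")
    else:
        report["skipped"].append("activity: stream missing")

    if contacts is not None and len(contacts):
        if logger_windows is None:
            logger_windows = {}
            if activity is not None:
                logger_windows.update({s.individual_id: s.logger_window
                                       for s in activity})
            rec = contacts.records
            for i in contacts.ids:
                if i not in logger_windows:
                    mask = (rec["id_a"] == i) | (rec["id_b"] == i)
                    ts = rec.loc[mask, "timestamp"]
                    logger_windows[i] = (ts.min(), ts.max() + pd.Timedelta(minutes=1))
        lw = {i: w for i, w in logger_windows.items() if i in known}
        rec = contacts.records
        keep = rec["id_a"].isin(known) & rec["id_b"].isin(known)
        log = ContactLog(rec[keep].reset_index(drop=True))
        if len(log):
            report["networks"] = _network_block(log, meta, lw, cfg, tether_calendar)
        else:
            report["skipped"].append("contacts: no ids matched metadata")
    else:
        report["skipped"].append("contacts: stream missing")

    if gps is not None and len(gps) >= 2:
        report["cohesion"] = _cohesion_block(
            {i: t for i, t in gps.items() if i in known}, cfg)
    else:
        report["skipped"].append("gps: stream missing or fewer than two tracks")

    return report


def write_report(report: dict, out_dir) -> Path:
    """Write the machine-readable JSON results index; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "results.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
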