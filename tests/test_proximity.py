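"""Contact logs, corrected association matrices, modularity, contrasts."""
import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from herdscope import proximity, sim
from herdscope.proximity import (AssociationMatrix, ContactLog, build_association,
                                 centrality_vs_age, contrast_windows,
                                 max_modularity, mean_signals, modularity_q,
                                 split_day_night)

UTC = "UTC"


def _log(rows):
    return ContactLog(pd.DataFrame(rows, columns=["id_a", "id_b", "timestamp", "rssi"]))


# ---------------------------------------------------------------------------
# ContactLog

def test_contact_log_canonicalises_dyads_and_collapses_duplicates():
    log = _log([("b", "a", "2022-03-10T10:00:00Z", -50.0),
                ("a", "b", "2022-03-10T10:00:00Z", -60.0),
                ("a", "b", "2022-03-10T10:01:00Z", -55.0)])
    assert len(log) == 2
    assert (log.records["id_a"] == "a").all()


def test_contact_log_rejects_self_contacts_and_positive_rssi():
    with pytest.raises(ValueError, match="elf-contact"):
        _log([("a", "a", "2022-03-10T10:00:00Z", -50.0)])
    with pytest.raises(ValueError, match="RSSI"):
        _log([("a", "b", "2022-03-10T10:00:00Z", 5.0)])


# ---------------------------------------------------------------------------
# day/night split

def test_split_day_night_boundaries():
    # local noon is day; exactly 17:00 local is night (half-open window)
    noon = pd.Timestamp("2022-03-10 12:00", tz="Asia/Kathmandu").tz_convert(UTC)
    five = pd.Timestamp("2022-03-10 17:00", tz="Asia/Kathmandu").tz_convert(UTC)
    six = pd.Timestamp("2022-03-10 06:00", tz="Asia/Kathmandu").tz_convert(UTC)
    log = _log([("a", "b", noon.isoformat(), -50.0),
                ("a", "b", five.isoformat(), -50.0),
                ("a", "b", six.isoformat(), -50.0)])
    day, night = split_day_night(log)
    assert len(day) == 2 and len(night) == 1
    assert night.records["timestamp"].iloc[0] == five


def test_split_day_night_is_a_partition():
    rng = np.random.default_rng(5)
    t0 = pd.Timestamp("2022-03-10", tz=UTC)
    rows = [("a", "b", (t0 + pd.Timedelta(minutes=int(m))).isoformat(), -60.0)
            for m in rng.choice(1440, 200, replace=False)]
    log = _log(rows)
    day, night = split_day_night(log)
    merged = (pd.concat([day.records, night.records])
              .sort_values(["timestamp", "id_a", "id_b"]).reset_index(drop=True))
    pd.testing.assert_frame_equal(merged, log.records)


# ---------------------------------------------------------------------------
# association matrices

def test_rate_forced_by_definition():
    """Both loggers share 80 on-minutes; 40 contact minutes -> rate 0.5."""
    t0 = pd.Timestamp("2022-03-10 10:00", tz=UTC)
    lw = {"a": (t0, t0 + pd.Timedelta(minutes=80)),
          "b": (t0, t0 + pd.Timedelta(minutes=100))}
    rows = [("a", "b", (t0 + pd.Timedelta(minutes=2 * k)).isoformat(), -60.0)
            for k in range(40)]
    mat = build_association(_log(rows), lw, "all")
    i, j = mat.ids.index("a"), mat.ids.index("b")
    assert mat.effort[i, j] == 80
    assert mat.raw_count[i, j] == 40
    assert mat.rate[i, j] == pytest.approx(0.5)


def test_dead_logger_gives_flagged_undefined_rate():
    t0 = pd.Timestamp("2022-03-10 10:00", tz=UTC)
    lw = {"a": (t0, t0 + pd.Timedelta(minutes=60)),
          "b": (t0, t0)}  # logger b never on
    log = _log([("a", "c", t0.isoformat(), -60.0)])
    lw["c"] = (t0, t0 + pd.Timedelta(minutes=60))
    mat = build_association(log, lw, "all")
    i, j = mat.ids.index("a"), mat.ids.index("b")
    assert mat.effort[i, j] == 0 and np.isnan(mat.rate[i, j])


def test_missing_logger_window_is_an_error():
    log = _log([("a", "b", "2022-03-10T10:00:00Z", -60.0)])
    with pytest.raises(ValueError, match="missing a logger window"):
        build_association(log, {"a": (pd.Timestamp("2022-03-10", tz=UTC),
                                      pd.Timestamp("2022-03-11", tz=UTC))}, "all")


def _brute_force_rates(log, logger_windows, window, day_window, tz):
    """Independent oracle: scan every minute for each dyad."""
    ids = sorted(logger_windows)
    t0 = min(w[0] for w in logger_windows.values()).floor("min")
    t1 = max(w[1] for w in logger_windows.values()).ceil("min")
    minutes = pd.date_range(t0, t1, freq="min", inclusive="left")
    contact = {}
    for row in log.records.itertuples():
        contact.setdefault((row.id_a, row.id_b), set()).add(row.timestamp.floor("min"))
    start, end = day_window
    result = {}
    for a, b in itertools.combinations(ids, 2):
        eff = 0
        cnt = 0
        for m in minutes:
            loc = m.tz_convert(tz).time()
            is_day = start <= loc < end
            if window == "day" and not is_day:
                continue
            if window == "night" and is_day:
                continue
            on_a = logger_windows[a][0] <= m < logger_windows[a][1]
            on_b = logger_windows[b][0] <= m < logger_windows[b][1]
            if on_a and on_b:
                eff += 1
                if m in contact.get((a, b), set()):
                    cnt += 1
        result[(a, b)] = (cnt, eff)
    return result


@pytest.mark.parametrize("window", ["all", "day", "night"])
def test_association_matches_brute_force_minute_scan(window):
    cfg = sim.SimulationConfig(n_individuals=4, n_juveniles=0, duration_days=1,
                               rng_seed=9,
                               battery_death={"herd1_y03": 10.5})
    res = sim.simulate_herd(cfg)
    mat = build_association(res.contacts, res.logger_windows, window)
    oracle = _brute_force_rates(res.contacts, res.logger_windows, window,
                                proximity.DEFAULT_DAY_WINDOW, proximity.DEFAULT_TZ)
    for (a, b), (cnt, eff) in oracle.items():
        i, j = mat.ids.index(a), mat.ids.index(b)
        assert mat.raw_count[i, j] == cnt
        assert mat.effort[i, j] == eff
    rate = mat.rate
    assert np.array_equal(rate, rate.T) or np.allclose(rate, rate.T, equal_nan=True)
    ok = mat.effort > 0
    assert ((rate[ok] >= 0) & (rate[ok] <= 1)).all()


def test_association_invariant_to_record_order_and_chunking(small_sim):
    log = small_sim.contacts
    lw = small_sim.logger_windows
    base = build_association(log, lw, "all")
    shuffled = ContactLog(log.records.sample(frac=1, random_state=3)
                          .reset_index(drop=True))
    again = build_association(shuffled, lw, "all")
    assert np.array_equal(base.raw_count, again.raw_count)
    assert np.array_equal(base.effort, again.effort)
    # chunking: rebuild from two halves concatenated
    half = len(log.records) // 2
    rejoined = ContactLog(pd.concat([log.records.iloc[half:], log.records.iloc[:half]])
                          .reset_index(drop=True))
    again2 = build_association(rejoined, lw, "all")
    assert np.array_equal(base.raw_count, again2.raw_count)


# ---------------------------------------------------------------------------
# mean signals

def _matrix_from_rates(ids, rate, minutes=660.0, label="day"):
    rate = np.asarray(rate, dtype=float)
    effort = np.full_like(rate, 1000.0)
    np.fill_diagonal(effort, 0.0)
    raw = (rate * effort).astype(np.int64)
    return AssociationMatrix(ids=tuple(ids), raw_count=raw,
                             effort=effort.astype(np.int64), window_label=label,
                             window_minutes_per_day=minutes)


def test_mean_signals_uniform_rates():
    m = _matrix_from_rates(["a", "b", "c"],
                           [[0, .5, .5], [.5, 0, .5], [.5, .5, 0]], minutes=1.0)
    per_id, gmean, gsd = mean_signals(m)
    assert np.allclose(per_id, 0.5)
    assert gmean == pytest.approx(0.5) and gsd == pytest.approx(0.0)


def test_mean_signals_isolated_individual_scores_zero():
    m = _matrix_from_rates(["a", "b", "c"],
                           [[0, 0, 0], [0, 0, .4], [0, .4, 0]], minutes=1.0)
    per_id, _, _ = mean_signals(m)
    assert per_id["a"] == 0.0


def test_mean_signals_scales_to_reference_duration():
    m = _matrix_from_rates(["a", "b"], [[0, .25], [.25, 0]], minutes=660.0)
    per_id, _, _ = mean_signals(m)
    assert per_id["a"] == pytest.approx(0.25 * 660.0)


def test_tethered_juveniles_exchange_more_night_signals():
    """Paired seeds: tethered nights drive juvenile association above the
    untethered counterfactual."""
    wins = 0
    for seed in range(10):
        per = {}
        for tether in (True, False):
            cfg = sim.SimulationConfig(
                n_individuals=6, n_juveniles=3, duration_days=1, rng_seed=200 + seed,
                tether_enabled=tether,
                tether_positions=tuple(sim.default_tether_line(3)) if tether else None)
            res = sim.simulate_herd(cfg)
            mat = build_association(res.contacts, res.logger_windows, "night")
            per_id, _, _ = mean_signals(mat)
            per[tether] = per_id[list(cfg.juvenile_ids)].mean()
        wins += per[True] > per[False]
    assert wins >= 9


# ---------------------------------------------------------------------------
# modularity

def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f")])
    return g


def _matrix_from_graph(g):
    ids = tuple(sorted(g.nodes))
    n = len(ids)
    raw = np.zeros((n, n), dtype=np.int64)
    for u, v, d in g.edges(data=True):
        w = int(d.get("weight", 1) * 100)
        i, j = ids.index(u), ids.index(v)
        raw[i, j] = raw[j, i] = w
    effort = np.full((n, n), 100, dtype=np.int64)
    np.fill_diagonal(effort, 0)
    return AssociationMatrix(ids=ids, raw_count=np.minimum(raw, effort), effort=effort,
                             window_label="all", window_minutes_per_day=1440.0)


def test_two_disjoint_triangles_q_half():
    res = max_modularity(_matrix_from_graph(two_triangles()))
    assert res.modularity_q == pytest.approx(0.5)
    part = res.partition
    assert part["a"] == part["b"] == part["c"]
    assert part["d"] == part["e"] == part["f"]
    assert part["a"] != part["d"]


def test_complete_graph_single_community():
    res = max_modularity(_matrix_from_graph(nx.complete_graph(5)))
    assert res.modularity_q == pytest.approx(0.0)
    assert len(set(res.partition.values())) == 1


def test_reported_q_consistent_with_partition():
    rng = np.random.default_rng(11)
    g = nx.gnp_random_graph(7, 0.5, seed=4)
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
    mat = _matrix_from_graph(g)
    res = max_modularity(mat)
    ids = sorted(res.partition)
    w = np.zeros((len(ids), len(ids)))
    rate = mat.rate
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if a != b:
                w[i, j] = rate[mat.ids.index(a), mat.ids.index(b)]
    labels = np.array([res.partition[a] for a in ids])
    # independent recomputation through networkx's modularity
    comms = [set(np.array(ids)[labels == c]) for c in sorted(set(labels))]
    gq = nx.Graph()
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if w[i, j] > 0:
                gq.add_edge(a, ids[j], weight=w[i, j])
    q_nx = nx.community.modularity(gq, comms, weight="weight")
    assert res.modularity_q == pytest.approx(q_nx)


def test_no_positive_edge_is_an_error():
    n = 3
    mat = AssociationMatrix(ids=("a", "b", "c"),
                            raw_count=np.zeros((n, n), dtype=np.int64),
                            effort=np.full((n, n), 10, dtype=np.int64)
                            - 10 * np.eye(n, dtype=np.int64),
                            window_label="all", window_minutes_per_day=1440.0)
    with pytest.raises(ValueError, match="no positive edge"):
        max_modularity(mat)


# ---------------------------------------------------------------------------
# correlations and contrasts

def test_strictly_decreasing_signals_give_r_minus_one():
    ids = [f"i{k}" for k in range(6)]
    ages = {i: k + 1 for k, i in enumerate(ids)}
    sig = {i: 10.0 - k for k, i in enumerate(ids)}
    res = centrality_vs_age(sig, ages)
    assert res.statistic == pytest.approx(-1.0)


def test_rank_correlation_matches_hand_computed_instance():
    # ranks of x: 1,2,3,4; ranks of y: 2,1,4,3 -> sum d^2 = 4
    # r = 1 - 6*4/(4*15) = 0.6
    x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
    y = {"a": 20.0, "b": 10.0, "c": 40.0, "d": 30.0}
    res = centrality_vs_age(x, y)
    assert res.statistic == pytest.approx(0.6)
    assert res.extra["S"] == pytest.approx(4.0)


def test_null_correlation_centred_on_zero():
    rng = np.random.default_rng(13)
    rs = []
    for _ in range(1000):
        sig = rng.normal(size=30)
        age = rng.normal(size=30)
        ids = [str(k) for k in range(30)]
        rs.append(centrality_vs_age(dict(zip(ids, sig)), dict(zip(ids, age))).statistic)
    assert abs(np.mean(rs)) < 0.05


def test_constant_vector_rejected():
    ids = ["a", "b", "c", "d"]
    with pytest.raises(ValueError, match="constant"):
        centrality_vs_age(dict.fromkeys(ids, 1.0), dict(zip(ids, [1, 2, 3, 4])))


def test_identical_paired_samples_give_p_one():
    res = contrast_windows([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert res.p_value == 1.0


def test_constant_positive_shift_one_sided_signed_rank():
    x = np.arange(10, dtype=float)
    res = contrast_windows(x + 5.0, x, paired=True, alternative="greater")
    assert res.p_value == pytest.approx(2.0 ** -10, rel=1e-6)


def test_paired_length_mismatch_rejected():
    with pytest.raises(ValueError, match="unequal"):
        contrast_windows([1.0, 2.0], [1.0], paired=True)
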