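"""Logger QC pipeline: unit harmonization, range filters, hourly
aggregation, cross-site removal, IDW gap filling and bioclim summaries."""

import numpy as np
import pandas as pd
import pytest

from urbanocc import microclimate as mc
from urbanocc import synthetic


def _records(rows):
    return pd.DataFrame(rows, columns=["site_id", "timestamp", "variable",
                                       "value", "unit"])


def _hourly(rows):
    df = pd.DataFrame(rows, columns=["site_id", "hour", "t_min", "t_max", "rh"])
    df["hour"] = pd.to_datetime(df["hour"])
    df["temp_flag"] = np.where(df["t_min"].notna(), "observed", "missing")
    df["rh_flag"] = np.where(df["rh"].notna(), "observed", "missing")
    return df


# ---------------------------------------------------------------------------
# harmonize
# ---------------------------------------------------------------------------

def test_fahrenheit_converted_exactly():
    raw = _records([("A", "2017-01-01 00:00", "air_temperature", 68.0, "F")])
    out, _ = mc.harmonize(raw)
    assert out["value"].iloc[0] == pytest.approx(20.0)
    assert out["unit"].iloc[0] == "C"


def test_duplicates_keep_first():
    raw = _records([
        ("A", "2017-01-01 00:00", "air_temperature", 20.0, "C"),
        ("A", "2017-01-01 00:00", "air_temperature", 21.0, "C"),
    ])
    out, rep = mc.harmonize(raw)
    assert len(out) == 1 and out["value"].iloc[0] == 20.0
    assert rep["removed_duplicates"] == 1


def test_unknown_unit_names_the_record():
    raw = _records([("B", "2017-01-01 00:00", "air_temperature", 20.0, "K")])
    with pytest.raises(ValueError, match="B"):
        mc.harmonize(raw)


def test_mixed_unit_site_count_conserved():
    land = synthetic.generate_landscape(4, (5, 5), seed=1)
    art = synthetic.LoggerArtifacts(fahrenheit_fraction=0.5, spike_rate=0.0,
                                    duplicate_rate=0.01,
                                    missing_blocks_per_site=0, hot_site=False)
    streams = synthetic.generate_logger_streams(land, days=2, seed=2,
                                                artifacts=art)
    out, rep = mc.harmonize(streams.records)
    assert set(out["unit"]) == {"C", "percent"}
    assert rep["output"] == rep["input"] - rep["removed_duplicates"]


# ---------------------------------------------------------------------------
# range filter (strict thresholds)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("value,kept", [
    (55.0, False),   # above 50
    (50.0, True),    # exactly 50: "more than" is strict
    (-5.0, True),    # exactly -5: "less than" is strict
    (-5.01, False),
    (20.0, True),
])
def test_temperature_range_rule(value, kept):
    raw = _records([("A", "2017-01-01 00:00", "air_temperature", value, "C")])
    out, _ = mc.filter_variables_and_range(raw)
    assert (len(out) == 1) == kept


@pytest.mark.parametrize("value,kept", [(101.0, False), (100.0, True),
                                        (0.0, True), (-0.5, False)])
def test_rh_range_rule(value, kept):
    raw = _records([("A", "2017-01-01 00:00", "relative_humidity", value,
                     "percent")])
    out, _ = mc.filter_variables_and_range(raw)
    assert (len(out) == 1) == kept


def test_non_target_variables_dropped():
    raw = _records([
        ("A", "2017-01-01 00:00", "soil_temperature", 15.0, "C"),
        ("A", "2017-01-01 00:00", "insolation", 600.0, "W/m2"),
        ("A", "2017-01-01 00:00", "air_temperature", 15.0, "C"),
    ])
    out, rep = mc.filter_variables_and_range(raw)
    assert list(out["variable"]) == ["air_temperature"]
    assert rep["removed_other_variables"] == 2


# ---------------------------------------------------------------------------
# site exclusions
# ---------------------------------------------------------------------------

def test_empty_exclusion_list_is_identity():
    raw = _records([("A", "2017-01-01 00:00", "air_temperature", 20.0, "C")])
    out, rep = mc.apply_site_exclusions(raw, [])
    pd.testing.assert_frame_equal(out, raw)
    assert rep["removed"] == 0


def test_exclusion_drops_interval_records():
    rows = [("A", f"2017-0{m}-15 00:00", "air_temperature", 20.0, "C")
            for m in range(1, 5)]
    raw = _records(rows)
    excl = [("A", "air_temperature", ("2017-02-01", "2017-04-01"))]
    out, rep = mc.apply_site_exclusions(raw, excl)
    assert len(out) == 2 and rep["removed"] == 2


def test_unknown_site_exclusion_warns_and_noop():
    raw = _records([("A", "2017-01-01 00:00", "air_temperature", 20.0, "C")])
    with pytest.warns(UserWarning):
        out, _ = mc.apply_site_exclusions(
            raw, [("Z", "air_temperature", ("2017-01-01", "2017-02-01"))])
    assert len(out) == 1


def test_malformed_interval_rejected():
    raw = _records([("A", "2017-01-01 00:00", "air_temperature", 20.0, "C")])
    with pytest.raises(ValueError):
        mc.apply_site_exclusions(raw, [("A", "air_temperature",
                                        ("2017-03-01", "2017-01-01"))])


def test_hot_run_interval_empties_site_temperature():
    land = synthetic.generate_landscape(5, (5, 5), seed=3)
    art = synthetic.LoggerArtifacts(fahrenheit_fraction=0.0, spike_rate=0.0,
                                    duplicate_rate=0.0,
                                    missing_blocks_per_site=0,
                                    hot_site=True, hot_run_days=2)
    streams = synthetic.generate_logger_streams(land, days=4, seed=4,
                                                artifacts=art)
    s, _ = mc.harmonize(streams.records)
    excl = mc.flag_hot_runs(s)
    assert {e[0] for e in excl} == {streams.truth["hot_site"]}
    out, _ = mc.apply_site_exclusions(s, excl)
    site, var, (lo, hi) = excl[0]
    ts = pd.to_datetime(out["timestamp"])
    in_interval = ((out["site_id"] == site) & (out["variable"] == var)
                   & (ts >= lo) & (ts < hi))
    assert in_interval.sum() == 0


# ---------------------------------------------------------------------------
# hourly aggregation
# ---------------------------------------------------------------------------

def _slots(site, hour, values, variable="air_temperature", unit="C"):
    base = pd.Timestamp(hour)
    return [(site, base + pd.Timedelta(minutes=5 * i), variable, v, unit)
            for i, v in enumerate(values) if v is not None]


def test_constant_hour_gives_equal_min_max():
    raw = _records(_slots("A", "2017-01-01 00:00", [20.0] * 12))
    h = mc.hourly_minmax(raw)
    assert h["t_min"].iloc[0] == 20.0 and h["t_max"].iloc[0] == 20.0


def test_two_missing_slots_exceed_ten_percent():
    vals = [20.0] * 10 + [None, None]  # 2/12 = 16.7% missing
    h = mc.hourly_minmax(_records(_slots("A", "2017-01-01 00:00", vals)))
    assert np.isnan(h["t_min"].iloc[0])


def test_one_missing_slot_is_tolerated():
    vals = [20.0] * 11 + [None]  # 8.3% missing
    h = mc.hourly_minmax(_records(_slots("A", "2017-01-01 00:00", vals)))
    assert h["t_min"].iloc[0] == 20.0


def test_three_of_twelve_slots_is_missing_hour():
    vals = [18.0, 19.0, 21.0] + [None] * 9
    h = mc.hourly_minmax(_records(_slots("A", "2017-01-01 00:00", vals)))
    assert np.isnan(h["t_min"].iloc[0])


# ---------------------------------------------------------------------------
# cross-site removal (strict 25% rule)
# ---------------------------------------------------------------------------

def _hour_grid(n_sites, n_missing):
    hour = "2017-01-01 05:00"
    rows = []
    for i in range(n_sites):
        v = None if i < n_missing else 20.0
        rows.append((f"S{i:02d}", hour, v, v, 50.0))
    return _hourly(rows)


def test_sixteen_of_sixty_missing_drops_hour_everywhere():
    h, rep = mc.cross_site_removal(_hour_grid(60, 16), n_sites=60)
    assert h["t_min"].isna().all()
    assert (h["temp_flag"] == "removed").all()
    assert rep["temperature"]["hours_removed"] == 1


def test_fifteen_of_sixty_missing_is_retained():
    h, _ = mc.cross_site_removal(_hour_grid(60, 15), n_sites=60)
    assert h["t_min"].notna().sum() == 45


def test_single_present_site_retained():
    h, _ = mc.cross_site_removal(_hour_grid(1, 0), n_sites=1)
    assert h["t_min"].notna().all()


# ---------------------------------------------------------------------------
# IDW gap fill
# ---------------------------------------------------------------------------

def _coords(points):
    return pd.DataFrame([{"site_id": s, "x": x, "y": y} for s, x, y in points])


def test_idw_constant_donors_fill_with_constant():
    h = _hourly([("A", "2017-01-01 00:00", None, None, None),
                 ("B", "2017-01-01 00:00", 10.0, 12.0, 50.0),
                 ("C", "2017-01-01 00:00", 10.0, 12.0, 50.0)])
    coords = _coords([("A", 0, 0), ("B", 1, 0), ("C", 0, 2)])
    out, rep = mc.idw_gap_fill(h, coords)
    a = out[out["site_id"] == "A"].iloc[0]
    assert a["t_min"] == pytest.approx(10.0)
    assert a["rh"] == pytest.approx(50.0)
    assert a["temp_flag"] == "idw_filled"


def test_idw_hand_computed_weighted_mean():
    """Donors at d=1,2,4 with values 10,20,40 -> 30/1.75."""
    h = _hourly([("A", "2017-01-01 00:00", None, None, None),
                 ("B", "2017-01-01 00:00", 10.0, 10.0, 10.0),
                 ("C", "2017-01-01 00:00", 20.0, 20.0, 20.0),
                 ("D", "2017-01-01 00:00", 40.0, 40.0, 40.0)])
    coords = _coords([("A", 0, 0), ("B", 1, 0), ("C", 2, 0), ("D", 4, 0)])
    out, _ = mc.idw_gap_fill(h, coords)
    a = out[out["site_id"] == "A"].iloc[0]
    expected = (10 / 1 + 20 / 2 + 40 / 4) / (1 + 0.5 + 0.25)
    assert a["t_min"] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(30 / 1.75)


def test_idw_uses_available_donors_when_fewer_than_three():
    h = _hourly([("A", "2017-01-01 00:00", None, None, None),
                 ("B", "2017-01-01 00:00", 10.0, 10.0, 10.0),
                 ("C", "2017-01-01 00:00", 30.0, 30.0, 30.0)])
    coords = _coords([("A", 0, 0), ("B", 1, 0), ("C", 3, 0)])
    out, _ = mc.idw_gap_fill(h, coords)
    a = out[out["site_id"] == "A"].iloc[0]
    assert a["t_min"] == pytest.approx((10 / 1 + 30 / 3) / (1 + 1 / 3), abs=1e-9)


def test_idw_no_donors_leaves_missing_with_warning():
    h = _hourly([("A", "2017-01-01 00:00", None, None, 40.0),
                 ("B", "2017-01-01 00:00", None, None, 50.0)])
    coords = _coords([("A", 0, 0), ("B", 1, 0)])
    with pytest.warns(UserWarning):
        out, rep = mc.idw_gap_fill(h, coords)
    assert out["t_min"].isna().all()
    assert rep["unfillable"] > 0


def test_idw_matches_brute_force_oracle_and_is_convex():
    rng = np.random.default_rng(17)
    for trial in range(20):
        n = int(rng.integers(4, 9))
        xy = rng.uniform(0, 10, size=(n, 2))
        vals = rng.uniform(0, 30, size=n)
        missing = int(rng.integers(0, n))
        rows, pts = [], []
        for i in range(n):
            v = None if i == missing else float(vals[i])
            rows.append((f"S{i:02d}", "2017-01-01 00:00", v, v, v))
            pts.append((f"S{i:02d}", xy[i, 0], xy[i, 1]))
        out, _ = mc.idw_gap_fill(_hourly(rows), _coords(pts))
        got = out[out["site_id"] == f"S{missing:02d}"]["t_min"].iloc[0]
        # independent brute force: 3 nearest donors, weights 1/d
        d = np.sqrt(((xy - xy[missing]) ** 2).sum(1))
        donors = [i for i in np.argsort(d, kind="stable") if i != missing][:3]
        w = 1.0 / d[donors]
        expected = float((w * vals[donors]).sum() / w.sum())
        assert got == pytest.approx(expected, abs=1e-9)
        assert vals[donors].min() - 1e-12 <= got <= vals[donors].max() + 1e-12


# ---------------------------------------------------------------------------
# annual bioclim
# ---------------------------------------------------------------------------

def _full_days(site, temps, rh=50.0, start="2017-01-01"):
    """Hourly rows covering len(temps)/24 complete days."""
    hours = pd.date_range(start, periods=len(temps), freq="h")
    return _hourly([(site, h, t, t, rh) for h, t in zip(hours, temps)])


def test_constant_temperature_gives_flat_bioclim():
    h = _full_days("A", [20.0] * 48)
    out, _ = mc.annual_bioclim(h)
    assert out["bio1"].iloc[0] == pytest.approx(20.0)
    assert out["bio2"].iloc[0] == pytest.approx(0.0)


def test_sinusoid_recovers_mean_and_range():
    hours = np.arange(24 * 10)
    temps = 18.0 + 4.0 * np.sin(2 * np.pi * hours / 24)
    out, _ = mc.annual_bioclim(_full_days("A", list(temps)))
    assert out["bio1"].iloc[0] == pytest.approx(18.0, abs=0.05)
    # daily range of a +/-4 sinusoid sampled hourly is slightly under 8
    assert out["bio2"].iloc[0] == pytest.approx(8.0, abs=0.15)


def test_partial_days_excluded_from_daily_range():
    temps = [15.0] * 12 + [10.0] * 24 + [30.0] * 24 + [40.0] * 5
    h = _full_days("A", temps, start="2017-01-01 12:00")
    out, _ = mc.annual_bioclim(h)
    # only the two complete days count; each is constant -> range 0
    assert out["n_complete_days"].iloc[0] == 2
    assert out["bio2"].iloc[0] == pytest.approx(0.0)


def test_empty_site_omitted_with_warning():
    h = _hourly([("A", "2017-01-01 00:00", None, None, 50.0),
                 ("B", "2017-01-01 00:00", 20.0, 20.0, 50.0)])
    with pytest.warns(UserWarning):
        out, rep = mc.annual_bioclim(h)
    assert list(out["site_id"]) == ["B"]
    assert rep["sites_omitted"] == ["A"]


def test_bioclim_round_trip_through_generator():
    """Zero-artifact streams reproduce the generating site climate."""
    land = synthetic.generate_landscape(8, (8, 8), seed=5)
    streams = synthetic.generate_logger_streams(
        land, days=10, seed=6, artifacts=synthetic.ZERO_ARTIFACTS)
    coords = land.sites[["site_id", "x", "y"]]
    bioclim, _, _ = mc.clean_pipeline(streams.records, coords)
    merged = bioclim.merge(land.sites, on="site_id")
    assert np.allclose(merged["bio1"], merged["t_mean"], atol=0.2)
    assert np.allclose(merged["bio2"], merged["diurnal_range"], atol=0.2)
    assert np.allclose(merged["rh_mean_x"], merged["rh_mean_y"], atol=1.0)


# ---------------------------------------------------------------------------
# pipeline-level invariants
# ---------------------------------------------------------------------------

def test_early_steps_are_idempotent():
    land = synthetic.generate_landscape(5, (5, 5), seed=9)
    streams = synthetic.generate_logger_streams(land, days=3, seed=10)
    s1, _ = mc.harmonize(streams.records)
    excl = mc.flag_hot_runs(s1)
    s1, _ = mc.filter_variables_and_range(s1)
    s1, _ = mc.apply_site_exclusions(s1, excl)
    s2, rep_h = mc.harmonize(s1)
    s2, rep_f = mc.filter_variables_and_range(s2)
    s2, rep_e = mc.apply_site_exclusions(s2, excl)
    assert rep_h["removed_duplicates"] == 0
    assert rep_f["removed_temperature_range"] == 0
    assert rep_e["removed"] == 0
    pd.testing.assert_frame_equal(
        s1.reset_index(drop=True), s2.reset_index(drop=True))


def test_conservation_ledger_reconciles():
    land = synthetic.generate_landscape(6, (6, 6), seed=11)
    streams = synthetic.generate_logger_streams(land, days=4, seed=12)
    coords = land.sites[["site_id", "x", "y"]]
    _, _, report = mc.clean_pipeline(streams.records, coords)
    h = report["harmonize"]
    assert h["input"] - h["removed_duplicates"] == h["output"]
    f = report["range_filter"]
    assert (f["input"] - f["removed_other_variables"]
            - f["removed_temperature_range"] - f["removed_rh_range"]
            == f["output"])
    e = report["site_exclusions"]
    assert e["input"] - e["removed"] == e["output"]
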