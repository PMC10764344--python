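"""Environmental-logger QC pipeline and annual bioclimatic summaries.

The cleaning sequence is order-fixed:

1. harmonize units and drop duplicate records,
2. keep only air temperature and relative humidity,
3. range-filter physically impossible values (temperature outside
   (-5, 50) C, humidity outside [0, 100] %),
4. drop configured site/variable/interval exclusions (e.g. a logger that
   recorded a months-long run above 60 C),
5. aggregate to hourly Tmin/Tmax and hourly mean RH, treating an hour as
   missing when more than 10% of its twelve 5-minute slots are absent,
6. remove an hour for *all* sites when more than 25% of sites are missing
   it,
7. fill remaining gaps by inverse-distance weighting over the three
   nearest sites with valid values (power 1), and
8. summarize each site's year as BIO1 (mean annual temperature), BIO2
   (mean diurnal range) and mean relative humidity.

Every filtering step reports ``removed + retained = input`` counts in a QC
ledger.  All thresholds are strict inequalities, exactly as worded in the
protocol ("less than", "more than").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

KEEP_VARIABLES = ("air_temperature", "relative_humidity")
KNOWN_UNITS = ("C", "F", "percent", "W/m2")
TEMP_MIN_C, TEMP_MAX_C = -5.0, 50.0
HOUR_SLOTS = 12
SLOT_MISSING_FRACTION = 0.10
SITE_MISSING_FRACTION = 0.25
IDW_NEIGHBORS = 3
IDW_POWER = 1.0

_HOURLY_VARS = {"t_min": "temp", "t_max": "temp", "rh": "rh"}


def harmonize(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop duplicate records and convert Fahrenheit temperatures to Celsius."""
    df = raw.copy()
    unknown = ~df["unit"].isin(KNOWN_UNITS)
    if unknown.any():
        rec = df[unknown].iloc[0]
        raise ValueError(
            f"unknown unit {rec['unit']!r} at site {rec['site_id']} "
            f"{rec['timestamp']} ({rec['variable']})"
        )
    n_in = len(df)
    df = df.drop_duplicates(subset=["site_id", "timestamp", "variable"], keep="first")
    n_dupes = n_in - len(df)
    in_f = df["unit"] == "F"
    df = df.copy()
    df.loc[in_f, "value"] = (df.loc[in_f, "value"] - 32.0) * 5.0 / 9.0
    df.loc[in_f, "unit"] = "C"
    report = {"input": n_in, "removed_duplicates": n_dupes,
              "converted_fahrenheit": int(in_f.sum()), "output": len(df)}
    return df.reset_index(drop=True), report


def filter_variables_and_range(s: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep air temperature and RH; drop out-of-range values (strict bounds)."""
    n_in = len(s)
    df = s[s["variable"].isin(KEEP_VARIABLES)]
    n_var = n_in - len(df)
    is_t = df["variable"] == "air_temperature"
    bad_t = is_t & ((df["value"] < TEMP_MIN_C) | (df["value"] > TEMP_MAX_C))
    bad_rh = ~is_t & ((df["value"] < 0.0) | (df["value"] > 100.0))
    df = df[~(bad_t | bad_rh)].reset_index(drop=True)
    report = {"input": n_in, "removed_other_variables": n_var,
              "removed_temperature_range": int(bad_t.sum()),
              "removed_rh_range": int(bad_rh.sum()), "output": len(df)}
    return df, report


def flag_hot_runs(s: pd.DataFrame, threshold: float = 60.0,
                  min_readings: int = 12) -> list[tuple]:
    """Exclusion intervals for sites with implausibly hot temperature runs.

    A calendar month is flagged when a site logs more than ``min_readings``
    air-temperature values above the threshold — a sustained run pointing at
    a broken logger, as opposed to isolated spikes that the range filter
    already removes.  The whole span of flagged months is excluded
    (generalizing the one-bad-logger rule of the original QC).
    """
    temp = s[s["variable"] == "air_temperature"]
    out = []
    for sid, grp in temp.groupby("site_id"):
        hot = grp[grp["value"] > threshold]
        if hot.empty:
            continue
        months = pd.to_datetime(hot["timestamp"]).dt.to_period("M")
        counts = months.value_counts()
        flagged = counts[counts > min_readings].index
        if len(flagged) == 0:
            continue
        lo = flagged.min().to_timestamp()
        hi = (flagged.max() + 1).to_timestamp()
        out.append((sid, "air_temperature", (lo, hi)))
    return out


def apply_site_exclusions(s: pd.DataFrame, exclusions) -> tuple[pd.DataFrame, dict]:
    """Drop records matching (site, variable, [start, end)) exclusion rules."""
    n_in = len(s)
    drop = np.zeros(n_in, dtype=bool)
    applied = []
    ts = pd.to_datetime(s["timestamp"])
    for site, variable, interval in exclusions or []:
        try:
            lo, hi = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
        except (TypeError, ValueError, IndexError) as err:
            raise ValueError(f"malformed exclusion interval {interval!r}") from err
        if lo > hi:
            raise ValueError(f"exclusion interval reversed: {interval!r}")
        if site not in set(s["site_id"]):
            warnings.warn(f"exclusion for unknown site {site!r} ignored")
            continue
        sel = ((s["site_id"] == site) & (s["variable"] == variable)
               & (ts >= lo) & (ts < hi)).to_numpy()
        drop |= sel
        applied.append({"site": site, "variable": variable,
                        "start": str(lo), "end": str(hi),
                        "n_removed": int(sel.sum())})
    df = s[~drop].reset_index(drop=True)
    report = {"input": n_in, "removed": int(drop.sum()), "output": len(df),
              "exclusions": applied}
    return df, report


def hourly_minmax(s: pd.DataFrame) -> pd.DataFrame:
    """Hourly Tmin/Tmax and mean RH; hours with >10% missing slots are NaN.

    Returns a wide frame with columns (site_id, hour, t_min, t_max, rh,
    temp_flag, rh_flag); flags are 'observed' or 'missing'.
    """
    df = s.copy()
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.floor("h")
    min_slots = int(np.ceil(HOUR_SLOTS * (1.0 - SLOT_MISSING_FRACTION)))

    temp = df[df["variable"] == "air_temperature"]
    rh = df[df["variable"] == "relative_humidity"]
    ta = temp.groupby(["site_id", "hour"])["value"].agg(["min", "max", "count"])
    ra = rh.groupby(["site_id", "hour"])["value"].agg(["mean", "count"])
    out = pd.DataFrame(index=ta.index.union(ra.index))
    out["t_min"] = ta["min"].where(ta["count"] >= min_slots)
    out["t_max"] = ta["max"].where(ta["count"] >= min_slots)
    out["rh"] = ra["mean"].where(ra["count"] >= min_slots)
    out = out.reset_index().rename(columns={"level_0": "site_id", "level_1": "hour"})
    out["temp_flag"] = np.where(out["t_min"].notna(), "observed", "missing")
    out["rh_flag"] = np.where(out["rh"].notna(), "observed", "missing")
    return out


def _full_grid(h: pd.DataFrame, sites) -> pd.DataFrame:
    """Reindex the hourly frame onto the full site x hour lattice."""
    hours = np.sort(h["hour"].unique())
    idx = pd.MultiIndex.from_product([list(sites), hours], names=["site_id", "hour"])
    out = h.set_index(["site_id", "hour"]).reindex(idx).reset_index()
    for flag in ("temp_flag", "rh_flag"):
        out[flag] = out[flag].fillna("missing")
    return out


def cross_site_removal(h: pd.DataFrame, n_sites: int,
                       sites=None) -> tuple[pd.DataFrame, dict]:
    """Remove an hour for all sites when >25% of sites are missing it."""
    sites = list(sites) if sites is not None else sorted(h["site_id"].unique())
    out = _full_grid(h, sites)
    report = {}
    for var, flag in (("t_min", "temp_flag"), ("rh", "rh_flag")):
        present = out.groupby("hour")[var].count()
        frac_missing = 1.0 - present / float(n_sites)
        bad_hours = present.index[frac_missing > SITE_MISSING_FRACTION]
        sel = out["hour"].isin(bad_hours)
        n_removed = int((sel & out[var].notna()).sum())
        cols = ["t_min", "t_max"] if var == "t_min" else ["rh"]
        out.loc[sel, cols] = np.nan
        out.loc[sel, flag] = "removed"
        report[var if var == "rh" else "temperature"] = {
            "hours_removed": len(bad_hours), "records_removed": n_removed}
    return out, report


def idw_gap_fill(h: pd.DataFrame, coords: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Fill remaining missing hours by inverse-distance weighting.

    For each missing (site, hour, variable) not struck by the cross-site
    rule, the fill is the 1/d-weighted mean over the three nearest sites
    holding valid values that hour (fewer if fewer donors exist; none
    leaves the value missing with a warning).  Distances are Euclidean in
    the projected site coordinates; nearest-neighbor ties break by site id.
    """
    coords = coords.set_index("site_id") if "site_id" in coords.columns else coords
    sites = sorted(h["site_id"].unique())
    xy = coords.loc[sites, ["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    # distance-ordered neighbor lists, ties broken by site id (index order)
    d_rank = d.copy()
    np.fill_diagonal(d_rank, np.inf)
    order = np.argsort(d_rank, kind="stable", axis=1)

    out = h.sort_values(["hour", "site_id"], kind="stable").reset_index(drop=True)
    site_pos = {s: i for i, s in enumerate(sites)}
    pos = out["site_id"].map(site_pos).to_numpy()
    n_filled = {"t_min": 0, "t_max": 0, "rh": 0}
    n_unfillable = 0
    for var, flag in (("t_min", "temp_flag"), ("t_max", "temp_flag"), ("rh", "rh_flag")):
        vals = out[var].to_numpy(dtype=float).copy()
        flags = out[flag].to_numpy(dtype=object)
        for hour, idx in out.groupby("hour").indices.items():
            v = vals[idx]
            missing = np.isnan(v) & (flags[idx] != "removed")
            if not missing.any() or np.isnan(v).all():
                if missing.any():
                    n_unfillable += int(missing.sum())
                continue
            by_site = np.full(len(sites), np.nan)
            by_site[pos[idx]] = v
            valid = ~np.isnan(by_site)
            for local_i in np.where(missing)[0]:
                si = pos[idx[local_i]]
                donors = [j for j in order[si] if valid[j]][:IDW_NEIGHBORS]
                if not donors:
                    n_unfillable += 1
                    continue
                dd = d[si, donors]
                if (dd == 0).any():
                    fill = by_site[np.asarray(donors)[dd == 0]].mean()
                else:
                    w = 1.0 / dd ** IDW_POWER
                    fill = float((w * by_site[donors]).sum() / w.sum())
                vals[idx[local_i]] = fill
                n_filled[var] += 1
                flags[idx[local_i]] = "idw_filled"
        out[var] = vals
        out[flag] = flags
    if n_unfillable:
        warnings.warn(f"{n_unfillable} missing values had no donor sites")
    return out, {"filled": n_filled, "unfillable": n_unfillable}


def annual_bioclim(h: pd.DataFrame, bio1_method: str = "midpoint"
                   ) -> tuple[pd.DataFrame, dict]:
    """Site-level BIO1, BIO2 and mean RH from the cleaned hourly series.

    BIO1 is the mean of hourly (Tmin+Tmax)/2 midpoints ('midpoint', the
    default) or the mean over complete days of (daily max + daily min)/2
    ('daily_extremes').  BIO2 is the mean over complete days (all 24 hourly
    values present, so partial first/last days drop out) of the daily range
    max(Tmax) - min(Tmin).
    """
    if bio1_method not in ("midpoint", "daily_extremes"):
        raise ValueError(f"unknown bio1_method {bio1_method!r}")
    rows = []
    skipped = []
    for sid, grp in h.groupby("site_id"):
        t = grp[grp["t_min"].notna() & grp["t_max"].notna()].copy()
        if t.empty:
            skipped.append(sid)
            continue
        t["day"] = t["hour"].dt.floor("D")
        daily = t.groupby("day").agg(
            hi=("t_max", "max"), lo=("t_min", "min"), n=("t_min", "count"))
        complete = daily[daily["n"] == 24]
        if bio1_method == "midpoint":
            bio1 = float(((t["t_min"] + t["t_max"]) / 2.0).mean())
        else:
            bio1 = float(((complete["hi"] + complete["lo"]) / 2.0).mean())
        bio2 = float((complete["hi"] - complete["lo"]).mean()) if len(complete) else np.nan
        rh = grp["rh"].dropna()
        rows.append({"site_id": sid, "bio1": bio1, "bio2": bio2,
                     "rh_mean": float(rh.mean()) if len(rh) else np.nan,
                     "n_complete_days": int(len(complete))})
    if skipped:
        warnings.warn(f"sites without cleaned temperature data omitted: {skipped}")
    return pd.DataFrame(rows), {"sites_omitted": skipped}


def clean_pipeline(raw: pd.DataFrame, coords: pd.DataFrame, exclusions=None,
                   auto_exclude_hot: bool = True, n_sites: int | None = None,
                   bio1_method: str = "midpoint"):
    """Run the full QC sequence; returns (bioclim table, hourly frame, report)."""
    report: dict = {}
    s, report["harmonize"] = harmonize(raw)
    excl = list(exclusions or [])
    if auto_exclude_hot:
        excl += flag_hot_runs(s)
    s, report["range_filter"] = filter_variables_and_range(s)
    s, report["site_exclusions"] = apply_site_exclusions(s, excl)
    h = hourly_minmax(s)
    n_sites = n_sites if n_sites is not None else coords["site_id"].nunique()
    h, report["cross_site"] = cross_site_removal(
        h, n_sites, sites=sorted(coords["site_id"]))
    h, report["idw"] = idw_gap_fill(h, coords)
    bioclim, report["bioclim"] = annual_bioclim(h, bio1_method=bio1_method)
    fills = h.groupby("site_id")[["temp_flag", "rh_flag"]].agg(
        lambda f: float(np.mean(f == "idw_filled")))
    report["fill_fraction_per_site"] = {
        str(k): {"temp": float(v["temp_flag"]), "rh": float(v["rh_flag"])}
        for k, v in fills.iterrows()}
    return bioclim, h, report
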