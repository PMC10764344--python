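"""Synthetic study system with known ground truth.

Emulates the design of a city-wide Malaise-trap monitoring network: ~60
backyard sites sampled one week per month for a year, six arthropod groups
whose species respond heterogeneously to landscape covariates, and
five-minute environmental logger streams recorded beside each trap.  The
landscape covariates are generated from a linear structural equation model
over the same causal DAG the analysis assumes, so confounding is present by
construction and backdoor adjustment genuinely matters downstream.

Everything is driven by numpy Generators: the same seed reproduces the same
landscape, community, detection histories and logger streams byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .causal import ALL_MODEL_TERMS, CausalDAG, default_dag
from .occupancy import SurveyData, month_squared
from .rasters import Raster

#: Species per taxonomic group in the study community.
GROUP_SIZES = {
    "Phoridae": 108,
    "Syrphidae": 34,
    "Tipuloidea": 20,
    "Drosophilidae": 27,
    "Mycetophilidae": 23,
    "Araneae": 24,
}

COVARIATES = ALL_MODEL_TERMS + ("rh_mean",)

#: Structural coefficients of the generating DAG on the standardized latent
#: scale.  Chosen to give moderate confounding (|r| ~ 0.3-0.6): elevation and
#: ocean proximity raise living desirability, inland cells swing harder
#: between day and night, development dries the air.
DEFAULT_SEM_COEFS = {
    ("elevation", "d_natural"): -0.5,
    ("elevation", "land_value"): 0.45,
    ("elevation", "impervious"): -0.4,
    ("d_ocean", "diurnal_range"): 0.6,
    ("d_ocean", "land_value"): -0.45,
    ("d_ocean", "impervious"): 0.35,
    ("d_natural", "land_value"): -0.3,
    ("d_natural", "impervious"): 0.35,
    ("elevation", "rh_mean"): -0.3,
    ("d_ocean", "rh_mean"): -0.5,
    ("t_mean", "rh_mean"): -0.35,
    ("impervious", "rh_mean"): -0.25,
}

#: Affine / monotone maps from the latent z-scale to physical units.
_PHYSICAL = {
    "elevation": lambda z: 300.0 + 220.0 * z,
    "d_ocean": lambda z: 50.0 + 18.0 * z,
    "d_natural": lambda z: np.exp(7.0 + 0.8 * z),
    "t_mean": lambda z: 18.0 + 2.0 * z,
    "diurnal_range": lambda z: 12.0 + 2.5 * z,
    "rh_mean": lambda z: 100.0 * expit(0.2 + 0.35 * z),
    "impervious": lambda z: 100.0 * expit(0.2 + 0.8 * z),
    "land_value": lambda z: np.exp(12.0 + 0.5 * z),
}


@dataclass
class SyntheticLandscape:
    """Site table + covariate raster stack + the DAG that generated them."""

    sites: pd.DataFrame
    rasters: dict
    dag: CausalDAG

    def site_covariates(self, terms=None) -> pd.DataFrame:
        terms = list(terms) if terms is not None else list(COVARIATES)
        return self.sites.set_index("site_id")[terms]


def generate_landscape(
    n_sites: int = 60,
    grid_shape: tuple[int, int] = (40, 40),
    dag: CausalDAG | None = None,
    coefs: dict | None = None,
    noise_sd: float = 1.0,
    smooth_sigma: float = 3.0,
    seed: int = 0,
) -> SyntheticLandscape:
    """Generate a DAG-consistent covariate landscape and sample sites on it.

    Each covariate is a linear structural equation in its DAG parents plus
    spatially smoothed Gaussian noise of standard deviation ``noise_sd`` on
    the latent z-scale; root variables also carry weak spatial trends
    (elevation rises northward, ocean distance eastward) scaled by
    ``noise_sd``.  Latent fields map monotonically to physical units, so
    edge-coefficient signs survive in the physical covariates.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    nrows, ncols = grid_shape
    if n_sites > nrows * ncols:
        raise ValueError("more sites than grid cells")
    dag = dag or default_dag("Phoridae").without_outcome()
    if not nx.is_directed_acyclic_graph(dag.graph):
        raise ValueError("generating DAG must be acyclic")
    coefs = DEFAULT_SEM_COEFS if coefs is None else coefs

    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(dag.graph))
    # covariates not in the DAG are treated as independent roots
    order += [v for v in COVARIATES if v not in order]

    def smooth_noise():
        white = rng.standard_normal((nrows, ncols))
        f = gaussian_filter(white, smooth_sigma, mode="reflect")
        sd = f.std()
        return (f - f.mean()) / sd if sd > 0 else f - f.mean()

    col = np.linspace(-1.0, 1.0, ncols)[None, :] * np.ones((nrows, 1))
    row = np.linspace(1.0, -1.0, nrows)[:, None] * np.ones((1, ncols))
    trends = {"elevation": row, "d_ocean": col}

    z: dict[str, np.ndarray] = {}
    for var in order:
        parents = list(dag.graph.predecessors(var)) if var in dag.graph else []
        fld = np.zeros((nrows, ncols))
        for par in parents:
            coef = coefs.get((par, var), 0.0)
            fld = fld + coef * z[par]
        fld = fld + noise_sd * smooth_noise()
        if not parents:
            fld = fld + noise_sd * trends.get(var, 0.0)
        z[var] = fld

    rasters = {
        var: Raster(_PHYSICAL[var](z[var]), xll=0.0, yll=0.0, cellsize=1.0)
        for var in COVARIATES
    }

    cells = rng.choice(nrows * ncols, size=n_sites, replace=False)
    rows_i, cols_i = np.divmod(cells, ncols)
    sites = pd.DataFrame({
        "site_id": [f"S{i:02d}" for i in range(1, n_sites + 1)],
        "row": rows_i,
        "col": cols_i,
        "x": (cols_i + 0.5) * 1.0,
        "y": (nrows - rows_i - 0.5) * 1.0,
    })
    for var in COVARIATES:
        sites[var] = rasters[var].data[rows_i, cols_i]
    return SyntheticLandscape(sites=sites, rasters=rasters, dag=dag)


# ---------------------------------------------------------------------------
# Community ground truth
# ---------------------------------------------------------------------------

@dataclass
class TrueParameters:
    """Generating parameters of the occupancy and detection model."""

    psi0: float
    mu_slope: dict
    sigma_slope: dict
    sigma_species_psi: float
    p0: float
    p_month2: float
    sigma_species_p: float
    species_slopes: pd.DataFrame
    species_intercepts_psi: np.ndarray
    species_effects_p: np.ndarray

    def __post_init__(self):
        sds = [self.sigma_species_psi, self.sigma_species_p,
               *self.sigma_slope.values()]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        n = len(self.species_slopes)
        if not (len(self.species_intercepts_psi) == n
                and len(self.species_effects_p) == n):
            raise ValueError("species arrays have inconsistent lengths")
        if not np.isfinite(self.species_slopes.to_numpy()).all():
            raise ValueError("slopes must be finite")

    @property
    def n_species(self) -> int:
        return len(self.species_slopes)

    @property
    def predictors(self) -> tuple:
        return tuple(self.species_slopes.columns)


#: Community-mean slopes on standardized covariates; directions loosely echo
#: the field's expectations (diurnal swings and land value suppress
#: occupancy, proximity to natural areas helps).
DEFAULT_MU_SLOPE = {
    "t_mean": 0.2,
    "diurnal_range": -0.4,
    "elevation": 0.1,
    "d_ocean": 0.0,
    "d_natural": -0.2,
    "impervious": -0.1,
    "land_value": -0.2,
    "rh_mean": 0.1,
}


def generate_community(
    n_species: int,
    seed: int = 0,
    predictors=ALL_MODEL_TERMS,
    mu_slope: dict | None = None,
    sigma_slope: dict | float = 0.3,
    sigma_species_psi: float = 0.75,
    psi0: float = 0.0,
    p0: float = 0.0,
    p_month2: float = -0.4,
    sigma_species_p: float = 0.4,
    species_names=None,
) -> TrueParameters:
    """Draw a species community from the group-level normals."""
    if n_species < 1:
        raise ValueError("need at least one species")
    predictors = tuple(predictors)
    mu = {t: (mu_slope or DEFAULT_MU_SLOPE).get(t, 0.0) for t in predictors}
    if np.isscalar(sigma_slope):
        sig = {t: float(sigma_slope) for t in predictors}
    else:
        sig = {t: float(sigma_slope[t]) for t in predictors}
    if any(s < 0 for s in sig.values()) or min(sigma_species_psi, sigma_species_p) < 0:
        raise ValueError("standard deviations must be non-negative")

    rng = np.random.default_rng(seed)
    slopes = pd.DataFrame(
        {t: mu[t] + sig[t] * rng.standard_normal(n_species) for t in predictors}
    )
    if species_names is None:
        species_names = [f"sp{i:03d}" for i in range(1, n_species + 1)]
    slopes.index = list(species_names)
    return TrueParameters(
        psi0=psi0,
        mu_slope=mu,
        sigma_slope=sig,
        sigma_species_psi=sigma_species_psi,
        p0=p0,
        p_month2=p_month2,
        sigma_species_p=sigma_species_p,
        species_slopes=slopes,
        species_intercepts_psi=sigma_species_psi * rng.standard_normal(n_species),
        species_effects_p=sigma_species_p * rng.standard_normal(n_species),
    )


def group_community(group: str, seed: int = 0, **kwargs) -> TrueParameters:
    """Community preset sized to one of the study's taxonomic groups."""
    n = GROUP_SIZES[group]
    names = [f"{group}_{i:03d}" for i in range(1, n + 1)]
    return generate_community(n, seed=seed, species_names=names, **kwargs)


# ---------------------------------------------------------------------------
# Detection histories
# ---------------------------------------------------------------------------

def standardize_sites(landscape: SyntheticLandscape, terms) -> pd.DataFrame:
    """Z-score site covariates over sites (the occupancy-model input scale)."""
    cov = landscape.site_covariates(terms)
    sd = cov.std(ddof=0)
    if (sd == 0).any():
        raise ValueError("constant covariate cannot be standardized")
    return (cov - cov.mean()) / sd


def true_occupancy_probability(truth: TrueParameters, X: np.ndarray) -> np.ndarray:
    """psi[i, j] from the generating parameters and standardized design X."""
    eta = (
        truth.psi0
        + truth.species_intercepts_psi[:, None]
        + truth.species_slopes.to_numpy() @ X.T
    )
    return expit(eta)


def simulate_detections(
    truth: TrueParameters,
    landscape: SyntheticLandscape,
    n_months: int = 12,
    seed: int = 0,
    missing_rate: float = 0.0,
    group: str = "",
) -> SurveyData:
    """Simulate detection/non-detection histories under the generating model.

    Latent presence z ~ Bernoulli(psi) per species x site; detections
    y ~ Bernoulli(z * p) per month, with the mid-year detection peak from
    the squared-month term.  Missing visits (whole site-months) are dropped
    completely at random at ``missing_rate``.
    """
    X = standardize_sites(landscape, truth.predictors).to_numpy()
    n = truth.species_slopes.shape[0]
    if (X.shape[1] != truth.species_slopes.shape[1]
            or len(truth.species_intercepts_psi) != n
            or len(truth.species_effects_p) != n):
        raise ValueError("landscape/truth dimension mismatch")
    rng = np.random.default_rng(seed)
    psi = true_occupancy_probability(truth, X)  # (S, J)
    S, J = psi.shape
    months = np.arange(1, n_months + 1)
    m2 = month_squared(months)
    p = expit(truth.p0 + truth.p_month2 * m2[None, :]
              + truth.species_effects_p[:, None])  # (S, K)
    z = (rng.random((S, J)) < psi).astype(float)
    y = (rng.random((S, J, n_months)) < z[:, :, None] * p[:, None, :]).astype(float)
    if missing_rate > 0:
        miss = rng.random((J, n_months)) < missing_rate
        # keep at least one surveyed visit per site
        full = miss.all(axis=1)
        miss[full, 0] = False
        y[:, miss] = np.nan
    return SurveyData(
        y,
        species=list(truth.species_slopes.index),
        sites=list(landscape.sites["site_id"]),
        months=months,
        group=group,
        z_true=z,
    )


# ---------------------------------------------------------------------------
# Logger streams
# ---------------------------------------------------------------------------

@dataclass
class LoggerArtifacts:
    """Corruption rates for the raw logger streams.

    Defaults exercise every cleaning rule at least once on a typical run:
    unit flips, out-of-range spikes, duplicate rows, missing blocks and one
    implausibly hot site.
    """

    fahrenheit_fraction: float = 0.25
    spike_rate: float = 2e-4
    duplicate_rate: float = 2e-4
    missing_blocks_per_site: int = 1
    missing_block_hours: int = 6
    hot_site: bool = True
    hot_run_days: int = 30

    def __post_init__(self):
        rates = (self.fahrenheit_fraction, self.spike_rate, self.duplicate_rate)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if self.missing_blocks_per_site < 0 or self.missing_block_hours < 0:
            raise ValueError("missing-block settings must be non-negative")


ZERO_ARTIFACTS = LoggerArtifacts(
    fahrenheit_fraction=0.0, spike_rate=0.0, duplicate_rate=0.0,
    missing_blocks_per_site=0, hot_site=False,
)


@dataclass
class LoggerStreams:
    """Raw 5-minute records plus the injected-corruption ground truth."""

    records: pd.DataFrame  # site_id, timestamp, variable, value, unit
    truth: dict = field(default_factory=dict)


#: Instrument noise SD on 5-minute readings; logger-resolution scale so the
#: annual summaries are dominated by the diurnal signal, not sensor jitter.
SENSOR_NOISE_C = 0.03
SENSOR_NOISE_RH = 0.2
RH_DIURNAL_AMPLITUDE = 5.0


def generate_logger_streams(
    landscape: SyntheticLandscape,
    days: int = 365,
    seed: int = 0,
    artifacts: LoggerArtifacts | None = None,
    start: str = "2017-01-01",
) -> LoggerStreams:
    """Per-site 5-minute air temperature and relative humidity streams.

    Temperature follows a sinusoidal diurnal cycle around the site's mean
    with peak mid-afternoon and amplitude half the site's diurnal range;
    humidity swings in antiphase.  Configured artifacts are then injected
    and recorded in the returned ground truth.
    """
    if days < 1:
        raise ValueError("need at least one day")
    art = artifacts if artifacts is not None else LoggerArtifacts()
    rng = np.random.default_rng(seed)
    times = pd.date_range(start, periods=days * 288, freq="5min")
    hours = (times - times[0]).total_seconds().to_numpy() / 3600.0
    phase = np.sin(2 * np.pi * (hours % 24 - 9.0) / 24.0)

    frames = []
    site_ids = list(landscape.sites["site_id"])
    f_sites = [s for s in site_ids
               if rng.random() < art.fahrenheit_fraction]
    for _, site in landscape.sites.iterrows():
        sid = site["site_id"]
        temp = (site["t_mean"] + 0.5 * site["diurnal_range"] * phase
                + SENSOR_NOISE_C * rng.standard_normal(len(times)))
        rh = np.clip(
            site["rh_mean"] - RH_DIURNAL_AMPLITUDE * phase
            + SENSOR_NOISE_RH * rng.standard_normal(len(times)),
            0.0, 100.0,
        )
        for var, vals, unit in (("air_temperature", temp, "C"),
                                ("relative_humidity", rh, "percent")):
            frames.append(pd.DataFrame({
                "site_id": sid, "timestamp": times, "variable": var,
                "value": vals, "unit": unit,
            }))
    df = pd.concat(frames, ignore_index=True)
    truth: dict = {"fahrenheit_sites": f_sites, "exclusions": []}

    # spikes: physically impossible readings that the range filter must catch
    is_temp = df["variable"] == "air_temperature"
    spike = rng.random(len(df)) < art.spike_rate
    t_spike = spike & is_temp
    r_spike = spike & ~is_temp
    df.loc[t_spike, "value"] = rng.choice([80.0, -20.0], size=int(t_spike.sum()))
    df.loc[r_spike, "value"] = 105.0
    truth["n_spikes"] = int(spike.sum())

    # one site with an implausibly hot run ("sequence of months")
    if art.hot_site and days >= 2:
        hot = site_ids[int(rng.integers(len(site_ids)))]
        run_days = min(art.hot_run_days, days - 1)
        lo = times[0]
        hi = times[0] + pd.Timedelta(days=run_days)
        sel = (df["site_id"] == hot) & is_temp & (df["timestamp"] >= lo) & (df["timestamp"] < hi)
        df.loc[sel, "value"] = 65.0 + rng.standard_normal(int(sel.sum()))
        truth["hot_site"] = hot
        truth["exclusions"].append((hot, "air_temperature", (lo, hi)))

    # unit flips: whole-site temperature streams recorded in Fahrenheit
    in_f = df["site_id"].isin(f_sites) & is_temp
    df.loc[in_f, "value"] = df.loc[in_f, "value"] * 9.0 / 5.0 + 32.0
    df.loc[in_f, "unit"] = "F"

    # missing blocks: contiguous dropouts per site and variable
    if art.missing_blocks_per_site > 0 and art.missing_block_hours > 0:
        drop = np.zeros(len(df), dtype=bool)
        for sid in site_ids:
            for _ in range(art.missing_blocks_per_site):
                start_h = float(rng.uniform(0, max(days * 24 - art.missing_block_hours, 1)))
                lo = times[0] + pd.Timedelta(hours=start_h)
                hi = lo + pd.Timedelta(hours=art.missing_block_hours)
                drop |= ((df["site_id"] == sid)
                         & (df["timestamp"] >= lo) & (df["timestamp"] < hi))
        df = df[~drop]
    # duplicate rows
    dup = df.sample(frac=art.duplicate_rate, random_state=int(rng.integers(2**31)))
    truth["n_duplicates"] = len(dup)
    df = pd.concat([df, dup], ignore_index=True)
    df = df.sort_values(["site_id", "variable", "timestamp"],
                        kind="stable").reset_index(drop=True)
    return LoggerStreams(records=df, truth=truth)
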