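"""Multi-species hierarchical occupancy model.

Occupancy of species *i* at site *j* follows

    logit(psi_ij) = psi0 + a_i + sum_t b_it * x_jt

with species intercepts a_i ~ N(0, sigma_a^2) and species slopes
b_it ~ N(mu_t, sigma_t^2) drawn from group-level normals; detection of a
present species on visit k is

    logit(p_ik) = p0 + p_m2 * month2_k + c_i,      c_i ~ N(0, sigma_c^2)

where month2 is the squared centered-and-scaled calendar month, encoding a
mid-year detection peak when p_m2 < 0.  The latent presence z_ij ~
Bernoulli(psi_ij) is observed through y_ijk ~ Bernoulli(z_ij * p_ik);
missing visits contribute no detection term.

Fitting is by Markov chain Monte Carlo with latent-z data augmentation:
z has a closed-form Bernoulli full conditional, group-level means are
Gibbs-updated, and remaining parameters use random-walk Metropolis with
step sizes adapted during burn-in (frozen afterwards, so chains are
deterministic given the seed).  Priors are weakly informative on the scale
of standardized covariates: N(0, 10^2) on location parameters and
Uniform(0, 10) on standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, xlogy

from .causal import ModelSpec

MONTH_CENTER = 6.5
#: population SD of calendar months 1..12, used to scale the month covariate
MONTH_SCALE = float(np.std(np.arange(1, 13)))

_PRIOR_SD = 10.0  # N(0, 10^2) on location parameters
_SIGMA_MAX = 10.0  # Uniform(0, 10) on standard deviations


def month_squared(months) -> np.ndarray:
    """Squared centered/scaled calendar month (1..12)."""
    m = np.asarray(months, dtype=float)
    return ((m - MONTH_CENTER) / MONTH_SCALE) ** 2


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class SurveyData:
    """Detection histories y[species, site, month] with NaN = missing visit."""

    y: np.ndarray
    species: list
    sites: list
    months: np.ndarray
    group: str = ""
    z_true: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.months = np.asarray(self.months)
        S, J, K = self.y.shape
        if len(self.species) != S or len(self.sites) != J or len(self.months) != K:
            raise ValueError("label lengths inconsistent with y dimensions")
        vals = self.y[~np.isnan(self.y)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("detections must be 0, 1 or missing")
        if np.isnan(self.y).all(axis=(0, 2)).any():
            raise ValueError("every site needs at least one surveyed visit")
        if self.z_true is not None:
            seen = np.nan_to_num(self.y).max(axis=2) > 0
            if (seen & ~self.z_true.astype(bool)).any():
                raise ValueError("y=1 at a site where true z=0")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def to_long(self) -> pd.DataFrame:
        S, J, K = self.y.shape
        idx = np.indices((S, J, K))
        df = pd.DataFrame(
            {
                "species": np.asarray(self.species)[idx[0].ravel()],
                "site": np.asarray(self.sites)[idx[1].ravel()],
                "month": np.asarray(self.months)[idx[2].ravel()],
                "detected": self.y.ravel(),
            }
        )
        return df[~df["detected"].isna()].reset_index(drop=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame, group: str = "") -> "SurveyData":
        species = sorted(df["species"].unique())
        sites = sorted(df["site"].unique())
        months = np.arange(df["month"].min(), df["month"].max() + 1)
        y = np.full((len(species), len(sites), len(months)), np.nan)
        si = {s: i for i, s in enumerate(species)}
        ji = {s: i for i, s in enumerate(sites)}
        ki = {m: i for i, m in enumerate(months)}
        for row in df.itertuples(index=False):
            y[si[row.species], ji[row.site], ki[row.month]] = row.detected
        return cls(y, species, sites, months, group=group)


@dataclass
class McmcSettings:
    """Sampler settings; defaults follow the published run configuration."""

    iterations: int = 100_000
    burn_in: int = 1_000
    thin: int = 100
    chains: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.iterations, self.burn_in, self.thin, self.chains) <= 0:
            raise ValueError("all MCMC settings must be positive")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be below iterations")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Posterior samples, one leading (chain, draw) pair of axes per array."""

    params: dict
    species: list
    terms: tuple
    spec: ModelSpec | None = None

    def __post_init__(self):
        shapes = {k: v.shape[:2] for k, v in self.params.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"inconsistent chain/draw shapes: {shapes}")
        for key in ("sigma", "sigma_a", "sigma_c"):
            if key in self.params and (self.params[key] <= 0).any():
                raise ValueError(f"{key} draws must be positive")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws for one parameter with chain/draw axes merged."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _design(covariates: pd.DataFrame, sites, terms) -> np.ndarray:
    X = covariates.loc[list(sites), list(terms)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite covariate values")
    return X


def marginal_loglik(params: dict, data: SurveyData, covariates: pd.DataFrame,
                    spec: ModelSpec) -> float:
    """Marginal log-likelihood with the latent presence state summed out.

    Per species x site the likelihood is
    ``psi * prod_k Bern(y_k | p_k) + (1 - psi) * [all surveyed y_k = 0]``.
    """
    X = _design(covariates, data.sites, spec.terms)
    slopes = np.asarray(params["b"], dtype=float)
    eta = params["psi0"] + np.asarray(params["a"])[:, None] + slopes @ X.T
    etap = (
        params["p0"]
        + params["p_month2"] * month_squared(data.months)[None, :]
        + np.asarray(params["c"])[:, None]
    )
    if not (np.isfinite(eta).all() and np.isfinite(etap).all()):
        raise ValueError("non-finite linear predictor")
    psi = expit(eta)
    p = expit(etap)  # (S, K)
    mask = data.mask
    y = np.nan_to_num(data.y)
    ll_det = (xlogy(y, p[:, None, :]) + xlogy(1 - y, 1 - p[:, None, :]))
    ll_det = np.where(mask, ll_det, 0.0).sum(axis=2)  # (S, J)
    never = (np.where(mask, y, 0.0).sum(axis=2) == 0)
    lik = psi * np.exp(ll_det) + (1 - psi) * never
    return float(np.log(lik).sum())


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _log1pexp(x):
    return np.logaddexp(0.0, x)


_SIGMA_FLOOR = 1e-3  # keeps 1/sigma^2 finite when the data pin sigma at 0


def _sd_gibbs(ss, n, current, rng):
    """Gibbs draw of hierarchical SDs under the Uniform(0, 10) prior.

    With a flat prior on sigma the full conditional of sigma^2 is
    InvGamma((n-1)/2, ss/2) truncated to sigma < 10; rejection-sample the
    truncation and keep the current value if it keeps failing.
    """
    ss = np.maximum(np.asarray(ss, dtype=float), _SIGMA_FLOOR ** 2)
    out = np.array(current, dtype=float, copy=True)
    if n < 2:
        return out
    shape = (n - 1) / 2.0
    for idx in range(out.size):
        for _ in range(20):
            s2 = ss.flat[idx] / (2.0 * rng.gamma(shape))
            if s2 < _SIGMA_MAX ** 2:
                out.flat[idx] = max(np.sqrt(s2), _SIGMA_FLOOR)
                break
    return out


class _Adapt:
    """Per-block random-walk step with burn-in-only Robbins-Monro tuning."""

    def __init__(self, step, target=0.35):
        self.step = np.asarray(step, dtype=float)
        self.target = target
        self.accepts = np.zeros_like(self.step)
        self.count = 0

    def record(self, accepted):
        self.accepts = self.accepts + accepted
        self.count += 1

    def adapt(self):
        if self.count == 0:
            return
        rate = self.accepts / self.count
        self.step = self.step * np.exp(np.clip(rate - self.target, -0.5, 0.5))
        self.accepts = np.zeros_like(self.step)
        self.count = 0


def _run_chain(seed, X, Ym, M, m2, settings, record_z=False):
    """One MCMC chain. Ym = detections zero-filled, M = surveyed mask."""
    rng = np.random.default_rng(seed)
    S, J, K = Ym.shape
    P = X.shape[1]

    # sufficient statistics independent of state
    anyy = Ym.sum(axis=2) > 0  # (S, J): at least one detection forces z=1
    Mm = M.astype(float)
    NM = Mm - Ym  # per-(s,j,k) count of surveyed non-detections

    psi0, a, b = 0.0, np.zeros(S), np.zeros((S, P))
    mu, sig = np.zeros(P), np.full(P, 0.5)
    sig_a = 0.5
    p0, pm2, c, sig_c = 0.0, 0.0, np.zeros(S), 0.5
    z = anyy.astype(float)

    eta = psi0 + a[:, None] + b @ X.T  # (S, J)
    etap = p0 + pm2 * m2[None, :] + c[:, None]  # (S, K)

    # heuristic initial steps from rough Fisher information
    st_a = _Adapt(np.full(S, 2.4 / np.sqrt(max(J, 1) * 0.25)))
    st_b = [_Adapt(np.full(S, 2.4 / np.sqrt(max(J, 1) * 0.25)))
            for _ in range(P)]
    st_psi0 = _Adapt(2.4 / np.sqrt(S * J * 0.25))
    st_scale = _Adapt(np.full(2 + P, 0.3))  # joint (effects, SD) scale moves
    st_c = _Adapt(np.full(S, 2.4 / np.sqrt(max(J * K, 1) * 0.125)))
    st_p0 = _Adapt(2.4 / np.sqrt(S * J * K * 0.125))
    st_pm2 = _Adapt(2.4 / np.sqrt(S * J * K * 0.125 * max(np.mean(m2 ** 2), 1e-2)))
    blocks = [st_a, *st_b, st_psi0, st_scale, st_c, st_p0, st_pm2]

    n_keep = (settings.iterations - settings.burn_in) // settings.thin
    out = {
        "psi0": np.empty(n_keep), "a": np.empty((n_keep, S)),
        "b": np.empty((n_keep, S, P)), "mu": np.empty((n_keep, P)),
        "sigma": np.empty((n_keep, P)), "sigma_a": np.empty(n_keep),
        "p0": np.empty(n_keep), "p_month2": np.empty(n_keep),
        "c": np.empty((n_keep, S)), "sigma_c": np.empty(n_keep),
    }
    if record_z:
        out["z"] = np.empty((n_keep, S, J))
    kept = 0
    reject_streak = 0

    for it in range(settings.iterations):
        # -- latent presence -------------------------------------------
        log1mp = -_log1pexp(etap)  # log(1 - p) (S, K)
        sumlog = np.einsum("sk,sjk->sj", log1mp, Mm)
        psi = expit(eta)
        q = np.exp(sumlog)
        pz = psi * q / (psi * q + (1.0 - psi))
        z = np.where(anyy, 1.0, (rng.random((S, J)) < pz).astype(float))

        # detection sufficient statistics given z
        n1 = np.einsum("sjk,sj->sk", Ym, z)
        n0 = np.einsum("sjk,sj->sk", NM, z)
        ntot = n1 + n0

        ll_occ = (z * eta).sum(axis=1) - _log1pexp(eta).sum(axis=1)  # (S,)

        # -- species occupancy intercepts ------------------------------
        da = st_a.step * rng.standard_normal(S)
        eta_new = eta + da[:, None]
        ll_new = (z * eta_new).sum(axis=1) - _log1pexp(eta_new).sum(axis=1)
        dprior = (a ** 2 - (a + da) ** 2) / (2 * sig_a ** 2)
        acc = np.log(rng.random(S)) < (ll_new - ll_occ + dprior)
        a = np.where(acc, a + da, a)
        eta = np.where(acc[:, None], eta_new, eta)
        ll_occ = np.where(acc, ll_new, ll_occ)
        st_a.record(acc)

        # -- species slopes, one predictor block at a time -------------
        for t in range(P):
            db = st_b[t].step * rng.standard_normal(S)
            eta_new = eta + db[:, None] * X[:, t][None, :]
            ll_new = (z * eta_new).sum(axis=1) - _log1pexp(eta_new).sum(axis=1)
            bt = b[:, t]
            dprior = ((bt - mu[t]) ** 2 - (bt + db - mu[t]) ** 2) / (2 * sig[t] ** 2)
            acc = np.log(rng.random(S)) < (ll_new - ll_occ + dprior)
            b[:, t] = np.where(acc, bt + db, bt)
            eta = np.where(acc[:, None], eta_new, eta)
            ll_occ = np.where(acc, ll_new, ll_occ)
            st_b[t].record(acc)

        # -- global occupancy intercept --------------------------------
        d0 = st_psi0.step * rng.standard_normal()
        eta_new = eta + d0
        ll_new = ((z * eta_new).sum() - _log1pexp(eta_new).sum())
        dprior = (psi0 ** 2 - (psi0 + d0) ** 2) / (2 * _PRIOR_SD ** 2)
        if np.log(rng.random()) < ll_new - ll_occ.sum() + dprior:
            psi0 += d0
            eta = eta_new
            ll_occ = (z * eta).sum(axis=1) - _log1pexp(eta).sum(axis=1)
            st_psi0.record(1.0)
        else:
            st_psi0.record(0.0)

        # -- group-level means: conjugate normal update ----------------
        prec = S / sig ** 2 + 1.0 / _PRIOR_SD ** 2
        mean = (b.sum(axis=0) / sig ** 2) / prec
        mu = mean + rng.standard_normal(P) / np.sqrt(prec)

        # -- recenter the global/species intercept split ---------------
        # The likelihood fixes psi0 + a_i; the split between them is prior
        # business only, so a shared-shift Gibbs move keeps it mixing.
        prec_t = 1.0 / _PRIOR_SD ** 2 + S / sig_a ** 2
        mean_t = (a.sum() / sig_a ** 2 - psi0 / _PRIOR_SD ** 2) / prec_t
        t_shift = mean_t + rng.standard_normal() / np.sqrt(prec_t)
        psi0 += t_shift
        a = a - t_shift

        # -- scale parameters: Gibbs (truncated inverse-gamma) ---------
        ss = ((b - mu[None, :]) ** 2).sum(axis=0)
        sig = _sd_gibbs(ss, S, sig, rng)
        sig_a = float(_sd_gibbs(np.array([(a ** 2).sum()]), S,
                                np.array([sig_a]), rng)[0])
        sig_c = float(_sd_gibbs(np.array([(c ** 2).sum()]), S,
                                np.array([sig_c]), rng)[0])

        # -- joint (effects, SD) scale moves -------------------------------
        # Multiplying a random-effect vector and its SD by a common factor
        # walks along the hierarchical funnel; after cancelling the prior
        # against the proposal Jacobian the acceptance ratio is the
        # likelihood change plus log k.
        scale_acc = np.zeros(2 + P)
        ks = np.exp(st_scale.step * rng.standard_normal(2 + P))
        us = np.log(rng.random(2 + P))

        k = ks[0]  # occupancy species intercepts
        if sig_a * k < _SIGMA_MAX:
            eta_new = eta + (k - 1.0) * a[:, None]
            dll = ((z * eta_new).sum() - _log1pexp(eta_new).sum()
                   - (z * eta).sum() + _log1pexp(eta).sum())
            if us[0] < dll + np.log(k):
                a, sig_a, eta = k * a, sig_a * k, eta_new
                scale_acc[0] = 1.0

        k = ks[1]  # detection species effects
        if sig_c * k < _SIGMA_MAX:
            etap_new = etap + (k - 1.0) * c[:, None]
            dll = ((n1 * etap_new - ntot * _log1pexp(etap_new)).sum()
                   - (n1 * etap - ntot * _log1pexp(etap)).sum())
            if us[1] < dll + np.log(k):
                c, sig_c, etap = k * c, sig_c * k, etap_new
                scale_acc[1] = 1.0

        for t in range(P):  # slope deviations about the group mean
            k = ks[2 + t]
            if sig[t] * k >= _SIGMA_MAX:
                continue
            resid = b[:, t] - mu[t]
            eta_new = eta + (k - 1.0) * resid[:, None] * X[:, t][None, :]
            dll = ((z * eta_new).sum() - _log1pexp(eta_new).sum()
                   - (z * eta).sum() + _log1pexp(eta).sum())
            if us[2 + t] < dll + np.log(k):
                b[:, t] = mu[t] + k * resid
                sig[t] *= k
                eta = eta_new
                scale_acc[2 + t] = 1.0
        st_scale.record(scale_acc)

        # -- detection parameters --------------------------------------
        ll_det = (n1 * etap - ntot * _log1pexp(etap)).sum(axis=1)  # (S,)

        dc = st_c.step * rng.standard_normal(S)
        etap_new = etap + dc[:, None]
        ll_new = (n1 * etap_new - ntot * _log1pexp(etap_new)).sum(axis=1)
        dprior = (c ** 2 - (c + dc) ** 2) / (2 * sig_c ** 2)
        acc = np.log(rng.random(S)) < (ll_new - ll_det + dprior)
        c = np.where(acc, c + dc, c)
        etap = np.where(acc[:, None], etap_new, etap)
        ll_det = np.where(acc, ll_new, ll_det)
        st_c.record(acc)

        # recenter the detection intercept split (likelihood fixes p0 + c_i)
        prec_t = 1.0 / _PRIOR_SD ** 2 + S / sig_c ** 2
        mean_t = (c.sum() / sig_c ** 2 - p0 / _PRIOR_SD ** 2) / prec_t
        t_shift = mean_t + rng.standard_normal() / np.sqrt(prec_t)
        p0 += t_shift
        c = c - t_shift

        for scalar, adapt, shift in ((0, st_p0, None), (1, st_pm2, m2)):
            d = adapt.step * rng.standard_normal()
            etap_new = etap + (d if shift is None else d * shift[None, :])
            ll_new = (n1 * etap_new - ntot * _log1pexp(etap_new)).sum()
            cur = p0 if scalar == 0 else pm2
            dprior = (cur ** 2 - (cur + d) ** 2) / (2 * _PRIOR_SD ** 2)
            if np.log(rng.random()) < ll_new - ll_det.sum() + dprior:
                if scalar == 0:
                    p0 += d
                else:
                    pm2 += d
                etap = etap_new
                ll_det = (n1 * etap - ntot * _log1pexp(etap)).sum(axis=1)
                adapt.record(1.0)
                reject_streak = 0
            else:
                adapt.record(0.0)
                reject_streak += 1
        if reject_streak > 4000:
            raise RuntimeError("chain divergence: all proposals rejected over a window")

        if it < settings.burn_in:
            if (it + 1) % 100 == 0:
                for blk in blocks:
                    blk.adapt()
        elif (it - settings.burn_in + 1) % settings.thin == 0 and kept < n_keep:
            out["psi0"][kept] = psi0
            out["a"][kept] = a
            out["b"][kept] = b
            out["mu"][kept] = mu
            out["sigma"][kept] = sig
            out["sigma_a"][kept] = sig_a
            out["p0"][kept] = p0
            out["p_month2"][kept] = pm2
            out["c"][kept] = c
            out["sigma_c"][kept] = sig_c
            if record_z:
                out["z"][kept] = z
            kept += 1
    return out


def fit(spec: ModelSpec, data: SurveyData, covariates: pd.DataFrame,
        mcmc: McmcSettings | None = None, record_z: bool = False) -> PosteriorDraws:
    """Fit the multi-species occupancy model for one specification by MCMC."""
    mcmc = mcmc or McmcSettings()
    X = _design(covariates, data.sites, spec.terms)
    Ym = np.nan_to_num(data.y)
    M = data.mask
    m2 = month_squared(data.months)
    chains = []
    ss = np.random.SeedSequence(mcmc.seed)
    for child in ss.spawn(mcmc.chains):
        chains.append(_run_chain(child, X, Ym, M, m2, mcmc, record_z=record_z))
    params = {
        k: np.stack([ch[k] for ch in chains]) for k in chains[0]
    }
    return PosteriorDraws(params, list(data.species), tuple(spec.terms), spec=spec)


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws, params=None) -> dict:
    """Split-chain potential scale reduction factor per scalar parameter."""
    if draws.n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    if draws.n_draws < 4:
        raise ValueError("R-hat needs at least four draws per chain")
    names = params or [k for k in draws.params if k != "z"]
    return {name: split_rhat(draws.params[name]) for name in names}


def split_rhat(samples: np.ndarray) -> np.ndarray:
    """Split-R-hat for an array shaped (chains, draws, ...)."""
    samples = np.asarray(samples, dtype=float)
    C, D = samples.shape[:2]
    half = D // 2
    split = np.concatenate([samples[:, :half], samples[:, half: 2 * half]], axis=0)
    m, n = split.shape[0], split.shape[1]
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


def convergence_report(draws: PosteriorDraws, threshold: float = 1.1) -> pd.DataFrame:
    rows = []
    for name, rh in gelman_rubin(draws).items():
        rh = np.atleast_1d(rh)
        for idx, val in np.ndenumerate(rh):
            rows.append({
                "parameter": name if rh.size == 1 else f"{name}{list(idx)}",
                "rhat": float(val),
                "converged": bool(val < threshold),
            })
    return pd.DataFrame(rows)


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior means, equal-tailed 95% intervals and significance flags.

    One row per species slope per predictor, plus one ``level='group'`` row
    per predictor for the community mean; a slope is starred when its
    interval excludes zero.
    """
    rows = []

    def interval(x):
        lo, hi = np.quantile(x, [0.025, 0.975])
        return float(np.mean(x)), float(lo), float(hi)

    b = draws.flat("b")  # (n, S, P)
    mu = draws.flat("mu")  # (n, P)
    for t, term in enumerate(draws.terms):
        for i, sp in enumerate(draws.species):
            m, lo, hi = interval(b[:, i, t])
            rows.append({"level": "species", "name": sp, "predictor": term,
                         "mean": m, "lo": lo, "hi": hi,
                         "significant": bool(lo > 0 or hi < 0)})
        m, lo, hi = interval(mu[:, t])
        rows.append({"level": "group", "name": "mu", "predictor": term,
                     "mean": m, "lo": lo, "hi": hi,
                     "significant": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)


def marginal_effect_curve(draws: PosteriorDraws, spec: ModelSpec, predictor: str,
                          grid: np.ndarray) -> pd.DataFrame:
    """Per-species occupancy response along one standardized predictor.

    Other covariates sit at 0 (their standardized mean); curves use
    posterior-mean coefficients and carry the species significance class.
    """
    if predictor not in spec.terms:
        raise KeyError(f"{predictor!r} not in model terms {spec.terms}")
    t = spec.terms.index(predictor)
    grid = np.asarray(grid, dtype=float)
    psi0 = draws.flat("psi0").mean()
    a = draws.flat("a").mean(axis=0)
    bt = draws.flat("b")[:, :, t]
    b_mean = bt.mean(axis=0)
    lo, hi = np.quantile(bt, [0.025, 0.975], axis=0)
    signif = np.where(lo > 0, "positive", np.where(hi < 0, "negative", "none"))
    eta = psi0 + a[:, None] + b_mean[:, None] * grid[None, :]
    psi = expit(eta)
    frames = []
    for i, sp in enumerate(draws.species):
        frames.append(pd.DataFrame({
            "species": sp, "x": grid, "psi": psi[i],
            "significance": signif[i],
        }))
    return pd.concat(frames, ignore_index=True)
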