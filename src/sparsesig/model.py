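"""Bayesian sparse random-intercept negative-binomial model of transcript abundance.

The observed count of gene g in sample s (cell type c, dataset r) is modelled

    Y_{s,g} ~ NB( exp(alpha_{g,c} + beta_{g,r} + epsilon_s), theta_g ),

with a log link on the mean and on the overdispersion theta_g = exp(sigma_g)
(variance mu + mu^2/theta).  alpha is the population-level (fixed) cell-type
log abundance; beta is a per-dataset random intercept with gene-wise scale
rho_g ~ gamma(omega, o); sigma follows a linear trend in the gene's mean log
abundance (the latent mean-overdispersion association); alpha is drawn from a
skew normal across genes.  Trend and skew-normal hyperpriors are centered on
constants estimated outside the model, with prior SD at 20% of each constant.
Unobserved (sample, gene) pairs are missing data and are simply omitted from
the likelihood.  Inference is Hamiltonian Monte Carlo (NUTS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, digamma, log_ndtr

from .catalogue import ExposureVector, validate_observation_table
from . import sampler as _sampler

_LOG2PI = np.log(2.0 * np.pi)
_ETA_CLIP = 40.0  # log-mean bound: exp(40) ~ 2e17, far beyond count support


# ---------------------------------------------------------------------------
# negative binomial, mean/overdispersion parameterization

def nb_log_pmf(n, mean, overdispersion):
    """Log pmf of NB(mean mu, overdispersion theta); var = mu + mu^2/theta.

    Vectorized; evaluated via log-gamma functions.
    """
    n = np.asarray(n)
    mu = np.asarray(mean, dtype=float)
    theta = np.asarray(overdispersion, dtype=float)
    if np.any(n < 0) or np.any(np.asarray(n) % 1 != 0):
        raise ValueError("n must be a nonnegative integer")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mean and overdispersion must be positive")
    n = n.astype(float)
    return (
        gammaln(n + theta)
        - gammaln(theta)
        - gammaln(n + 1.0)
        + theta * (np.log(theta) - np.log(mu + theta))
        + n * (np.log(mu) - np.log(mu + theta))
    )


# ---------------------------------------------------------------------------
# hyperprior constants, estimated outside the model

@dataclass
class HyperpriorConstants:
    """Empirical centers of the trend and abundance hyperpriors.

    lambda0/lambda1/delta: intercept, slope and residual SD of the
    log-overdispersion vs mean-log-abundance trend.  mu/psi/upsilon: location,
    log-scale and shape of the skew normal generating expected log abundances.
    Prior SDs are 20% of each center's magnitude (floored away from zero so a
    near-zero center never degenerates the prior).
    """

    lambda0: float
    lambda1: float
    delta: float
    mu: float
    psi: float
    upsilon: float
    omega_loc: float = 3.0
    omega_scale: float = 1.0
    sd_floor: float = 0.05

    def prior_sd(self, name: str) -> float:
        return max(abs(getattr(self, name)) / 5.0, self.sd_floor)

    def to_dict(self) -> dict:
        return asdict(self)


_MAX_SKEW_SHAPE = 10.0  # skewness saturates beyond |shape| ~ 10 (gamma1 = 0.956
# of the attainable 0.995); larger centers make the skew-normal prior a hard
# half-line barrier with unbounded gradients


def _skewnorm_moment_fit(x: np.ndarray) -> tuple[float, float, float]:
    """Moment-matched skew-normal (shape, loc, scale) with bounded shape.

    Sample skewness is capped at the value implied by ``_MAX_SKEW_SHAPE``
    before inversion, so the returned shape is always finite and moderate —
    unlike the ML fit, which degenerates to boundary solutions on small
    samples.
    """
    from scipy.optimize import brentq

    g1_cap = float(stats.skewnorm.stats(_MAX_SKEW_SHAPE, moments="s"))
    g1 = float(np.clip(stats.skew(x), -g1_cap, g1_cap))

    def implied_skew(delta):
        m = delta * np.sqrt(2.0 / np.pi)
        return (4.0 - np.pi) / 2.0 * m**3 / (1.0 - m**2) ** 1.5

    if abs(g1) < 1e-12:
        delta = 0.0
    else:
        delta = brentq(lambda d: implied_skew(d) - abs(g1), 0.0, 0.999999)
        delta = delta if g1 >= 0 else -delta
    shape = delta / np.sqrt(max(1.0 - delta**2, 1e-12))
    m = delta * np.sqrt(2.0 / np.pi)
    scale = float(np.std(x, ddof=1) / np.sqrt(1.0 - m**2))
    loc = float(np.mean(x) - scale * m)
    return float(shape), loc, scale


def _corrected_wide(table: pd.DataFrame, exposure: ExposureVector) -> pd.DataFrame:
    wide = table.pivot_table(index="sample", columns="gene", values="count")
    eps = exposure.as_series().reindex(wide.index)
    return wide.div(np.exp(eps), axis=0)


def estimate_hyperpriors(table: pd.DataFrame, exposure: ExposureVector) -> HyperpriorConstants:
    """Method-of-moments estimates of the trend and skew-normal hyperprior centers.

    Per (gene, cell type) group with >= 2 exposure-corrected observations, the
    sample mean m and variance v give a moment estimate of the overdispersion
    theta = m^2/(v - m) (groups with v <= m carry no overdispersion signal and
    are skipped).  OLS of log theta on log m yields (lambda0*, lambda1*) with
    residual SD delta*; a skew-normal ML fit to the group log-means yields
    (mu*, psi*, upsilon*).
    """
    validate_observation_table(table)
    corr = _corrected_wide(table, exposure)
    ann = table[["sample", "cell_type"]].drop_duplicates().set_index("sample")["cell_type"]
    groups = corr.groupby(ann.reindex(corr.index).to_numpy())
    log_means, log_thetas = [], []
    n_positive_var = 0
    for _, sub in groups:
        m = sub.mean(axis=0, skipna=True)
        v = sub.var(axis=0, ddof=1, skipna=True)
        nobs = sub.notna().sum(axis=0)
        ok = (nobs >= 2) & (m > 0) & v.notna()
        n_positive_var += int(((v > 0) & ok).sum())
        log_means.append(np.log(m[ok]))
        over = ok & (v > m)
        theta = m[over] ** 2 / (v[over] - m[over])
        log_thetas.append(pd.Series(np.log(theta), index=m[over].index))
    if n_positive_var < 10:
        raise ValueError(
            "fewer than 10 genes with positive variance; supply hyperprior "
            "constants directly instead of estimating them"
        )
    lm_all = np.concatenate([x.to_numpy() for x in log_means])
    trend_x, trend_y = [], []
    for lm, lt in zip(log_means, log_thetas):
        shared = lt.index
        trend_x.append(lm.loc[shared].to_numpy())
        trend_y.append(lt.to_numpy())
    x = np.concatenate(trend_x)
    y = np.concatenate(trend_y)
    if x.size < 10:
        raise ValueError(
            "fewer than 10 overdispersed genes; supply hyperprior constants directly"
        )
    slope, intercept, *_ = stats.linregress(x, y)[:5]
    resid = y - (intercept + slope * x)
    delta_star = float(max(np.std(resid, ddof=2), 1e-3))
    a, loc, scale = stats.skewnorm.fit(lm_all)
    if not np.isfinite([a, loc, scale]).all() or abs(a) > _MAX_SKEW_SHAPE:
        # the ML fit hit a degenerate boundary solution (common on few group
        # log-means); fall back to the bounded moment fit
        a, loc, scale = _skewnorm_moment_fit(lm_all)
    return HyperpriorConstants(
        lambda0=float(intercept),
        lambda1=float(slope),
        delta=delta_star,
        mu=float(loc),
        psi=float(np.log(scale)),
        upsilon=float(a),
    )


# ---------------------------------------------------------------------------
# design

@dataclass
class DesignInfo:
    """Index structure of a harmonized catalogue.

    Samples, genes, cell types and datasets are in sorted label order.  y and
    mask are S x G; unobserved pairs never enter likelihood sums.
    """

    samples: list[str]
    genes: list[str]
    cell_types: list[str]
    datasets: list[str]
    cell_of: np.ndarray
    dataset_of: np.ndarray
    epsilon: np.ndarray
    y: np.ndarray
    mask: np.ndarray

    @property
    def S(self) -> int:
        return len(self.samples)

    @property
    def G(self) -> int:
        return len(self.genes)

    @property
    def C(self) -> int:
        return len(self.cell_types)

    @property
    def R(self) -> int:
        return len(self.datasets)

    @property
    def X(self) -> np.ndarray:
        """S x C one-hot sample -> cell type indicator."""
        X = np.zeros((self.S, self.C))
        X[np.arange(self.S), self.cell_of] = 1.0
        return X

    @property
    def Z(self) -> np.ndarray:
        """S x R one-hot sample -> dataset indicator."""
        Z = np.zeros((self.S, self.R))
        Z[np.arange(self.S), self.dataset_of] = 1.0
        return Z

    def n_observed(self) -> int:
        return int(self.mask.sum())


def build_design(table: pd.DataFrame, exposure: ExposureVector) -> DesignInfo:
    """Construct indicators, observation mask and aligned exposures."""
    validate_observation_table(table)
    samples = sorted(table["sample"].unique())
    genes = sorted(table["gene"].unique())
    cell_types = sorted(table["cell_type"].unique())
    datasets = sorted(table["dataset"].unique())
    s_idx = {s: i for i, s in enumerate(samples)}
    g_idx = {g: i for i, g in enumerate(genes)}
    ann = table[["sample", "cell_type", "dataset"]].drop_duplicates().set_index("sample")
    cell_of = np.array([cell_types.index(ann.loc[s, "cell_type"]) for s in samples])
    dataset_of = np.array([datasets.index(ann.loc[s, "dataset"]) for s in samples])
    eps = exposure.as_series()
    missing_eps = [s for s in samples if s not in eps.index]
    if missing_eps:
        raise ValueError(f"exposure missing for samples: {missing_eps[:5]}")
    epsilon = eps.reindex(samples).to_numpy()
    y = np.zeros((len(samples), len(genes)), dtype=np.int64)
    mask = np.zeros_like(y, dtype=bool)
    si = table["sample"].map(s_idx).to_numpy()
    gi = table["gene"].map(g_idx).to_numpy()
    y[si, gi] = table["count"].to_numpy()
    mask[si, gi] = True
    return DesignInfo(samples, genes, cell_types, datasets, cell_of, dataset_of, epsilon, y, mask)


# ---------------------------------------------------------------------------
# parameters and joint density (constrained scale)

@dataclass
class ModelParameters:
    """One point in constrained parameter space."""

    alpha: np.ndarray   # (G, C) expected log abundance
    beta: np.ndarray    # (G, R) dataset random intercepts
    rho: np.ndarray     # (G,) random-effect SDs, > 0
    sigma: np.ndarray   # (G,) log overdispersion
    lambda0: float
    lambda1: float
    delta: float        # > 0
    mu: float
    psi: float
    upsilon: float
    omega: float        # gamma shape, > 1
    o: float            # gamma rate, > 1

    @property
    def theta(self) -> np.ndarray:
        """Overdispersion on the natural scale."""
        return np.exp(self.sigma)


def _normal_lpdf(x, loc, scale):
    return -np.log(scale) - 0.5 * _LOG2PI - 0.5 * ((x - loc) / scale) ** 2


def _skewnorm_lpdf(x, loc, scale, shape):
    z = (x - loc) / scale
    return np.log(2.0) - np.log(scale) - 0.5 * _LOG2PI - 0.5 * z**2 + log_ndtr(shape * z)


def _gamma_lpdf(x, shape, rate):
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x


def joint_log_density(
    params: ModelParameters,
    design: DesignInfo,
    hyper: HyperpriorConstants,
) -> float:
    """Log of the unnormalized joint density (likelihood x priors x hyperpriors).

    Missing (sample, gene) pairs contribute nothing.  Returns -inf (with a
    warning) for non-finite parameter values.
    """
    flat = np.concatenate(
        [
            params.alpha.ravel(),
            params.beta.ravel(),
            params.rho,
            params.sigma,
            [params.lambda0, params.lambda1, params.delta, params.mu, params.psi,
             params.upsilon, params.omega, params.o],
        ]
    )
    if not np.all(np.isfinite(flat)):
        warnings.warn("non-finite parameter in joint_log_density", RuntimeWarning)
        return -np.inf

    eta = (
        params.alpha.T[design.cell_of]
        + params.beta.T[design.dataset_of]
        + design.epsilon[:, None]
    )
    m = design.mask
    mu_obs = np.exp(eta[m])
    theta_obs = np.broadcast_to(params.theta, eta.shape)[m]
    lp = float(np.sum(nb_log_pmf(design.y[m], mu_obs, theta_obs)))

    lp += float(np.sum(_normal_lpdf(params.beta, 0.0, params.rho[:, None])))
    lp += float(np.sum(_gamma_lpdf(params.rho, params.omega, params.o)))
    abar = params.alpha.mean(axis=1)
    lp += float(np.sum(_normal_lpdf(params.sigma, params.lambda0 + params.lambda1 * abar, params.delta)))
    lp += float(np.sum(_skewnorm_lpdf(params.alpha, params.mu, np.exp(params.psi), params.upsilon)))

    lp += float(_normal_lpdf(params.lambda0, hyper.lambda0, hyper.prior_sd("lambda0")))
    lp += float(_normal_lpdf(params.lambda1, hyper.lambda1, hyper.prior_sd("lambda1")))
    lp += float(_normal_lpdf(params.delta, hyper.delta, hyper.prior_sd("delta")))
    lp += float(_normal_lpdf(params.mu, hyper.mu, hyper.prior_sd("mu")))
    lp += float(_normal_lpdf(params.psi, hyper.psi, hyper.prior_sd("psi")))
    lp += float(_normal_lpdf(params.upsilon, hyper.upsilon, hyper.prior_sd("upsilon")))
    lp += float(_normal_lpdf(params.omega, hyper.omega_loc, hyper.omega_scale))
    lp += float(_normal_lpdf(params.o, hyper.omega_loc, hyper.omega_scale))
    return lp


# ---------------------------------------------------------------------------
# unconstrained posterior with analytic gradient (used by the sampler)

class _UnconstrainedPosterior:
    """Joint density on the sampler's unconstrained scale.

    Transforms: beta = rho * btilde (non-centered, btilde ~ N(0,1));
    rho = exp(t); delta = exp(d); omega = 1 + exp(uw); o = 1 + exp(uo);
    with the corresponding log-Jacobian terms.  The remaining parameters are
    unconstrained already.
    """

    def __init__(self, design: DesignInfo, hyper: HyperpriorConstants):
        self.design = design
        self.hyper = hyper
        G, C, R = design.G, design.C, design.R
        self.G, self.C, self.R = G, C, R
        self.dim = G * C + G * R + 2 * G + 8
        self._slices = {}
        off = 0
        for name, size in [("alpha", G * C), ("btilde", G * R), ("t", G), ("sigma", G)]:
            self._slices[name] = slice(off, off + size)
            off += size
        self._scalar_names = ["lambda0", "lambda1", "d", "mu", "psi", "upsilon", "uw", "uo"]
        for name in self._scalar_names:
            self._slices[name] = off
            off += 1
        # cache per-observation structures
        self.mask = design.mask
        self.yobs = design.y[self.mask].astype(float)
        self.cell_of = design.cell_of
        self.dataset_of = design.dataset_of
        self.eps = design.epsilon

    def unpack(self, z: np.ndarray) -> dict:
        G, C, R = self.G, self.C, self.R
        s = self._slices
        return {
            "alpha": z[s["alpha"]].reshape(G, C),
            "btilde": z[s["btilde"]].reshape(G, R),
            "t": z[s["t"]],
            "sigma": z[s["sigma"]],
            **{n: z[s[n]] for n in self._scalar_names},
        }

    def pack(self, **kw) -> np.ndarray:
        z = np.empty(self.dim)
        s = self._slices
        z[s["alpha"]] = kw["alpha"].ravel()
        z[s["btilde"]] = kw["btilde"].ravel()
        z[s["t"]] = kw["t"]
        z[s["sigma"]] = kw["sigma"]
        for n in self._scalar_names:
            z[s[n]] = kw[n]
        return z

    def to_constrained(self, z: np.ndarray) -> ModelParameters:
        p = self.unpack(z)
        rho = np.exp(p["t"])
        return ModelParameters(
            alpha=p["alpha"],
            beta=rho[:, None] * p["btilde"],
            rho=rho,
            sigma=p["sigma"],
            lambda0=float(p["lambda0"]),
            lambda1=float(p["lambda1"]),
            delta=float(np.exp(p["d"])),
            mu=float(p["mu"]),
            psi=float(p["psi"]),
            upsilon=float(p["upsilon"]),
            omega=float(1.0 + np.exp(p["uw"])),
            o=float(1.0 + np.exp(p["uo"])),
        )

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.unpack(z)
        alpha, btilde, t, sigma = p["alpha"], p["btilde"], p["t"], p["sigma"]
        lam0, lam1 = float(p["lambda0"]), float(p["lambda1"])
        d, mu_h, psi_h, ups = float(p["d"]), float(p["mu"]), float(p["psi"]), float(p["upsilon"])
        uw, uo = float(p["uw"]), float(p["uo"])
        hyper = self.hyper
        G, C, R = self.G, self.C, self.R

        rho = np.exp(t)
        beta = rho[:, None] * btilde
        delta = np.exp(d)
        omega = 1.0 + np.exp(uw)
        o = 1.0 + np.exp(uo)
        theta = np.exp(np.clip(sigma, -_ETA_CLIP, _ETA_CLIP))

        g_alpha = np.zeros((G, C))
        g_btilde = np.zeros((G, R))
        g_t = np.zeros(G)
        g_sigma = np.zeros(G)

        # --- likelihood
        eta = alpha.T[self.cell_of] + beta.T[self.dataset_of] + self.eps[:, None]
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        eta_obs = eta[self.mask]
        m_obs = np.exp(eta_obs)
        th = np.broadcast_to(theta, eta.shape)[self.mask]
        y = self.yobs
        mt = m_obs + th
        lp = float(
            np.sum(
                gammaln(y + th) - gammaln(th) - gammaln(y + 1.0)
                + th * (np.log(th) - np.log(mt))
                + y * (eta_obs - np.log(mt))
            )
        )
        d_eta = np.zeros_like(eta)
        d_eta[self.mask] = y - (y + th) * m_obs / mt
        d_th_obs = digamma(y + th) - digamma(th) + np.log(th) - np.log(mt) + 1.0 - (y + th) / mt
        d_theta_full = np.zeros_like(eta)
        d_theta_full[self.mask] = d_th_obs
        g_sigma += theta * d_theta_full.sum(axis=0)

        gc = np.zeros((C, G))
        np.add.at(gc, self.cell_of, d_eta)
        g_alpha += gc.T
        gr = np.zeros((R, G))
        np.add.at(gr, self.dataset_of, d_eta)
        g_beta = gr.T
        g_btilde += rho[:, None] * g_beta
        g_t += rho * np.sum(btilde * g_beta, axis=1)

        # --- btilde ~ N(0,1) (non-centered random intercepts)
        lp += float(np.sum(-0.5 * btilde**2 - 0.5 * _LOG2PI))
        g_btilde += -btilde

        # --- rho ~ gamma(omega, o), sampled as t = log rho
        lp += float(np.sum(omega * np.log(o) - gammaln(omega) + (omega - 1.0) * t - o * rho))
        lp += float(np.sum(t))  # Jacobian
        g_t += (omega - 1.0) + 1.0 - o * rho
        g_omega = float(np.sum(np.log(o) - digamma(omega) + t))
        g_o = float(np.sum(omega / o - rho))

        # --- sigma trend prior
        abar = alpha.mean(axis=1)
        res = sigma - lam0 - lam1 * abar
        lp += float(np.sum(-np.log(delta) - 0.5 * _LOG2PI - 0.5 * (res / delta) ** 2))
        g_sigma += -res / delta**2
        g_alpha += (lam1 / C) * (res / delta**2)[:, None]
        g_lam0 = float(np.sum(res) / delta**2)
        g_lam1 = float(np.sum(res * abar) / delta**2)
        g_d = float(np.sum(res**2) / delta**2 - G)

        # --- skew-normal prior on alpha
        w = np.exp(psi_h)
        zsc = (alpha - mu_h) / w
        lp += float(np.sum(np.log(2.0) - psi_h - 0.5 * _LOG2PI - 0.5 * zsc**2 + log_ndtr(ups * zsc)))
        # q is the inverse Mills ratio phi(s)/Phi(s); in the far left tail the
        # direct form loses precision (difference of huge logs can overflow
        # the exp), so switch to its asymptotic expansion -s - 1/s there
        s_arg = ups * zsc
        q = np.empty_like(s_arg)
        near = s_arg > -30.0
        q[near] = np.exp(-0.5 * s_arg[near] ** 2 - 0.5 * _LOG2PI - log_ndtr(s_arg[near]))
        q[~near] = -s_arg[~near] - 1.0 / s_arg[~near]
        g_alpha += (-zsc + ups * q) / w
        g_mu = float(np.sum((zsc - ups * q) / w))
        g_psi = float(np.sum(-1.0 + zsc**2 - ups * zsc * q))
        g_ups = float(np.sum(zsc * q))

        # --- hyperpriors
        def np_term(x, loc, scale):
            return _normal_lpdf(x, loc, scale), -(x - loc) / scale**2

        term, g = np_term(lam0, hyper.lambda0, hyper.prior_sd("lambda0"))
        lp += term
        g_lam0 += g
        term, g = np_term(lam1, hyper.lambda1, hyper.prior_sd("lambda1"))
        lp += term
        g_lam1 += g
        term, g = np_term(delta, hyper.delta, hyper.prior_sd("delta"))
        lp += term + d  # + Jacobian of delta = exp(d)
        g_d += g * delta + 1.0
        term, g = np_term(mu_h, hyper.mu, hyper.prior_sd("mu"))
        lp += term
        g_mu += g
        term, g = np_term(psi_h, hyper.psi, hyper.prior_sd("psi"))
        lp += term
        g_psi += g
        term, g = np_term(ups, hyper.upsilon, hyper.prior_sd("upsilon"))
        lp += term
        g_ups += g
        # omega = 1 + exp(uw): prior normal(3,1) on omega, Jacobian log(omega-1) = uw
        term, g = np_term(omega, hyper.omega_loc, hyper.omega_scale)
        lp += term + uw
        g_uw = (g_omega + g) * (omega - 1.0) + 1.0
        term, g = np_term(o, hyper.omega_loc, hyper.omega_scale)
        lp += term + uo
        g_uo = (g_o + g) * (o - 1.0) + 1.0

        grad = self.pack(
            alpha=g_alpha,
            btilde=g_btilde,
            t=g_t,
            sigma=g_sigma,
            lambda0=g_lam0,
            lambda1=g_lam1,
            d=g_d,
            mu=g_mu,
            psi=g_psi,
            upsilon=g_ups,
            uw=g_uw,
            uo=g_uo,
        )
        if not np.isfinite(lp):
            lp = -np.inf
            grad = np.zeros_like(grad)
        return lp, grad

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.1) -> np.ndarray:
        """Data-informed starting point: alpha at exposure-corrected log means,
        btilde at 0, sigma at the trend prediction, hypers at their centers."""
        des, hyper = self.design, self.hyper
        corr = np.where(des.mask, des.y / np.exp(des.epsilon)[:, None], np.nan)
        alpha0 = np.full((self.G, self.C), hyper.mu)
        for c in range(self.C):
            rows = des.cell_of == c
            if rows.any():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    m = np.nanmean(corr[rows], axis=0)
                seen = np.isfinite(m)
                alpha0[seen, c] = np.log(np.maximum(m[seen], 0.05))
        abar0 = alpha0.mean(axis=1)
        sigma0 = hyper.lambda0 + hyper.lambda1 * abar0
        z0 = self.pack(
            alpha=alpha0,
            btilde=np.zeros((self.G, self.R)),
            t=np.full(self.G, np.log(0.5)),
            sigma=sigma0,
            lambda0=hyper.lambda0,
            lambda1=hyper.lambda1,
            d=np.log(max(hyper.delta, 1e-3)),
            mu=hyper.mu,
            psi=hyper.psi,
            upsilon=hyper.upsilon,
            uw=np.log(2.0),
            uo=np.log(2.0),
        )
        return z0 + jitter * rng.standard_normal(self.dim)


# ---------------------------------------------------------------------------
# posterior container, fitting, summaries

@dataclass
class PosteriorDraws:
    """Posterior draws of every model parameter plus sampler metadata."""

    alpha: np.ndarray    # (D, G, C)
    beta: np.ndarray     # (D, G, R)
    rho: np.ndarray      # (D, G)
    sigma: np.ndarray    # (D, G)
    hypers: pd.DataFrame  # D rows: lambda0, lambda1, delta, mu, psi, upsilon, omega, o
    genes: list[str]
    cell_types: list[str]
    datasets: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def theta(self) -> np.ndarray:
        return np.exp(self.sigma)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws table (parameter, gene, level, chain, iteration, value)."""
        D = self.n_draws
        chains = self.meta.get("chains", 1)
        per = D // chains if chains else D
        chain_idx = np.repeat(np.arange(chains), per)[:D]
        iter_idx = np.tile(np.arange(per), chains)[:D]
        frames = []
        for name, arr, levels in [
            ("alpha", self.alpha, self.cell_types),
            ("beta", self.beta, self.datasets),
        ]:
            for gi, gene in enumerate(self.genes):
                for li, level in enumerate(levels):
                    frames.append(
                        pd.DataFrame(
                            {
                                "parameter": name,
                                "gene": gene,
                                "level": level,
                                "chain": chain_idx,
                                "iteration": iter_idx,
                                "value": arr[:, gi, li],
                            }
                        )
                    )
        for name, arr in [("rho", self.rho), ("sigma", self.sigma)]:
            for gi, gene in enumerate(self.genes):
                frames.append(
                    pd.DataFrame(
                        {
                            "parameter": name,
                            "gene": gene,
                            "level": "",
                            "chain": chain_idx,
                            "iteration": iter_idx,
                            "value": arr[:, gi],
                        }
                    )
                )
        for name in self.hypers.columns:
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "gene": "",
                        "level": "",
                        "chain": chain_idx,
                        "iteration": iter_idx,
                        "value": self.hypers[name].to_numpy(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


HYPER_COLS = ["lambda0", "lambda1", "delta", "mu", "psi", "upsilon", "omega", "o"]


def save_draws(draws: PosteriorDraws, directory) -> None:
    """Persist draws as a long columnar TSV plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    draws.to_dataframe().to_csv(directory / "draws.tsv", sep="\t", index=False)
    meta = {
        "genes": draws.genes,
        "cell_types": draws.cell_types,
        "datasets": draws.datasets,
        "meta": draws.meta,
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh)


def load_draws(directory) -> PosteriorDraws:
    """Load draws previously written by :func:`save_draws`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        info = json.load(fh)
    long = pd.read_csv(directory / "draws.tsv", sep="\t", keep_default_na=False)
    genes, cell_types, datasets = info["genes"], info["cell_types"], info["datasets"]
    g_idx = {g: i for i, g in enumerate(genes)}
    chains = sorted(long["chain"].unique())
    iters = sorted(long["iteration"].unique())
    D = len(chains) * len(iters)
    d_of = {
        (ch, it): k
        for k, (ch, it) in enumerate((c, i) for c in chains for i in iters)
    }
    long["draw"] = [d_of[(c, i)] for c, i in zip(long["chain"], long["iteration"])]
    G, C, R = len(genes), len(cell_types), len(datasets)
    alpha = np.empty((D, G, C))
    beta = np.empty((D, G, R))
    rho = np.empty((D, G))
    sigma = np.empty((D, G))
    hyp = pd.DataFrame(index=range(D), columns=HYPER_COLS, dtype=float)
    for (param, level), sub in long.groupby(["parameter", "level"], sort=False):
        if param == "alpha":
            ci = cell_types.index(level)
            alpha[sub["draw"], [g_idx[g] for g in sub["gene"]], ci] = sub["value"]
        elif param == "beta":
            ri = datasets.index(level)
            beta[sub["draw"], [g_idx[g] for g in sub["gene"]], ri] = sub["value"]
        elif param == "rho":
            rho[sub["draw"], [g_idx[g] for g in sub["gene"]]] = sub["value"]
        elif param == "sigma":
            sigma[sub["draw"], [g_idx[g] for g in sub["gene"]]] = sub["value"]
        elif param in HYPER_COLS:
            hyp.loc[sub["draw"].to_numpy(), param] = sub["value"].to_numpy()
    return PosteriorDraws(alpha, beta, rho, sigma, hyp, genes, cell_types, datasets, info["meta"])


def fit_posterior(
    table: pd.DataFrame,
    design: DesignInfo,
    hyper: HyperpriorConstants,
    chains: int = 4,
    warmup: int = 300,
    sampling: int = 500,
    seed: int = 0,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> PosteriorDraws:
    """Sample the joint posterior with the no-U-turn sampler.

    Returns chains x sampling draws.  A warning is recorded in the metadata if
    more than 10% of post-warmup transitions diverge.
    """
    post = _UnconstrainedPosterior(design, hyper)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    all_z = []
    divergences = 0
    accept_rates = []
    step_sizes = []
    for chain in range(chains):
        rng = np.random.default_rng(seeds[chain])
        z0 = post.initial_point(rng)
        lp0, _ = post.logp_grad(z0)
        if not np.isfinite(lp0):
            raise RuntimeError(
                "joint density non-finite at initialization; review hyperprior constants"
            )
        zs, diag = _sampler.nuts_sample(
            post.logp_grad,
            z0,
            n_warmup=warmup,
            n_samples=sampling,
            rng=rng,
            target_accept=target_accept,
            max_treedepth=max_treedepth,
        )
        all_z.append(zs)
        divergences += diag["divergences"]
        accept_rates.append(diag["mean_accept"])
        step_sizes.append(diag["step_size"])
    Z = np.concatenate(all_z, axis=0)
    D = Z.shape[0]
    G, C, R = design.G, design.C, design.R
    alpha = np.empty((D, G, C))
    beta = np.empty((D, G, R))
    rho = np.empty((D, G))
    sigma = np.empty((D, G))
    hyp = np.empty((D, len(HYPER_COLS)))
    for i in range(D):
        par = post.to_constrained(Z[i])
        alpha[i], beta[i], rho[i], sigma[i] = par.alpha, par.beta, par.rho, par.sigma
        hyp[i] = [par.lambda0, par.lambda1, par.delta, par.mu, par.psi, par.upsilon, par.omega, par.o]
    meta = {
        "chains": chains,
        "warmup": warmup,
        "sampling": sampling,
        "seed": seed,
        "divergences": int(divergences),
        "mean_accept": float(np.mean(accept_rates)),
        "step_sizes": [float(s) for s in step_sizes],
    }
    if divergences > 0.10 * D:
        meta["warning"] = f"{divergences} divergent transitions (> 10% of {D} draws)"
        warnings.warn(meta["warning"], RuntimeWarning)
    return PosteriorDraws(alpha, beta, rho, sigma, pd.DataFrame(hyp, columns=HYPER_COLS),
                          list(design.genes), list(design.cell_types), list(design.datasets), meta)


def tail_draw_count(n_draws: int, quantile: float) -> int:
    """Number of draws in the tail bounded by the requested quantile."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    q = min(quantile, 1.0 - quantile)
    return int(np.floor(q * n_draws))


def summarize_posterior(draws: PosteriorDraws, quantiles: list[float]) -> pd.DataFrame:
    """Empirical quantiles per scalar parameter, plus tail draw counts.

    The returned frame has one row per scalar parameter (gene/level resolved)
    and one column per quantile, with a ``tail_draws`` count per quantile in
    ``DataFrame.attrs["tail_draws"]``.
    """
    D = draws.n_draws
    if D < 40:
        raise ValueError("need at least 40 draws to summarize")
    for q in quantiles:
        if not 0 < q < 1:
            raise ValueError(f"quantile {q} outside (0, 1)")
    rows = []
    values = []

    def add(name, gene, level, samples):
        rows.append((name, gene, level))
        values.append(samples)

    for gi, gene in enumerate(draws.genes):
        for ci, ct in enumerate(draws.cell_types):
            add("alpha", gene, ct, draws.alpha[:, gi, ci])
        for ri, ds in enumerate(draws.datasets):
            add("beta", gene, ds, draws.beta[:, gi, ri])
        add("rho", gene, "", draws.rho[:, gi])
        add("sigma", gene, "", draws.sigma[:, gi])
    for name in draws.hypers.columns:
        add(name, "", "", draws.hypers[name].to_numpy())
    V = np.asarray(values)
    out = pd.DataFrame(rows, columns=["parameter", "gene", "level"])
    for q in quantiles:
        out[f"q{q:g}"] = np.quantile(V, q, axis=1)
    out.attrs["tail_draws"] = {q: tail_draw_count(D, q) for q in quantiles}
    out.attrs["n_draws"] = D
    return out
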