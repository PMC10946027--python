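"""Bayesian group x time estimation with Student-t likelihoods.

Group comparisons use a robust cell-means model: each (group, time) cell's
observations are Student-t distributed with its own location mu_gt and scale
sigma_gt and a normality parameter nu shared across cells. Priors follow the
wide, data-anchored convention of robust Bayesian estimation (Kruschke-style
"BEST"): mu_gt ~ Normal(pooled mean, 100 * pooled SD), sigma_gt ~
Uniform(pooled SD / 1000, pooled SD * 1000), nu ~ 1 + Exponential(mean 29).
The pooled statistics are computed from the model's data slice exactly once.

Inference is by MCMC: an affine-invariant ensemble sampler (emcee) run as
several independent ensembles ("chains"), each discarding a burn-in
("tuning") segment; convergence is checked with split-Rhat and bulk ESS
(arviz), and any fit with max Rhat > 1.01 is flagged unreliable.

All scientific conclusions are read off posterior *contrasts* — differences
of posterior draws: a "group difference" mu_RPE,t - mu_TE,t at one
timepoint, or a "slope difference" (mu_RPE,late - mu_RPE,early) -
(mu_TE,late - mu_TE,early), the interaction analogue. Each contrast is
summarised by its mean, the 95% highest-density interval (the narrowest
span containing 95% of the contrast distribution), and the probability of
direction (the share of the contrast's mass on one side of zero).

A small robust regression (y = a + b*x with Student-t residuals) supports
per-subject predictor analyses such as regressing aftereffects on percent
success.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

import emcee

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

__all__ = [
    "MCMCConfig",
    "CellModelSpec",
    "Diagnostics",
    "DiagnosticError",
    "PosteriorDraws",
    "PosteriorContrast",
    "fit_cell_model",
    "group_difference",
    "slope_difference",
    "hdi",
    "p_direction",
    "summarize_contrast",
    "fit_regression",
]

logger = logging.getLogger(__name__)

RHAT_WARN = 1.01


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration: draws retained per chain, chain count, burn-in steps."""

    draws: int = 10_000
    chains: int = 4
    tune: int = 2_000
    thin: int = 12  # ensemble steps between retained draws (decorrelates walkers)
    walkers: int | None = None  # default: max(32, 2*ndim + 2), rounded even

    def n_walkers(self, ndim: int) -> int:
        w = self.walkers or max(32, 2 * ndim + 2)
        return w + (w % 2)


@dataclass(frozen=True)
class CellModelSpec:
    """Prior constants of the robust cell-means model (BEST convention)."""

    mean_sd_factor: float = 100.0
    sigma_lo_div: float = 1000.0
    sigma_hi_mul: float = 1000.0
    nu_mean: float = 29.0
    shared_nu: bool = True


@dataclass(frozen=True)
class Diagnostics:
    """Convergence summary of one fit."""

    max_rhat: float
    min_ess_bulk: float
    per_param: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return bool(np.isfinite(self.max_rhat) and self.max_rhat <= RHAT_WARN)


class DiagnosticError(RuntimeError):
    """Sampling failed; carries the diagnostics of the broken fit."""

    def __init__(self, message: str, diagnostics: Diagnostics | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class PosteriorDraws:
    """Named posterior draws, shaped (n_chains, n_draws) per scalar parameter."""

    params: dict[str, np.ndarray]
    groups: tuple[str, ...]
    times: tuple[str, ...]
    diagnostics: Diagnostics

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)


@dataclass(frozen=True)
class PosteriorContrast:
    """Posterior contrast summary: mean, 95% HDI, probability of direction."""

    name: str
    mean: float
    hdi_low: float
    hdi_high: float
    p_direction: float
    direction: str  # "gt0" or "lt0"
    reliable: bool = True

    def summary(self) -> str:
        sign = ">" if self.direction == "gt0" else "<"
        note = "" if self.reliable else "  [UNRELIABLE: poor MCMC convergence]"
        return (
            f"{self.name}: {self.mean:.2f} [{self.hdi_low:.2f} {self.hdi_high:.2f}], "
            f"{self.p_direction:.1f}% {sign} 0{note}"
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "mean": self.mean,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "p_direction": self.p_direction,
            "direction": self.direction,
            "reliable": self.reliable,
        }


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the narrowest window of order statistics.

    Sorts the draws, slides a window of ceil(mass * n) consecutive order
    statistics, and returns the narrowest one; ties break to the lowest
    starting index. Valid for unimodal posteriors, which is all this package
    summarises.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    a = np.sort(np.asarray(samples, dtype=float).ravel())
    n = a.size
    w = int(math.ceil(mass * n))
    if n < 2 or w > n:
        raise ValueError(f"need at least {max(2, w)} draws for mass={mass}, got {n}")
    if w == n:
        return float(a[0]), float(a[-1])
    widths = a[w - 1:] - a[: n - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(a[i]), float(a[i + w - 1])


def p_direction(samples) -> tuple[float, str]:
    """Probability of direction: dominant share of posterior mass on one side of 0.

    Returns (percent in [50, 100], "gt0" or "lt0"); draws exactly at zero are
    split evenly between the sides.
    """
    a = np.asarray(samples, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("p_direction of an empty draw vector")
    share_gt = (np.sum(a > 0) + 0.5 * np.sum(a == 0)) / a.size
    if share_gt >= 0.5:
        return float(100.0 * share_gt), "gt0"
    return float(100.0 * (1.0 - share_gt)), "lt0"


def summarize_contrast(
    samples, name: str, mass: float = 0.95, diagnostics: Diagnostics | None = None
) -> PosteriorContrast:
    lo, hi = hdi(samples, mass)
    pd_pct, direction = p_direction(samples)
    return PosteriorContrast(
        name=name,
        mean=float(np.mean(samples)),
        hdi_low=lo,
        hdi_high=hi,
        p_direction=pd_pct,
        direction=direction,
        reliable=diagnostics.ok if diagnostics is not None else True,
    )


# ---------------------------------------------------------------------------
# Student-t cell-means model
# ---------------------------------------------------------------------------

def _t_logpdf_sum(data: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                  nu: np.ndarray) -> np.ndarray:
    """Sum of Student-t log densities of `data` for each walker (vectorised)."""
    z = (data[None, :] - mu[:, None]) / sigma[:, None]
    nu_ = nu[:, None]
    lp = (
        gammaln((nu_ + 1.0) / 2.0)
        - gammaln(nu_ / 2.0)
        - 0.5 * np.log(nu_ * np.pi)
        - np.log(sigma[:, None])
        - (nu_ + 1.0) / 2.0 * np.log1p(z * z / nu_)
    )
    return lp.sum(axis=1)


def _run_chains(
    log_prob,
    init_center: np.ndarray,
    init_scale: np.ndarray,
    clip_lo: np.ndarray,
    clip_hi: np.ndarray,
    mcmc: MCMCConfig,
    seed: int,
) -> np.ndarray:
    """Run independent ensembles and return draws shaped (chains, draws, ndim).

    Scale-like parameters are expected on the log scale by the caller;
    differential-evolution moves mix markedly better than the default stretch
    move on the correlated (scales, normality) block of the robust model.
    """
    ndim = init_center.size
    walkers = mcmc.n_walkers(ndim)
    steps_keep = int(math.ceil(mcmc.draws / walkers))
    chain_seeds = np.random.SeedSequence(seed).generate_state(2 * mcmc.chains)
    out = np.empty((mcmc.chains, mcmc.draws, ndim))
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[2 * c])
        p0 = init_center[None, :] + init_scale[None, :] * rng.standard_normal((walkers, ndim))
        p0 = np.clip(p0, clip_lo[None, :], clip_hi[None, :])
        lp0 = log_prob(p0)
        if not np.any(np.isfinite(lp0)):
            raise DiagnosticError("no finite starting point for the sampler")
        # replace infeasible walkers with the best feasible one, jittered
        bad = ~np.isfinite(lp0)
        if np.any(bad):
            best = p0[np.argmax(lp0)]
            p0[bad] = best[None, :] + 1e-4 * init_scale[None, :] * rng.standard_normal(
                (int(bad.sum()), ndim))
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(walkers, ndim, log_prob, vectorize=True, moves=moves)
        state = emcee.State(
            p0, random_state=np.random.RandomState(int(chain_seeds[2 * c + 1])).get_state()
        )
        sampler.run_mcmc(state, mcmc.tune + steps_keep * mcmc.thin, progress=False,
                         skip_initial_state_check=True)
        chain = sampler.get_chain(discard=mcmc.tune, thin=mcmc.thin)  # (steps, walkers, ndim)
        out[c] = chain.reshape(-1, ndim)[: mcmc.draws]
    return out


def _diagnose(params: dict[str, np.ndarray]) -> Diagnostics:
    per: dict[str, tuple[float, float]] = {}
    for name, arr in params.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = float(az.rhat(arr))
            e = float(az.ess(arr, method="bulk"))
        per[name] = (r, e)
    max_rhat = max(v[0] for v in per.values())
    min_ess = min(v[1] for v in per.values())
    diag = Diagnostics(max_rhat=max_rhat, min_ess_bulk=min_ess, per_param=per)
    if not diag.ok:
        logger.warning("MCMC convergence suspect: max rhat = %.4f (> %.2f)",
                       max_rhat, RHAT_WARN)
    return diag


def fit_cell_model(
    data: pd.DataFrame,
    spec: CellModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    group_order: Sequence[str] | None = None,
    time_order: Sequence[str] | None = None,
    value_col: str = "value",
    group_col: str = "group",
    time_col: str = "epoch",
) -> PosteriorDraws:
    """Fit the Student-t cell-means model to one measure's long-format slice.

    ``data`` needs group, epoch (timepoint) and value columns; every
    (group, time) cell must be non-empty with finite values. Group order
    defaults to RPE first (matching the RPE-minus-TE contrast sign
    convention); time order defaults to order of appearance.

    Deterministic given ``seed`` and the sampler version.
    """
    spec = spec or CellModelSpec()
    mcmc = mcmc or MCMCConfig()

    df = data.dropna(subset=[value_col])
    values_all = df[value_col].to_numpy(dtype=float)
    if len(values_all) == 0 or not np.all(np.isfinite(values_all)):
        raise ValueError("model data must be non-empty and finite")

    if group_order is None:
        present = list(dict.fromkeys(df[group_col]))
        group_order = [g for g in ("RPE", "TE") if g in present] or sorted(present)
        group_order += [g for g in present if g not in group_order]
    groups = tuple(group_order)
    times = tuple(time_order) if time_order else tuple(dict.fromkeys(df[time_col]))

    cells = []
    for g in groups:
        for t in times:
            v = df[(df[group_col] == g) & (df[time_col] == t)][value_col].to_numpy(dtype=float)
            if len(v) == 0:
                raise ValueError(f"cell (group={g!r}, time={t!r}) has no observations")
            cells.append(((g, t), v))
    C = len(cells)

    pooled_mean = float(np.mean(values_all))
    pooled_sd = float(np.std(values_all, ddof=1)) if len(values_all) > 1 else 0.0
    if not pooled_sd > 0:
        pooled_sd = max(1e-6, 1e-3 * max(1.0, abs(pooled_mean)))
        logger.warning("pooled SD is zero; prior scales fall back to %.2g", pooled_sd)

    mu_sd = spec.mean_sd_factor * pooled_sd
    sig_lo = pooled_sd / spec.sigma_lo_div
    sig_hi = pooled_sd * spec.sigma_hi_mul
    nu_scale = spec.nu_mean

    cell_data = [v for _, v in cells]
    log_sig_lo, log_sig_hi = math.log(sig_lo), math.log(sig_hi)

    # internal parameterization: theta = [mu_1..C, log sigma_1..C, log(nu - 1)];
    # log scales keep the ensemble moves well conditioned, with Jacobian terms
    # restoring the Uniform(sigma) and shifted-Exponential(nu) priors
    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu = theta[:, :C]
        log_sig = theta[:, C:2 * C]
        u = theta[:, -1]
        lp = np.zeros(theta.shape[0])
        bad = (
            np.any(log_sig < log_sig_lo, axis=1)
            | np.any(log_sig > log_sig_hi, axis=1)
            | (u > 20.0)
        )
        lp[bad] = -np.inf
        ok = ~bad
        if np.any(ok):
            sigma = np.exp(log_sig[ok])
            nu = 1.0 + np.exp(u[ok])
            acc = -0.5 * np.sum(((mu[ok] - pooled_mean) / mu_sd) ** 2, axis=1)
            acc = acc + np.sum(log_sig[ok], axis=1)          # Uniform(sigma) Jacobian
            acc = acc - np.exp(u[ok]) / nu_scale + u[ok]     # shifted-Exp(nu) + Jacobian
            for c, v in enumerate(cell_data):
                acc = acc + _t_logpdf_sum(v, mu[ok, c], sigma[:, c], nu)
            lp[ok] = acc
        return lp

    cell_means = np.array([np.mean(v) for v in cell_data])
    cell_sds = np.array([max(np.std(v, ddof=1) if len(v) > 1 else 0.0, 1e-3 * pooled_sd)
                         for v in cell_data])
    cell_sems = cell_sds / np.sqrt([len(v) for v in cell_data])

    log_sds = np.log(np.clip(cell_sds, 2 * sig_lo, sig_hi / 2))
    init_center = np.concatenate([cell_means, log_sds, [math.log(20.0)]])
    init_scale = np.concatenate([np.maximum(cell_sems, 1e-3 * pooled_sd),
                                 np.full(C, 0.3), [0.5]])
    clip_lo = np.concatenate([np.full(C, -np.inf), np.full(C, log_sig_lo + 0.01), [-10.0]])
    clip_hi = np.concatenate([np.full(C, np.inf), np.full(C, log_sig_hi - 0.01), [19.0]])

    draws3 = _run_chains(log_prob, init_center, init_scale, clip_lo, clip_hi, mcmc, seed)

    params: dict[str, np.ndarray] = {}
    for c, ((g, t), _) in enumerate(cells):
        params[f"mu[{g},{t}]"] = draws3[:, :, c]
        params[f"sigma[{g},{t}]"] = np.exp(draws3[:, :, C + c])
    params["nu"] = 1.0 + np.exp(draws3[:, :, -1])

    diag = _diagnose(params)
    return PosteriorDraws(params=params, groups=groups, times=times, diagnostics=diag)


def group_difference(draws: PosteriorDraws, time: str | None = None) -> PosteriorContrast:
    """Between-group contrast at one timepoint: first group minus second.

    With the default group order this is RPE minus TE, so negative values
    mean the TE group is larger — matching the reporting convention.
    """
    if len(draws.groups) != 2:
        raise ValueError(f"group_difference needs two groups, have {draws.groups}")
    time = time if time is not None else draws.times[0]
    if time not in draws.times:
        raise ValueError(f"time {time!r} not among {draws.times}")
    g0, g1 = draws.groups
    samples = draws.flat(f"mu[{g0},{time}]") - draws.flat(f"mu[{g1},{time}]")
    return summarize_contrast(samples, f"group_difference[{time}]",
                              diagnostics=draws.diagnostics)


def slope_difference(draws: PosteriorDraws) -> PosteriorContrast:
    """Interaction-style contrast: the groups' early-to-late changes, differenced.

    (mu_g0,late - mu_g0,early) - (mu_g1,late - mu_g1,early) with (early, late)
    taken as the fitted time order.
    """
    if len(draws.groups) != 2 or len(draws.times) != 2:
        raise ValueError(
            f"slope_difference needs 2 groups x 2 times, have {draws.groups} x {draws.times}"
        )
    g0, g1 = draws.groups
    t_early, t_late = draws.times
    d0 = draws.flat(f"mu[{g0},{t_late}]") - draws.flat(f"mu[{g0},{t_early}]")
    d1 = draws.flat(f"mu[{g1},{t_late}]") - draws.flat(f"mu[{g1},{t_early}]")
    return summarize_contrast(d0 - d1, f"slope_difference[{t_early}->{t_late}]",
                              diagnostics=draws.diagnostics)


def fit_regression(
    x,
    y,
    mcmc: MCMCConfig | None = None,
    seed: int = 0,
    spec: CellModelSpec | None = None,
) -> PosteriorContrast:
    """Robust Bayesian simple regression; returns the slope's posterior summary.

    y = alpha + beta * x with Student-t residuals and wide data-anchored
    priors (alpha ~ Normal(mean y, 100 sd_y), beta ~ Normal(0, 100 sd_y/sd_x),
    sigma ~ Uniform(sd_y/1000, 1000 sd_y), nu ~ 1 + Exponential(29)).
    """
    spec = spec or CellModelSpec()
    mcmc = mcmc or MCMCConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs n >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("regression inputs must be finite")
    sd_x = float(np.std(x, ddof=1))
    sd_y = float(np.std(y, ddof=1))
    if not sd_x > 0:
        raise ValueError("predictor x is constant; slope is unidentifiable")
    if not sd_y > 0:
        sd_y = max(1e-6, 1e-3 * max(1.0, abs(float(np.mean(y)))))
    mean_y = float(np.mean(y))

    a_sd = spec.mean_sd_factor * sd_y
    b_sd = spec.mean_sd_factor * sd_y / sd_x
    sig_lo, sig_hi = sd_y / spec.sigma_lo_div, sd_y * spec.sigma_hi_mul
    nu_scale = spec.nu_mean

    log_sig_lo, log_sig_hi = math.log(sig_lo), math.log(sig_hi)

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        alpha, beta, log_sig, u = theta.T
        lp = np.zeros(theta.shape[0])
        bad = (log_sig < log_sig_lo) | (log_sig > log_sig_hi) | (u > 20.0)
        lp[bad] = -np.inf
        ok = ~bad
        if np.any(ok):
            sigma = np.exp(log_sig[ok])
            nu = 1.0 + np.exp(u[ok])
            resid = y[None, :] - alpha[ok, None] - beta[ok, None] * x[None, :]
            z = resid / sigma[:, None]
            nu_ = nu[:, None]
            like = (
                gammaln((nu_ + 1) / 2) - gammaln(nu_ / 2)
                - 0.5 * np.log(nu_ * np.pi) - log_sig[ok, None]
                - (nu_ + 1) / 2 * np.log1p(z * z / nu_)
            ).sum(axis=1)
            prior = (
                -0.5 * ((alpha[ok] - mean_y) / a_sd) ** 2
                - 0.5 * (beta[ok] / b_sd) ** 2
                + log_sig[ok]                       # Uniform(sigma) Jacobian
                - np.exp(u[ok]) / nu_scale + u[ok]  # shifted-Exp(nu) + Jacobian
            )
            lp[ok] = like + prior
        return lp

    b_ols, a_ols = np.polyfit(x, y, 1)
    resid_sd = max(float(np.std(y - (a_ols + b_ols * x), ddof=1)), 2 * sig_lo)
    init_center = np.array([a_ols, b_ols, math.log(min(resid_sd, sig_hi / 2)),
                            math.log(20.0)])
    init_scale = np.array([max(resid_sd / math.sqrt(x.size), 1e-3 * sd_y),
                           max(resid_sd / (sd_x * math.sqrt(x.size)), 1e-3 * sd_y / sd_x),
                           0.3, 0.5])
    clip_lo = np.array([-np.inf, -np.inf, log_sig_lo + 0.01, -10.0])
    clip_hi = np.array([np.inf, np.inf, log_sig_hi - 0.01, 19.0])

    draws3 = _run_chains(log_prob, init_center, init_scale, clip_lo, clip_hi, mcmc, seed)
    params = {"alpha": draws3[:, :, 0], "beta": draws3[:, :, 1],
              "sigma": np.exp(draws3[:, :, 2]), "nu": 1.0 + np.exp(draws3[:, :, 3])}
    diag = _diagnose(params)
    return summarize_contrast(draws3[:, :, 1].ravel(), "slope", diagnostics=diag)
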