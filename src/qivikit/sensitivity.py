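"""Morris elementary-effects screening and MCMC uncertainty for the PBK model.

The elementary effect is the normalized relative sensitivity
(Delta f / f) / (Delta theta / theta), evaluated in its step-size-free
log-log form SC = ln(f1/f0) / ln(theta1/theta0), so a power-law response
f ~ theta^a yields SC = a exactly at any step width (the finite-difference
quotient is used as a fallback when an output is non-positive). Parameters are perturbed over a two-fold range around their baseline
(log-uniform grid). MCMC is an adaptive random-walk Metropolis sampler in
log-parameter space with log-uniform priors over the same two-fold range and
a Gaussian likelihood on log-concentrations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .pbk import ModelSpec, build_model, simulate
from .records import DosingSchedule, ValidationError

log = logging.getLogger(__name__)

#: the four compound-specific screening parameters and the CompoundRecord
#: fields they map to
PARAM_FIELDS = {
    "fub": "fub",
    "papp": "papp",
    "clint": "clint_value",
    "solubility": "water_solubility",
}


@dataclass
class MorrisResult:
    mu: dict
    mu_star: dict
    sigma: dict
    ranking: list
    config: dict
    effects: dict = field(default_factory=dict)


def morris_screen(
    model_runner: Callable[[dict], float],
    params: dict,
    range_fold: float = 2.0,
    r: int = 20,
    levels: int = 4,
    seed: int = 0,
    printed_form: bool = False,
    upper_caps: Optional[dict] = None,
) -> MorrisResult:
    """Morris screening of a scalar model output over a fold-range.

    ``model_runner`` maps a full parameter dict to a scalar; ``params`` holds
    strictly positive baselines. Each trajectory perturbs one parameter at a
    time on a ``levels``-point log-uniform grid spanning
    [theta/range_fold, theta*range_fold] (optionally capped from above, e.g.
    fractions at 1). ``printed_form`` multiplies instead of dividing by the
    relative parameter step (compatibility only; it vanishes as the step
    shrinks and cannot rank parameters).
    """
    names = sorted(params)
    if any(params[n] <= 0 for n in names):
        raise ValidationError("Morris baselines must be > 0")
    upper_caps = upper_caps or {}
    rng = np.random.default_rng(seed)
    k = len(names)
    grid = np.linspace(0.0, 1.0, levels)
    delta = levels / (2.0 * (levels - 1.0))  # standard Morris step

    def to_theta(name, x):
        theta = params[name] * range_fold ** (2.0 * x - 1.0)
        cap = upper_caps.get(name)
        return min(theta, cap) if cap is not None else theta

    effects: dict = {n: [] for n in names}
    for traj in range(r):
        x = {n: rng.choice(grid[grid <= 1.0 - delta + 1e-12]) for n in names}
        theta = {n: to_theta(n, x[n]) for n in names}
        f0 = model_runner(dict(theta))
        if not np.isfinite(f0):
            raise ValidationError(
                f"non-finite model output at trajectory {traj} base point {theta}"
            )
        order = rng.permutation(names)
        for name in order:
            x1 = dict(x)
            x1[name] = x[name] + delta
            theta1 = {n: to_theta(n, x1[n]) for n in names}
            f1 = model_runner(dict(theta1))
            if not np.isfinite(f1):
                raise ValidationError(
                    f"non-finite model output at trajectory {traj}, "
                    f"parameter '{name}', point {theta1}"
                )
            dth = (theta1[name] - theta[name]) / theta[name]
            if dth == 0:
                continue  # cap collapsed the step
            rel_f = (f1 - f0) / f0 if f0 != 0 else math.inf
            if printed_form:
                sc = rel_f * dth
            elif f0 > 0 and f1 > 0:
                # log-log slope: the relative sensitivity in the step-size
                # free form; exact exponent for power-law responses
                sc = math.log(f1 / f0) / math.log(theta1[name] / theta[name])
            else:
                sc = rel_f / dth
            effects[name].append(sc)
            x, theta, f0 = x1, theta1, f1

    mu, mu_star, sigma = {}, {}, {}
    for n in names:
        e = np.asarray(effects[n], float)
        if e.size == 0:
            mu[n] = mu_star[n] = sigma[n] = 0.0
            continue
        mu[n] = float(e.mean())
        mu_star[n] = float(np.abs(e).mean())
        sigma[n] = float(e.std(ddof=1)) if e.size > 1 else 0.0
    ranking = sorted(names, key=lambda n: (-mu_star[n], n))
    return MorrisResult(
        mu=mu, mu_star=mu_star, sigma=sigma, ranking=ranking,
        config={"r": r, "levels": levels, "range_fold": range_fold,
                "seed": seed, "printed_form": printed_form},
        effects=effects,
    )


# ---------------------------------------------------------------------------
# model-space helpers
# ---------------------------------------------------------------------------

def rebuild_with_params(model: ModelSpec, theta: dict) -> ModelSpec:
    """New ModelSpec with screening parameters replaced on the compound."""
    changes = {PARAM_FIELDS[n]: v for n, v in theta.items()}
    compound = model.compound.copy(**changes)
    return build_model(compound, model.physiology, model.route)


def make_cmax_runner(
    model: ModelSpec,
    schedule: DosingSchedule,
    horizon: float,
    output: str = "cmax",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Callable[[dict], float]:
    """Scalar PK output (cmax, auc) as a function of the ADME parameters."""

    def run(theta: dict) -> float:
        m = rebuild_with_params(model, theta)
        ts = simulate(m, schedule, horizon, rtol=rtol, atol=atol, n_points=400)
        if output == "cmax":
            return float(np.max(ts.venous_plasma))
        if output == "cmax_unbound":
            return float(np.max(ts.unbound_plasma))
        if output == "auc":
            return float(np.trapezoid(ts.venous_plasma, ts.times))
        raise ValidationError(f"unknown output '{output}'")

    return run


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    draws: np.ndarray  # samples x parameters
    param_names: list
    log_posterior: np.ndarray
    acceptance_rate: float
    config: dict
    prior_bounds: dict

    def mean(self) -> dict:
        return {n: float(self.draws[:, i].mean())
                for i, n in enumerate(self.param_names)}


def mcmc_calibrate(
    model: ModelSpec,
    observed_times: Sequence[float],
    observed_conc: Sequence[float],
    schedule: DosingSchedule,
    prior_fold: float = 2.0,
    n_steps: int = 10_000,
    burn_in: int = 2_000,
    seed: int = 0,
    sigma: Optional[float] = None,
    target_acceptance: float = 0.30,
    rtol: float = 1e-6,
) -> PosteriorSamples:
    """Posterior over (fub, papp, clint, solubility) given a noisy profile.

    Log-uniform priors span [theta/prior_fold, theta*prior_fold] around the
    model's baseline (fub capped at 1). Likelihood: iid Gaussian residuals on
    log-concentration with scale ``sigma`` (estimated from baseline residuals
    when not given). Adaptive random-walk Metropolis in log-space; proposal
    scale tuned toward ``target_acceptance`` during burn-in only, so the
    retained chain is a valid fixed-kernel Metropolis sample.
    """
    t_obs = np.asarray(observed_times, float)
    c_obs = np.asarray(observed_conc, float)
    if t_obs.size < 5:
        raise ValidationError("need at least 5 observed points")
    if np.any(c_obs <= 0):
        raise ValidationError("observed concentrations must be > 0")
    names = sorted(PARAM_FIELDS)
    base = {
        "fub": model.compound.fub,
        "papp": model.compound.papp,
        "clint": max(model.compound.clint_value, 1e-6),
        "solubility": model.compound.water_solubility
        if model.compound.water_solubility > 0 else 1e6,
    }
    if any(base[n] is None or base[n] <= 0 for n in names):
        raise ValidationError("priors require strictly positive baselines")
    lo = {n: base[n] / prior_fold for n in names}
    hi = {n: base[n] * prior_fold for n in names}
    hi["fub"] = min(hi["fub"], 1.0)
    horizon = float(max(t_obs.max(), schedule.duration))

    def predict(theta: dict) -> np.ndarray:
        m = rebuild_with_params(model, theta)
        ts = simulate(m, schedule, horizon, rtol=rtol, atol=1e-9, n_points=300)
        return np.interp(t_obs, ts.times, ts.venous_plasma)

    log_obs = np.log(c_obs)

    def log_like(theta: dict, sig: float) -> float:
        pred = predict(theta)
        if np.any(pred <= 0):
            return -math.inf
        resid = log_obs - np.log(pred)
        return float(-0.5 * np.sum((resid / sig) ** 2)
                     - resid.size * math.log(sig))

    if sigma is None:
        pred0 = predict(base)
        resid0 = log_obs - np.log(np.clip(pred0, 1e-300, None))
        sigma = max(float(np.std(resid0)), 0.05)

    rng = np.random.default_rng(seed)
    logx = np.array([math.log(base[n]) for n in names])
    lo_v = np.array([math.log(lo[n]) for n in names])
    hi_v = np.array([math.log(hi[n]) for n in names])
    logx = np.clip(logx, lo_v, hi_v)
    scale = 0.15
    lp = log_like({n: math.exp(v) for n, v in zip(names, logx)}, sigma)
    draws, lps = [], []
    accepted = accepted_recent = 0
    for step in range(n_steps):
        prop = logx + rng.normal(0.0, scale, size=len(names))
        if np.any(prop < lo_v) or np.any(prop > hi_v):
            lp_prop = -math.inf
        else:
            lp_prop = log_like({n: math.exp(v) for n, v in zip(names, prop)},
                               sigma)
        if math.log(rng.uniform()) < lp_prop - lp:
            logx, lp = prop, lp_prop
            accepted += 1
            accepted_recent += 1
        if step < burn_in and (step + 1) % 25 == 0:
            rate = accepted_recent / 25.0
            scale *= math.exp(1.5 * (rate - target_acceptance))
            accepted_recent = 0
        if step >= burn_in:
            draws.append(np.exp(logx))
            lps.append(lp)
    rate = accepted / n_steps
    if rate < 0.01 or rate > 0.99:
        log.warning(
            "degenerate chain: acceptance rate %.3f (proposal scale %.3g)",
            rate, scale,
        )
    return PosteriorSamples(
        draws=np.asarray(draws),
        param_names=names,
        log_posterior=np.asarray(lps),
        acceptance_rate=rate,
        config={"n_steps": n_steps, "burn_in": burn_in, "seed": seed,
                "proposal_scale": scale, "sigma": sigma,
                "prior_fold": prior_fold},
        prior_bounds={n: (lo[n], hi[n]) for n in names},
    )


def credible_bands(
    post: PosteriorSamples,
    model: ModelSpec,
    schedule: DosingSchedule,
    grid: Sequence[float],
    n_draws: int = 50,
    rtol: float = 1e-6,
) -> dict:
    """Pointwise posterior mean, 50% (central) and 95% (wide) bands.

    Returns arrays over ``grid`` for the venous plasma concentration. Bands
    are nested by construction (quantile ordering).
    """
    if post.draws.size == 0:
        raise ValidationError("posterior is empty")
    grid = np.asarray(grid, float)
    idx = np.unique(
        np.linspace(0, len(post.draws) - 1, min(n_draws, len(post.draws)))
        .astype(int)
    )
    horizon = float(max(grid.max(), schedule.duration))
    curves = []
    for i in idx:
        theta = dict(zip(post.param_names, post.draws[i]))
        m = rebuild_with_params(model, theta)
        ts = simulate(m, schedule, horizon, rtol=rtol, atol=1e-9, n_points=300)
        curves.append(np.interp(grid, ts.times, ts.venous_plasma))
    curves = np.asarray(curves)
    return {
        "times": grid,
        "mean": curves.mean(axis=0),
        "central_low": np.quantile(curves, 0.25, axis=0),
        "central_high": np.quantile(curves, 0.75, axis=0),
        "wide_low": np.quantile(curves, 0.025, axis=0),
        "wide_high": np.quantile(curves, 0.975, axis=0),
    }
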