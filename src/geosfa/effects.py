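"""Post-estimation layer: technical efficiency, the variance ratio
gamma, slack resources, marginal effects and policy-scenario
extrapolation.

Technical efficiency is TE = exp(-u) in (0, 1].  For a half-normal
inefficiency with scale sigma_u the closed-form mean efficiency is

    E[exp(-u)] = 2 exp(sigma_u^2 / 2) Phi(-sigma_u),

used both as a fast evaluation at the 'average hospital' (all
covariates at sample means) and as the oracle against Monte-Carlo
draw-averaging.  Slack resources are the input-oriented, one-input-at-
a-time contraction: holding output and the other inputs fixed, a unit
with inefficiency u could shed

    slack_k = x_k (1 - exp(-u / beta_k))

of input k (beta_k its output elasticity).  Marginal effects of an
inefficiency determinant z_j propagate through the scale
sigma_u = sigma_u* exp(eta_u): d sigma_u / d z_j = delta_j sigma_u.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mcmc import PosteriorDraws
from .model import ModelDesign

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# closed-form half-normal efficiency

def expected_te_halfnormal(sigma_u) -> np.ndarray | float:
    """E[exp(-u)] for u half-normal with scale sigma_u:
    2 exp(sigma_u^2/2) Phi(-sigma_u), evaluated in log space so large
    scales do not overflow."""
    from scipy.special import log_ndtr
    s = np.asarray(sigma_u, dtype=float)
    out = np.exp(np.log(2.0) + s * s / 2.0 + log_ndtr(-s))
    return float(out) if out.ndim == 0 else out


def d_expected_te_dsigma(sigma_u) -> np.ndarray | float:
    """d E[exp(-u)] / d sigma_u = 2 (sigma e^{sigma^2/2} Phi(-sigma)
    - 1/sqrt(2 pi)); negative for all sigma > 0.  (The e^{sigma^2/2}
    phi(sigma) product collapses to the constant 1/sqrt(2 pi).)"""
    from scipy.special import log_ndtr
    s = np.asarray(sigma_u, dtype=float)
    out = 2.0 * (s * np.exp(s * s / 2.0 + log_ndtr(-s))
                 - 1.0 / np.sqrt(2.0 * np.pi))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# technical efficiency and gamma

def technical_efficiency(draws: PosteriorDraws, design: ModelDesign):
    """Posterior-mean TE per hospital-year and the grand mean.

    TE_it = mean over stored draws of exp(-u*_it alpha_it).
    """
    if draws.u_star is None:
        raise ValueError("draws contain no latent inefficiency samples")
    te_by_obs = np.exp(-draws.u(design)).mean(axis=0)
    return te_by_obs, float(te_by_obs.mean())


def variance_ratio_gamma(sigma_u2: float, sigma_v2: float) -> float:
    """gamma = sigma_u^2 / (sigma_v^2 + sigma_u^2), the share of
    composed-error variation attributed to inefficiency."""
    if sigma_u2 <= 0 or sigma_v2 <= 0:
        raise ValueError("variances must be positive")
    return sigma_u2 / (sigma_v2 + sigma_u2)


def _mean_eta_u_draws(draws: PosteriorDraws, design: ModelDesign) -> np.ndarray:
    """Per-draw inefficiency predictor at the sample-mean covariate
    vector (mean of the design columns, spatial and wave terms
    included)."""
    zbar = design.Z.mean(axis=0)
    eta = draws.delta @ zbar
    if draws.f_struct is not None and design.struct_idx is not None:
        eta = eta + draws.f_struct[:, design.struct_idx].mean(axis=1)
    if draws.f_unstruct is not None and design.unstruct_idx is not None:
        eta = eta + draws.f_unstruct[:, design.unstruct_idx].mean(axis=1)
    if draws.h is not None:
        eta = eta + draws.h[:, design.hospital_idx].mean(axis=1)
    return eta


def sigma_u_at_means(draws: PosteriorDraws, design: ModelDesign) -> np.ndarray:
    """Per-draw sigma_u = sigma_u* exp(eta_u) at sample means."""
    return np.sqrt(draws.sigma_ustar2) * np.exp(_mean_eta_u_draws(draws, design))


def gamma_from_draws(draws: PosteriorDraws, design: ModelDesign) -> float:
    """Posterior-mean gamma with sigma_u^2 evaluated at sample-mean
    covariates (the documented, configurable evaluation point)."""
    su = sigma_u_at_means(draws, design)
    g = su ** 2 / (draws.sigma_v2 + su ** 2)
    return float(g.mean())


# ---------------------------------------------------------------------------
# slack resources

def slack_from_u(u, beta_k: float, x_k) -> np.ndarray:
    """Input-oriented single-input contraction
    slack = x_k (1 - exp(-u / beta_k)), capped at x_k."""
    if beta_k <= 0:
        raise ValueError(
            f"slack undefined for nonpositive output elasticity {beta_k}: "
            "contracting this input cannot hold output fixed")
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        frac = -np.expm1(-u / beta_k)
    if np.any(u / beta_k > 700):
        logger.warning("slack capped at the input level for extreme u")
    return np.asarray(x_k) * np.clip(frac, 0.0, 1.0)


def expected_slack_halfnormal(sigma_u, beta_k: float, x_k):
    """E[slack] at half-normal u with scale sigma_u:
    x_k (1 - E[exp(-u/beta_k)])."""
    s = np.asarray(sigma_u, dtype=float) / beta_k
    return np.asarray(x_k) * (1.0 - expected_te_halfnormal(s))


def slack_resources(draws: PosteriorDraws, design: ModelDesign,
                    input_name: str, x_level, at: str = "average_hospital"):
    """Posterior slack distribution for one input.

    at="average_hospital": per stored draw, the expected slack of a
    hospital with all covariates at sample means and input level
    ``x_level`` (a scalar, normally the sample-mean input in levels).

    at="per_observation": slack per hospital-year evaluated at the
    posterior mean of its inefficiency u; ``x_level`` is then a vector
    of input levels per observation.  National totals are sums within a
    wave of these per-observation slacks.
    """
    try:
        k = design.x_names.index(input_name)
    except ValueError:
        raise KeyError(f"input {input_name!r} not in the frontier design")
    beta_k = float(draws.beta[:, k].mean())
    if beta_k <= 0:
        raise ValueError(f"posterior-mean elasticity of {input_name!r} is "
                         f"{beta_k:.4f} <= 0; slack undefined")
    if at == "average_hospital":
        sigma_u = sigma_u_at_means(draws, design)
        return expected_slack_halfnormal(sigma_u, beta_k, x_level)
    elif at == "per_observation":
        u_mean = draws.u(design).mean(axis=0)
        return slack_from_u(u_mean, beta_k, np.asarray(x_level, dtype=float))
    raise ValueError(f"unknown evaluation mode {at!r}")


def national_totals(slack_by_obs: np.ndarray, design: ModelDesign) -> dict:
    """Sum per-observation slacks within each wave."""
    out = {}
    for t in np.unique(design.wave_of_obs):
        out[int(t)] = float(slack_by_obs[design.wave_of_obs == t].sum())
    return out


# ---------------------------------------------------------------------------
# marginal effects

def _delta_of(draws: PosteriorDraws, design: ModelDesign, covariate: str):
    try:
        j = design.z_names.index(covariate)
    except ValueError:
        raise KeyError(f"covariate {covariate!r} not in the inefficiency "
                       "predictor")
    return j


def marginal_effect_te(draws: PosteriorDraws, design: ModelDesign,
                       covariate: str, mode: str = "derivative",
                       times100: bool = True) -> float:
    """Marginal effect of an inefficiency determinant on expected TE,
    evaluated at sample means and averaged over posterior draws.

    derivative mode: delta_j sigma_u dE[TE]/dsigma_u.  discrete mode
    (for binary determinants): E[TE | z_j=1] - E[TE | z_j=0] with the
    other covariates at their means.
    """
    j = _delta_of(draws, design, covariate)
    dj = draws.delta[:, j]
    sigma_u = sigma_u_at_means(draws, design)
    if mode == "derivative":
        eff = dj * sigma_u * d_expected_te_dsigma(sigma_u)
    elif mode == "discrete":
        zj_mean = design.Z[:, j].mean() + design.z_means[j]
        s0 = sigma_u * np.exp(dj * (0.0 - zj_mean))
        s1 = sigma_u * np.exp(dj * (1.0 - zj_mean))
        eff = expected_te_halfnormal(s1) - expected_te_halfnormal(s0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scale = 100.0 if times100 else 1.0
    return float(np.mean(eff)) * scale


def marginal_effect_slack(draws: PosteriorDraws, design: ModelDesign,
                          covariate: str, input_name: str, x_level,
                          mode: str = "derivative") -> float:
    """Marginal effect of a determinant on the slack of one input at the
    average hospital; opposite in sign to the TE effect (more
    efficiency, less slack)."""
    j = _delta_of(draws, design, covariate)
    k = design.x_names.index(input_name)
    beta_k = float(draws.beta[:, k].mean())
    if beta_k <= 0:
        raise ValueError(f"nonpositive elasticity for {input_name!r}")
    dj = draws.delta[:, j]
    sigma_u = sigma_u_at_means(draws, design)
    if mode == "derivative":
        # slack(s) = x (1 - E_te(s/b)); d(s/b)/dz_j = delta_j s / b
        sb = sigma_u / beta_k
        eff = dj * sb * (-np.asarray(x_level)) * d_expected_te_dsigma(sb)
    elif mode == "discrete":
        zj_mean = design.Z[:, j].mean() + design.z_means[j]
        s0 = sigma_u * np.exp(dj * (0.0 - zj_mean))
        s1 = sigma_u * np.exp(dj * (1.0 - zj_mean))
        eff = (expected_slack_halfnormal(s1, beta_k, x_level)
               - expected_slack_halfnormal(s0, beta_k, x_level))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.mean(eff))


def scenario_savings(per_hospital_effect: float, n_hospitals: float):
    """National extrapolation of a per-hospital effect: the product,
    reported raw and rounded to the nearest integer."""
    if per_hospital_effect < 0 or n_hospitals < 0:
        raise ValueError("effect and count must be nonnegative")
    raw = per_hospital_effect * n_hospitals
    return raw, int(round(raw))


# ---------------------------------------------------------------------------
# assembled report

@dataclass
class EffectsReport:
    """Bundle of post-estimation results for one fitted model."""

    te_by_obs: np.ndarray
    te_overall: float
    gamma: float
    marginal_te: pd.DataFrame
    slack_average: dict = field(default_factory=dict)
    marginal_slack: pd.DataFrame | None = None
    scenario_table: pd.DataFrame | None = None

    def validate(self) -> None:
        if np.any(self.te_by_obs <= 0) or np.any(self.te_by_obs > 1.0 + 1e-12):
            raise ValueError("TE outside (0, 1]")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma outside (0, 1)")


def build_effects_report(draws: PosteriorDraws, design: ModelDesign,
                         input_levels: dict | None = None,
                         binary_covariates: set | None = None) -> EffectsReport:
    """Compute the standard effects report: TE, gamma, marginal TE
    effects per determinant (discrete differences for binaries by
    default), and average-hospital slack distributions for the inputs
    given in ``input_levels`` (input design name -> mean level)."""
    te_by_obs, te_overall = technical_efficiency(draws, design)
    gamma = gamma_from_draws(draws, design)
    binaries = binary_covariates or set()
    rows = []
    for z in design.z_names:
        mode = "discrete" if z in binaries else "derivative"
        rows.append({"covariate": z, "mode": mode,
                     "marginal_te_x100": marginal_effect_te(
                         draws, design, z, mode=mode)})
    mte = pd.DataFrame(rows).set_index("covariate")

    slack_avg = {}
    srows = []
    for input_name, x_level in (input_levels or {}).items():
        try:
            slack_avg[input_name] = slack_resources(
                draws, design, input_name, x_level, at="average_hospital")
        except ValueError as exc:
            # nonpositive posterior-mean elasticity: slack undefined
            logger.warning("skipping slack for %s: %s", input_name, exc)
            continue
        for z in design.z_names:
            mode = "discrete" if z in binaries else "derivative"
            srows.append({"covariate": z, "input": input_name,
                          "effect": marginal_effect_slack(
                              draws, design, z, input_name, x_level,
                              mode=mode)})
    mslack = (pd.DataFrame(srows).pivot(index="covariate", columns="input",
                                        values="effect")
              if srows else None)
    report = EffectsReport(te_by_obs=te_by_obs, te_overall=te_overall,
                           gamma=gamma, marginal_te=mte,
                           slack_average=slack_avg, marginal_slack=mslack)
    report.validate()
    return report
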