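"""MCMC fitting of the geoadditive stochastic frontier model, plus
DIC/WAIC model-selection criteria.

One sweep updates, in order: (1) the frontier coefficients beta by a
conjugate Gaussian draw on the adjusted response y + alpha u*; (2) the
latent half-normal innovations u* by exact truncated-normal draws from
their full conditional; (3) the inefficiency-scaling coefficients delta
by blocked adaptive random-walk Metropolis; (4) the structured (GMRF)
district effect by single-site Metropolis within graph-coloring classes
(prior-conditional Gibbs for districts without hospitals), followed by
per-component sum-to-zero re-centering with a compensating rescale of
(u*, sigma_u*^2) that leaves the likelihood invariant; (5) the
unstructured district effect and optional hospital effect by grouped
adaptive Metropolis; (6) all variances by conjugate inverse-gamma draws.

All randomness flows through one numpy Generator seeded from the model
spec, so identical seeds give bitwise-identical stored draws.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import log_ndtr, ndtri_exp, logsumexp

from .model import (
    ModelDesign,
    ModelSpec,
    ParameterState,
    loglik_conditional,
    loglik_marginal,
    skewnormal_loglik,
)
from .regions import RegionGraph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# truncated-normal primitive

def _truncnorm_nonneg(m, s, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from N(m, s^2) truncated to [0, inf), vectorized and
    robust for extreme standardized bounds (inverse log-CDF; no
    rejection loop)."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    a = -m / s
    logu = np.log1p(-rng.random(size=np.broadcast_shapes(m.shape, s.shape)))
    x = -ndtri_exp(logu + log_ndtr(-a))
    return m + s * x


def sample_ustar_conditional(residual, alpha, sigma_v2, sigma_ustar2,
                             rng: np.random.Generator,
                             mu_star: float = 0.0) -> np.ndarray:
    """Draw the inefficiency innovation u* from its full conditional.

    Given the residual r = y - eta_y, the conditional is the truncated
    normal N+(m, s^2) with s^2 = (1/sigma_u*^2 + alpha^2/sigma_v^2)^-1
    and m = s^2 (alpha (eta_y - y)/sigma_v^2 + mu*/sigma_u*^2).
    """
    if sigma_v2 <= 0 or sigma_ustar2 <= 0:
        raise ValueError("scale parameters must be positive")
    residual = np.asarray(residual, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    prec = 1.0 / sigma_ustar2 + alpha * alpha / sigma_v2
    s2 = 1.0 / prec
    m = s2 * (-alpha * residual / sigma_v2 + mu_star / sigma_ustar2)
    return _truncnorm_nonneg(m, np.sqrt(s2), rng)


def map_initial_state(design: ModelDesign,
                      rng: np.random.Generator) -> ParameterState:
    """Warm start: maximize the marginal (skew-normal) likelihood over
    (intercept shift, delta, log sigma_v2, log sigma_u*2) with the other
    frontier coefficients at OLS and spatial effects at zero, then draw
    u* from its conditional at that mode.  Keeps short chains honest by
    starting them near the posterior bulk."""
    from scipy.optimize import minimize

    from .model import skewnormal_loglik

    X, Z, y = design.X, design.Z, design.y
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    eps0 = y - X @ beta0
    q = Z.shape[1]
    v0 = max(float(np.var(eps0)), 1e-3)

    def nll(theta):
        off, delta = theta[0], theta[1:1 + q]
        sv2 = np.exp(theta[1 + q])
        su = np.exp(theta[2 + q])
        sigma_u = su * np.exp(Z @ delta) if q else np.full(len(y), su)
        with np.errstate(all="ignore"):
            ll = skewnormal_loglik(eps0 - off, sv2, sigma_u)
        return -float(ll.sum()) if np.all(np.isfinite(ll)) else 1e12

    x0 = np.concatenate([[0.0], np.zeros(q),
                         [np.log(v0 / 2.0), 0.5 * np.log(v0 / 2.0)]])
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": 300, "maxfun": 20000})
    off, delta = res.x[0], res.x[1:1 + q]
    sv2 = float(np.exp(res.x[1 + q]))
    su = float(np.exp(res.x[2 + q]))
    beta0[0] += off
    alpha = np.exp(Z @ delta) if q else np.ones(len(y))
    spec = design.spec
    if spec.ustar_level == "hospital":
        H = len(design.hospital_ids)
        a2 = np.bincount(design.hospital_idx, weights=alpha ** 2, minlength=H)
        ar = np.bincount(design.hospital_idx,
                         weights=alpha * (y - X @ beta0), minlength=H)
        prec = 1.0 / su ** 2 + a2 / sv2
        ustar = _truncnorm_nonneg(-(ar / sv2) / prec, np.sqrt(1.0 / prec), rng)
    else:
        ustar = sample_ustar_conditional(y - X @ beta0, alpha, sv2, su ** 2,
                                         rng, mu_star=spec.mu_star)
    n_s = design.struct_graph.n_regions if design.struct_graph else 0
    n_u = design.unstruct_graph.n_regions if design.unstruct_graph else 0
    return ParameterState(
        beta=beta0, delta=delta,
        f_struct=np.zeros(n_s) if n_s else None,
        f_unstruct=np.zeros(n_u) if n_u else None,
        h=np.zeros(len(design.hospital_ids)) if spec.hospital_effect else None,
        u_star=ustar, sigma_v2=sv2, sigma_ustar2=su ** 2,
        tau2_struct=0.1, tau2_unstruct=0.1, tau2_hospital=0.1)


# ---------------------------------------------------------------------------
# stored draws

@dataclass
class PosteriorDraws:
    """Thinned post-burn-in MCMC samples with bookkeeping metadata."""

    beta: np.ndarray
    delta: np.ndarray
    u_star: np.ndarray
    alpha: np.ndarray
    sigma_v2: np.ndarray
    sigma_ustar2: np.ndarray
    f_struct: np.ndarray | None = None
    f_unstruct: np.ndarray | None = None
    h: np.ndarray | None = None
    tau2_struct: np.ndarray | None = None
    tau2_unstruct: np.ndarray | None = None
    tau2_hospital: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def u(self, design: ModelDesign) -> np.ndarray:
        """Per-draw, per-observation inefficiency u = u* alpha."""
        if design.spec.ustar_level == "hospital":
            return self.u_star[:, design.hospital_idx] * self.alpha
        return self.u_star * self.alpha

    def state_at(self, s: int) -> ParameterState:
        return ParameterState(
            beta=self.beta[s], delta=self.delta[s],
            f_struct=None if self.f_struct is None else self.f_struct[s],
            f_unstruct=None if self.f_unstruct is None else self.f_unstruct[s],
            h=None if self.h is None else self.h[s],
            u_star=self.u_star[s],
            sigma_v2=float(self.sigma_v2[s]),
            sigma_ustar2=float(self.sigma_ustar2[s]),
            tau2_struct=float(self.tau2_struct[s]) if self.tau2_struct is not None else 1.0,
            tau2_unstruct=float(self.tau2_unstruct[s]) if self.tau2_unstruct is not None else 1.0,
            tau2_hospital=float(self.tau2_hospital[s]) if self.tau2_hospital is not None else 1.0,
        )

    def mean_state(self) -> ParameterState:
        """Posterior-mean plug-in state (u_star left at its mean too)."""
        return ParameterState(
            beta=self.beta.mean(axis=0), delta=self.delta.mean(axis=0),
            f_struct=None if self.f_struct is None else self.f_struct.mean(axis=0),
            f_unstruct=None if self.f_unstruct is None else self.f_unstruct.mean(axis=0),
            h=None if self.h is None else self.h.mean(axis=0),
            u_star=self.u_star.mean(axis=0),
            sigma_v2=float(self.sigma_v2.mean()),
            sigma_ustar2=float(self.sigma_ustar2.mean()),
            tau2_struct=float(self.tau2_struct.mean()) if self.tau2_struct is not None else 1.0,
            tau2_unstruct=float(self.tau2_unstruct.mean()) if self.tau2_unstruct is not None else 1.0,
            tau2_hospital=float(self.tau2_hospital.mean()) if self.tau2_hospital is not None else 1.0,
        )

    # -- summaries ----------------------------------------------------------
    def summary(self, which: str = "delta") -> pd.DataFrame:
        """Posterior mean, sd, credible intervals and interval-based
        'significance' stars (credibility interval excluding zero at
        1/5/10%)."""
        arr = getattr(self, which)
        names = self.meta.get({"beta": "x_names", "delta": "z_names"}.get(which),
                              None) or [f"{which}[{i}]" for i in range(arr.shape[1])]
        rows = []
        for j, nm in enumerate(names):
            d = arr[:, j]
            lo1, hi1 = np.quantile(d, [0.005, 0.995])
            lo5, hi5 = np.quantile(d, [0.025, 0.975])
            lo10, hi10 = np.quantile(d, [0.05, 0.95])
            stars = ("***" if lo1 * hi1 > 0 else
                     "**" if lo5 * hi5 > 0 else
                     "*" if lo10 * hi10 > 0 else "")
            rows.append({"name": nm, "mean": d.mean(), "sd": d.std(ddof=1),
                         "q2.5": lo5, "q97.5": hi5, "stars": stars})
        return pd.DataFrame(rows).set_index("name")

    def diagnostics(self) -> pd.DataFrame:
        """Split-chain R-hat and effective sample size per scalar block."""
        import arviz as az
        out = []
        scalars = {"sigma_v2": self.sigma_v2, "sigma_ustar2": self.sigma_ustar2}
        for nm, arr in [("tau2_struct", self.tau2_struct),
                        ("tau2_unstruct", self.tau2_unstruct)]:
            if arr is not None:
                scalars[nm] = arr
        for j, nm in enumerate(self.meta.get("z_names", [])):
            scalars[f"delta_{nm}"] = self.delta[:, j]
        for nm, d in scalars.items():
            chain = d.reshape(1, -1)
            ess = float(az.ess(chain))
            rhat = float(az.rhat(d.reshape(2, -1))) if len(d) >= 4 else np.nan
            if ess < 100:
                logger.warning("low effective sample size for %s: %.0f", nm, ess)
            out.append({"name": nm, "mean": d.mean(), "ess": ess,
                        "split_rhat": rhat})
        return pd.DataFrame(out).set_index("name")

    # -- persistence --------------------------------------------------------
    def save(self, path_prefix: str) -> None:
        arrays = {k: v for k, v in self.__dict__.items()
                  if isinstance(v, np.ndarray)}
        np.savez_compressed(path_prefix + ".npz", **arrays)
        with open(path_prefix + ".json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    @classmethod
    def load(cls, path_prefix: str) -> "PosteriorDraws":
        data = dict(np.load(path_prefix + ".npz"))
        with open(path_prefix + ".json") as fh:
            meta = json.load(fh)
        return cls(meta=meta, **data)


# ---------------------------------------------------------------------------
# sampler

class GibbsSampler:
    """Markov transition kernel for the geoadditive SFA posterior.

    Exposed separately from :func:`run_mcmc` so sampler-validation
    schemes (successive-conditional simulation) can interleave
    parameter transitions with data redraws.
    """

    def __init__(self, design: ModelDesign, rng: np.random.Generator,
                 initial: ParameterState | None = None):
        self.design = design
        self.spec = design.spec
        self.rng = rng
        self.X = design.X
        self.Z = design.Z
        self.y = design.y.copy()
        self.n = design.n_obs
        self.XtX = self.X.T @ self.X

        mc = self.spec.mcmc
        q = self.Z.shape[1]
        self.blocks = [np.arange(i, min(i + mc.delta_block_size, q))
                       for i in range(0, q, mc.delta_block_size)]
        # per-column proposal scaling: steps proportional to 1/sd(z_j),
        # upgraded to the empirical posterior covariance (Haario-style)
        # once enough adaptation history has accumulated
        sds = self.Z.std(axis=0) if q else np.zeros(0)
        self.z_scale = 1.0 / np.where(sds > 1e-12, sds, 1.0)
        self.block_scales = np.full(len(self.blocks), 0.1)
        self._d_count = 0
        self._d_mean = np.zeros(q)
        self._d_m2 = np.zeros((q, q))
        self._block_chol = [None] * len(self.blocks)
        self.block_acc = np.zeros(len(self.blocks))
        self.block_tries = np.zeros(len(self.blocks))

        # spatial bookkeeping
        self._setup_group("struct", design.struct_graph, design.struct_idx)
        self._setup_group("unstruct", design.unstruct_graph, design.unstruct_idx)
        if self.spec.hospital_effect:
            hg = len(design.hospital_ids)
            self._setup_group("hospital", None, design.hospital_idx, size=hg)
        self.ustar_size = (len(design.hospital_ids)
                           if self.spec.ustar_level == "hospital" else self.n)

        # the delta and spatial-effect updates integrate u* out
        # analytically (partially-collapsed Gibbs) whenever the
        # skew-normal marginal exists pointwise: half-normal case with
        # observation-specific innovations
        self.collapsed = (self.spec.mu_star == 0.0
                          and self.spec.ustar_level == "observation")

        self._init_state(initial)
        self._adapt_count = 0
        self._iter = 0

    # -- grouped-effect bookkeeping ----------------------------------------
    def _setup_group(self, name: str, graph: RegionGraph | None,
                     idx: np.ndarray | None, size: int | None = None):
        if idx is None and size is None:
            setattr(self, f"{name}_size", 0)
            return
        size = size if size is not None else graph.n_regions
        setattr(self, f"{name}_size", size)
        setattr(self, f"{name}_idx", idx)
        order = np.argsort(idx, kind="stable")
        sorted_groups = idx[order]
        starts = np.searchsorted(sorted_groups, np.arange(size))
        present = np.zeros(size, dtype=bool)
        present[idx] = True
        setattr(self, f"{name}_order", order)
        setattr(self, f"{name}_starts", starts)
        setattr(self, f"{name}_present", present)
        setattr(self, f"{name}_scales", np.full(size, 0.5))
        setattr(self, f"{name}_acc", np.zeros(size))
        setattr(self, f"{name}_tries", np.zeros(size))
        if graph is not None:
            setattr(self, f"{name}_graph", graph)
            setattr(self, f"{name}_colors", graph.coloring())
            setattr(self, f"{name}_degrees", graph.degrees.astype(float))
            import scipy.sparse as sp
            n = graph.n_regions
            if graph.edges.size:
                i, j = graph.edges[:, 0], graph.edges[:, 1]
                A = sp.csr_matrix(
                    (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])),
                    shape=(n, n))
            else:
                A = sp.csr_matrix((n, n))
            setattr(self, f"{name}_adj", A)
            comps = graph.components()
            setattr(self, f"{name}_components", comps)
            setattr(self, f"{name}_ncomp", int(comps.max()) + 1)
            setattr(self, f"{name}_rank", graph.n_regions - int(comps.max()) - 1)

    def _group_sums(self, name: str, values: np.ndarray) -> np.ndarray:
        """Per-group sums of a per-observation vector."""
        order = getattr(self, f"{name}_order")
        starts = getattr(self, f"{name}_starts")
        size = getattr(self, f"{name}_size")
        c = np.concatenate([[0.0], np.cumsum(values[order])])
        ends = np.append(starts[1:], len(values))
        return c[ends] - c[starts]

    # -- state --------------------------------------------------------------
    def _init_state(self, initial: ParameterState | None):
        d = self.design
        if initial is not None:
            s = initial
            self.beta = s.beta.astype(float).copy()
            self.delta = s.delta.astype(float).copy()
            self.fs = None if s.f_struct is None else s.f_struct.copy()
            self.fu = None if s.f_unstruct is None else s.f_unstruct.copy()
            self.hh = None if s.h is None else s.h.copy()
            self.ustar = s.u_star.astype(float).copy()
            self.sv2, self.su2 = float(s.sigma_v2), float(s.sigma_ustar2)
            self.t2s, self.t2u = float(s.tau2_struct), float(s.tau2_unstruct)
            self.t2h = float(s.tau2_hospital)
        else:
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            resid = self.y - self.X @ beta
            self.beta = beta
            self.delta = np.zeros(self.Z.shape[1])
            self.fs = np.zeros(self.struct_size) if self.struct_size else None
            self.fu = np.zeros(self.unstruct_size) if self.unstruct_size else None
            self.hh = (np.zeros(self.hospital_size)
                       if getattr(self, "hospital_size", 0) else None)
            self.sv2 = max(float(np.var(resid)) * 0.5, 1e-4)
            self.su2 = max(float(np.var(resid)) * 0.5, 1e-4)
            self.t2s = self.t2u = self.t2h = 0.1
            self.ustar = np.abs(self.rng.standard_normal(self.ustar_size)
                                * np.sqrt(self.su2))
        self._refresh_caches()

    def _refresh_caches(self):
        self.xb = self.X @ self.beta
        etau = self.Z @ self.delta if self.Z.shape[1] else np.zeros(self.n)
        if self.fs is not None:
            etau = etau + self.fs[self.struct_idx]
        if self.fu is not None:
            etau = etau + self.fu[self.unstruct_idx]
        if self.hh is not None:
            etau = etau + self.hh[self.design.hospital_idx]
        self.etau = etau
        self.alpha = np.exp(etau)

    def _ustar_obs(self) -> np.ndarray:
        if self.spec.ustar_level == "hospital":
            return self.ustar[self.design.hospital_idx]
        return self.ustar

    def state(self) -> ParameterState:
        return ParameterState(
            beta=self.beta.copy(), delta=self.delta.copy(),
            f_struct=None if self.fs is None else self.fs.copy(),
            f_unstruct=None if self.fu is None else self.fu.copy(),
            h=None if self.hh is None else self.hh.copy(),
            u_star=self.ustar.copy(), sigma_v2=self.sv2,
            sigma_ustar2=self.su2, tau2_struct=self.t2s,
            tau2_unstruct=self.t2u, tau2_hospital=self.t2h)

    def set_y(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, dtype=float).copy()

    def draw_data(self) -> np.ndarray:
        """Draw y from the observation model at the current state (used
        by successive-conditional sampler validation)."""
        mean = self.xb - self.alpha * self._ustar_obs()
        return mean + np.sqrt(self.sv2) * self.rng.standard_normal(self.n)

    # -- individual updates -------------------------------------------------
    def _update_beta(self):
        ytil = self.y + self.alpha * self._ustar_obs()
        A = self.XtX.copy()
        c = self.spec.priors.beta_prior_var
        if c is not None:
            A[np.diag_indices_from(A)] += self.sv2 / c
        L = cholesky(A, lower=True)
        mean = cho_solve((L, True), self.X.T @ ytil)
        z = self.rng.standard_normal(len(mean))
        self.beta = mean + np.sqrt(self.sv2) * solve_triangular(
            L.T, z, lower=False)
        self.xb = self.X @ self.beta

    def _update_ustar(self):
        r = self.y - self.xb
        mu = self.spec.mu_star
        if self.spec.ustar_level == "hospital":
            # aggregate over each hospital's observations
            hidx = self.design.hospital_idx
            H = self.ustar_size
            a2 = np.bincount(hidx, weights=self.alpha ** 2, minlength=H)
            ar = np.bincount(hidx, weights=self.alpha * r, minlength=H)
            prec = 1.0 / self.su2 + a2 / self.sv2
            s2 = 1.0 / prec
            m = s2 * (-ar / self.sv2 + mu / self.su2)
            self.ustar = _truncnorm_nonneg(m, np.sqrt(s2), self.rng)
        else:
            self.ustar = sample_ustar_conditional(
                r, self.alpha, self.sv2, self.su2, self.rng, mu_star=mu)

    def _rm_step(self) -> float:
        return (1.0 + self._adapt_count) ** -0.6

    def _marg_ll(self) -> np.ndarray:
        """Pointwise skew-normal marginal log-likelihood at the current
        state (u* integrated out)."""
        eps = self.y - self.xb
        return skewnormal_loglik(eps, self.sv2,
                                 np.sqrt(self.su2) * self.alpha)

    def _update_delta(self, adapt: bool):
        if not self.Z.shape[1]:
            return
        c = self.spec.priors.delta_prior_var
        target = self.spec.mcmc.target_accept_block
        if self.collapsed:
            eps = self.y - self.xb
            su = np.sqrt(self.su2)
            mll = self._mll
        else:
            u = self._ustar_obs()
            r = self.y - self.xb
            e = r + self.alpha * u
            sse = e @ e
        for b, bidx in enumerate(self.blocks):
            z = self.rng.standard_normal(len(bidx))
            if self._block_chol[b] is not None:
                dz = self.block_scales[b] * (self._block_chol[b] @ z)
            else:
                dz = self.block_scales[b] * self.z_scale[bidx] * z
            deta = self.Z[:, bidx] @ dz
            alpha_new = self.alpha * np.exp(deta)
            if self.collapsed:
                mll_new = skewnormal_loglik(eps, self.sv2, su * alpha_new)
                logr = float(mll_new.sum() - mll.sum())
            else:
                e_new = r + alpha_new * u
                sse_new = e_new @ e_new
                logr = (sse - sse_new) / (2.0 * self.sv2)
            if c is not None:
                dnew = self.delta[bidx] + dz
                logr += (self.delta[bidx] @ self.delta[bidx]
                         - dnew @ dnew) / (2.0 * c)
            acc_p = min(1.0, float(np.exp(min(logr, 0.0))))
            self.block_tries[b] += 1
            if np.log1p(-self.rng.random()) < logr:
                self.delta[bidx] += dz
                self.alpha = alpha_new
                self.etau = self.etau + deta
                if self.collapsed:
                    mll = mll_new
                else:
                    e, sse = e_new, sse_new
                self.block_acc[b] += 1
            if adapt:
                self.block_scales[b] *= np.exp(self._rm_step() * (acc_p - target))
        if self.collapsed:
            self._mll = mll
        if adapt:
            self._adapt_delta_cov()

    def _adapt_delta_cov(self):
        """Welford update of the delta history covariance; periodically
        refresh per-block proposal Cholesky factors."""
        self._d_count += 1
        dlt = self.delta - self._d_mean
        self._d_mean += dlt / self._d_count
        self._d_m2 += np.outer(dlt, self.delta - self._d_mean)
        if self._d_count >= 200 and self._d_count % 100 == 0:
            cov = self._d_m2 / (self._d_count - 1)
            for b, bidx in enumerate(self.blocks):
                sub = cov[np.ix_(bidx, bidx)].copy()
                k = len(bidx)
                sub[np.diag_indices(k)] += 1e-10 + 1e-3 * np.diag(sub)
                try:
                    L = np.linalg.cholesky(sub)
                except np.linalg.LinAlgError:
                    continue
                # renormalize so block_scales keeps its acceptance role
                norm = np.sqrt(np.trace(sub) / k)
                if norm > 0:
                    self._block_chol[b] = L / norm

    def _update_sites(self, name: str, adapt: bool):
        """Grouped single-site Metropolis for a region- or hospital-level
        effect.  For the structured effect, updates proceed by coloring
        class so neighbour sums stay fixed within a vectorized batch."""
        f = {"struct": self.fs, "unstruct": self.fu, "hospital": self.hh}[name]
        if f is None:
            return
        tau2 = {"struct": self.t2s, "unstruct": self.t2u,
                "hospital": self.t2h}[name]
        idx = getattr(self, f"{name}_idx", None)
        if idx is None:
            idx = self.design.hospital_idx
        present = getattr(self, f"{name}_present")
        scales = getattr(self, f"{name}_scales")
        if self.collapsed:
            eps = self.y - self.xb
            su = np.sqrt(self.su2)
        else:
            u = self._ustar_obs()
            r = self.y - self.xb
            e = r + self.alpha * u
            e2 = e * e
        target = self.spec.mcmc.target_accept_site

        structured = name == "struct"
        if structured:
            colors = getattr(self, f"{name}_colors")
            adj = getattr(self, f"{name}_adj")
            deg = getattr(self, f"{name}_degrees")
            classes = [np.flatnonzero(colors == k)
                       for k in range(colors.max() + 1)]
            # obs whose region falls in each color class (marginal
            # updates only need the likelihood on these)
            cache = getattr(self, "_struct_class_obs", None)
            if cache is None:
                obs_color = colors[idx]
                cache = [np.flatnonzero(obs_color == k)
                         for k in range(colors.max() + 1)]
                self._struct_class_obs = cache
            class_obs = cache
        else:
            classes = [np.flatnonzero(present)]
            class_obs = [np.arange(self.n)]

        for cls, sub in zip(classes, class_obs):
            if structured:
                S = adj @ f  # neighbour sums at current values
            data_cls = cls[present[cls]]
            # ----- Metropolis for sites with data
            if data_cls.size:
                dv = np.zeros(len(f))
                dv[data_cls] = scales[data_cls] * self.rng.standard_normal(
                    len(data_cls))
                deta = dv[idx]
                if self.collapsed:
                    mll_new_sub = skewnormal_loglik(
                        eps[sub], self.sv2,
                        su * self.alpha[sub] * np.exp(deta[sub]))
                    diff = np.zeros(self.n)
                    diff[sub] = mll_new_sub - self._mll[sub]
                    sums = self._group_sums(name, diff)
                    logr = sums[data_cls]
                else:
                    e_new = r + self.alpha * np.exp(deta) * u
                    diff = e2 - e_new * e_new
                    sums = self._group_sums(name, diff)
                    logr = sums[data_cls] / (2.0 * self.sv2)
                fold = f[data_cls]
                fnew = fold + dv[data_cls]
                if structured:
                    logr += -(deg[data_cls] * (fnew ** 2 - fold ** 2)
                              - 2.0 * (fnew - fold) * S[data_cls]) / (2.0 * tau2)
                else:
                    logr += (fold ** 2 - fnew ** 2) / (2.0 * tau2)
                accept = np.log1p(-self.rng.random(len(data_cls))) < logr
                acc_sites = data_cls[accept]
                if acc_sites.size:
                    f[acc_sites] += dv[acc_sites]
                    applied = np.zeros(len(f))
                    applied[acc_sites] = dv[acc_sites]
                    shift = applied[idx]
                    self.etau = self.etau + shift
                    self.alpha = self.alpha * np.exp(shift)
                    if self.collapsed:
                        moved = shift[sub] != 0.0
                        self._mll[sub[moved]] = mll_new_sub[moved]
                    else:
                        e = r + self.alpha * u
                        e2 = e * e
                getattr(self, f"{name}_tries")[data_cls] += 1
                getattr(self, f"{name}_acc")[acc_sites] += 1
                if adapt:
                    accp = np.minimum(1.0, np.exp(np.minimum(logr, 0.0)))
                    scales[data_cls] *= np.exp(self._rm_step()
                                               * (accp - target))
            # ----- exact prior-conditional Gibbs for empty sites
            if structured:
                empty_cls = cls[~present[cls]]
                if empty_cls.size:
                    S = adj @ f
                    pos = empty_cls[deg[empty_cls] > 0]
                    f[empty_cls] = 0.0
                    if pos.size:
                        f[pos] = (S[pos] / deg[pos]
                                  + np.sqrt(tau2 / deg[pos])
                                  * self.rng.standard_normal(len(pos)))

        if structured:
            self._recenter_struct()
            # on a connected graph the compensating rescale leaves
            # sigma_u* alpha exactly invariant, so the marginal
            # likelihood is unchanged; multi-component graphs get the
            # per-component shifts and need a refresh
            if self.collapsed and self.struct_ncomp > 1:
                self._mll = self._marg_ll()

    def _recenter_struct(self):
        """Sum-to-zero per connected component, with compensating
        rescale of u* and sigma_u*^2 so u = u* alpha and hence the
        likelihood are exactly unchanged."""
        comps = getattr(self, "struct_components")
        means = np.zeros(comps.max() + 1)
        for k in range(len(means)):
            mask = comps == k
            means[k] = self.fs[mask].mean()
            self.fs[mask] -= means[k]
        shift = means[comps][self.struct_idx]  # per-obs level removed
        self.etau = self.etau - shift
        self.alpha = self.alpha * np.exp(-shift)
        if self.spec.ustar_level == "hospital":
            hshift = np.zeros(self.ustar_size)
            hshift[self.design.hospital_idx] = shift
            self.ustar = self.ustar * np.exp(hshift)
            self.su2 *= float(np.exp(2.0 * hshift.mean()))
        else:
            self.ustar = self.ustar * np.exp(shift)
            self.su2 *= float(np.exp(2.0 * shift.mean()))

    def _update_variances(self):
        a, b = self.spec.priors.ig_shape, self.spec.priors.ig_scale
        rg = self.rng

        def ig(shape, rate):
            return rate / rg.gamma(shape)

        v = self.y - self.xb + self.alpha * self._ustar_obs()
        self.sv2 = ig(a + self.n / 2.0, b + 0.5 * float(v @ v))
        du = self.ustar - self.spec.mu_star
        self.su2 = ig(a + len(self.ustar) / 2.0, b + 0.5 * float(du @ du))
        if self.fs is not None:
            from .regions import gmrf_quadform
            self.t2s = ig(a + self.struct_rank / 2.0,
                          b + 0.5 * gmrf_quadform(self.fs, self.struct_graph))
        if self.fu is not None:
            obs = self.unstruct_present
            self.t2u = ig(a + obs.sum() / 2.0,
                          b + 0.5 * float(self.fu[obs] @ self.fu[obs]))
        if self.hh is not None:
            self.t2h = ig(a + len(self.hh) / 2.0,
                          b + 0.5 * float(self.hh @ self.hh))

    # -- one sweep ----------------------------------------------------------
    def step(self, adapt: bool = False):
        if self.collapsed:
            # collapsed block (delta, f, h | u* integrated out), then a
            # fresh u* draw: jointly a draw of (delta, f, h, u*)
            self._mll = self._marg_ll()
            self._update_delta(adapt)
            self._update_sites("struct", adapt)
            self._update_sites("unstruct", adapt)
            if self.hh is not None:
                self._update_sites("hospital", adapt)
            self._update_ustar()
            self._update_beta()
        else:
            self._update_beta()
            self._update_ustar()
            self._update_delta(adapt)
            self._update_sites("struct", adapt)
            self._update_sites("unstruct", adapt)
            if self.hh is not None:
                self._update_sites("hospital", adapt)
        self._update_variances()
        if adapt:
            self._adapt_count += 1
        self._iter += 1
        if self._iter % 500 == 0:
            self._check_finite()

    def _check_finite(self):
        vals = [self.beta, self.delta, self.ustar,
                np.array([self.sv2, self.su2])]
        if not all(np.all(np.isfinite(v)) for v in vals):
            dump = {"iter": self._iter, "beta": self.beta.tolist(),
                    "sigma_v2": self.sv2, "sigma_ustar2": self.su2}
            raise RuntimeError(f"non-finite posterior state: {dump}")

    def acceptance_rates(self) -> dict:
        out = {}
        if len(self.blocks):
            with np.errstate(invalid="ignore"):
                out["delta_blocks"] = (self.block_acc
                                       / np.maximum(self.block_tries, 1)).tolist()
        for nm in ("struct", "unstruct", "hospital"):
            tries = getattr(self, f"{nm}_tries", None)
            if tries is not None and tries.sum() > 0:
                acc = getattr(self, f"{nm}_acc")
                out[nm] = float(acc.sum() / max(tries.sum(), 1))
        return out


def run_mcmc(panel_or_design, graph: RegionGraph | None = None,
             spec: ModelSpec | None = None,
             initial: ParameterState | str | None = "map") -> PosteriorDraws:
    """Fit the model by MCMC and return thinned post-burn-in draws.

    Accepts either a prepared :class:`HospitalPanel` plus graph and
    spec, or a ready :class:`ModelDesign`.  ``initial`` may be an
    explicit state, ``"map"`` (default; marginal-likelihood warm start)
    or ``None`` (OLS-based heuristics).
    """
    from .model import build_design
    if isinstance(panel_or_design, ModelDesign):
        design = panel_or_design
    else:
        if spec is None:
            raise ValueError("spec required")
        design = build_design(panel_or_design, graph, spec)
    mc = design.spec.mcmc
    rng = np.random.default_rng(mc.seed)
    if isinstance(initial, str):
        if initial != "map":
            raise ValueError(f"unknown initializer {initial!r}")
        initial = map_initial_state(design, rng)
    sampler = GibbsSampler(design, rng, initial=initial)

    S = mc.n_stored
    n_store_u = sampler.ustar_size
    store = {
        "beta": np.empty((S, design.X.shape[1])),
        "delta": np.empty((S, design.Z.shape[1])),
        "u_star": np.empty((S, n_store_u)),
        "alpha": np.empty((S, design.n_obs)),
        "sigma_v2": np.empty(S), "sigma_ustar2": np.empty(S),
    }
    if sampler.fs is not None:
        store["f_struct"] = np.empty((S, len(sampler.fs)))
        store["tau2_struct"] = np.empty(S)
    if sampler.fu is not None:
        store["f_unstruct"] = np.empty((S, len(sampler.fu)))
        store["tau2_unstruct"] = np.empty(S)
    if sampler.hh is not None:
        store["h"] = np.empty((S, len(sampler.hh)))
        store["tau2_hospital"] = np.empty(S)

    t0 = time.time()
    k = 0
    adapt_until = mc.burn_in
    for it in range(mc.iterations):
        sampler.step(adapt=it < adapt_until)
        if it >= mc.burn_in and (it - mc.burn_in) % mc.thinning == mc.thinning - 1:
            store["beta"][k] = sampler.beta
            store["delta"][k] = sampler.delta
            store["u_star"][k] = sampler.ustar
            store["alpha"][k] = sampler.alpha
            store["sigma_v2"][k] = sampler.sv2
            store["sigma_ustar2"][k] = sampler.su2
            if sampler.fs is not None:
                store["f_struct"][k] = sampler.fs
                store["tau2_struct"][k] = sampler.t2s
            if sampler.fu is not None:
                store["f_unstruct"][k] = sampler.fu
                store["tau2_unstruct"][k] = sampler.t2u
            if sampler.hh is not None:
                store["h"][k] = sampler.hh
                store["tau2_hospital"][k] = sampler.t2h
            k += 1

    acc = sampler.acceptance_rates()
    for nm, val in acc.items():
        vals = val if isinstance(val, list) else [val]
        for v in vals:
            if not (0.05 <= v <= 0.7):
                logger.warning("acceptance rate for %s outside [0.05, 0.7]: "
                               "%.3f", nm, v)
    meta = {
        "seed": mc.seed, "iterations": mc.iterations, "burn_in": mc.burn_in,
        "thinning": mc.thinning, "n_stored": S,
        "acceptance_rates": acc, "runtime_s": time.time() - t0,
        "x_names": design.x_names, "z_names": design.z_names,
        "data_fingerprint": design.data_fingerprint(),
        "design_fingerprint": design.fingerprint(),
        "spec": json.loads(design.spec.to_json()),
    }
    return PosteriorDraws(meta=meta, **store)


# ---------------------------------------------------------------------------
# model-selection criteria

def pointwise_loglik(draws: PosteriorDraws, design: ModelDesign,
                     which: str = "marginal") -> np.ndarray:
    """(n_draws, n_obs) matrix of pointwise log-likelihood values.

    ``which="marginal"`` integrates the latent inefficiency out
    analytically (skew-normal composed error), making models with
    different latent dimensions comparable; ``which="conditional"``
    conditions on the stored u draws.
    """
    fn = {"marginal": loglik_marginal, "conditional": loglik_conditional}[which]
    S = draws.n_draws
    out = np.empty((S, design.n_obs))
    for s in range(S):
        out[s] = fn(draws.state_at(s), design, pointwise=True)
    return out


def _check_draws_design(draws: PosteriorDraws, design: ModelDesign):
    fp = draws.meta.get("data_fingerprint")
    if fp is not None and fp != design.data_fingerprint():
        raise ValueError("draws were produced on different observations "
                         "than this design (data fingerprint mismatch)")


def compute_dic(draws: PosteriorDraws, design: ModelDesign,
                which: str = "marginal",
                ll_matrix: np.ndarray | None = None) -> tuple[float, float]:
    """Deviance information criterion: DIC = Dbar + pD with
    pD = Dbar - D(theta_bar), D = -2 log-likelihood."""
    _check_draws_design(draws, design)
    if draws.n_draws < 100:
        raise ValueError("need at least 100 stored draws for DIC")
    if ll_matrix is None:
        ll_matrix = pointwise_loglik(draws, design, which)
    fn = {"marginal": loglik_marginal, "conditional": loglik_conditional}[which]
    dbar = float(np.mean(-2.0 * ll_matrix.sum(axis=1)))
    dhat = -2.0 * fn(draws.mean_state(), design)
    pd_ = dbar - dhat
    return dbar + pd_, pd_


def compute_waic(draws: PosteriorDraws, design: ModelDesign,
                 which: str = "marginal",
                 ll_matrix: np.ndarray | None = None) -> tuple[float, float]:
    """Watanabe-Akaike criterion:
    WAIC = -2 sum_i [log mean_s p_i(s) - var_s log p_i(s)]."""
    _check_draws_design(draws, design)
    if draws.n_draws < 100:
        raise ValueError("need at least 100 stored draws for WAIC")
    if ll_matrix is None:
        ll_matrix = pointwise_loglik(draws, design, which)
    S = ll_matrix.shape[0]
    lppd_i = logsumexp(ll_matrix, axis=0) - np.log(S)
    p_i = ll_matrix.var(axis=0, ddof=1)
    p_waic = float(p_i.sum())
    waic = -2.0 * (float(lppd_i.sum()) - p_waic)
    return waic, p_waic
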