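"""Model specification, linear predictors and composed-error likelihoods.

The frontier is an empirical Cobb-Douglas (optionally translog)
production function

    y_it = eta_y_it + v_it - u*_it exp(eta_u_it),

with y the centered log risk-adjusted patient volume, v ~ N(0, sigma_v^2)
idiosyncratic noise and u* ~ N+(0, sigma_u*^2) a half-normal inefficiency
innovation multiplied by the covariate-driven scale alpha = exp(eta_u).
Because u is the *random variable* scaled by alpha, its standard
deviation is sigma_u* alpha (the scaling-property formulation).

eta_y contains the zero-input dummies, the log quality and staffing
inputs, wave effects and an intercept.  eta_u contains the inefficiency
determinants, wave effects and district-level structured/unstructured
(and optionally hospital) random effects — and no intercept, whose role
is played by the scale of u*.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.special import log_ndtr

from .panel import COVARIATES, LOG_COVARIATES, HospitalPanel
from .regions import RegionGraph

LOG2PI = float(np.log(2.0 * np.pi))

#: frontier input sets (Cobb-Douglas first-order terms, by performance notion)
FRONTIER_SETS = {
    "quality_resource": ["D_mor", "D_readm", "log_mor_star", "log_readm_star",
                         "log_phys", "log_nurse"],
    "quality_only": ["D_mor", "D_readm", "log_mor_star", "log_readm_star"],
    "resource_only": ["log_phys", "log_nurse"],
}

#: continuous log inputs eligible for translog second-order terms
_TRANSLOG_BASE = ["log_mor_star", "log_readm_star", "log_phys", "log_nurse"]

#: canonical inefficiency determinants (design-column names; covariates
#: measured as shares/sizes enter on the log scale)
EQ7_COVARIATES = [
    ("log_" + c if c in LOG_COVARIATES else c) for c in COVARIATES
]


@dataclass
class Priors:
    """Inverse-gamma (shape, scale) hyperpriors on all variances; linear
    coefficients are flat by default, optionally Gaussian with the given
    prior variance (needed e.g. for sampler validation)."""
    ig_shape: float = 0.001
    ig_scale: float = 0.001
    beta_prior_var: float | None = None
    delta_prior_var: float | None = None


@dataclass
class MCMCSettings:
    iterations: int = 120_000
    burn_in: int = 20_000
    thinning: int = 100
    seed: int = 20060101
    delta_block_size: int = 8
    target_accept_block: float = 0.25
    target_accept_site: float = 0.44

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if (self.iterations - self.burn_in) % self.thinning:
            raise ValueError("(iterations - burn_in) must be divisible by "
                             "thinning")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class ModelSpec:
    """Complete specification of one frontier model.

    ``frontier_inputs`` is one of the named sets above or an explicit
    column list; ``struct_level`` / ``unstruct_level`` place the
    structured (GMRF) and unstructured (iid) spatial effect at
    ``"district"``, ``"coarse"`` or ``None``; mixed-level variants use
    different levels for the two.
    """

    name: str = "model"
    frontier_inputs: str | list = "quality_resource"
    functional_form: str = "cobb_douglas"
    ineff_covariates: list = field(default_factory=lambda: list(EQ7_COVARIATES))
    struct_level: str | None = "district"
    unstruct_level: str | None = "district"
    hospital_effect: bool = False
    ustar_level: str = "observation"
    mu_star: float = 0.0
    center_ineff_covariates: bool = True
    priors: Priors = field(default_factory=Priors)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if self.functional_form not in ("cobb_douglas", "translog"):
            raise ValueError(f"unknown functional form {self.functional_form!r}")
        for lv in (self.struct_level, self.unstruct_level):
            if lv not in (None, "district", "coarse"):
                raise ValueError(f"unknown spatial level {lv!r}")
        if self.ustar_level not in ("observation", "hospital"):
            raise ValueError(f"unknown ustar level {self.ustar_level!r}")
        if self.functional_form == "translog" and not self.frontier_columns():
            raise ValueError("translog requires frontier inputs")

    def frontier_columns(self) -> list:
        if isinstance(self.frontier_inputs, str):
            return list(FRONTIER_SETS[self.frontier_inputs])
        return list(self.frontier_inputs)

    def with_updates(self, **kw) -> "ModelSpec":
        return replace(self, **kw)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "ModelSpec":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        d["priors"] = Priors(**d.get("priors", {}))
        d["mcmc"] = MCMCSettings(**d.get("mcmc", {}))
        return cls(**d)


@dataclass
class ModelDesign:
    """Numeric design assembled from a prepared panel, graph and spec.

    X carries the frontier design (intercept, inputs, wave dummies,
    translog terms); Z the inefficiency design (covariates, wave
    dummies), mean-centered when the spec says so with the offsets kept
    in ``z_means``.  Index arrays map each observation to its structured
    region, unstructured region and hospital.
    """

    y: np.ndarray
    X: np.ndarray
    x_names: list
    Z: np.ndarray
    z_names: list
    z_means: np.ndarray
    struct_graph: RegionGraph | None
    struct_idx: np.ndarray | None
    unstruct_graph: RegionGraph | None
    unstruct_idx: np.ndarray | None
    unstruct_observed: np.ndarray | None
    hospital_ids: list
    hospital_idx: np.ndarray
    wave_of_obs: np.ndarray
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.y).tobytes())
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(np.ascontiguousarray(self.Z).tobytes())
        return h.hexdigest()[:16]

    def data_fingerprint(self) -> str:
        """Fingerprint of the observations only (y); model comparisons
        are valid only across identical observation sets."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.y).tobytes())
        return h.hexdigest()[:16]


def _wave_dummies(years: np.ndarray, reference: int):
    waves = sorted(int(t) for t in np.unique(years))
    cols, names = [], []
    for t in waves:
        if t == reference:
            continue
        cols.append((years == t).astype(float))
        names.append(f"wave_{t}")
    return cols, names


def build_design(panel: HospitalPanel, graph: RegionGraph | None,
                 spec: ModelSpec) -> ModelDesign:
    """Assemble the numeric design on the frontier-usable rows."""
    df = panel.frontier_rows().reset_index(drop=True)
    if "y" not in df.columns or df["y"].isna().any():
        raise ValueError("panel not prepared: run prepare_panel first")
    years = df["year"].to_numpy(int)
    ref = panel.reference_year

    # frontier design
    fcols = spec.frontier_columns()
    missing = [c for c in fcols if c not in df.columns]
    if missing:
        raise KeyError(f"frontier design columns missing from panel: {missing}")
    if panel.zero_mode == "rescale_half":
        fcols = [c for c in fcols if c not in ("D_mor", "D_readm")]
    Xc = [np.ones(len(df))]
    x_names = ["const"]
    for c in fcols:
        Xc.append(df[c].to_numpy(float))
        x_names.append(c)
    if spec.functional_form == "translog":
        base = [c for c in fcols if c in _TRANSLOG_BASE]
        for a_i, a in enumerate(base):
            for b in base[a_i:]:
                Xc.append(df[a].to_numpy(float) * df[b].to_numpy(float))
                x_names.append(f"{a}*{b}" if a != b else f"{a}^2")
    wd, wn = _wave_dummies(years, ref)
    Xc += wd
    x_names += wn
    X = np.column_stack(Xc)

    # inefficiency design
    Zc, z_names = [], []
    for c in spec.ineff_covariates:
        if c in df.columns:
            v = df[c].to_numpy(float)
        elif c.startswith("log_") and c[4:] in df.columns:
            raw = df[c[4:]].to_numpy(float)
            if np.any(raw <= 0):
                raise ValueError(f"cannot log-transform nonpositive {c[4:]!r}")
            v = np.log(raw)
        else:
            raise KeyError(f"inefficiency covariate {c!r} not in panel")
        Zc.append(v)
        z_names.append(c)
    wd, wn = _wave_dummies(years, ref)
    Zc += wd
    z_names += [w.replace("wave_", "itau_") for w in wn]
    Z = np.column_stack(Zc) if Zc else np.zeros((len(df), 0))
    if spec.center_ineff_covariates and Z.shape[1]:
        ncov = len(z_names) - len(wn)  # wave dummies kept raw
        z_means = np.concatenate([Z[:, :ncov].mean(axis=0), np.zeros(len(wn))])
    else:
        z_means = np.zeros(Z.shape[1])
    Z = Z - z_means

    # spatial / hospital indexing
    struct_graph = unstruct_graph = None
    struct_idx = unstruct_idx = unstruct_observed = None
    if spec.struct_level or spec.unstruct_level:
        if graph is None:
            raise ValueError("spec requests spatial effects but no graph given")
        district_idx = graph.index_of(df["district_id"].tolist())
        for level, role in ((spec.struct_level, "struct"),
                            (spec.unstruct_level, "unstruct")):
            if level is None:
                continue
            if level == "district":
                lg, li = graph, district_idx
            else:
                if graph.coarse_map is None:
                    raise ValueError("coarse spatial level requires a "
                                     "coarse_map on the graph")
                lg = graph.coarsen()
                li = lg.index_of([graph.coarse_map[r]
                                  for r in df["district_id"]])
            if role == "struct":
                struct_graph, struct_idx = lg, li
            else:
                unstruct_graph, unstruct_idx = lg, li
        if unstruct_graph is not None:
            obs = np.zeros(unstruct_graph.n_regions, dtype=bool)
            obs[unstruct_idx] = True
            unstruct_observed = obs

    hospitals = sorted(df["hospital_id"].unique().tolist())
    hidx = {h: i for i, h in enumerate(hospitals)}
    hospital_idx = np.array([hidx[h] for h in df["hospital_id"]], dtype=int)

    return ModelDesign(
        y=df["y"].to_numpy(float), X=X, x_names=x_names, Z=Z, z_names=z_names,
        z_means=z_means, struct_graph=struct_graph, struct_idx=struct_idx,
        unstruct_graph=unstruct_graph, unstruct_idx=unstruct_idx,
        unstruct_observed=unstruct_observed, hospital_ids=hospitals,
        hospital_idx=hospital_idx, wave_of_obs=years, spec=spec)


# ---------------------------------------------------------------------------
# parameter state and predictors

@dataclass
class ParameterState:
    """One point in parameter space (a single MCMC state)."""
    beta: np.ndarray
    delta: np.ndarray
    f_struct: np.ndarray | None = None
    f_unstruct: np.ndarray | None = None
    h: np.ndarray | None = None
    u_star: np.ndarray | None = None
    sigma_v2: float = 1.0
    sigma_ustar2: float = 1.0
    tau2_struct: float = 1.0
    tau2_unstruct: float = 1.0
    tau2_hospital: float = 1.0

    def validate(self) -> None:
        for nm in ("sigma_v2", "sigma_ustar2", "tau2_struct",
                   "tau2_unstruct", "tau2_hospital"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.u_star is not None and np.any(self.u_star < 0):
            raise ValueError("u_star must be nonnegative")


def eta_y(state: ParameterState, design: ModelDesign) -> np.ndarray:
    """Frontier predictor X beta."""
    if len(state.beta) != design.X.shape[1]:
        raise ValueError("beta length does not match frontier design")
    return design.X @ state.beta


def eta_u(state: ParameterState, design: ModelDesign) -> np.ndarray:
    """Inefficiency predictor: covariates + wave effects + spatial and
    hospital random effects (no intercept)."""
    out = design.Z @ state.delta if design.Z.shape[1] else np.zeros(design.n_obs)
    if design.struct_idx is not None and state.f_struct is not None:
        out = out + state.f_struct[design.struct_idx]
    if design.unstruct_idx is not None and state.f_unstruct is not None:
        out = out + state.f_unstruct[design.unstruct_idx]
    if state.h is not None:
        out = out + state.h[design.hospital_idx]
    return out


def alpha_of(state: ParameterState, design: ModelDesign) -> np.ndarray:
    """Inefficiency scaling factor alpha = exp(eta_u) > 0."""
    return np.exp(eta_u(state, design))


def ustar_per_obs(state: ParameterState, design: ModelDesign) -> np.ndarray:
    u = state.u_star
    if u is None:
        raise ValueError("state has no u_star draws")
    if design.spec.ustar_level == "hospital":
        return u[design.hospital_idx]
    return u


# ---------------------------------------------------------------------------
# likelihoods

def loglik_conditional(state: ParameterState, design: ModelDesign,
                       pointwise: bool = False):
    """Gaussian log-likelihood of y given the latent inefficiencies:
    each residual v = y - eta_y + alpha u* is N(0, sigma_v^2)."""
    if state.sigma_v2 <= 0:
        raise ValueError("sigma_v2 must be positive")
    v = design.y - eta_y(state, design) + alpha_of(state, design) * \
        ustar_per_obs(state, design)
    ll = -0.5 * (LOG2PI + np.log(state.sigma_v2)) - v * v / (2.0 * state.sigma_v2)
    return ll if pointwise else float(ll.sum())


def skewnormal_loglik(eps: np.ndarray, sigma_v2: float,
                      sigma_u: np.ndarray) -> np.ndarray:
    """Pointwise log-density of the composed error eps = v - u with
    v ~ N(0, sigma_v2) and u half-normal with scale sigma_u (possibly
    observation-specific):

        log f(eps) = log 2 - log sigma_c + log phi(eps/sigma_c)
                     + log Phi(-eps lambda / sigma_c),

    sigma_c^2 = sigma_v2 + sigma_u^2, lambda = sigma_u / sigma_v.
    Underflow in the Gaussian CDF is handled via log_ndtr.
    """
    eps = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("non-finite composed-error residuals")
    if sigma_v2 <= 0:
        raise ValueError("sigma_v2 must be positive")
    sigma_u = np.broadcast_to(np.asarray(sigma_u, dtype=float), eps.shape)
    s2 = sigma_v2 + sigma_u ** 2
    sc = np.sqrt(s2)
    lam = sigma_u / np.sqrt(sigma_v2)
    return (np.log(2.0) - 0.5 * np.log(s2) - 0.5 * LOG2PI
            - eps * eps / (2.0 * s2) + log_ndtr(-eps * lam / sc))


def loglik_marginal(state: ParameterState, design: ModelDesign,
                    pointwise: bool = False):
    """Composed-error (skew-normal) log-likelihood with u integrated out
    analytically; requires the half-normal case mu_star = 0."""
    if design.spec.mu_star != 0.0:
        raise ValueError("marginal likelihood implemented for mu_star = 0 only")
    eps = design.y - eta_y(state, design)
    sigma_u = np.sqrt(state.sigma_ustar2) * alpha_of(state, design)
    ll = skewnormal_loglik(eps, state.sigma_v2, sigma_u)
    return ll if pointwise else float(ll.sum())
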