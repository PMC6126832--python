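"""Synthetic hospital-panel generator with known ground truth.

Emulates the statistical structure the frontier analysis assumes: an
unbalanced hospital-year panel over five waves, districts on a rook
lattice with a spatially smooth (intrinsic GMRF) plus an iid district
inefficiency component, count-valued quality inputs with a sizeable
atom at exactly zero (rising across waves), strongly correlated
physician/nurse staffing, binary certification/ownership/teaching
determinants, and a stroke-unit certification process that switches on
over time (so matching + difference-in-differences designs have
switchers to work with).

Default effect sizes and variances are chosen to place fixtures in the
regime of a large published German hospital application (they are
simulation defaults, not estimates).  The half-normal innovation scale
default (1.517, i.e. sigma_u^2 = 2.30 at mean covariates against
sigma_v^2 = 0.142, gamma = 0.94) makes inefficiency the dominant
composed-error component, as in that regime; a scale near 0.42 instead
puts the *unconditional* mean of exp(-u) near 0.73.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .panel import HospitalPanel
from .regions import RegionGraph, make_lattice_graph, sample_icar

#: simulation-default frontier coefficients
DEFAULT_BETA = {
    "const": 0.470, "D_mor": -0.329, "D_readm": -0.186,
    "log_mor_star": 0.397, "log_readm_star": 0.282,
    "log_phys": 0.056, "log_nurse": 0.015,
    "wave_2008": -0.025, "wave_2010": -0.085, "wave_2012": -0.107,
    "wave_2013": -0.056,
}

#: simulation-default inefficiency-determinant coefficients
DEFAULT_DELTA = {
    "Spec": -0.022, "MSStrDis": -0.829, "NumStrHospDis": 0.009,
    "log_PatShaStroke": -0.252, "MedDepCon": -0.228, "SUCert": -1.167,
    "SUnonCert": -0.592, "log_GPsPerDis": -0.004, "log_HosBed": -0.555,
    "PrivHos": 0.310, "NonProfHos": 0.158, "Teach": -0.069, "UniHos": 0.175,
    "ShaI61": 0.619, "ShaI64": -0.299, "DiagCon": 0.394, "ShaTRHOMB": 0.052,
    "itau_2008": 0.064, "itau_2010": 0.235, "itau_2012": 0.253,
    "itau_2013": 0.362,
}

DEFAULT_WAVES = (2006, 2008, 2010, 2012, 2013)

#: per-wave target fractions of exact-zero quality inputs
DEFAULT_ZERO_FRAC_MOR = {2006: 0.08, 2008: 0.11, 2010: 0.15, 2012: 0.15,
                         2013: 0.16}
DEFAULT_ZERO_FRAC_READM = {2006: 0.09, 2008: 0.11, 2010: 0.16, 2012: 0.18,
                           2013: 0.17}


@dataclass
class SimConfig:
    """Generating conditions for one synthetic panel."""

    lattice_size: int = 20
    coarse_block: int = 4
    hospitals_per_district: float = 3.2
    waves: tuple = DEFAULT_WAVES
    dropout: float = 0.03
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    delta: dict = field(default_factory=lambda: dict(DEFAULT_DELTA))
    sigma_v2: float = 0.142
    sigma_ustar: float = 1.517
    tau2_struct: float = 0.15
    tau2_unstruct: float = 0.02
    zero_frac_mor: dict | float = field(
        default_factory=lambda: dict(DEFAULT_ZERO_FRAC_MOR))
    zero_frac_readm: dict | float = field(
        default_factory=lambda: dict(DEFAULT_ZERO_FRAC_READM))
    staffing_corr: float = 0.95
    mean_mortality_rate: float = 0.148
    p_cert_track: float = 0.12
    p_noncert_su: float = 0.24
    count_model: str = "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_size < 2:
            raise ValueError("lattice_size must be >= 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout probability outside [0, 1)")
        if not (0.0 <= self.staffing_corr < 1.0):
            raise ValueError(
                f"infeasible staffing correlation target {self.staffing_corr}")
        for fr in self._zero_fracs():
            if not (0.0 <= fr < 1.0):
                raise ValueError(f"infeasible zero fraction target {fr}")
        if self.sigma_v2 <= 0 or self.sigma_ustar < 0:
            raise ValueError("noise scales must be positive (sigma_ustar "
                             "may be 0 for the fully-efficient case)")
        if self.count_model not in ("continuous", "poisson"):
            raise ValueError(f"unknown count model {self.count_model!r}")

    def _zero_fracs(self):
        out = []
        for z in (self.zero_frac_mor, self.zero_frac_readm):
            out.extend(z.values() if isinstance(z, dict) else [z])
        return out

    def zero_frac(self, which: str, wave: int) -> float:
        z = self.zero_frac_mor if which == "mor" else self.zero_frac_readm
        return float(z[wave]) if isinstance(z, dict) else float(z)


@dataclass
class SimTruth:
    """Everything that generated the panel (reproducible from config+seed)."""

    config: SimConfig
    beta: dict
    delta: dict
    f_struct: np.ndarray
    f_unstruct: np.ndarray
    u: np.ndarray
    v: np.ndarray
    te: np.ndarray
    eta_u: np.ndarray

    def to_json(self, path) -> None:
        d = {"config": asdict(self.config), "beta": self.beta,
             "delta": self.delta,
             "f_struct": self.f_struct.tolist(),
             "f_unstruct": self.f_unstruct.tolist(),
             "u": self.u.tolist(), "v": self.v.tolist(),
             "te": self.te.tolist(), "eta_u": self.eta_u.tolist()}
        with open(path, "w") as fh:
            json.dump(d, fh)


def _hospital_frame(cfg: SimConfig, graph: RegionGraph,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Static hospital-level traits."""
    counts = 1 + rng.poisson(max(cfg.hospitals_per_district - 1.0, 0.0),
                             size=graph.n_regions)
    rows = []
    hid = 0
    waves = list(cfg.waves)
    for d_i, district in enumerate(graph.regions):
        share = rng.dirichlet(np.ones(counts[d_i]) * 1.2)
        for kk in range(counts[d_i]):
            su = rng.random()
            if su < cfg.p_cert_track:
                track = "cert"
                # most certificates predate the panel; the rest switch on
                if len(waves) == 1 or rng.random() < 0.6:
                    adopt = waves[0]
                else:
                    adopt = waves[rng.integers(1, len(waves))]
            elif su < cfg.p_cert_track + cfg.p_noncert_su:
                track, adopt = "noncert", None
            else:
                track, adopt = "none", None
            rows.append({
                "hospital_id": f"h{hid:05d}", "district_id": district,
                "district_idx": d_i, "su_track": track, "cert_wave": adopt,
                "MSStrDis": share[kk], "NumStrHospDis": float(counts[d_i]),
                "PrivHos": float(rng.random() < 0.19),
                "NonProfHos_l": rng.random(),
                "Teach": float(rng.random() < 0.46),
                "UniHos": float(rng.random() < 0.03),
                "Spec": float(np.abs(rng.normal(1.4, 0.8))),
                "MedDepCon": float(rng.beta(6.0, 1.1)),
                "ShaI61": float(rng.beta(2.0, 18.0)),
                "ShaI64": float(rng.beta(1.5, 12.0)),
                "DiagCon": float(rng.beta(8.0, 3.1)),
                "ShaTRHOMB": float(rng.beta(1.2, 22.0)),
                "PatShaStroke": float(np.clip(np.exp(rng.normal(-4.55, 1.4)),
                                              1e-6, 1.0)),
            })
            hid += 1
    df = pd.DataFrame(rows)
    # ownership categories are exclusive
    df["NonProfHos"] = ((df["NonProfHos_l"] < 0.44) & (df["PrivHos"] == 0)).astype(float)
    df = df.drop(columns=["NonProfHos_l"])
    # district-level GP density
    gps = np.exp(rng.normal(3.9, 0.16, size=graph.n_regions))
    df["GPsPerDis"] = gps[df["district_idx"].to_numpy()]
    # staffing: bivariate lognormal hitting the correlation target
    rho = cfg.staffing_corr
    z1 = rng.standard_normal(len(df))
    z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(len(df))
    df["log_phys0"] = -0.6 + 1.6 * z1
    df["log_nurse0"] = 0.55 + 1.65 * z2
    df["log_hosbed"] = 5.5 + 0.4 * (df["log_nurse0"] - 0.55) \
        + rng.normal(0.0, 0.6, len(df))
    df["HosBed"] = np.exp(df["log_hosbed"])
    return df.drop(columns=["log_hosbed"])


def _threshold_zero(latent: np.ndarray, frac: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Mark the lowest ``frac`` share of a latent severity index as
    exact zeros (small hospitals are likelier to record none)."""
    n = len(latent)
    k = int(round(frac * n))
    if k == 0:
        return np.zeros(n, dtype=bool)
    jitter = latent + rng.normal(0.0, 1e-9, n)  # break ties reproducibly
    cut = np.partition(jitter, k - 1)[k - 1]
    return jitter <= cut


def simulate_panel(cfg: SimConfig):
    """Generate (panel, graph, truth) from the forward model.

    The panel comes back *unprepared* (raw columns only); run
    :func:`geosfa.panel.prepare_panel` to reconstruct the output and
    derived inputs, which then invert the simulation exactly up to the
    generated noise.
    """
    rng = np.random.default_rng(cfg.seed)
    graph = make_lattice_graph(cfg.lattice_size, coarse_block=cfg.coarse_block)
    hosp = _hospital_frame(cfg, graph, rng)
    waves = list(cfg.waves)

    # unbalancedness: drop a hospital-wave with the dropout probability,
    # always keeping the first wave
    rows = []
    for t_i, t in enumerate(waves):
        present = (np.ones(len(hosp), dtype=bool) if t_i == 0
                   else rng.random(len(hosp)) >= cfg.dropout)
        sub = hosp[present].copy()
        sub["year"] = t
        rows.append(sub)
    df = pd.concat(rows, ignore_index=True)
    n = len(df)

    # time-varying certification status
    cert = np.zeros(n)
    noncert = np.zeros(n)
    track = df["su_track"].to_numpy()
    cw = pd.to_numeric(df["cert_wave"], errors="coerce").fillna(np.inf).to_numpy()
    yr = df["year"].to_numpy()
    is_cert = (track == "cert") & (cw <= yr)
    cert[is_cert] = 1.0
    noncert[((track == "cert") & ~is_cert) | (track == "noncert")] = 1.0
    df["SUCert"] = cert
    df["SUnonCert"] = noncert

    # staffing with small wave-level wobble (keeps correlation high)
    lp = df["log_phys0"].to_numpy() + rng.normal(0, 0.08, n)
    ln = df["log_nurse0"].to_numpy() + rng.normal(0, 0.08, n)
    df["physicians"] = np.exp(lp)
    df["nurses"] = np.exp(ln)

    # quality inputs: latent severity ties zeros to small size
    size_idx = 0.5 * (lp + ln)
    wave_mu = {t: m for t, m in zip(waves,
                                    np.linspace(1.75, 1.50, len(waves)))}
    mor = np.zeros(n)
    readm = np.zeros(n)
    for t in waves:
        m = yr == t
        lat = size_idx[m] + rng.normal(0, 0.8, m.sum())
        if cfg.count_model == "poisson":
            lam = np.exp(wave_mu[t] + 0.7 * (size_idx[m] - size_idx.mean()))
            mor[m] = rng.poisson(lam)
            lamr = np.exp(wave_mu[t] - 0.15
                          + 0.7 * (size_idx[m] - size_idx.mean()))
            readm[m] = rng.poisson(lamr)
        else:
            z_m = _threshold_zero(lat, cfg.zero_frac(("mor"), t), rng)
            val = np.exp(rng.normal(wave_mu[t], 1.0, m.sum())
                         + 0.55 * (size_idx[m] - size_idx.mean()))
            mor[m] = np.where(z_m, 0.0, np.maximum(np.round(val, 1), 0.1))
            lat2 = size_idx[m] + rng.normal(0, 0.8, m.sum())
            z_r = _threshold_zero(lat2, cfg.zero_frac("readm", t), rng)
            val2 = np.exp(rng.normal(wave_mu[t] - 0.15, 1.0, m.sum())
                          + 0.55 * (size_idx[m] - size_idx.mean()))
            readm[m] = np.where(z_r, 0.0, np.maximum(np.round(val2, 1), 0.1))
    df["obs_mortality"] = mor
    df["obs_readmissions"] = readm

    # frontier predictor at the generating coefficients
    d_mor = (mor == 0).astype(float)
    d_readm = (readm == 0).astype(float)
    lmor = np.log(np.maximum(mor, d_mor))
    lreadm = np.log(np.maximum(readm, d_readm))
    b = cfg.beta
    eta_y = (b["const"] + b["D_mor"] * d_mor + b["D_readm"] * d_readm
             + b["log_mor_star"] * lmor + b["log_readm_star"] * lreadm
             + b["log_phys"] * lp + b["log_nurse"] * ln)
    for t in waves[1:]:
        eta_y = eta_y + b.get(f"wave_{t}", 0.0) * (yr == t)

    # inefficiency predictor: centered covariates, wave effects, spatial
    f_struct = (sample_icar(graph, cfg.tau2_struct, rng)
                if cfg.tau2_struct > 0 else np.zeros(graph.n_regions))
    f_unstruct = (rng.normal(0.0, np.sqrt(cfg.tau2_unstruct),
                             graph.n_regions)
                  if cfg.tau2_unstruct > 0 else np.zeros(graph.n_regions))
    f_unstruct = f_unstruct - f_unstruct.mean()
    didx = df["district_idx"].to_numpy()
    eta_u = f_struct[didx] + f_unstruct[didx]
    for name, dval in cfg.delta.items():
        if name.startswith("itau_"):
            eta_u = eta_u + dval * (yr == int(name[5:]))
            continue
        col = name[4:] if name.startswith("log_") else name
        vals = df[col].to_numpy(float)
        if name.startswith("log_"):
            vals = np.log(vals)
        eta_u = eta_u + dval * (vals - vals.mean())
    alpha = np.exp(eta_u)
    ustar = np.abs(rng.standard_normal(n)) * cfg.sigma_ustar
    u = ustar * alpha
    v = rng.normal(0.0, np.sqrt(cfg.sigma_v2), n)
    y = eta_y + v - u

    # QSR-style case volumes give the wave mean observed mortality rate;
    # expected mortality is then chosen so the prepared output equals y
    rate = np.clip(rng.normal(cfg.mean_mortality_rate, 0.04, n), 0.02, 0.5)
    volume = np.maximum(mor, 1.0) / rate
    df["case_volume"] = np.round(volume, 1)
    rates_by_wave = {}
    r_obs = mor / df["case_volume"].to_numpy()
    for t in waves:
        rates_by_wave[t] = float(np.mean(r_obs[yr == t]))
    rbar = np.array([rates_by_wave[t] for t in yr])
    df["exp_mortality"] = rbar * np.exp(y)

    keep = ["hospital_id", "year", "district_id", "exp_mortality",
            "obs_mortality", "obs_readmissions", "physicians", "nurses",
            "case_volume", "Spec", "MSStrDis", "NumStrHospDis",
            "PatShaStroke", "MedDepCon", "SUCert", "SUnonCert", "GPsPerDis",
            "HosBed", "PrivHos", "NonProfHos", "Teach", "UniHos", "ShaI61",
            "ShaI64", "DiagCon", "ShaTRHOMB"]
    panel = HospitalPanel(df[keep].copy(), reference_year=waves[0])
    truth = SimTruth(config=cfg, beta=dict(cfg.beta), delta=dict(cfg.delta),
                     f_struct=f_struct, f_unstruct=f_unstruct, u=u, v=v,
                     te=np.exp(-u), eta_u=eta_u)
    return panel, graph, truth


def emit(cfg: SimConfig, outdir) -> None:
    """Write the standard file set: panel CSV, edge list, truth JSON."""
    import os

    from .panel import write_panel
    panel, graph, truth = simulate_panel(cfg)
    os.makedirs(outdir, exist_ok=True)
    write_panel(panel, os.path.join(outdir, "panel.csv"))
    with open(os.path.join(outdir, "edges.txt"), "w") as fh:
        for a, b in graph.edges:
            fh.write(f"{graph.regions[a]} {graph.regions[b]}\n")
    truth.to_json(os.path.join(outdir, "truth.json"))
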