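"""Hospital-year panel data model and variable construction.

The observation unit is a hospital-year.  The frontier's output is
risk-adjusted patient volume: expected 30-day stroke deaths (from a
patient-level risk adjustment, taken as given) scaled up by the inverse
of the wave-average observed mortality rate.  Quality inputs (observed
deaths, readmissions) contain a substantial fraction of exact zeros,
handled either by the zero-input dummy device (indicator plus
floor-at-one, so the log is well defined) or by adding 0.5 before the
log transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: inefficiency determinants on their raw (file) scale
COVARIATES = [
    "Spec", "MSStrDis", "NumStrHospDis", "PatShaStroke", "MedDepCon",
    "SUCert", "SUnonCert", "GPsPerDis", "HosBed", "PrivHos", "NonProfHos",
    "Teach", "UniHos", "ShaI61", "ShaI64", "DiagCon", "ShaTRHOMB",
]

#: covariates entering the inefficiency predictor on the log scale
LOG_COVARIATES = ["PatShaStroke", "GPsPerDis", "HosBed"]

BINARY_COVARIATES = ["SUCert", "SUnonCert", "PrivHos", "NonProfHos",
                     "Teach", "UniHos"]

REQUIRED_COLUMNS = [
    "hospital_id", "year", "district_id", "exp_mortality", "obs_mortality",
    "obs_readmissions", "physicians", "nurses",
]

#: frontier variables that are log-transformed and then centered
FRONTIER_LOG_VARS = ["log_mor_star", "log_readm_star", "log_phys", "log_nurse"]


@dataclass
class HospitalPanel:
    """Unbalanced hospital-year panel.

    Wraps a DataFrame with one row per (hospital, year).  Derived
    columns (``y``, zero-input dummies, starred and log inputs) are
    added by the construction operations below; ``offsets`` records
    centering offsets so raw values are exactly recoverable and
    ``wave_rates`` the wave-level mean observed mortality rates used to
    build the output.
    """

    df: pd.DataFrame
    reference_year: int | None = None
    offsets: dict = field(default_factory=dict)
    wave_rates: dict = field(default_factory=dict)
    zero_mode: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"panel is missing required columns: {missing}")
        dup = self.df.duplicated(subset=["hospital_id", "year"])
        if dup.any():
            keys = self.df.loc[dup, ["hospital_id", "year"]].values.tolist()
            raise ValueError(f"duplicate (hospital_id, year) keys: {keys[:5]}")
        for col, strict in [("exp_mortality", False), ("obs_mortality", False),
                            ("obs_readmissions", False), ("physicians", True),
                            ("nurses", True)]:
            vals = self.df[col].to_numpy(dtype=float)
            bad = (vals <= 0) if strict else (vals < 0)
            if np.any(bad):
                rows = np.flatnonzero(bad)[:5].tolist()
                op = "<= 0" if strict else "< 0"
                raise ValueError(f"column {col!r} {op} at rows {rows}")
        if self.reference_year is None:
            self.reference_year = int(self.df["year"].min())
        if self.reference_year not in set(self.df["year"]):
            raise ValueError(f"reference year {self.reference_year} not in panel")

    @property
    def waves(self) -> list[int]:
        return sorted(int(t) for t in self.df["year"].unique())

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_hospitals(self) -> int:
        return self.df["hospital_id"].nunique()

    def copy(self) -> "HospitalPanel":
        # bypass __post_init__: derived panels (e.g. centered columns)
        # need not satisfy the raw-data validation again
        new = object.__new__(HospitalPanel)
        new.df = self.df.copy()
        new.reference_year = self.reference_year
        new.offsets = dict(self.offsets)
        new.wave_rates = dict(self.wave_rates)
        new.zero_mode = self.zero_mode
        return new

    def frontier_rows(self) -> pd.DataFrame:
        """Rows usable for frontier fitting (exp_mortality > 0)."""
        if "frontier_ok" in self.df.columns:
            return self.df[self.df["frontier_ok"]]
        return self.df


def build_risk_adjusted_output(panel: HospitalPanel,
                               wave_rates: dict | None = None,
                               volume_weighted: bool = False) -> HospitalPanel:
    """Fill the log risk-adjusted patient-volume output ``y``.

    ``y_it = log(exp_mortality_it / rbar_t)`` where ``rbar_t`` is the
    wave-t mean observed mortality rate across hospitals — unweighted by
    default (simple average across hospitals), volume-weighted behind a
    flag.  Rates are computed from a ``case_volume`` column when
    present, otherwise they must be supplied per wave.

    Records with ``exp_mortality == 0`` have no defined log output; they
    are flagged (``frontier_ok = False``) and excluded from fitting with
    a logged warning.
    """
    panel = panel.copy()
    df = panel.df
    rates: dict[int, float] = {}
    for t in panel.waves:
        if wave_rates is not None and t in wave_rates:
            rates[t] = float(wave_rates[t])
        elif "case_volume" in df.columns:
            sub = df[df["year"] == t]
            r = sub["obs_mortality"].to_numpy(float) / sub["case_volume"].to_numpy(float)
            if volume_weighted:
                w = sub["case_volume"].to_numpy(float)
                rates[t] = float(np.sum(w * r) / np.sum(w))
            else:
                rates[t] = float(np.mean(r))
        else:
            raise ValueError(
                f"no wave rate for wave {t}: supply wave_rates or a "
                "case_volume column")
        if not np.isfinite(rates[t]) or rates[t] <= 0:
            raise ValueError(f"wave {t}: nonpositive or undefined mean rate")
    rbar = df["year"].map(rates).to_numpy(float)
    expm = df["exp_mortality"].to_numpy(float)
    ok = expm > 0
    if not ok.all():
        logger.warning("%d records with exp_mortality == 0 excluded from "
                       "frontier fitting", int((~ok).sum()))
    y = np.full(len(df), np.nan)
    y[ok] = np.log(expm[ok] / rbar[ok])
    df["y"] = y
    df["frontier_ok"] = ok
    panel.wave_rates = rates
    return panel


def encode_zero_inputs(panel: HospitalPanel, mode: str = "dummy") -> HospitalPanel:
    """Encode exact-zero quality inputs so their logs exist.

    mode="dummy": indicator D=1 and floored input k* = max(k, D) when
    k = 0 (so log k* = 0), else D=0, k* = k.  mode="rescale_half":
    k* = k + 0.5 for every record and the D columns are all zero (and
    dropped from the design downstream).
    """
    if mode not in ("dummy", "rescale_half"):
        raise ValueError(f"unknown zero-input mode {mode!r}")
    panel = panel.copy()
    df = panel.df
    for raw, dcol, star in [("obs_mortality", "D_mor", "mor_star"),
                            ("obs_readmissions", "D_readm", "readm_star")]:
        k = df[raw].to_numpy(float)
        if np.any(k < 0):
            raise ValueError(f"negative counts in {raw}")
        if mode == "dummy":
            d = (k == 0).astype(float)
            df[dcol] = d
            df[star] = np.maximum(k, d)
        else:
            df[dcol] = 0.0
            df[star] = k + 0.5
    df["log_mor_star"] = np.log(df["mor_star"])
    df["log_readm_star"] = np.log(df["readm_star"])
    df["log_phys"] = np.log(df["physicians"])
    df["log_nurse"] = np.log(df["nurses"])
    panel.zero_mode = mode
    return panel


def center_variables(panel: HospitalPanel, which: list[str]) -> HospitalPanel:
    """Center named variables by their grand sample mean, storing offsets.

    The frontier intercept is then the frontier value at sample means.
    Centering a binary dummy is allowed but flagged with a warning.
    """
    panel = panel.copy()
    df = panel.df
    for name in which:
        if name not in df.columns:
            raise KeyError(f"cannot center unknown variable {name!r}")
        vals = df[name].to_numpy(float)
        uniq = np.unique(vals[np.isfinite(vals)])
        if set(uniq.tolist()) <= {0.0, 1.0}:
            logger.warning("centering binary dummy %r", name)
        mean = float(np.nanmean(vals))
        df[name] = vals - mean
        panel.offsets[name] = panel.offsets.get(name, 0.0) + mean
    return panel


def uncenter_variables(panel: HospitalPanel,
                       which: list[str] | None = None) -> HospitalPanel:
    """Exactly undo :func:`center_variables` using the stored offsets."""
    panel = panel.copy()
    for name in (which if which is not None else list(panel.offsets)):
        off = panel.offsets.pop(name)
        panel.df[name] = panel.df[name].to_numpy(float) + off
    return panel


def prepare_panel(panel: HospitalPanel,
                  wave_rates: dict | None = None,
                  zero_mode: str = "dummy",
                  center: bool = True,
                  volume_weighted: bool = False) -> HospitalPanel:
    """Standard preparation: output, zero encoding, logs, centering.

    The output and the four log input variables are centered (the
    inefficiency covariates are centered later, inside the design
    builder, where their offsets are absorbed by the inefficiency
    scale).
    """
    panel = build_risk_adjusted_output(panel, wave_rates=wave_rates,
                                       volume_weighted=volume_weighted)
    panel = encode_zero_inputs(panel, mode=zero_mode)
    if center:
        panel = center_variables(panel, ["y"] + FRONTIER_LOG_VARS)
    return panel


# ---------------------------------------------------------------------------
# plain-text IO

def read_panel(path, schema: dict | str | None = None, sep: str | None = None,
               na_token: str = "", reference_year: int | None = None,
               graph=None) -> HospitalPanel:
    """Read a delimited-text hospital panel (header row, one row per
    hospital-year).

    ``schema`` maps arbitrary source headers to canonical column names;
    it may be a dict or the path of a JSON file.  With ``graph`` given,
    district ids are validated against it.
    """
    if isinstance(schema, str):
        with open(schema) as fh:
            schema = json.load(fh)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     na_values=[na_token] if na_token else None)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = [c for c in df.columns if c not in ("hospital_id", "district_id")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(
                f"{path}: non-numeric values in column {col!r} at file "
                f"lines {rows}")
    n0 = len(df)
    df = df.dropna(subset=[c for c in REQUIRED_COLUMNS + COVARIATES
                           if c in df.columns])
    if len(df) < n0:
        logger.warning("dropped %d rows with missing required fields", n0 - len(df))
    df = df.reset_index(drop=True)
    panel = HospitalPanel(df, reference_year=reference_year)
    if graph is not None:
        unknown = set(df["district_id"]) - set(graph.regions)
        if unknown:
            raise ValueError(f"{path}: district ids not in region graph: "
                             f"{sorted(unknown)[:5]}")
    return panel


def write_panel(panel: HospitalPanel, path, sep: str = ",") -> None:
    """Write the panel as delimited text (round-trips with read_panel)."""
    panel.df.to_csv(path, sep=sep, index=False)
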