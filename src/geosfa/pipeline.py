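"""Study orchestration: the model-selection suite, the matching +
difference-in-differences certification analysis, and report rendering.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from .effects import EffectsReport
from .mcmc import PosteriorDraws, compute_dic, compute_waic, pointwise_loglik, run_mcmc
from .model import ModelDesign, ModelSpec, build_design
from .panel import HospitalPanel
from .regions import RegionGraph, export_choropleth_geojson

logger = logging.getLogger(__name__)


def run_model_suite(panel: HospitalPanel, graph: RegionGraph,
                    specs: list[ModelSpec], which_loglik: str = "marginal",
                    keep_draws: bool = False):
    """Fit each spec on the same prepared panel and tabulate DIC, pD,
    WAIC and p_waic; the minimum-DIC model is flagged.

    All fits must share the observation set (enforced by a data
    fingerprint) and the same likelihood notion, otherwise the criteria
    are not comparable.  A failing preset is recorded and the suite
    continues.
    """
    rows = []
    fits = {}
    fingerprint = None
    for spec in specs:
        try:
            design = build_design(panel, graph, spec)
            if fingerprint is None:
                fingerprint = design.data_fingerprint()
            elif design.data_fingerprint() != fingerprint:
                raise ValueError("observation set differs from the first "
                                 "preset; criteria not comparable")
            draws = run_mcmc(design)
            ll = pointwise_loglik(draws, design, which_loglik)
            dic, pd_ = compute_dic(draws, design, which_loglik, ll_matrix=ll)
            waic, p_waic = compute_waic(draws, design, which_loglik,
                                        ll_matrix=ll)
            rows.append({"model": spec.name, "DIC": dic, "pD": pd_,
                         "WAIC": waic, "p_waic": p_waic, "error": ""})
            if keep_draws:
                fits[spec.name] = (draws, design)
        except Exception as exc:  # suite continues past a failed preset
            logger.error("preset %s failed: %s", spec.name, exc)
            rows.append({"model": spec.name, "DIC": np.nan, "pD": np.nan,
                         "WAIC": np.nan, "p_waic": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows).set_index("model")
    ok = table["DIC"].dropna()
    table["best_dic"] = False
    if len(ok):
        table.loc[ok.idxmin(), "best_dic"] = True
    table.attrs["data_fingerprint"] = fingerprint
    table.attrs["which_loglik"] = which_loglik
    return (table, fits) if keep_draws else table


# ---------------------------------------------------------------------------
# matching + difference-in-differences

def _baseline_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Earliest observed wave per hospital."""
    return (df.sort_values("year").groupby("hospital_id", as_index=False)
            .first())


def match_switchers(panel: HospitalPanel, covariates: list[str] | None = None,
                    caliper: float | None = None, seed: int = 0):
    """Propensity-score 1:1 nearest-neighbour matching of hospitals that
    become certified during the panel to never-certified hospitals.

    Propensities come from a logistic model of ever-switching on
    baseline (first-wave) characteristics; matching is without
    replacement, greedy in a seeded-shuffle order with hospital-id
    tie-breaks.  Returns (pairs DataFrame, switcher ids, control ids).
    """
    import statsmodels.api as sm

    df = panel.df
    first_cert = df[df["SUCert"] > 0].groupby("hospital_id")["year"].min()
    ever = df.groupby("hospital_id")["SUCert"].max()
    base_year = df.groupby("hospital_id")["year"].min()
    # switchers: certified at some point but not in their first observed wave
    switchers = [h for h in first_cert.index
                 if first_cert[h] > base_year[h]]
    never = ever[ever == 0].index.tolist()
    if not switchers:
        raise ValueError("no hospitals switch certification status during "
                         "the panel; matching + DID needs switchers")
    base = _baseline_rows(df)
    base = base[base["hospital_id"].isin(switchers + never)].copy()
    base["treated"] = base["hospital_id"].isin(switchers).astype(float)

    if covariates is None:
        covariates = ["Spec", "MSStrDis", "NumStrHospDis", "MedDepCon",
                      "SUnonCert", "PrivHos", "NonProfHos", "Teach", "UniHos",
                      "ShaI61", "ShaI64", "DiagCon", "ShaTRHOMB"]
        covariates = [c for c in covariates if c in base.columns]
        for raw in ("PatShaStroke", "HosBed", "GPsPerDis"):
            if raw in base.columns:
                base[f"log_{raw}"] = np.log(base[raw])
                covariates.append(f"log_{raw}")
    Zb = base[covariates].to_numpy(float)
    keep = Zb.std(axis=0) > 1e-12  # constant columns carry no information
    X = sm.add_constant(Zb[:, keep])
    import warnings as _warnings
    model = sm.Logit(base["treated"].to_numpy(), X)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            if not (np.all(np.isfinite(fit.params))
                    and fit.mle_retvals.get("converged", True)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError,
                sm.tools.sm_exceptions.PerfectSeparationError):
            # small samples can separate perfectly; penalized fallback
            fit = model.fit_regularized(alpha=1e-3, disp=0, maxiter=500)
    base["pscore"] = fit.predict(X)

    treated = base[base["treated"] == 1].copy()
    controls = base[base["treated"] == 0].copy()
    rng = np.random.default_rng(seed)
    treated = treated.sort_values("hospital_id").reset_index(drop=True)
    treated = treated.iloc[rng.permutation(len(treated))]
    pairs, unmatched = [], []
    avail = controls.set_index("hospital_id")["pscore"].to_dict()
    for _, row in treated.iterrows():
        if not avail:
            unmatched.append(row["hospital_id"])
            continue
        ids = sorted(avail)  # deterministic tie-break by id
        dist = np.abs(np.array([avail[i] for i in ids]) - row["pscore"])
        j = int(np.argmin(dist))
        if caliper is not None and dist[j] > caliper:
            unmatched.append(row["hospital_id"])
            continue
        pairs.append({"switcher": row["hospital_id"], "control": ids[j],
                      "ps_switcher": row["pscore"], "ps_control": avail[ids[j]],
                      "distance": float(dist[j])})
        del avail[ids[j]]
    if unmatched:
        raise ValueError(f"no propensity-score support for switchers: "
                         f"{sorted(unmatched)}")
    return pd.DataFrame(pairs), switchers, [p["control"] for p in pairs]


def run_matching_did(panel: HospitalPanel, graph: RegionGraph,
                     base_spec: ModelSpec, caliper: float | None = None,
                     seed: int = 0, covariates: list[str] | None = None):
    """Matching + DID certification analysis on the inefficiency term.

    The frontier is refit on *all* observations (a common production
    frontier); the certification effect is decomposed into the matched
    pairs' interaction D_m x SUCert (the DID effect) and the
    non-matched hospitals' (1 - D_m) x SUCert, with the matched-pair
    indicator D_m itself also included.  Returns (draws, design,
    summary-of-interactions, pairs).
    """
    pairs, switchers, controls = match_switchers(panel, covariates=covariates,
                                                 caliper=caliper, seed=seed)
    matched = set(pairs["switcher"]) | set(pairs["control"])
    panel = panel.copy()
    df = panel.df
    dm = df["hospital_id"].isin(matched).astype(float)
    df["Dm"] = dm
    df["Dm_SUCert"] = dm * df["SUCert"]
    df["nonDm_SUCert"] = (1.0 - dm) * df["SUCert"]
    cov = [c for c in base_spec.ineff_covariates if c != "SUCert"]
    spec = base_spec.with_updates(
        name=base_spec.name + "_did",
        ineff_covariates=cov + ["Dm", "Dm_SUCert", "nonDm_SUCert"])
    design = build_design(panel, graph, spec)
    draws = run_mcmc(design)
    summ = draws.summary("delta").loc[["Dm", "Dm_SUCert", "nonDm_SUCert"]]
    return draws, design, summ, pairs


# ---------------------------------------------------------------------------
# reporting

def render_reports(fits: dict, outdir, effects: EffectsReport | None = None,
                   graph: RegionGraph | None = None,
                   comparison: pd.DataFrame | None = None,
                   log_lines: list[str] | None = None) -> list[str]:
    """Write coefficient tables (with credibility-interval stars),
    optional model-comparison table, spatial-effect choropleths, slack
    density plots and a machine-readable JSON of all numbers.

    ``fits`` maps a model name to (PosteriorDraws, ModelDesign).
    Reruns overwrite deterministically.  Returns the written paths.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    results: dict = {}
    for name, (draws, design) in fits.items():
        for which in ("beta", "delta"):
            tab = draws.summary(which)
            p = os.path.join(outdir, f"{name}_{which}.csv")
            tab.to_csv(p)
            written.append(p)
            results.setdefault(name, {})[which] = {
                r: {"mean": float(row["mean"]), "sd": float(row["sd"])}
                for r, row in tab.iterrows()}
        # spatial choropleth
        if graph is not None and draws.f_struct is not None \
                and design.struct_graph is not None \
                and design.struct_graph.n_regions == graph.n_regions:
            vals = {"f_struct": draws.f_struct.mean(axis=0)}
            if draws.f_unstruct is not None and \
                    design.unstruct_graph is not None and \
                    design.unstruct_graph.n_regions == graph.n_regions:
                vals["f_unstruct"] = draws.f_unstruct.mean(axis=0)
                vals["f_composite"] = vals["f_struct"] + vals["f_unstruct"]
            p = os.path.join(outdir, f"{name}_spatial.geojson")
            export_choropleth_geojson(graph, vals, p)
            written.append(p)
        elif graph is None:
            logger.info("no geometry/graph supplied; skipping maps")
    if comparison is not None:
        p = os.path.join(outdir, "model_comparison.csv")
        comparison.to_csv(p)
        written.append(p)
        results["comparison"] = json.loads(
            comparison.drop(columns=["error"], errors="ignore").to_json())
    if effects is not None:
        results["effects"] = {
            "te_overall": float(effects.te_overall),
            "gamma": float(effects.gamma),
            "marginal_te_x100": {
                k: float(v) for k, v in
                effects.marginal_te["marginal_te_x100"].items()},
        }
        if effects.slack_average:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, axes = plt.subplots(1, len(effects.slack_average),
                                     figsize=(4 * len(effects.slack_average), 3))
            axes = np.atleast_1d(axes)
            for ax, (k, v) in zip(axes, effects.slack_average.items()):
                ax.hist(np.asarray(v), bins=40, density=True)
                ax.set_title(f"slack: {k}")
            fig.tight_layout()
            p = os.path.join(outdir, "slack_densities.png")
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
            results["effects"]["slack_posterior_mean"] = {
                k: float(np.mean(v)) for k, v in effects.slack_average.items()}
    p = os.path.join(outdir, "results.json")
    with open(p, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    written.append(p)
    p = os.path.join(outdir, "run_log.txt")
    with open(p, "w") as fh:
        for name, (draws, _) in fits.items():
            fh.write(f"{name}: seed={draws.meta.get('seed')} "
                     f"iterations={draws.meta.get('iterations')} "
                     f"fingerprint={draws.meta.get('data_fingerprint')}\n")
        for line in log_lines or []:
            fh.write(line + "\n")
    written.append(p)
    return written
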