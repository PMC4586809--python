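"""Model comparison, cluster detection and convergence checks.

DIC follows the classical construction: Dbar is the posterior mean
deviance, the plug-in deviance is evaluated at the posterior mean of each
cell's linear predictor (the canonical scale for the log link), and
pD = Dbar - Dhat estimates the effective number of parameters;
DIC = Dbar + pD, lower is better.

Exceedence probabilities Pr(quantity > theta*) turn posterior draws into
a Bayesian cluster-detection summary: a high posterior probability that
the focal-group relative risk exceeds a critical level (1.25 by default)
marks an area as part of a disparity cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph import AdjacencyGraph
from .mcmc import FitResult, McmcConfig, fit_design, summarize
from .models import CellDesign, ModelError, ModelSpec, poisson_loglik

# presentation bands for exceedence exports; the top band flags clusters
EXCEEDENCE_BANDS = ((0.0, 0.8, "low"), (0.8, 0.95, "suggestive"), (0.95, 1.01, "significant"))


@dataclass
class DicReport:
    """Deviance information criterion components for one fit."""

    dbar: float
    dhat: float
    pd: float
    dic: float
    negative_pd: bool

    def as_row(self) -> dict:
        return {"dbar": self.dbar, "dhat": self.dhat, "pd": self.pd, "dic": self.dic}


@dataclass
class ExceedenceMap:
    """Per-area (or per-cell) posterior exceedence probabilities."""

    threshold: float
    level: str
    data: pd.DataFrame  # column 'probability' plus identifying columns


def dic(fit: FitResult) -> DicReport:
    """DIC from retained draws: Dbar + pD with a linear-predictor plug-in."""
    if fit.n_draws == 0:
        raise ModelError("fit has no retained draws")
    dbar = float(fit.deviance.mean())
    if "eta" not in fit.draws:
        raise ModelError("DIC needs cell draws; fit with store_cell_draws=True")
    eta_bar = fit.draws["eta"].astype(np.float64).mean(axis=0)
    mu_hat = fit.design.e * np.exp(eta_bar)
    dhat = -2.0 * float(np.sum(poisson_loglik(fit.design.y, mu_hat)))
    p_d = dbar - dhat
    return DicReport(dbar=dbar, dhat=dhat, pd=p_d, dic=dbar + p_d, negative_pd=p_d < 0)


def exceedence(
    fit: FitResult,
    threshold: float | None = None,
    level: str = "area-disparity",
) -> ExceedenceMap:
    """Fraction of draws in which a relative-risk quantity exceeds theta*.

    ``area-disparity`` applies the threshold to the disparity relative risk
    e^(delta0 + d_i) per area; ``cell`` applies it to the fitted relative
    risk theta of every (area, year, group) cell.
    """
    thr = fit.spec.exceedence_threshold if threshold is None else float(threshold)
    if thr <= 0:
        raise ModelError("exceedence threshold must be positive")
    d = fit.design
    warnings = []
    if level == "area-disparity":
        delta = fit.draws["delta0"][:, None]
        if fit.spec.has_varying_disparity:
            delta = delta + fit.draws["delta_area"].astype(np.float64)
        else:
            delta = np.repeat(delta, d.n_areas, axis=1)
            warnings.append(
                "Model 1 has a single statewide disparity; the map is constant"
            )
        prob = (np.exp(delta) > thr).mean(axis=0)
        df = pd.DataFrame({"cancer": d.cancer, "area_id": d.areas, "probability": prob})
    elif level == "cell":
        if "eta" not in fit.draws:
            raise ModelError("cell-level exceedence needs stored cell draws")
        theta = np.exp(fit.draws["eta"].astype(np.float64))
        prob = (theta > thr).mean(axis=0)
        df = pd.DataFrame(
            {
                "cancer": d.cancer,
                "area_id": np.asarray(d.areas, dtype=object)[d.area_idx],
                "year": np.asarray(d.years)[d.year_idx],
                "group": d.eth,
                "probability": prob,
            }
        )
    else:
        raise ModelError(f"unknown exceedence level {level!r}")
    df["band"] = [_band(p) for p in df["probability"]]
    out = ExceedenceMap(threshold=thr, level=level, data=df)
    for w in warnings:
        out.data.attrs.setdefault("warnings", []).append(w)
    return out


def _band(p: float) -> str:
    for lo, hi, name in EXCEEDENCE_BANDS:
        if lo <= p < hi:
            return name
    return "significant"


def exceedence_from_draws(draws: np.ndarray, threshold: float) -> float:
    """Exceedence probability of a plain draw vector (quantity > threshold)."""
    return float(np.mean(np.asarray(draws, dtype=float) > threshold))


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of the same data by DIC (ascending) with a delta column."""
    if not fits:
        raise ModelError("no fits to compare")
    prints = {f.fingerprint for f in fits}
    if len(prints) > 1:
        raise ModelError("fits were made on different data; refusing to compare")
    rows = []
    for f in fits:
        rep = dic(f)
        rows.append({"model": f.spec.model_id, **rep.as_row()})
    tab = pd.DataFrame(rows).sort_values("dic", kind="stable").reset_index(drop=True)
    tab["delta_dic"] = tab["dic"] - tab["dic"].iloc[0]
    return tab


def prior_sensitivity(
    spec: ModelSpec,
    design: CellDesign,
    graph: AdjacencyGraph,
    config: McmcConfig,
    grid_points: int = 101,
) -> pd.DataFrame:
    """Refit under Gamma vs flat precision priors and pair the tau summaries.

    Returns one row per precision parameter and prior arm with the posterior
    mean, 95% interval, an interval-overlap indicator, and a kernel-density
    grid (JSON-encoded) for marginal-density plots.
    """
    arms = {}
    for prior in ("gamma", "flat"):
        d = spec.to_dict()
        d["precision_prior"] = prior
        arms[prior] = fit_design(ModelSpec.from_dict(d), design, graph, config)
    tau_names = [k for k in arms["gamma"].draws if k.startswith("tau_")]
    if spec.model_id == 1:
        tau_names = [k for k in tau_names if k != "tau_delta"]
    rows = []
    for name in tau_names:
        summ = {p: summarize(arms[p].draws[name]) for p in arms}
        (m_g, lo_g, hi_g), (m_f, lo_f, hi_f) = summ["gamma"], summ["flat"]
        overlap = (lo_g <= hi_f) and (lo_f <= hi_g)
        for prior, (m, lo, hi) in summ.items():
            draws = arms[prior].draws[name]
            grid = np.linspace(np.min(draws) * 0.9, np.max(draws) * 1.1, grid_points)
            dens = stats.gaussian_kde(draws)(grid)
            rows.append(
                {
                    "parameter": name,
                    "prior": prior,
                    "mean": m,
                    "lo95": lo,
                    "hi95": hi,
                    "intervals_overlap": overlap,
                    "density_grid": ";".join(f"{x:.6g}" for x in grid),
                    "density_value": ";".join(f"{x:.6g}" for x in dens),
                }
            )
    return pd.DataFrame(rows)


def convergence(fit: FitResult, rhat_warn: float = 1.05) -> pd.DataFrame:
    """Split-Rhat and effective sample size per scalar parameter.

    Uses the rank-normalized split-Rhat of ArviZ.  With a single chain the
    chain is split in half.  Constant chains yield NaN and a warning flag.
    """
    import arviz as az

    n_chains = fit.config.chains
    L = fit.chain_length
    rows = []
    scalars = {}
    for name in ("alpha", "delta0", "tau_u", "tau_v", "tau_t", "tau_psi", "tau_delta"):
        if name in fit.draws:
            scalars[name] = fit.draws[name]
    for k in range(fit.draws["beta"].shape[1]):
        scalars[f"beta[{k}]"] = fit.draws["beta"][:, k]
    for name, arr in scalars.items():
        if n_chains * L < 4:
            raise ModelError("too few draws for convergence diagnostics")
        mat = np.asarray(arr, dtype=float).reshape(n_chains, L)
        if np.allclose(mat.std(), 0):
            rows.append({"parameter": name, "rhat": np.nan, "ess": np.nan, "flag": "constant"})
            continue
        data = az.convert_to_dataset(mat)
        r = float(az.rhat(data)["x"].values)
        e = float(az.ess(data)["x"].values)
        rows.append(
            {
                "parameter": name,
                "rhat": r,
                "ess": e,
                "flag": "high-rhat" if r > rhat_warn else "",
            }
        )
    return pd.DataFrame(rows)
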