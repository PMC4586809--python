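"""Replicate validation studies run on synthetic panels.

Each function generates data from the synthetic-truth model, runs the
fitting machinery, and measures how well a known quantity is recovered.
They are used both by the test suite and by the reproduction script.
Problem sizes default to settings that keep a full study in the
minutes range on one core; each docstring states the study design.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats
from scipy.special import digamma

from .diagnostics import dic, exceedence_from_draws, prior_sensitivity
from .mcmc import McmcConfig, fit_model, summarize
from .models import ModelSpec, build_design
from .simulate import GenConfig, simulate_dataset


def enumerate_connected_graphs(max_nodes: int = 5):
    """Every connected labelled graph on 2..max_nodes nodes."""
    import itertools

    from .graph import AdjacencyGraph

    for n in range(2, max_nodes + 1):
        nodes = [f"v{i}" for i in range(n)]
        pairs = list(itertools.combinations(range(n), 2))
        for bits in itertools.product([0, 1], repeat=len(pairs)):
            nb = {v: set() for v in nodes}
            for (i, j), b in zip(pairs, bits):
                if b:
                    nb[nodes[i]].add(nodes[j])
                    nb[nodes[j]].add(nodes[i])
            g = AdjacencyGraph(nodes, nb)
            if g.n_components() == 1:
                yield g


def icar_oracle_deviation(seed: int = 0, max_nodes: int = 5,
                          n_vectors: int = 100) -> dict:
    """ICAR log density vs the degenerate-Gaussian quadratic form.

    On every connected graph with up to ``max_nodes`` nodes, the pairwise
    difference density must equal -(tau/2) u' (D - W) u up to an additive
    constant; reports the maximum absolute deviation after removing the
    per-graph mean offset.
    """
    from .models import icar_logdensity

    rng = np.random.default_rng([seed, 303])
    worst = 0.0
    n_graphs = 0
    for g in enumerate_connected_graphs(max_nodes):
        n_graphs += 1
        L = g.laplacian()
        tau = float(rng.uniform(0.2, 5.0))
        U = rng.standard_normal((n_vectors, g.n_areas))
        ours = np.array([icar_logdensity(u, tau, g) for u in U])
        oracle = -0.5 * tau * np.einsum("ki,ij,kj->k", U, L, U)
        gap = ours - oracle
        worst = max(worst, float(np.max(np.abs(gap - gap.mean()))))
    return {"max_abs_deviation": worst, "n_graphs": n_graphs,
            "n_vectors": n_vectors}


def conjugate_limit_check(seed: int = 0, n_cells: int = 20,
                          iterations: int = 3000, burnin: int = 500) -> dict:
    """Intercept-only fit vs the closed-form log-Gamma posterior.

    With every random-effect block switched off and a flat intercept
    prior, exp(alpha) | y is exactly Gamma(sum y, sum e), so alpha has
    posterior mean digamma(sum y) - log(sum e).  Returns the MCMC mean,
    the analytic mean, and the discrepancy in Monte-Carlo standard errors.
    """
    import pandas as pd

    from .panel import ArealPanel
    from .standardize import ExpectedCounts
    from .graph import AdjacencyGraph

    rng = np.random.default_rng([seed, 101])
    e = rng.uniform(2.0, 8.0, n_cells)
    y = rng.poisson(e)
    df = pd.DataFrame(
        {
            "cancer": "toy",
            "area_id": [f"a{i:02d}" for i in range(n_cells)],
            "year": 2000,
            "group": 0,
            "count": y,
            "population": 1000,
        }
    )
    panel = ArealPanel(df)
    expected = ExpectedCounts(
        values=pd.Series(e, index=panel.data.index),
        rates=pd.DataFrame({"cancer": ["toy"], "group": [0], "rate": [1e-3]}),
    )
    graph = AdjacencyGraph(panel.areas(), {a: set() for a in panel.areas()})
    spec = ModelSpec(
        model_id=1,
        include_covariates=False,
        include_spatial=False,
        include_heterogeneity=False,
        include_temporal=False,
        include_interaction=False,
    )
    cfg = McmcConfig(chains=1, iterations=iterations, burnin=burnin, thinning=1,
                     seed=seed, store_cell_draws=False)
    fit = fit_model(spec, panel, expected, graph, cfg)
    draws = fit.draws["alpha"]
    analytic = float(digamma(y.sum()) - np.log(e.sum()))
    mc_se = float(draws.std() / np.sqrt(len(draws)))  # draws are iid Gibbs
    return {
        "mcmc_mean": float(draws.mean()),
        "analytic_mean": analytic,
        "mc_se": mc_se,
        "z": float((draws.mean() - analytic) / mc_se),
    }


def _replicate_fits(config: GenConfig, spec: ModelSpec, mcmc: McmcConfig,
                    n_reps: int, seed: int):
    for rep in range(n_reps):
        panel, expected, graph, truth = simulate_dataset(config, seed=seed * 1000 + rep)
        cfg = replace(mcmc, seed=(seed * 1000 + rep) % (2**31 - 1))
        yield truth, fit_model(spec, panel, expected, graph, cfg)


def delta0_recovery(seed: int = 0, n_reps: int = 20, config: GenConfig | None = None,
                    iterations: int = 3000, burnin: int = 1500, thinning: int = 3) -> dict:
    """Recovery of the statewide disparity delta0 over replicate panels.

    Simulates ``n_reps`` panels at the configured dimensions (defaults:
    the full 254 areas x 9 years x 2 groups), fits Model 3, and reports
    the fraction of replicates whose posterior mean lies within +/-0.05
    of the generating value.
    """
    config = config or GenConfig()
    mcmc = McmcConfig(chains=1, iterations=iterations, burnin=burnin,
                      thinning=thinning, seed=0, store_cell_draws=False)
    spec = ModelSpec(model_id=config.model_id)
    errs = []
    for truth, fit in _replicate_fits(config, spec, mcmc, n_reps, seed):
        errs.append(float(fit.draws["delta0"].mean() - config.delta0))
    errs = np.asarray(errs)
    return {
        "n_reps": n_reps,
        "fraction_within_005": float(np.mean(np.abs(errs) < 0.05)),
        "mean_abs_error": float(np.mean(np.abs(errs))),
        "errors": errs.tolist(),
    }


def delta0_coverage(seed: int = 0, n_reps: int = 50, n_areas: int = 100,
                    n_years: int = 5, iterations: int = 3000, burnin: int = 1500,
                    thinning: int = 3) -> dict:
    """Frequentist coverage of the 95% interval for delta0.

    Reduced-size replicates (default 100 areas x 5 years); reports the
    fraction of replicates whose equal-tailed 95% credible interval
    contains the generating delta0.
    """
    config = GenConfig(n_areas=n_areas, n_years=n_years)
    mcmc = McmcConfig(chains=1, iterations=iterations, burnin=burnin,
                      thinning=thinning, seed=0, store_cell_draws=False)
    spec = ModelSpec(model_id=3)
    hits = []
    for truth, fit in _replicate_fits(config, spec, mcmc, n_reps, seed):
        _, lo, hi = summarize(fit.draws["delta0"])
        hits.append(lo <= config.delta0 <= hi)
    return {"n_reps": n_reps, "coverage": float(np.mean(hits))}


def dic_selection(seed: int = 0, n_reps: int = 20, n_areas: int = 150,
                  n_years: int = 6, iterations: int = 2200, burnin: int = 1000,
                  thinning: int = 2) -> dict:
    """DIC model choice when the truth has spatially varying disparities.

    Data are generated from Model 3 with pronounced slope variation
    (tau_delta ~ 16); Models 1 and 3 are both fit and compared.  Reports
    the fraction of replicates in which DIC prefers Model 3.
    """
    config = GenConfig(n_areas=n_areas, n_years=n_years, model_id=3)
    mcmc = McmcConfig(chains=1, iterations=iterations, burnin=burnin,
                      thinning=thinning, seed=0)
    wins = 0
    margins = []
    for rep in range(n_reps):
        panel, expected, graph, truth = simulate_dataset(config, seed=seed * 1000 + rep)
        cfg = replace(mcmc, seed=(seed * 1000 + rep) % (2**31 - 1))
        fits = {
            m: fit_model(ModelSpec(model_id=m), panel, expected, graph, cfg)
            for m in (1, 3)
        }
        d1, d3 = dic(fits[1]).dic, dic(fits[3]).dic
        wins += d3 < d1
        margins.append(d1 - d3)
    return {
        "n_reps": n_reps,
        "fraction_model3_preferred": wins / n_reps,
        "mean_dic_margin": float(np.mean(margins)),
    }


def exceedence_calibration(seed: int = 0, n_draws: int = 100_000,
                           threshold: float = 1.25) -> dict:
    """Exceedence probability of lognormal risk draws vs the closed form.

    With log theta ~ N(0, 1), Pr(theta > theta*) = 1 - Phi(ln theta*);
    at theta* = 1.25 that is about 0.4117.
    """
    rng = np.random.default_rng([seed, 202])
    draws = np.exp(rng.standard_normal(n_draws))
    est = exceedence_from_draws(draws, threshold)
    exact = float(1.0 - stats.norm.cdf(np.log(threshold)))
    return {"estimate": est, "exact": exact, "abs_error": abs(est - exact)}


def sensitivity_overlap(seed: int = 0, n_areas: int = 254, n_years: int = 9,
                        iterations: int = 6000, burnin: int = 3000,
                        thinning: int = 3) -> dict:
    """Gamma(.5,.0005) vs flat precision priors on one synthetic Model 3 fit.

    Reports, per precision parameter, whether the two arms' 95% intervals
    overlap, plus the fraction of parameters that overlap.
    """
    config = GenConfig(n_areas=n_areas, n_years=n_years)
    panel, expected, graph, truth = simulate_dataset(config, seed=seed)
    spec = ModelSpec(model_id=3)
    design = build_design(panel, expected, config.cancer, spec)
    mcmc = McmcConfig(chains=1, iterations=iterations, burnin=burnin,
                      thinning=thinning, seed=seed % (2**31 - 1),
                      store_cell_draws=False)
    report = prior_sensitivity(spec, design, graph, mcmc)
    per_tau = report.groupby("parameter")["intervals_overlap"].first()
    return {
        "overlap_fraction": float(per_tau.mean()),
        "per_parameter": per_tau.to_dict(),
        "report": report,
    }
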