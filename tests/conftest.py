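import numpy as np
import pandas as pd
import pytest

import arealdisp as ad


def make_panel(n_areas=4, n_years=2, cancer="digestive", seed=0, covariates=True):
    """Small complete panel with Poisson-ish counts for unit tests."""
    rng = np.random.default_rng(seed)
    areas = [f"a{i:02d}" for i in range(n_areas)]
    rows = []
    for a in areas:
        pop = int(rng.integers(5_000, 60_000))
        share = float(rng.uniform(0.1, 0.5))
        for j in range(n_years):
            for g in (0, 1):
                n = int(pop * share) if g else pop - int(pop * share)
                rows.append(
                    {
                        "cancer": cancer,
                        "area_id": a,
                        "year": 2000 + j,
                        "group": g,
                        "count": int(rng.poisson(n * 7e-4)),
                        "population": n,
                    }
                )
    cov = None
    if covariates:
        cov = pd.DataFrame(
            {
                "area_id": areas,
                "poverty": rng.uniform(0.05, 0.35, n_areas),
                "hospitals_per10k": rng.uniform(0, 2, n_areas),
                "construction": rng.uniform(0.02, 0.15, n_areas),
                "metro": rng.integers(0, 2, n_areas).astype(float),
            }
        )
    return ad.ArealPanel(pd.DataFrame(rows), cov)


def path_graph(areas):
    nb = {a: set() for a in areas}
    for a, b in zip(areas, areas[1:]):
        nb[a].add(b)
        nb[b].add(a)
    return ad.AdjacencyGraph(list(areas), nb)


@pytest.fixture(scope="session")
def small_dataset():
    """One reduced synthetic dataset shared across fitting tests."""
    cfg = ad.GenConfig(n_areas=36, n_years=4)
    panel, expected, graph, truth = ad.simulate_dataset(cfg, seed=5)
    return cfg, panel, expected, graph, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short Model 3 fit on the shared dataset."""
    cfg, panel, expected, graph, truth = small_dataset
    mcmc = ad.McmcConfig(chains=2, iterations=600, burnin=300, thinning=2, seed=7)
    return ad.fit_model(ad.ModelSpec(model_id=3), panel, expected, graph, mcmc)
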