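import math

import numpy as np
import pandas as pd
import pytest

import arealdisp as ad
from arealdisp.models import ModelError

def one_cell_fit(eta_draws):
    """A minimal FitResult over a single cell with y = 1, e = 1."""
    df = pd.DataFrame(
        {"cancer": "toy", "area_id": ["a0"], "year": [2000], "group": [0],
         "count": [1], "population": [100]}
    )
    panel = ad.ArealPanel(df)
    expected = ad.ExpectedCounts(
        values=pd.Series([1.0], index=panel.data.index),
        rates=pd.DataFrame({"cancer": ["toy"], "group": [0], "rate": [0.01]}),
    )
    design = ad.build_design(panel, expected, "toy",
                             ad.ModelSpec(model_id=1, include_covariates=False))
    eta = np.asarray(eta_draws, dtype=np.float32).reshape(-1, 1)
    dev = np.array(
        [-2.0 * float(ad.poisson_loglik(1, math.exp(x))) for x in eta[:, 0]]
    )
    n = len(dev)
    draws = {
        "alpha": eta[:, 0].astype(float),
        "delta0": np.zeros(n),
        "beta": np.zeros((n, 0)),
        "delta_area": np.zeros((n, 1), dtype=np.float32),
        "eta": eta,
    }
    cfg = ad.McmcConfig(chains=1, iterations=2 * n, burnin=n, thinning=1, seed=0)
    return ad.FitResult(
        spec=ad.ModelSpec(model_id=1, include_covariates=False),
        config=cfg, design=design, draws=draws, deviance=dev,
        acceptance={}, chain_length=n, fingerprint=design.fingerprint(),
    )


class TestDic:
    def test_degenerate_posterior_has_zero_pd(self):
        fit = one_cell_fit([0.3, 0.3, 0.3, 0.3])
        rep = ad.dic(fit)
        assert rep.pd == pytest.approx(0.0, abs=1e-6)
        assert rep.dic == pytest.approx(rep.dbar)

    def test_two_draw_hand_computation(self):
        # theta draws {1, e}: deviances {2, 2e-2}; Dbar = e;
        # plug-in at mean log theta 0.5: Dhat = 2 e^0.5 - 1
        fit = one_cell_fit([0.0, 1.0])
        rep = ad.dic(fit)
        assert rep.dbar == pytest.approx(math.e, abs=1e-6)
        assert rep.dhat == pytest.approx(2 * math.exp(0.5) - 1, abs=1e-6)
        assert rep.pd == pytest.approx(0.42084, abs=1e-4)
        assert rep.dic == pytest.approx(3.13913, abs=1e-4)

    def test_dic_identity_holds(self, small_fit):
        rep = ad.dic(small_fit)
        assert rep.dic == pytest.approx(rep.dbar + rep.pd, rel=1e-12)
        assert rep.pd > 0

    def test_pd_tracks_free_parameter_count(self):
        # fixed-effect-only model: pD should approximate the number of
        # free parameters (here 1, the intercept)
        rng = np.random.default_rng(3)
        e = rng.uniform(50, 150, 30)
        y = rng.poisson(e)
        df = pd.DataFrame(
            {"cancer": "toy", "area_id": [f"a{i:02d}" for i in range(30)],
             "year": 2000, "group": 0, "count": y, "population": 1000}
        )
        panel = ad.ArealPanel(df)
        expected = ad.ExpectedCounts(
            values=pd.Series(e, index=panel.data.index),
            rates=pd.DataFrame({"cancer": ["toy"], "group": [0], "rate": [0.1]}),
        )
        graph = ad.AdjacencyGraph(panel.areas(), {a: set() for a in panel.areas()})
        spec = ad.ModelSpec(model_id=1, include_covariates=False, include_spatial=False,
                            include_heterogeneity=False, include_temporal=False,
                            include_interaction=False)
        cfg = ad.McmcConfig(chains=1, iterations=6000, burnin=1000, thinning=1, seed=5)
        fit = ad.fit_model(spec, panel, expected, graph, cfg)
        rep = ad.dic(fit)
        assert rep.pd == pytest.approx(1.0, rel=0.2)

    def test_empty_draws_rejected(self):
        fit = one_cell_fit([0.1, 0.2])
        fit.deviance = np.empty(0)
        with pytest.raises(ModelError):
            ad.dic(fit)


class TestExceedence:
    def test_all_draws_above_threshold(self):
        assert ad.exceedence_from_draws(np.full(50, 2.0), 1.25) == 1.0

    def test_half_above(self):
        draws = np.array([1.0, 1.3, 1.5, 1.2])
        assert ad.exceedence_from_draws(draws, 1.25) == 0.5

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        draws = np.exp(rng.standard_normal(2000))
        probs = [ad.exceedence_from_draws(draws, t) for t in (0.8, 1.0, 1.25, 1.5, 2.0)]
        assert probs == sorted(probs, reverse=True)

    def test_area_level_map(self, small_fit):
        emap = ad.exceedence(small_fit, threshold=1.25)
        assert emap.level == "area-disparity"
        assert len(emap.data) == small_fit.design.n_areas
        assert emap.data["probability"].between(0, 1).all()
        assert set(emap.data["band"]) <= {"low", "suggestive", "significant"}

    def test_cell_level_map(self, small_fit):
        emap = ad.exceedence(small_fit, threshold=1.0, level="cell")
        assert len(emap.data) == small_fit.design.n_cells
        # lower threshold never lowers any probability
        higher = ad.exceedence(small_fit, threshold=1.5, level="cell")
        assert (emap.data["probability"] >= higher.data["probability"]).all()

    def test_model1_map_is_constant_with_warning(self, small_dataset):
        cfg, panel, expected, graph, truth = small_dataset
        mc = ad.McmcConfig(chains=1, iterations=200, burnin=100, thinning=1, seed=9)
        fit = ad.fit_model(ad.ModelSpec(model_id=1), panel, expected, graph, mc)
        emap = ad.exceedence(fit)
        assert emap.data["probability"].nunique() == 1
        assert emap.data.attrs.get("warnings")


class TestCompareModels:
    def test_identical_fits_have_zero_delta(self, small_fit):
        tab = ad.compare_models([small_fit, small_fit])
        assert tab["delta_dic"].tolist() == [0.0, 0.0]

    def test_ranking_invariant_to_order(self, small_dataset):
        cfg, panel, expected, graph, truth = small_dataset
        mc = ad.McmcConfig(chains=1, iterations=400, burnin=200, thinning=1, seed=2)
        f1 = ad.fit_model(ad.ModelSpec(model_id=1), panel, expected, graph, mc)
        f3 = ad.fit_model(ad.ModelSpec(model_id=3), panel, expected, graph, mc)
        t_a = ad.compare_models([f1, f3])
        t_b = ad.compare_models([f3, f1])
        assert t_a["model"].tolist() == t_b["model"].tolist()

    def test_different_data_rejected(self, small_fit):
        other = ad.simulate_dataset(ad.GenConfig(n_areas=36, n_years=4), seed=99)
        panel, expected, graph, truth = other
        mc = ad.McmcConfig(chains=1, iterations=100, burnin=50, thinning=1, seed=1)
        fit2 = ad.fit_model(ad.ModelSpec(model_id=1), panel, expected, graph, mc)
        with pytest.raises(ModelError):
            ad.compare_models([small_fit, fit2])


class TestConvergence:
    def _fake_fit(self, chains_matrix):
        arr = np.asarray(chains_matrix, dtype=float)
        n_chains, L = arr.shape
        flat = arr.reshape(-1)
        draws = {
            "alpha": flat,
            "delta0": flat.copy(),
            "tau_u": np.abs(flat) + 1,
            "tau_v": np.abs(flat) + 1,
            "tau_t": np.abs(flat) + 1,
            "tau_psi": np.abs(flat) + 1,
            "tau_delta": np.abs(flat) + 1,
            "beta": np.zeros((flat.size, 0)),
        }
        cfg = ad.McmcConfig(chains=n_chains, iterations=2 * L, burnin=L, thinning=1, seed=0)
        fit = one_cell_fit([0.0, 1.0])
        fit.config = cfg
        fit.chain_length = L
        fit.draws = draws
        return fit

    def test_identical_noise_chains_near_one(self):
        rng = np.random.default_rng(0)
        fit = self._fake_fit(rng.standard_normal((2, 1000)))
        out = ad.convergence(fit).set_index("parameter")
        assert out.loc["alpha", "rhat"] == pytest.approx(1.0, abs=0.02)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(3, 1, 1000)])
        out = ad.convergence(self._fake_fit(chains)).set_index("parameter")
        assert out.loc["alpha", "rhat"] > 1.2
        assert out.loc["alpha", "flag"] == "high-rhat"

    def test_constant_chain_reported_as_degenerate(self):
        fit = self._fake_fit(np.zeros((2, 100)))
        out = ad.convergence(fit).set_index("parameter")
        assert np.isnan(out.loc["alpha", "rhat"])
        assert out.loc["alpha", "flag"] == "constant"

    def test_real_two_chain_fit(self, small_fit):
        # a deliberately short fit: Rhat must be computed for every scalar
        # block and the warning flag must track the 1.05 threshold
        out = ad.convergence(small_fit)
        assert {"alpha", "delta0", "tau_v"} <= set(out["parameter"])
        assert np.isfinite(out["rhat"]).all() and (out["rhat"] > 0.9).all()
        assert (out["ess"] > 0).all()
        flagged = out["rhat"] > 1.05
        assert (out.loc[flagged, "flag"] == "high-rhat").all()
        assert (out.loc[~flagged, "flag"] == "").all()


def test_prior_sensitivity_report_format(small_dataset):
    cfg, panel, expected, graph, truth = small_dataset
    design = ad.build_design(panel, expected, cfg.cancer, ad.ModelSpec(model_id=3))
    mc = ad.McmcConfig(chains=1, iterations=300, burnin=150, thinning=1, seed=6,
                       store_cell_draws=False)
    report = ad.prior_sensitivity(ad.ModelSpec(model_id=3), design, graph, mc)
    assert set(report["prior"]) == {"gamma", "flat"}
    assert {"parameter", "mean", "lo95", "hi95", "intervals_overlap",
            "density_grid", "density_value"} <= set(report.columns)
    # every tau appears in both arms with a plottable marginal density
    assert (report.groupby("parameter")["prior"].nunique() == 2).all()
    assert report["density_value"].str.contains(";").all()
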