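import itertools
import math

import numpy as np
import pytest
from scipy import integrate

import arealdisp as ad
from arealdisp.models import ModelError, _precision_logprior

from conftest import make_panel, path_graph


def all_connected_graphs(n):
    """Every connected labelled graph on n nodes, as AdjacencyGraph."""
    nodes = [f"v{i}" for i in range(n)]
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        nb = {v: set() for v in nodes}
        for (i, j), b in zip(pairs, bits):
            if b:
                nb[nodes[i]].add(nodes[j])
                nb[nodes[j]].add(nodes[i])
        g = ad.AdjacencyGraph(nodes, nb)
        if g.n_components() == 1:
            yield g


class TestLinearPredictor:
    @pytest.fixture()
    def design(self):
        panel = make_panel(n_areas=3, n_years=2, seed=2)
        rates = ad.statewide_rates(panel)
        expected = ad.expected_counts(panel, rates)
        return ad.build_design(panel, expected, "digestive")

    def test_zero_state_gives_unit_risk(self, design):
        st = ad.ParameterState.zeros(design.n_areas, design.n_years, design.n_covariates)
        eta = ad.linear_predictor(st, design)
        assert np.all(eta == 0)

    def test_intercept_plus_disparity(self, design):
        st = ad.ParameterState.zeros(design.n_areas, design.n_years, design.n_covariates)
        st.alpha, st.delta0 = 0.1, 0.05
        eta = ad.linear_predictor(st, design, model_id=1)
        assert eta[design.eth == 1] == pytest.approx(0.15)
        # reference group never sees the disparity coefficient
        assert eta[design.eth == 0] == pytest.approx(0.1)

    def test_model1_ignores_area_deviations(self, design):
        st = ad.ParameterState.zeros(design.n_areas, design.n_years, design.n_covariates)
        st.delta_area[:] = 5.0
        assert np.all(ad.linear_predictor(st, design, model_id=1) == 0)
        assert np.any(ad.linear_predictor(st, design, model_id=2) != 0)

    def test_dimension_mismatch_rejected(self, design):
        st = ad.ParameterState.zeros(design.n_areas + 1, design.n_years, design.n_covariates)
        with pytest.raises(ModelError):
            ad.linear_predictor(st, design)


class TestPoissonLoglik:
    @pytest.mark.parametrize(
        "y,mu,expected",
        [
            (0, 1.0, -1.0),
            (1, 1.0, -1.0),
            (2, 2.0, math.log(2) - 2),  # -2 + 2 ln 2 - ln 2
        ],
    )
    def test_hand_values(self, y, mu, expected):
        assert ad.poisson_loglik(y, mu) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ModelError):
            ad.poisson_loglik(1, 0.0)


class TestIcar:
    def test_constant_vector_is_zero(self):
        g = path_graph(["a", "b", "c"])
        assert ad.icar_logdensity(np.full(3, 2.7), 5.0, g) == 0.0

    def test_two_node_example(self):
        g = path_graph(["a", "b"])
        assert ad.icar_logdensity(np.array([0.0, 1.0]), 2.0, g) == pytest.approx(-1.0)

    def test_three_node_path(self):
        g = path_graph(["a", "b", "c"])
        # -(1/2)(1^2 + 2^2) = -2.5
        assert ad.icar_logdensity(np.array([0.0, 1.0, 3.0]), 1.0, g) == pytest.approx(-2.5)

    def test_matches_laplacian_quadratic_form(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 4):
            for g in all_connected_graphs(n):
                L = g.laplacian()
                for _ in range(5):
                    u = rng.standard_normal(n)
                    tau = float(rng.uniform(0.2, 3))
                    assert ad.icar_logdensity(u, tau, g) == pytest.approx(
                        -0.5 * tau * u @ L @ u, abs=1e-10
                    )

    def test_full_conditional_is_neighbour_average(self):
        # quadratic-form completion: the conditional of u_i given the rest
        # is N(mean of neighbours, 1/(tau n_i)); recover it numerically.
        g = path_graph(["a", "b", "c"])
        tau = 1.7
        u = np.array([0.4, 0.0, -1.1])
        grid = np.linspace(-3, 3, 7)
        logp = np.array(
            [ad.icar_logdensity(np.array([0.4, x, -1.1]), tau, g) for x in grid]
        )
        coef = np.polyfit(grid, logp, 2)
        cond_var = -1.0 / (2 * coef[0])
        cond_mean = -coef[1] / (2 * coef[0])
        assert cond_mean == pytest.approx((0.4 - 1.1) / 2, abs=1e-10)
        assert cond_var == pytest.approx(1 / (tau * 2), abs=1e-10)

    def test_islands_contribute_nothing(self):
        g = ad.AdjacencyGraph(["a", "b"], {"a": set(), "b": set()})
        assert ad.icar_logdensity(np.array([3.0, -4.0]), 2.0, g) == 0.0


class TestScalarPriors:
    def test_iid_normal_at_zero(self):
        tau = 3.3
        assert ad.iid_normal_logprior(0.0, tau) == pytest.approx(
            0.5 * (np.log(tau) - np.log(2 * np.pi))
        )

    def test_doubling_tau_raises_by_half_n_log2(self):
        x = np.zeros(7)
        assert ad.iid_normal_logprior(x, 2.0) - ad.iid_normal_logprior(x, 1.0) == pytest.approx(
            3.5 * np.log(2)
        )

    def test_gamma_density_integrates_to_one(self):
        shape, rate = 0.5, 0.0005
        val, err = integrate.quad(
            lambda t: np.exp(ad.gamma_logprior(t, shape, rate)), 1e-12, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ModelError):
            ad.iid_normal_logprior(0.0, 0.0)
        with pytest.raises(ModelError):
            ad.gamma_logprior(-1.0, 0.5, 0.0005)


class TestLogPosterior:
    @pytest.fixture()
    def setup(self):
        panel = make_panel(n_areas=4, n_years=2, seed=4)
        rates = ad.statewide_rates(panel)
        expected = ad.expected_counts(panel, rates)
        design = ad.build_design(panel, expected, "digestive")
        graph = path_graph(design.areas)
        rng = np.random.default_rng(1)
        st = ad.ParameterState.zeros(design.n_areas, design.n_years, design.n_covariates)
        st.alpha = 0.05
        st.delta0 = 0.1
        st.beta = rng.normal(0, 0.05, design.n_covariates)
        st.u = rng.normal(0, 0.1, design.n_areas)
        st.v = rng.normal(0, 0.1, design.n_areas)
        st.t = rng.normal(0, 0.05, design.n_years)
        st.psi = rng.normal(0, 0.05, design.n_areas * design.n_years)
        st.delta_area = rng.normal(0, 0.1, design.n_areas)
        return design, graph, st

    def test_decomposes_into_likelihood_plus_priors(self, setup):
        design, graph, st = setup
        spec = ad.ModelSpec(model_id=2)
        full = ad.log_posterior(st, design, graph, spec)
        lik = ad.log_likelihood(st, design, model_id=2)
        prior = full - lik
        assert np.isfinite(prior)
        st2 = st.copy()
        st2.alpha += 0.2
        full2 = ad.log_posterior(st2, design, graph, spec)
        lik2 = ad.log_likelihood(st2, design, model_id=2)
        assert full2 - lik2 == pytest.approx(prior, abs=1e-9)  # alpha prior is flat

    def test_models_1_and_2_nest(self, setup):
        design, graph, st = setup
        st.delta_area[:] = 0.0
        lp1 = ad.log_posterior(st, design, graph, ad.ModelSpec(model_id=1))
        lp2 = ad.log_posterior(st, design, graph, ad.ModelSpec(model_id=2))
        # they differ exactly by the (zero-effect) delta prior + tau prior
        gap = ad.iid_normal_logprior(st.delta_area, st.tau_delta) + _precision_logprior(
            st.tau_delta, ad.ModelSpec(model_id=2)
        )
        assert lp2 - lp1 == pytest.approx(gap, abs=1e-9)

    def test_vectorized_likelihood_matches_naive_loop(self, setup):
        design, graph, st = setup
        eta = ad.linear_predictor(st, design, model_id=3)
        naive = 0.0
        for c in range(design.n_cells):
            mu = design.e[c] * math.exp(eta[c])
            naive += float(ad.poisson_loglik(int(design.y[c]), mu))
        assert ad.log_likelihood(st, design, model_id=3) == pytest.approx(naive, abs=1e-10)


class TestModelSpec:
    def test_yaml_round_trip(self):
        spec = ad.ModelSpec(model_id=2, precision_prior="flat", exceedence_threshold=1.1)
        again = ad.ModelSpec.from_yaml(spec.to_yaml())
        assert again == spec

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"model_id": 4},
            {"precision_prior": "cauchy"},
            {"gamma_shape": -1.0},
            {"exceedence_threshold": 0.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ModelError):
            ad.ModelSpec(**kwargs)
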