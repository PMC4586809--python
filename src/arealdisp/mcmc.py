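"""Posterior sampling for the disparity models.

The sampler is Metropolis-within-Gibbs.  The intercept has a flat prior
and an exactly conjugate full conditional (a log-Gamma), so it is drawn
by Gibbs; the remaining fixed effects use adaptive random-walk steps.
Random-effect blocks are updated with vectorized single-site random walks
— iid blocks all at once (their full conditionals are independent given
the rest), ICAR blocks one graph colour class at a time so that no two
neighbours move together.  Precisions are drawn from their conjugate
Gamma full conditionals (truncated when the flat prior is selected).
Sum-to-zero identification of the ICAR blocks is maintained by
recentering each sweep, transferring the mean into the intercept (for u)
or into the mean disparity (for the spatially varying slopes), which
leaves the linear predictor untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .graph import AdjacencyGraph
from .models import (
    CellDesign,
    ModelError,
    ModelSpec,
    ParameterState,
    build_design,
    poisson_loglik,
)
from .panel import ArealPanel
from .standardize import ExpectedCounts

_ADAPT_TARGET = 0.35  # mid-range of the 20-50% acceptance band


@dataclass
class McmcConfig:
    """Sampler run lengths and reproducibility settings."""

    chains: int = 2
    iterations: int = 10_000
    burnin: int = 5_000
    thinning: int = 5
    seed: int = 0
    initial_scale: float = 0.1
    store_cell_draws: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.burnin < self.iterations):
            raise ModelError("need 0 <= burnin < iterations")
        if self.thinning < 1:
            raise ModelError("thinning must be >= 1")
        if self.chains < 1:
            raise ModelError("need at least one chain")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burnin) // self.thinning

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    """Retained draws and posterior summaries for one fitted model."""

    spec: ModelSpec
    config: McmcConfig
    design: CellDesign
    draws: dict  # name -> array of shape (n_draws, ...) stacked over chains
    deviance: np.ndarray  # (n_draws,)
    acceptance: dict
    chain_length: int
    fingerprint: str

    @property
    def n_draws(self) -> int:
        return len(self.deviance)

    def summaries(self) -> pd.DataFrame:
        """Tidy posterior summary table (mean and equal-tailed 95% CI)."""
        rows = []
        for name, arr in self.draws.items():
            if name == "eta":
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                m, lo, hi = summarize(arr)
                rows.append({"parameter": name, "index": -1, "mean": m, "lo95": lo, "hi95": hi})
            else:
                for k in range(arr.shape[1]):
                    m, lo, hi = summarize(arr[:, k])
                    rows.append(
                        {"parameter": name, "index": k, "mean": m, "lo95": lo, "hi95": hi}
                    )
        return pd.DataFrame(rows)


def summarize(draws) -> tuple[float, float, float]:
    """Posterior mean with equal-tailed 95% credible interval."""
    arr = np.asarray(draws, dtype=float)
    if arr.size < 2:
        raise ModelError("need at least two draws to summarize")
    lo, hi = np.quantile(arr, [0.025, 0.975])
    return float(arr.mean()), float(lo), float(hi)


def disparity_percent(delta) -> float | np.ndarray:
    """Excess risk in percent implied by a log relative-risk coefficient."""
    out = 100.0 * (np.exp(np.asarray(delta, dtype=float)) - 1.0)
    return float(out) if out.shape == () else out


# ---------------------------------------------------------------------------
# sampler internals


class _BlockScale:
    """Robbins-Monro adapted random-walk scale for one block."""

    def __init__(self, scale: float):
        self.log_scale = np.log(scale)
        self.accepted = 0.0
        self.proposed = 0.0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, acc_rate: float, it: int) -> None:
        gamma = 10.0 / (100.0 + it)
        self.log_scale += gamma * (acc_rate - _ADAPT_TARGET)
        self.log_scale = np.clip(self.log_scale, -12.0, 3.0)

    def record(self, accepted: float, proposed: float) -> None:
        self.accepted += accepted
        self.proposed += proposed

    def rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else np.nan


class _Sampler:
    def __init__(self, spec: ModelSpec, design: CellDesign, graph: AdjacencyGraph,
                 config: McmcConfig, rng: np.random.Generator):
        self.spec = spec
        self.d = design
        self.graph = graph.bind(design.areas)
        self.cfg = config
        self.rng = rng

        d = design
        self.n, self.J, self.p = d.n_areas, d.n_years, d.n_covariates
        self.q_idx = d.interaction_index()
        self.nq = self.n * self.J
        self.W = self.graph.adjacency_matrix()
        self.deg = self.graph.degrees().astype(float)
        self.colors = self.graph.coloring()
        self.rank_icar = self.n - self.graph.n_components()
        i, j = self.graph.edge_index()
        self.edge_i, self.edge_j = i, j

        self.sum_y = float(d.y.sum())
        self.Y_area = np.bincount(d.area_idx, weights=d.y, minlength=self.n)
        self.Y_year = np.bincount(d.year_idx, weights=d.y, minlength=self.J)
        self.Y_q = np.bincount(self.q_idx, weights=d.y, minlength=self.nq)
        self.focal = d.eth == 1
        self.has_focal = bool(self.focal.any())
        self.area_idx_H = d.area_idx[self.focal]
        self.Y_area_H = np.bincount(self.area_idx_H, weights=d.y[self.focal], minlength=self.n)
        self.sum_y_H = float(d.y[self.focal].sum())
        self.x_cells = [d.X[:, k][d.area_idx] for k in range(self.p)]

        s0 = config.initial_scale
        self.scales = {
            name: _BlockScale(s0)
            for name in ("delta0", "beta", "u", "v", "t", "psi", "delta")
        }

        # initial state
        st = ParameterState.zeros(self.n, self.J, self.p)
        st.alpha = float(np.log(max(self.sum_y, 0.5) / d.e.sum()))
        # gamma arm: prior-mean start; flat arm: moderate start so random
        # effects can reach the data scale before the precision adapts
        # (a huge initial tau pins the effects at zero, and the conjugate
        # draw then locks the chain in that degenerate corner)
        tau0 = (spec.gamma_shape / spec.gamma_rate) if spec.precision_prior == "gamma" else 100.0
        st.tau_u = st.tau_v = st.tau_t = st.tau_psi = st.tau_delta = tau0
        self.st = st
        self.eta = self._full_eta()
        if not np.all(np.isfinite(self.eta)):
            raise ModelError("non-finite linear predictor at initialization")

    # -- linear predictor maintenance -------------------------------------
    def _full_eta(self) -> np.ndarray:
        from .models import linear_predictor

        return linear_predictor(self.st, self.d, self.spec.model_id)

    def _mu(self) -> np.ndarray:
        return self.d.e * np.exp(self.eta)

    # -- block updates -----------------------------------------------------
    def _update_alpha(self) -> None:
        # flat prior; lambda = exp(alpha) | rest ~ Gamma(sum y, sum e*exp(eta - alpha))
        if self.sum_y <= 0:
            return
        rate = float(self._mu().sum() / np.exp(self.st.alpha))
        lam = self.rng.gamma(self.sum_y, 1.0 / rate)
        new_alpha = float(np.log(lam))
        self.eta += new_alpha - self.st.alpha
        self.st.alpha = new_alpha

    def _scalar_mh(self, name: str, delta_eta_unit: np.ndarray, current: float,
                   prior_tau: float, it: int, adapting: bool) -> float:
        """One random-walk step for a scalar whose eta-gradient is a fixed vector."""
        sc = self.scales[name]
        step = sc.scale * self.rng.standard_normal()
        mu = self._mu()
        d_eta = step * delta_eta_unit
        dll = float(np.sum(self.d.y * d_eta) - np.sum(mu * np.expm1(d_eta)))
        new = current + step
        dlp = dll - 0.5 * prior_tau * (new**2 - current**2)
        acc = np.log(self.rng.uniform()) < dlp
        sc.record(float(acc), 1.0)
        if adapting:
            sc.update(float(acc), it)
        if acc:
            self.eta += d_eta
            return new
        return current

    def _update_delta0(self, it, adapting) -> None:
        if not self.has_focal:
            return
        sc = self.scales["delta0"]
        step = sc.scale * self.rng.standard_normal()
        mu = self._mu()
        m_H = float(mu[self.focal].sum())
        dll = step * self.sum_y_H - np.expm1(step) * m_H
        new = self.st.delta0 + step
        tau0 = self.spec.fixed_effect_precision
        dlp = dll - 0.5 * tau0 * (new**2 - self.st.delta0**2)
        acc = np.log(self.rng.uniform()) < dlp
        sc.record(float(acc), 1.0)
        if adapting:
            sc.update(float(acc), it)
        if acc:
            self.eta[self.focal] += step
            self.st.delta0 = new

    def _update_beta(self, it, adapting) -> None:
        for k in range(self.p):
            self.st.beta[k] = self._scalar_mh(
                "beta", self.x_cells[k], self.st.beta[k],
                self.spec.fixed_effect_precision, it, adapting,
            )

    def _vector_mh_area(self, name, values, Y_by, M_by, prior, mask=None,
                        it=0, adapting=False):
        """Simultaneous single-site updates for a per-area (or per-index) block.

        ``prior`` maps (proposal vector, current values, mask) to the
        per-element log prior difference.  Returns the accepted-step vector.
        """
        sc = self.scales[name]
        size = len(values)
        step = np.zeros(size)
        active = np.ones(size, dtype=bool) if mask is None else mask
        n_active = int(active.sum())
        if n_active == 0:
            return np.zeros(size)
        step[active] = sc.scale * self.rng.standard_normal(n_active)
        dll = step * Y_by - np.expm1(step) * M_by
        dlp = dll + prior(step, values)
        logu = np.full(size, -np.inf)
        logu[active] = np.log(self.rng.uniform(size=n_active))
        acc = logu < dlp
        acc &= active
        sc.record(float(acc.sum()), float(n_active))
        if adapting:
            sc.update(float(acc.sum()) / n_active, it)
        out = np.where(acc, step, 0.0)
        values += out
        return out

    def _update_v(self, it, adapting) -> None:
        mu = self._mu()
        M = np.bincount(self.d.area_idx, weights=mu, minlength=self.n)
        tau = self.st.tau_v

        def prior(step, vals):
            return -0.5 * tau * ((vals + step) ** 2 - vals**2)

        dv = self._vector_mh_area("v", self.st.v, self.Y_area, M, prior,
                                  it=it, adapting=adapting)
        self.eta += dv[self.d.area_idx]

    def _update_t(self, it, adapting) -> None:
        mu = self._mu()
        M = np.bincount(self.d.year_idx, weights=mu, minlength=self.J)
        tau = self.st.tau_t

        def prior(step, vals):
            return -0.5 * tau * ((vals + step) ** 2 - vals**2)

        dt = self._vector_mh_area("t", self.st.t, self.Y_year, M, prior,
                                  it=it, adapting=adapting)
        self.eta += dt[self.d.year_idx]

    def _update_psi(self, it, adapting) -> None:
        mu = self._mu()
        M = np.bincount(self.q_idx, weights=mu, minlength=self.nq)
        tau = self.st.tau_psi

        def prior(step, vals):
            return -0.5 * tau * ((vals + step) ** 2 - vals**2)

        dpsi = self._vector_mh_area("psi", self.st.psi, self.Y_q, M, prior,
                                    it=it, adapting=adapting)
        self.eta += dpsi[self.q_idx]

    def _icar_prior_delta(self, step, vals, tau):
        # per-area change of -(tau/2) sum_edges (x_i - x_j)^2 when only
        # non-adjacent areas move: n_i (2 x_i dx + dx^2) - 2 dx s_i
        s = self.W.dot(vals)
        return -0.5 * tau * (self.deg * (2 * vals * step + step**2) - 2 * step * s)

    def _update_u(self, it, adapting) -> None:
        tau = self.st.tau_u
        for cmask in self.colors:
            mu = self._mu()
            M = np.bincount(self.d.area_idx, weights=mu, minlength=self.n)

            def prior(step, vals):
                return self._icar_prior_delta(step, vals, tau)

            du = self._vector_mh_area("u", self.st.u, self.Y_area, M, prior,
                                      mask=cmask, it=it, adapting=adapting)
            self.eta += du[self.d.area_idx]

    def _update_delta_area(self, it, adapting) -> None:
        tau = self.st.tau_delta
        if self.spec.model_id == 2:
            mu = self._mu()
            M = np.bincount(self.area_idx_H, weights=mu[self.focal], minlength=self.n)

            def prior(step, vals):
                return -0.5 * tau * ((vals + step) ** 2 - vals**2)

            dd = self._vector_mh_area("delta", self.st.delta_area,
                                      self.Y_area_H, M, prior, it=it, adapting=adapting)
            self.eta[self.focal] += dd[self.area_idx_H]
        else:  # ICAR slopes
            for cmask in self.colors:
                mu = self._mu()
                M = np.bincount(self.area_idx_H, weights=mu[self.focal], minlength=self.n)

                def prior(step, vals):
                    return self._icar_prior_delta(step, vals, tau)

                dd = self._vector_mh_area("delta", self.st.delta_area,
                                          self.Y_area_H, M, prior, mask=cmask,
                                          it=it, adapting=adapting)
                self.eta[self.focal] += dd[self.area_idx_H]

    # -- precisions --------------------------------------------------------
    def _draw_precision(self, df: float, quad: float) -> float:
        spec = self.spec
        if spec.precision_prior == "gamma":
            shape = spec.gamma_shape + 0.5 * df
            rate = spec.gamma_rate + 0.5 * quad
            return float(self.rng.gamma(shape, 1.0 / rate))
        # uniform-on-sd prior: p(tau) ~ tau^(-3/2) on tau >= flat_upper^-2,
        # giving a Gamma(df/2 - 1/2, quad/2) full conditional, left-truncated
        shape = max(0.5 * df - 0.5, 1e-3)
        rate = 0.5 * quad if quad > 0 else 1e-12
        floor = stats.gamma.cdf(spec.flat_upper ** -2, shape, scale=1.0 / rate)
        u = floor + self.rng.uniform() * (1.0 - floor)
        return float(stats.gamma.ppf(min(max(u, 1e-300), 1 - 1e-16), shape, scale=1.0 / rate))

    def _update_precisions(self) -> None:
        st, spec = self.st, self.spec
        if spec.include_heterogeneity:
            st.tau_v = self._draw_precision(self.n, float(np.sum(st.v**2)))
        if spec.include_temporal:
            st.tau_t = self._draw_precision(self.J, float(np.sum(st.t**2)))
        if spec.include_interaction:
            st.tau_psi = self._draw_precision(self.nq, float(np.sum(st.psi**2)))
        if spec.include_spatial:
            diff = st.u[self.edge_i] - st.u[self.edge_j]
            st.tau_u = self._draw_precision(self.rank_icar, float(np.sum(diff**2)))
        if spec.model_id == 2:
            st.tau_delta = self._draw_precision(self.n, float(np.sum(st.delta_area**2)))
        elif spec.model_id == 3:
            diff = st.delta_area[self.edge_i] - st.delta_area[self.edge_j]
            st.tau_delta = self._draw_precision(self.rank_icar, float(np.sum(diff**2)))

    def _recenter(self) -> None:
        st = self.st
        if self.spec.include_spatial and self.spec.constrain_spatial:
            m = float(st.u.mean())
            st.u -= m
            st.alpha += m
        if self.spec.model_id == 3 and self.spec.constrain_spatial:
            m = float(st.delta_area.mean())
            st.delta_area -= m
            st.delta0 += m

    # -- main loop ---------------------------------------------------------
    def run(self):
        cfg, spec = self.cfg, self.spec
        n_keep = cfg.draws_per_chain
        out = {
            "alpha": np.empty(n_keep),
            "delta0": np.empty(n_keep),
            "beta": np.empty((n_keep, self.p)),
            "tau_u": np.empty(n_keep),
            "tau_v": np.empty(n_keep),
            "tau_t": np.empty(n_keep),
            "tau_psi": np.empty(n_keep),
            "tau_delta": np.empty(n_keep),
            "u": np.empty((n_keep, self.n), dtype=np.float32),
            "t": np.empty((n_keep, self.J), dtype=np.float32),
            "delta_area": np.empty((n_keep, self.n), dtype=np.float32),
        }
        if cfg.store_cell_draws:
            out["eta"] = np.empty((n_keep, self.d.n_cells), dtype=np.float32)
        deviance = np.empty(n_keep)

        kept = 0
        for it in range(cfg.iterations):
            adapting = it < cfg.burnin
            self._update_alpha()
            self._update_delta0(it, adapting)
            if self.p:
                self._update_beta(it, adapting)
            if spec.include_spatial:
                self._update_u(it, adapting)
            if spec.include_heterogeneity:
                self._update_v(it, adapting)
            if spec.include_temporal:
                self._update_t(it, adapting)
            if spec.include_interaction:
                self._update_psi(it, adapting)
            if spec.has_varying_disparity and self.has_focal:
                self._update_delta_area(it, adapting)
            self._update_precisions()
            self._recenter()

            if it >= cfg.burnin and (it - cfg.burnin) % cfg.thinning == 0 and kept < n_keep:
                st = self.st
                out["alpha"][kept] = st.alpha
                out["delta0"][kept] = st.delta0
                out["beta"][kept] = st.beta
                out["tau_u"][kept] = st.tau_u
                out["tau_v"][kept] = st.tau_v
                out["tau_t"][kept] = st.tau_t
                out["tau_psi"][kept] = st.tau_psi
                out["tau_delta"][kept] = st.tau_delta
                out["u"][kept] = st.u
                out["t"][kept] = st.t
                out["delta_area"][kept] = st.delta_area
                if cfg.store_cell_draws:
                    out["eta"][kept] = self.eta
                deviance[kept] = -2.0 * float(
                    np.sum(poisson_loglik(self.d.y, self._mu()))
                )
                kept += 1
        rates = {name: sc.rate() for name, sc in self.scales.items()}
        return out, deviance, rates


def fit_model(
    spec: ModelSpec,
    panel: ArealPanel,
    expected: ExpectedCounts,
    graph: AdjacencyGraph,
    config: McmcConfig,
    cancer: str | None = None,
) -> FitResult:
    """Fit one model variant to one cancer stratum by MCMC.

    Runs ``config.chains`` independent chains from a stream-split seeded
    generator and stacks their retained draws.  Identical seeds give
    bitwise-identical results.
    """
    cancers = panel.cancers()
    if cancer is None:
        if len(cancers) != 1:
            raise ModelError(f"panel has several cancers {cancers}; pass cancer=...")
        cancer = cancers[0]
    design = build_design(panel, expected, cancer, spec)
    return fit_design(spec, design, graph, config)


def fit_design(spec: ModelSpec, design: CellDesign, graph: AdjacencyGraph,
               config: McmcConfig) -> FitResult:
    if design.n_cells == 0:
        raise ModelError("no cells with positive expected counts")
    all_draws: list[dict] = []
    all_dev = []
    rates = {}
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        sampler = _Sampler(spec, design, graph, config, rng)
        draws, dev, r = sampler.run()
        all_draws.append(draws)
        all_dev.append(dev)
        rates = {k: rates.get(k, 0.0) + v / config.chains for k, v in r.items()}
    stacked = {
        k: np.concatenate([d[k] for d in all_draws], axis=0) for k in all_draws[0]
    }
    return FitResult(
        spec=spec,
        config=config,
        design=design,
        draws=stacked,
        deviance=np.concatenate(all_dev),
        acceptance=rates,
        chain_length=config.draws_per_chain,
        fingerprint=design.fingerprint(),
    )


def fitted_sir(fit: FitResult) -> pd.DataFrame:
    """Posterior mean (and 95% CI) of exp(log theta) per cell.

    This is the model-based standardized incidence ratio surface; exported
    per (area, year, group) for mapping.
    """
    if "eta" not in fit.draws:
        raise ModelError("fit was run with store_cell_draws=False")
    theta = np.exp(fit.draws["eta"].astype(np.float64))
    mean = theta.mean(axis=0)
    lo, hi = np.quantile(theta, [0.025, 0.975], axis=0)
    d = fit.design
    return pd.DataFrame(
        {
            "cancer": d.cancer,
            "area_id": np.asarray(d.areas, dtype=object)[d.area_idx],
            "year": np.asarray(d.years)[d.year_idx],
            "group": d.eth,
            "fitted_sir": mean,
            "lo95": lo,
            "hi95": hi,
        }
    )


def disparity_surface(fit: FitResult) -> pd.DataFrame:
    """Per-area posterior summary of the disparity relative risk e^(delta0 + d_i).

    For Model 1 the statewide value e^delta0 is replicated for every area.
    """
    d = fit.design
    delta_draws = fit.draws["delta0"][:, None]
    if fit.spec.has_varying_disparity:
        delta_draws = delta_draws + fit.draws["delta_area"].astype(np.float64)
    else:
        delta_draws = np.repeat(delta_draws, d.n_areas, axis=1)
    rr = np.exp(delta_draws)
    mean = rr.mean(axis=0)
    lo, hi = np.quantile(rr, [0.025, 0.975], axis=0)
    return pd.DataFrame(
        {
            "cancer": d.cancer,
            "area_id": d.areas,
            "disparity_rr": mean,
            "lo95": lo,
            "hi95": hi,
        }
    )
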