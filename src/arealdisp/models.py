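"""Hierarchical Poisson disparity models: specifications and log densities.

Three nested models for the relative risk theta of cell (area i, year j,
group k) within one cancer stratum, all with log link:

    ln theta_ijk = alpha + delta_i * eth_k + x_i' beta + u_i + v_i + t_j + psi_ij

* Model 1: a single statewide disparity, delta_i = delta0 for every area.
* Model 2: unstructured random slopes, delta_i = delta0 + d_i,
  d_i ~ N(0, 1/tau_delta) iid.
* Model 3: spatially correlated random slopes, d_i following an intrinsic
  CAR (ICAR) prior on the contiguity graph.

u is the ICAR ("correlated heterogeneity") term of the BYM convolution
prior, v the iid heterogeneity, t an iid year effect and psi an iid
area-year interaction.  Gaussian priors are parameterized by mean and
precision (tau = 1/sigma^2); precisions get Gamma(0.5, 0.0005) priors by
default, with a vague uniform-on-sd alternative for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.special import gammaln

from .graph import AdjacencyGraph
from .panel import ArealPanel, COVARIATE_COLUMNS
from .standardize import ExpectedCounts


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Which model variant to fit, and every prior constant it needs."""

    model_id: int = 3
    fixed_effect_precision: float = 1e-4  # N(0, tau=1e-4) on delta0 and beta
    precision_prior: str = "gamma"  # "gamma" or "flat" (uniform on the sd scale)
    gamma_shape: float = 0.5
    gamma_rate: float = 0.0005
    flat_upper: float = 100.0  # upper bound of the uniform sd prior
    exceedence_threshold: float = 1.25
    include_covariates: bool = True
    include_spatial: bool = True  # u (ICAR)
    include_heterogeneity: bool = True  # v (iid)
    include_temporal: bool = True  # t (iid)
    include_interaction: bool = True  # psi (iid)
    standardize_covariates: bool = True
    constrain_spatial: bool = True  # sum-to-zero on u (and ICAR d_i)

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ModelError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if self.precision_prior not in ("gamma", "flat"):
            raise ModelError(f"unknown precision prior {self.precision_prior!r}")
        for name in ("fixed_effect_precision", "gamma_shape", "gamma_rate",
                     "flat_upper", "exceedence_threshold"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be strictly positive")

    @property
    def has_varying_disparity(self) -> bool:
        return self.model_id >= 2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class CellDesign:
    """One cancer stratum unpacked into aligned arrays for the likelihood.

    Cells with e = 0 are dropped here: the log link is undefined for them,
    so they carry no likelihood information.  ``row_index`` maps each kept
    cell back to its row in the panel frame.
    """

    cancer: str
    areas: list
    years: list
    y: np.ndarray  # kept cells
    e: np.ndarray
    area_idx: np.ndarray
    year_idx: np.ndarray
    eth: np.ndarray  # 1 = focal group
    X: np.ndarray  # (n_areas, p) covariates, standardized if requested
    covariate_names: list[str]
    covariate_means: np.ndarray
    covariate_scales: np.ndarray
    row_index: np.ndarray
    n_dropped: int

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_cells(self) -> int:
        return len(self.y)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def interaction_index(self) -> np.ndarray:
        """Flat (area, year) index for the psi block."""
        return self.area_idx * self.n_years + self.year_idx

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arr in (self.y, self.e.round(12), self.area_idx, self.year_idx, self.eth):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(self.cancer.encode())
        return h.hexdigest()[:16]


def build_design(
    panel: ArealPanel,
    expected: ExpectedCounts,
    cancer: str,
    spec: ModelSpec | None = None,
) -> CellDesign:
    """Assemble the likelihood arrays for one cancer stratum."""
    spec = spec or ModelSpec()
    df = panel.data
    mask = (df["cancer"] == cancer).to_numpy()
    if not mask.any():
        raise ModelError(f"no such cancer stratum: {cancer!r}")
    sub = df[mask]
    e_all = expected.values.to_numpy(dtype=float)[mask]
    areas = sorted(sub["area_id"].unique().tolist())
    years = sorted(sub["year"].unique().tolist())
    a_index = {a: i for i, a in enumerate(areas)}
    y_index = {y: j for j, y in enumerate(years)}

    keep = e_all > 0
    kept = sub[keep]
    if keep.sum() == 0:
        raise ModelError("no cells with positive expected counts")

    if spec.include_covariates:
        if panel.covariates is None:
            raise ModelError("panel has no covariates; set include_covariates=False")
        X = panel.covariates.loc[areas, COVARIATE_COLUMNS].to_numpy(dtype=float)
        names = list(COVARIATE_COLUMNS)
    else:
        X = np.zeros((len(areas), 0))
        names = []
    if spec.standardize_covariates and X.shape[1]:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])

    return CellDesign(
        cancer=cancer,
        areas=areas,
        years=years,
        y=kept["count"].to_numpy(dtype=np.int64),
        e=e_all[keep],
        area_idx=kept["area_id"].map(a_index).to_numpy(dtype=np.int64),
        year_idx=kept["year"].map(y_index).to_numpy(dtype=np.int64),
        eth=kept["group"].to_numpy(dtype=np.int64),
        X=X,
        covariate_names=names,
        covariate_means=mu,
        covariate_scales=sd,
        row_index=sub.index.to_numpy()[keep],
        n_dropped=int((~keep).sum()),
    )


@dataclass
class ParameterState:
    """A full set of model parameters for one cancer stratum."""

    alpha: float
    delta0: float
    beta: np.ndarray  # (p,)
    u: np.ndarray  # (n_areas,) ICAR spatial
    v: np.ndarray  # (n_areas,) iid heterogeneity
    t: np.ndarray  # (n_years,) iid temporal
    psi: np.ndarray  # (n_areas * n_years,) iid interaction
    delta_area: np.ndarray  # (n_areas,) disparity deviations d_i (0 for Model 1)
    tau_u: float = 1000.0
    tau_v: float = 1000.0
    tau_t: float = 1000.0
    tau_psi: float = 1000.0
    tau_delta: float = 1000.0

    @classmethod
    def zeros(cls, n_areas: int, n_years: int, n_covariates: int) -> "ParameterState":
        return cls(
            alpha=0.0,
            delta0=0.0,
            beta=np.zeros(n_covariates),
            u=np.zeros(n_areas),
            v=np.zeros(n_areas),
            t=np.zeros(n_years),
            psi=np.zeros(n_areas * n_years),
            delta_area=np.zeros(n_areas),
        )

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha=self.alpha,
            delta0=self.delta0,
            beta=self.beta.copy(),
            u=self.u.copy(),
            v=self.v.copy(),
            t=self.t.copy(),
            psi=self.psi.copy(),
            delta_area=self.delta_area.copy(),
            tau_u=self.tau_u,
            tau_v=self.tau_v,
            tau_t=self.tau_t,
            tau_psi=self.tau_psi,
            tau_delta=self.tau_delta,
        )


def linear_predictor(state: ParameterState, design: CellDesign, model_id: int = 3) -> np.ndarray:
    """log relative risk per kept cell.

    For Model 1 the per-area deviations are forced to zero; the disparity
    enters only through delta0, and only for focal-group cells (eth = 1).
    """
    n, J, p = design.n_areas, design.n_years, design.n_covariates
    for arr, size, name in (
        (state.u, n, "u"),
        (state.v, n, "v"),
        (state.t, J, "t"),
        (state.psi, n * J, "psi"),
        (state.delta_area, n, "delta_area"),
        (state.beta, p, "beta"),
    ):
        if len(arr) != size:
            raise ModelError(f"dimension mismatch for {name}: {len(arr)} != {size}")
    a, j = design.area_idx, design.year_idx
    d_area = state.delta_area if model_id >= 2 else np.zeros(n)
    delta = state.delta0 + d_area
    eta = (
        state.alpha
        + delta[a] * design.eth
        + (design.X @ state.beta)[a]
        + state.u[a]
        + state.v[a]
        + state.t[j]
        + state.psi[design.interaction_index()]
    )
    return eta


def poisson_loglik(y, mu) -> np.ndarray | float:
    """Poisson log probability mass -mu + y log mu - log y!."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ModelError("Poisson mean must be strictly positive")
    out = -mu + y * np.log(mu) - gammaln(y + 1.0)
    return out if out.shape else float(out)


def icar_logdensity(effects: np.ndarray, tau: float, graph: AdjacencyGraph) -> float:
    """Unnormalized ICAR log density -(tau/2) sum over edges (u_i - u_j)^2.

    Equivalent to the pairwise-difference (Besag) form whose full
    conditional for u_i is N(mean of neighbours, 1/(tau * n_i)).  Isolated
    areas contribute nothing.
    """
    effects = np.asarray(effects, dtype=float)
    if tau <= 0:
        raise ModelError("tau must be strictly positive")
    if len(effects) != graph.n_areas:
        raise ModelError("effects length does not match graph")
    i, j = graph.edge_index()
    if len(i) == 0:
        return 0.0
    diff = effects[i] - effects[j]
    return float(-0.5 * tau * np.sum(diff * diff))


def iid_normal_logprior(effects, tau: float) -> float:
    """Sum of N(0, 1/tau) log densities (mean-precision convention)."""
    if tau <= 0:
        raise ModelError("tau must be strictly positive")
    effects = np.atleast_1d(np.asarray(effects, dtype=float))
    n = len(effects)
    return float(0.5 * n * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * np.sum(effects**2))


def gamma_logprior(tau: float, shape: float, rate: float) -> float:
    """log Gamma(shape, rate) density at tau."""
    if tau <= 0:
        raise ModelError("tau must be strictly positive")
    if shape <= 0 or rate <= 0:
        raise ModelError("gamma shape and rate must be strictly positive")
    return float(
        shape * math.log(rate) - gammaln(shape) + (shape - 1) * math.log(tau) - rate * tau
    )


def _precision_logprior(tau: float, spec: ModelSpec) -> float:
    """Log prior for one precision under the spec's chosen family.

    The vague alternative to the Gamma prior is uniform on the standard
    deviation, sigma = tau^(-1/2) ~ U(0, flat_upper]; on the precision
    scale that is p(tau) proportional to tau^(-3/2).  A uniform prior
    placed directly on a bounded precision range is not used: for weakly
    identified variance components its posterior piles up where the
    random effect collapses, which is a property of that prior rather
    than of the data.
    """
    if spec.precision_prior == "gamma":
        return gamma_logprior(tau, spec.gamma_shape, spec.gamma_rate)
    if tau < spec.flat_upper ** -2:
        return -np.inf
    return -1.5 * math.log(tau)


def log_likelihood(state: ParameterState, design: CellDesign, model_id: int = 3) -> float:
    eta = linear_predictor(state, design, model_id)
    return float(np.sum(poisson_loglik(design.y, design.e * np.exp(eta))))


def log_posterior(
    state: ParameterState,
    design: CellDesign,
    graph: AdjacencyGraph,
    spec: ModelSpec,
) -> float:
    """Poisson log likelihood over e > 0 cells plus every prior term.

    The flat prior on alpha contributes zero.  Model 1 has no disparity
    deviations (their prior term is absent); Model 2 gives them an iid
    normal prior; Model 3 an ICAR prior on the contiguity graph.
    """
    lp = log_likelihood(state, design, spec.model_id)
    tau0 = spec.fixed_effect_precision
    # fixed effects: delta0 and beta ~ N(0, tau0); alpha flat
    lp += iid_normal_logprior(state.delta0, tau0)
    if design.n_covariates:
        lp += iid_normal_logprior(state.beta, tau0)
    if spec.include_spatial:
        lp += icar_logdensity(state.u, state.tau_u, graph)
        lp += _precision_logprior(state.tau_u, spec)
    if spec.include_heterogeneity:
        lp += iid_normal_logprior(state.v, state.tau_v)
        lp += _precision_logprior(state.tau_v, spec)
    if spec.include_temporal:
        lp += iid_normal_logprior(state.t, state.tau_t)
        lp += _precision_logprior(state.tau_t, spec)
    if spec.include_interaction:
        lp += iid_normal_logprior(state.psi, state.tau_psi)
        lp += _precision_logprior(state.tau_psi, spec)
    if spec.model_id == 2:
        lp += iid_normal_logprior(state.delta_area, state.tau_delta)
        lp += _precision_logprior(state.tau_delta, spec)
    elif spec.model_id == 3:
        lp += icar_logdensity(state.delta_area, state.tau_delta, graph)
        lp += _precision_logprior(state.tau_delta, spec)
    return lp
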