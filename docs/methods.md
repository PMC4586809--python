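# Methods

`arealdisp` implements a Bayesian spatio-temporal analysis of ethnic
disparities in county-level cancer incidence: indirect standardization of
stratified counts, three nested hierarchical Poisson models with a
(spatially varying) disparity coefficient, DIC model comparison, and
exceedence-probability cluster detection.  The motivating application is
the Hispanic / non-Hispanic disparity in digestive and respiratory cancer
incidence across the 254 Texas counties, 2000–2008; because the
registry's record-level file is restricted, the package validates every
stage on synthetic panels drawn from the same generative model.

## Standardization

For county *i*, year *j*, group *k* (1 = focal/Hispanic, 0 = reference)
the statewide group rate is the pooled
r_k = Σ_ij y_ijk / Σ_ij n_ijk over all years (person-years are raw
populations summed across years; no mid-year interpolation is applied,
since none is defined for the source panel).  Expected counts under equal
risk are e_ijk = n_ijk · r_k and the standardized incidence ratio is
SIR = y / e wherever e > 0; cells with e = 0 are flagged undefined rather
than dropped.  The per-year disparity summary divides the group-wise
means of the defined county SIRs ("ratio of means", robust to individual
zero-expected cells); a mean-of-ratios variant is available as an option.

## Models

With relative risk θ and log link, counts are modelled as
y_ijk | θ_ijk ~ Poisson(e_ijk · θ_ijk) and

    ln θ_ijk = α + δ_i · eth_k + x_i'β + u_i + v_i + t_j + ψ_ij

where u is an intrinsic CAR (ICAR) spatial field on the contiguity
graph, v iid heterogeneity (together the BYM convolution), t an iid year
effect, ψ an iid area–year interaction (Knorr-Held Type I), and x_i four
county covariates (poverty share, hospitals per 10 000, construction
share, metro indicator), z-standardized by default.  The disparity
coefficient δ_i takes three nested forms:

* **Model 1** — δ_i ≡ δ0, one statewide disparity;
* **Model 2** — δ_i = δ0 + d_i with d_i ~ N(0, 1/τ_δ) iid
  (unstructured random slopes);
* **Model 3** — d_i ICAR on the contiguity graph
  (spatially correlated random slopes).

All Gaussian priors are parameterized by mean and precision
(τ = 1/σ²): δ0 and β get N(0, τ = 10⁻⁴), α an improper flat prior, and
every precision a Gamma(0.5, 0.0005) prior by default.  The ICAR density
is the Besag pairwise-difference form
−(τ/2) Σ_{i~j} (u_i − u_j)², whose full conditional for u_i is
N(mean of neighbours, 1/(τ·n_i)).  The source notation writes the second
Normal argument as "τ/n_i"; read literally as a precision that would make
the conditional variance *grow* with neighbour count, so the package uses
the conventional Besag reading (conditional variance 1/(τ·n_i)), which is
also what INLA's `besag` model implements.

**Identifiability.** ICAR densities are invariant to a constant shift, so
u (always) and d (Model 3) carry exact sum-to-zero constraints,
maintained by recentering each sweep with the mean transferred into α
(resp. δ0) — a move that leaves the linear predictor, the ICAR prior and
the flat/near-flat parent prior unchanged.  The proper iid blocks
(v, t, ψ, Model-2 d) need no constraint and are not recentred; their
means are identified through their own priors, matching INLA's
convention of constraining only the ICAR terms.  Areas with no
neighbours contribute nothing to the ICAR density (their spatial effect
is absorbed by v).  Cells with e = 0 are excluded from the likelihood
(the log link is undefined there) but retained in the panel.

## Sampling

Metropolis-within-Gibbs:

* α — exact Gibbs: with a flat prior, exp(α) | rest ~ Gamma(Σy, Σ e·e^{η−α}).
* δ0, β — adaptive scalar random walks.
* v, t, ψ, Model-2 d — all elements updated simultaneously with
  independent random-walk proposals; valid because, given the rest, their
  full conditionals factorize over elements.
* u, Model-3 d — the same vectorized update applied one graph colour
  class at a time (greedy colouring), so no two neighbours move in the
  same proposal.
* precisions — conjugate Gamma full conditionals:
  Gamma(a + m/2, b + q/2) with m the number of effects (iid blocks) or
  the ICAR rank (n − number of components) and q the relevant quadratic
  form.

Proposal scales adapt by Robbins–Monro during burn-in toward ~35%
acceptance (the 20–50% band) and are frozen afterwards, preserving
detailed balance in the retained draws.  Initialization: α at
log(Σy/Σe), all effects at 0, precisions at the Gamma prior mean
(0.5/0.0005 = 1000).  Chains are seeded from a single integer with
per-chain stream splitting; identical seeds give bitwise-identical
output.  Defaults: 2 chains × 10 000 iterations, 5 000 burn-in,
thinning 5.  Summaries are posterior means with equal-tailed 95%
intervals; split-R̂ and effective sample sizes come from ArviZ.

## Model comparison and clustering

DIC = D̄ + pD with D̄ the posterior mean deviance and
pD = D̄ − D(plug-in); the plug-in deviance is evaluated at the posterior
mean of each cell's *linear predictor* (the canonical scale for the log
link), the standard Spiegelhalter construction.  INLA's pD differs
slightly, so exact equality with published DIC values is not expected;
rankings are the target.  Negative pD is reported, not hidden.

Exceedence probabilities are the fraction of retained draws with a risk
quantity above θ* (default 1.25, i.e. focal risk 25% higher).  The
default level thresholds the per-county disparity relative risk
e^{δ0+d_i}; a cell level (per county-year-group fitted SIR) is also
provided, since published cluster maps can be read either way.  Exports
carry presentation bands [0, 0.8), [0.8, 0.95), [0.95, 1] with the top
band flagging clusters.

## Prior sensitivity

The sensitivity harness refits a model with the Gamma(0.5, 0.0005)
precision priors replaced by a vague uniform alternative and pairs the
posterior τ summaries.  The uniform prior is placed on the **standard
deviation** scale, σ ~ U(0, 100], i.e. p(τ) ∝ τ^{−3/2}; a uniform prior
placed directly on a bounded precision range was implemented and
rejected: for variance components that the data only weakly identify
(the spatial and temporal precisions at these panel sizes) its posterior
is dominated by the flat upper tail where the random effect collapses —
a well-known property of uniform-on-precision priors, and one that would
make the sensitivity comparison report a discrepancy that reflects the
prior's pathology rather than the data.  Under the uniform-sd prior the
full conditional remains conjugate (Gamma(m/2 − 1/2, q/2), left-truncated
at τ = 10⁻⁴).  Flat-arm chains initialize precisions at 100 rather than
1000: a large initial τ with zero effects is an absorbing degenerate
corner for a single-site sampler (the conjugate draw locks τ high, which
pins the effects at zero).

## Synthetic panels

The generator draws from the model itself at the motivating study's
dimensions and reported hyperparameter magnitudes, so recovery tests
have a known truth:

* dimensions 254 areas × 9 years × 2 groups per cancer stratum;
* truth defaults (digestive stratum): α = −0.097, δ0 = 0.152,
  β = (−0.033, −0.016, −0.001, 0.021), τ_u = 428.7, τ_v = 92.6,
  τ_t = 478.0, τ_ψ = 296.5, τ_δ = 15.6; a respiratory preset carries the
  corresponding reported values (τ_t = 1538.8, τ_u = 923.1, τ_v = 20.8,
  τ_δ = 17.9, τ_ψ = 288.7);
* contiguity: a queen lattice trimmed to the area count (default), or a
  Delaunay triangulation of random points;
* ICAR fields are drawn from the degenerate Gaussian with precision
  τ(D − W) restricted to the sum-to-zero subspace (the conditional
  specification alone defines no proper joint);
* county populations are log-normal (median 16 000, σ_log = 1.6) and the
  focal population share Beta(1.3, 2.6); group rates are 4×10⁻⁴ (focal)
  and 7×10⁻⁴ (reference) cases per person-year.  These laws put many
  areas at small focal populations, which reproduces the source panel's
  hallmark sparsity — roughly 25–46% of focal county-years with zero
  cases — from a plain Poisson likelihood, with no zero inflation.
  Populations are constant across years within an area (the panel
  defines no interpolation scheme), and covariates are simulated from
  simple plausible laws (Beta poverty and construction shares, a
  quarter of areas with no hospitals, 30% metro).

Expected counts for synthetic panels apply the configured group rates to
the drawn populations (the provisional-rates pass); the analysis path
can equally recompute rates from the simulated counts.

What the generator does *not* emulate: real Texas geography and
adjacency, migration and residential history, registry confidentiality
suppression, age/sex structure, and population change over time.
Passing recovery tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to violations of it.

## Validation studies and problem sizes

The acceptance studies (in `arealdisp.experiments`, rerun by
`scripts/acceptance.py`) use these designs, chosen to make a full run a
matter of minutes on one core:

* ICAR oracle: all 771 connected labelled graphs on ≤5 nodes × 100
  random vectors against the Laplacian quadratic form (tolerance 1e−8);
* conjugate limit: 20 cells, intercept-only, 2 500 retained exact-Gibbs
  draws vs the log-Gamma posterior (3 Monte-Carlo SEs);
* δ0 recovery: 20 panels at the full 254 × 9 × 2 size, Model 3,
  3 000 iterations (1 500 burn-in, thin 3), one chain; target ≥90%
  of posterior means within ±0.05 of truth;
* δ0 coverage: 50 reduced panels (100 × 5), same chain lengths; target
  90–99% interval coverage;
* DIC selection: 20 panels at 150 × 6 generated from Model 3
  (τ_δ ≈ 16), Models 1 and 3 fit at 2 200 iterations; target Model 3
  preferred in ≥18/20;
* exceedence calibration: 100 000 lognormal draws vs 1 − Φ(ln 1.25)
  (±0.005);
* sparsity: one default panel's focal zero-count fraction in
  [0.25, 0.46];
* sensitivity: one full-size panel, Model 3, Gamma vs uniform-sd
  precision priors at 6 000 iterations; target overlapping 95% τ
  intervals.

## Known limitations

* Single-site random-walk updates mix slowly for strongly coupled
  blocks; the u/v decomposition in particular is only weakly identified
  (standard for BYM), so precision estimates carry wide intervals and
  order-of-magnitude recovery is the realistic expectation.
* pD uses the linear-predictor plug-in; fits with severe posterior
  skewness can yield small negative pD, which is reported as-is.
* The temporal block is exchangeable (iid); trend priors (e.g. first
  order random walks) are out of scope.
* The Poisson likelihood is fixed; overdispersion beyond the random
  effects and zero-inflated variants are out of scope.
* Queen/rook contiguity assumes polygon vertices shared exactly after
  snapping (default grid 1e−9); there is no geometry repair.
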