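# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data tests do and do not establish.

## Isotope preprocessing

All isotope values are per-mil (‰) deviations from PDB (carbon) and
atmospheric N₂ (nitrogen). The lipid correction
δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N is applied strictly when C:N > 3.5; equality
is left untouched. The spatial baseline correction subtracts the sampling
station's baseline isotope value and adds back the study-wide baseline mean;
it is exactly invertible given the local baselines, which the tests exploit.
Stations lacking baseline samples borrow the nearest station's baseline by
depth, with the substitution logged — depth is the dominant spatial axis in
shelf systems, making it the natural nearest-neighbour metric when the
baseline taxon is patchily sampled. Pipeline order is lipid correction first,
then baseline correction; both are per-sample affine maps of δ¹³C, so the
order is a bookkeeping convention, not a modelling choice.

Trophic levels use the classic primary-consumer anchor:
TL = 2 + (δ¹⁵N − δ¹⁵N_base)/3.4, with the baseline δ¹⁵N taken from a
filter-feeding bivalve (a long-lived primary consumer that integrates both
benthic and pelagic production and buffers short-term baseline fluctuation).
The constant 3.4 ‰ enrichment is retained for TL estimation even though the
mixing models use the proportional TEF below — the two serve different
estimators, and mixing conventions would silently rescale the TL axis.
`infer_baseline_d15n` recovers the baseline implied by a published TL table
by least squares (the closed form is the mean of δ¹⁵N − 3.4·(TL − 2)).

The nitrogen trophic enrichment factor scales with consumer trophic position:
Δ¹⁵N = 5.92 − 0.27·δ¹⁵N_consumer, so a consumer at δ¹⁵N ≈ 14 ‰ enriches by
~2.1 ‰ rather than the textbook 3.4 ‰. A group's TEF mean and SD come from
its members' values; the SD is therefore 0.27 × the group's δ¹⁵N SD. Carbon
enrichment is fixed at 1.0 ± 0.4 ‰. Group summaries use the sample (n − 1)
SD; single-member groups report SD 0 and carry a flag rather than being
dropped.

## Mixing model

For K sources with isotope means μ_k, SDs σ_k, TEF means Δ_k and TEF SDs τ_k,
each consumer observation is modelled per isotope as

    x ~ Normal( Σ_k p_k (μ_k + Δ_k),  Σ_k p_k² (σ_k² + τ_k²) + σ_res² )

with p ~ Dirichlet(1, …, 1) and, by default, a per-isotope residual SD σ_res
with a half-Cauchy(1 ‰) prior. The residual term is what lets the model
remain coherent when a consumer sits outside the TEF-corrected source hull
(as real consumers often do); it can be toggled off, and the brute-force
oracle comparisons run with it off so the quadrature stays low-dimensional.

Source and TEF uncertainty enter the consumer variance analytically
(Σ p²(σ² + τ²)) rather than by resampling sources per individual; the
synthetic-data generator uses the identical expression, so simulator and
likelihood are exactly conjugate and parameter-recovery tests measure the
inference, not a model mismatch.

Sampling is random-walk Metropolis on the ILR transform of p (plus the log
residual SDs), with the exact Jacobian term (Σ log p_k) so the chain targets
the stated posterior over p. Proposals adapt only during burn-in: the first
half tunes a scalar step toward ~30% acceptance, the second half additionally
learns the empirical proposal covariance (Haario-style adaptive Metropolis),
which is what makes the near-degenerate posteriors tractable — with K sources
and two isotopes the mean constraints leave a (K − 3)-dimensional ridge that
only the variance structure and the prior soften. The proposal is frozen
before any retained draw. Defaults: 4 chains, 20 000 iterations, half
burn-in, thin 10.

Convergence is checked with split Gelman–Rubin R-hat (threshold 1.1) and
Geweke z-scores (first 10% vs last 50% of each chain, spectral-density-at-zero
standard errors estimated by Bartlett-weighted autocovariance truncation).
Per-proportion Geweke scores are combined across chains (Stouffer) and gated
at a Bonferroni-adjusted two-sided 5% familywise threshold, floored at |z| = 2:
with C chains × K proportions, a fixed |z| ≤ 2 rule would flag a perfectly
calibrated sampler with probability ≈ 1 − 0.95^(CK), so the familywise
correction keeps the false-flag rate at the intended 5% regardless of K.
Failures set `converged=False` on the result; they never raise, so callers
can rerun longer.

Source merging follows the two-key rule: a pair merges only when its
posterior proportion correlation exceeds 0.5 in magnitude (strictly — a
correlation of exactly ±0.5 does not merge) *and* the user has declared the
pair ecologically similar. Similarity cannot be read off isotopes, so it is
always an explicit input. Transitive chains resolve by union-find. The
combined source takes the unweighted mean of member means and a
moment-matched SD, sqrt(mean of variances + variance of means); TEFs pool the
same way. The caller refits the reduced problem under the same MCMC settings.
Note the two-source corner case: with K = 2 the proportions are perfectly
anti-correlated by construction, so any flagged two-source pair merges.

With no consumers the posterior equals the prior (each mean 1/K); with a
single source the posterior is the point mass p = 1.

## Depth-covariate mixing

Individual diets follow p_i = ilr⁻¹(α + β·d_i) where d_i is depth
standardised to mean 0, SD 1 (ddof = 0) over the fitted individuals, and the
ILR basis is the Helmert-type default (first coordinate √½·log(p₁/p₂)).
Priors are Normal(0, 1) on α and β on the standardised scale — weakly
informative unit-scale coefficients. The likelihood given p_i is identical to
the plain model's. Curves report the per-source posterior mean and central
95% band over a depth grid limited to 10% extrapolation beyond the observed
range; mean curves sum to one at every depth by construction, and because
standardisation is internal, the curves are invariant to affine changes of
the raw depth units. Crossings of mean curves (where two sources exchange
dominance) are reported descriptively by linear interpolation of sign
changes; no changepoint test is implied. Coefficients are basis-dependent;
curves are not — the basis is recorded on the fit object.

The simulator uses the same standardisation convention (mean/SD of the
group's consumers, ddof 0), so simulated (α, β) and fitted (α, β) share a
scale and coverage checks compare like with like.

## Penalized additive models

Each smooth is a cubic B-spline basis (k = 10 functions by default; k ≥ 4
required) with interior knots at quantiles of the distinct covariate values
and a curvature penalty ∫f″² computed exactly (two-point Gauss–Legendre per
knot interval — second derivatives of cubics are piecewise linear). Each
smooth is centred (sum-to-zero over the observed design) next to a global
intercept. The penalty null space is exactly the linear functions, verified
via Greville-abscissa coefficients.

Smoothing parameters minimise GCV = n·RSS/(n − γ·tr H)² by coordinate descent
over a log₁₀ λ grid on [−4, 4] in 0.25 steps, at least two sweeps and then
polished until no single-term grid move improves the score (so reported λs
are grid-local minima). The effective-df inflation γ = 1.4 is the standard
guard against GCV's tendency to undersmooth at moderate n; γ = 1 recovers the
classical criterion.

Model selection fits every non-empty candidate subset up to four terms and
ranks by AICc (Gaussian, with k = γ·tr H + 1 effective parameters). Two
selection-specific devices are enabled by default in `select_model`:

- a null-space shrinkage penalty per smooth (the analogue of mgcv's
  `select=TRUE`), searched on its own coarse grid, so smoothness selection
  can remove an uninformative term entirely instead of always retaining a
  free linear degree of freedom; and
- a stronger γ = 3 during selection, plus the standard
  information-criterion equivalence reading: models within 2 AICc units of
  the minimum are treated as tied and the tie breaks toward fewer terms, then
  lower GCV.

Without these, subset selection admits a spurious smooth whenever its
GCV-optimised fit to noise clears a ~χ²(1) bar (~15% per candidate), which is
simply what unpenalised-null-space GCV/AICc selection does; with them, the
depth-only generative scenario is recovered in ~95% of replicates. Estimation
fits (`fit_additive`) keep γ = 1.4 and no shrinkage.

Per-term F statistics compare the residual sum of squares with and without
the term at fixed smoothing parameters, on edf and n − tr H degrees of
freedom; they are labelled approximate and should be read as screening
statistics, not exact tests. Reported fit statistics: AICc, GCV, %deviance
(1 − RSS/TSS), adjusted r², per-term edf. Fits are Gaussian identity-link
only, matching continuous δ responses.

## Synthetic surveys

The generator draws each consumer from the mixing likelihood itself, with an
additional per-isotope process SD (default 0.3 ‰) representing individual
physiology and tissue-turnover noise. Stations are evenly spaced over the
depth range (default 24 stations, 10–90 m); surface temperature, bottom
temperature, salinity and Chl-a are deterministic monotone functions of depth
plus seeded noise, emulating a shelf gradient from warm, fresher, productive
shallows to cool, saltier, oligotrophic deep water. Consumers are assigned to
stations round-robin. A single scenario seed spawns per-group substreams, so
adding a consumer group never perturbs existing groups' draws. Per-station
baseline offsets can be added to both isotopes and are stored for exact
inversion. Groups may eat a named subset of the scenario's sources.

What the simulator does *not* emulate: spatial autocorrelation beyond
per-station offsets, seasonality, tissue-specific turnover, size-structured
diets, concentration dependence, and source isotope distributions that vary
by station. Passing recovery tests therefore demonstrate that the inference
machinery is correct under the model's own assumptions — not that the model
is adequate for any particular field dataset.

## Reference summaries and benchmark problems

`trophlink.reference` embeds the published Beibu Gulf functional-group
summary table (17 groups; n, δ¹³C and δ¹⁵N means ± SD, trophic levels) from
an August 2022 bottom-trawl survey. Because the per-individual data are not
public, benchmark mixing problems simulate consumers at the printed group
mean ± SD and sample size. The acceptance script averages each benchmark's
posterior-mean diet share over 16 independently simulated surveys — the
single-survey value is unbiased but noisy at n = 14–30 consumers, and the
average estimates the same quantity with √16-fold less simulation noise.
Problem sizes used throughout the tests (n = 100 consumers for recovery
studies, 50/30/15-seed replications, 16 000–20 000 MCMC iterations, n = 200
for selection studies) were chosen as the smallest sizes at which the checked
properties are statistically stable.

## Known limitations

- The mixing model has no concentration dependence and no informative priors
  from stomach contents (stomach contents inform topology only).
- Metropolis sampling mixes slowly on strongly under-determined problems
  (many sources, two isotopes, tight source SDs); R-hat gates surface this
  rather than hide it, and reruns with more iterations are the remedy.
- The additive models fit no interactions, tensor products or spatial
  smooths.
- Geweke standard errors use a Bartlett-truncated long-run variance; very
  short retained chains (< ~100 draws in the early window) cannot be
  diagnosed and are reported as NaN with `converged=False`.
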