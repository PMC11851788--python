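# trophlink

Stable-isotope food-web analysis for shelf-sea fish communities: trophic-level
estimation, Bayesian diet mixing models with a continuous depth covariate, and
penalized additive models relating isotope values to environmental gradients.

The package targets the kind of question asked about the Beibu Gulf
(northwestern South China Sea) fish community: which carbon pathways (benthic
vs pelagic) feed which functional groups, and how does that benthic–pelagic
coupling change along the 10–90 m depth gradient? It is written for trophic
ecologists working with bulk δ¹³C/δ¹⁵N tissue measurements, stomach-content
link tables and station environment data.

## What it computes

**Isotope preprocessing** (`trophlink.prep`)

- δ notation: δX = (R_sample/R_standard − 1)·10³ (‰, PDB / atmospheric N₂).
- Lipid normalisation for C:N > 3.5: δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N.
- Spatial baseline correction per station:
  δX′ = δX_consumer − δX_local baseline + δX_mean baseline,
  with a filter-feeding bivalve as the recommended baseline taxon.
- Trophic level: TL = λ + (δ¹⁵N − δ¹⁵N_base)/Δ¹⁵N with λ = 2 and
  Δ¹⁵N = 3.4 ‰.
- Proportional nitrogen TEF: Δ¹⁵N = 5.92 − 0.27·δ¹⁵N_consumer, used by the
  mixing models instead of the constant 3.4 ‰ (carbon TEF is 1.0 ± 0.4 ‰).

**Bayesian mixing model** (`trophlink.mixing`) — each consumer observation
x_ij (individual i, isotope j) follows

    x_ij ~ Normal( Σ_k p_k (μ_kj + Δ_kj),  Σ_k p_k² (σ_kj² + τ_kj²) + σ_res,j² )

with diet proportions p on the simplex under a flat Dirichlet prior and an
optional per-isotope residual SD (half-Cauchy prior). Sampling is adaptive
random-walk Metropolis on the ILR transform of p; every fit reports posterior
means ± SD, central 25/50/75/95% credible intervals, split Gelman–Rubin R-hat
and Geweke z diagnostics, and the posterior correlation matrix between source
proportions. Sources whose proportions correlate with |r| > 0.5 *and* that the
user flags as ecologically similar are merged (moment-matched pooling) and the
model is rerun. Group-level topologies come from stomach-content species
links, and per-group posteriors assemble into a consumer × prey diet matrix.

**Depth-covariate mixing** (`trophlink.covariate`) — diet varies continuously
with depth through a linear model on the ILR scale, p_i =
ilr⁻¹(α + β·depth_i), with Normal(0, 1) priors on standardised depth; the
output is a per-source diet-vs-depth curve with a 95% band.

**Penalized additive models** (`trophlink.gam`) — Gaussian additive
regressions of δ¹³C or δ¹⁵N on Depth, SsTemp, BotTemp, Salinity and Chl-a,
with cubic B-spline smooths, curvature penalties chosen by GCV
(GCV = n·RSS/(n − γ·tr H)²) on a log₁₀ λ grid, and exhaustive AICc subset
selection capped at four variables.

**Synthetic surveys** (`trophlink.synthetic`) — forward simulation from known
diets (optionally depth-varying) over a station grid with depth-linked
temperature/salinity/Chl-a, plus per-station baseline offsets, so every stage
can be tested against ground truth.

**Pipeline** (`trophlink.pipeline`, CLI `trophlink`) — config-driven
orchestration: simulate/ingest → prep → topology → mixing (+ merge/rerun) →
depth-covariate mixing → additive-model selection, with a reproducibility
manifest.

## Worked example

Run the built-in demo survey (three basal sources, a bivalve
suspension-feeder baseline, zooplankton, and a planktivorous fish group whose
diet shifts with depth):

```bash
trophlink run --out demo_run --seed 0
```

The diet matrix (`demo_run/mixing/diet_matrix.csv`, posterior mean with SD in
parentheses; blank cells are non-links) comes out as:

| consumer | phytoplankton | pom | som | zooplankton | plankton_pool |
|---|---|---|---|---|---|
| benthic_suspension_feeder | 0.84(0.04) | 0.09(0.05) | 0.07(0.04) | | |
| planktivorous_fish | 0.25(0.04) | | | 0.75(0.04) | |
| zooplankton | | | | | 1.00(0.00) |

The suspension feeder is recovered as overwhelmingly phytoplankton-fed (true
share 0.90), and the zooplankton row shows the source-merging rule in action:
in a two-source model the proportions are perfectly anti-correlated, so the
flagged POM/phytoplankton pair merges into a single `plankton_pool`.
`demo_run/covariate/planktivorous_fish_curves.csv` holds the fish group's
diet-vs-depth curves: the posterior mean zooplankton share rises from 0.69
(95% band 0.55–0.83) at 10 m to 0.80 (0.65–0.91) at 90 m while the
phytoplankton share falls from 0.31 to 0.20 — the simulated weakening of
direct pelagic grazing with depth. Every mixing stage's summary CSV carries
its R-hat and Geweke diagnostics, and the run manifest
(`demo_run/manifest.json`) echoes the seed, the full configuration and its
hash, so the same command reproduces byte-identical summaries.

For a single group outside the pipeline:

```python
import numpy as np
from trophlink import MixingProblem, fit_mixture
from trophlink.reference import build_benchmark

problem, meta = build_benchmark("benthic_suspension_feeder", seed=1)
post = fit_mixture(problem, chains=4, iterations=20000, seed=1)
print(post.summary_frame().round(3))   # means, CIs, R-hat, Geweke z per source
```

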