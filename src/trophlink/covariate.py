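"""Continuous-covariate extension of the mixing model.

Diet proportions vary with station depth through a linear model on the ILR
scale: individual i at standardised depth d_i eats with proportions

    p_i = inverse_ilr( alpha + beta * d_i )

and its isotope likelihood is exactly the plain mixing model's given p_i.
Priors are weakly informative Normal(0, 1) on alpha and beta (depth is
standardised to mean 0, SD 1 internally, so these are unit-scale
coefficients). The output of interest is the diet-versus-depth curve per
source with a 95% posterior band.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositions import helmert_basis, inverse_ilr
from .datatypes import SourceSummary
from .diagnostics import combined_geweke, familywise_z_threshold, gelman_rubin
from .mixing import MixingProblem, _run_rw_chain

__all__ = ["CovariateProblem", "CovariateFit", "fit_covariate_mixture", "diet_curves", "curve_crossings"]


@dataclass
class CovariateProblem:
    """Mixing problem plus one continuous covariate value per individual."""

    consumers: np.ndarray  # (n, 2)
    sources: list[SourceSummary]
    covariate: np.ndarray  # (n,) raw covariate (depth, m)
    residual_error: bool = True
    residual_scale: float = 1.0
    coef_prior_sd: float = 1.0

    def __post_init__(self) -> None:
        self.consumers = np.atleast_2d(np.asarray(self.consumers, dtype=float))
        self.covariate = np.asarray(self.covariate, dtype=float)
        if self.consumers.shape[1] != 2:
            raise ValueError("consumers must be an (n, 2) array")
        if self.covariate.shape != (self.consumers.shape[0],):
            raise ValueError("covariate must supply one value per consumer")
        if not np.all(np.isfinite(self.consumers)) or not np.all(np.isfinite(self.covariate)):
            raise ValueError("consumer observations and covariate must be finite")
        if len(self.sources) < 2:
            raise ValueError("covariate mixing needs K >= 2 sources")
        if self.covariate.std(ddof=0) == 0:
            raise ValueError(
                "covariate is constant across individuals; use the plain fit_mixture instead"
            )

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sources]

    def standardised(self) -> tuple[np.ndarray, float, float]:
        """(standardised covariate, centre, scale) with ddof=0 scaling."""
        c = float(self.covariate.mean())
        s = float(self.covariate.std(ddof=0))
        return (self.covariate - c) / s, c, s

    def as_plain(self) -> MixingProblem:
        return MixingProblem(
            consumers=self.consumers,
            sources=self.sources,
            residual_error=self.residual_error,
            residual_scale=self.residual_scale,
        )


@dataclass
class CovariateFit:
    """Posterior over ILR intercepts/slopes and derived diet curves."""

    labels: list[str]
    alpha_draws: np.ndarray  # (n_chains, n_draws, K-1)
    beta_draws: np.ndarray   # (n_chains, n_draws, K-1)
    residual_draws: np.ndarray | None
    covariate_centre: float
    covariate_scale: float
    covariate_range: tuple[float, float]
    basis: np.ndarray
    rhat: np.ndarray        # over all coefficients (alpha then beta)
    geweke_z: np.ndarray
    converged: bool
    acceptance: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_sources(self) -> int:
        return len(self.labels)

    def pooled_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        ka = self.alpha_draws.shape[-1]
        return (
            self.alpha_draws.reshape(-1, ka),
            self.beta_draws.reshape(-1, ka),
        )

    def coefficient_summary(self) -> pd.DataFrame:
        a, b = self.pooled_coefficients()
        rows = []
        for j in range(a.shape[1]):
            for name, draws in (("alpha", a[:, j]), ("beta", b[:, j])):
                rows.append(
                    {
                        "coefficient": f"{name}_{j+1}",
                        "mean": draws.mean(),
                        "sd": draws.std(ddof=1),
                        "ci95_lo": np.quantile(draws, 0.025),
                        "ci95_hi": np.quantile(draws, 0.975),
                    }
                )
        return pd.DataFrame(rows).set_index("coefficient")

    def proportions_at(self, depth) -> np.ndarray:
        """Posterior draws of p at the given raw depth(s): (S, len(depth), K)."""
        depth = np.atleast_1d(np.asarray(depth, dtype=float))
        d_std = (depth - self.covariate_centre) / self.covariate_scale
        a, b = self.pooled_coefficients()
        z = a[:, None, :] + d_std[None, :, None] * b[:, None, :]
        return inverse_ilr(z, self.basis)


def fit_covariate_mixture(
    problem: CovariateProblem,
    *,
    chains: int = 4,
    iterations: int = 20_000,
    burn_in: int | None = None,
    thin: int = 10,
    seed: int = 0,
    fix_slope: bool = False,
) -> CovariateFit:
    """Sample the covariate mixing posterior by random-walk Metropolis.

    ``fix_slope=True`` pins beta at zero (every individual shares one diet),
    which is the degenerate model used to cross-check against the plain
    mixing fit.
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if burn_in is None:
        burn_in = iterations // 2
    if not (0 < burn_in < iterations):
        raise ValueError("need 0 < burn_in < iterations")

    k = problem.n_sources
    kc = k - 1
    basis = helmert_basis(k)
    d_std, centre, scale = problem.standardised()
    x = problem.consumers
    n = x.shape[0]
    mu = np.array([s.shifted_mu for s in problem.sources])   # (K, 2)
    var = np.array([s.pooled_var for s in problem.sources])  # (K, 2)
    with_res = problem.residual_error
    res_scale = problem.residual_scale
    prior_sd2 = problem.coef_prior_sd**2
    log2pi = np.log(2 * np.pi)
    n_beta = 0 if fix_slope else kc
    n_dim = kc + n_beta + (2 if with_res else 0)

    def logpdf(theta: np.ndarray) -> float:
        a = theta[:kc]
        b = theta[kc : kc + n_beta] if n_beta else np.zeros(kc)
        z = a[None, :] + d_std[:, None] * b[None, :]   # (n, K-1)
        y = z @ basis                                   # (n, K)
        y -= y.max(axis=1, keepdims=True)
        e = np.exp(y)
        p = e / e.sum(axis=1, keepdims=True)
        res2 = 0.0
        log_prior = -0.5 * float(np.sum(theta[: kc + n_beta] ** 2)) / prior_sd2
        if with_res:
            eta = theta[kc + n_beta :]
            sig = np.exp(eta)
            res2 = sig**2
            log_prior += float(np.sum(-np.log1p((sig / res_scale) ** 2) + eta))
        m = p @ mu                    # (n, 2)
        v = (p**2) @ var + res2       # (n, 2)
        if np.any(v <= 0):
            return -np.inf
        loglik = -0.5 * float(np.sum(log2pi + np.log(v) + (x - m) ** 2 / v))
        return loglik + log_prior

    data_sd = x.std(axis=0, ddof=0) if n > 1 else np.ones(2)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    alpha_c, beta_c, res_c, acc = [], [], [], []
    for cs in seeds:
        rng = np.random.default_rng(cs)
        x0 = np.zeros(n_dim)
        x0[: kc + n_beta] = 0.3 * rng.standard_normal(kc + n_beta)
        if with_res:
            x0[kc + n_beta :] = np.log(np.maximum(0.5 * data_sd, 0.05)) + 0.3 * rng.standard_normal(2)
        kept, rate = _run_rw_chain(logpdf, x0, iterations, burn_in, thin, rng, step0=0.15)
        alpha_c.append(kept[:, :kc])
        if n_beta:
            beta_c.append(kept[:, kc : kc + n_beta])
        else:
            beta_c.append(np.zeros((kept.shape[0], kc)))
        if with_res:
            res_c.append(np.exp(kept[:, kc + n_beta :]))
        acc.append(rate)

    alpha_draws = np.array(alpha_c)
    beta_draws = np.array(beta_c)
    residual = np.array(res_c) if with_res else None

    coef_draws = np.concatenate([alpha_draws, beta_draws], axis=2) if n_beta else alpha_draws
    rhat = np.atleast_1d(gelman_rubin(coef_draws))
    try:
        gz = combined_geweke(coef_draws)
    except ValueError:  # kept chains too short to diagnose
        gz = np.full(coef_draws.shape[-1], np.nan)
    z_thresh = familywise_z_threshold(coef_draws.shape[-1])
    converged = bool(
        np.all(rhat <= 1.1) and not np.any(np.isnan(gz)) and np.all(np.abs(gz) <= z_thresh)
    )

    return CovariateFit(
        labels=problem.labels,
        alpha_draws=alpha_draws,
        beta_draws=beta_draws,
        residual_draws=residual,
        covariate_centre=centre,
        covariate_scale=scale,
        covariate_range=(float(problem.covariate.min()), float(problem.covariate.max())),
        basis=basis,
        rhat=rhat,
        geweke_z=gz,
        converged=converged,
        acceptance=np.asarray(acc),
    )


def diet_curves(fit: CovariateFit, grid) -> pd.DataFrame:
    """Per-source posterior mean and 95% band of diet share along the grid.

    The grid may extend at most 10% of the observed covariate span beyond
    either end (mixing-model extrapolation is not meaningful further out).
    Mean curves sum to one at every grid depth by construction.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    lo, hi = fit.covariate_range
    span = hi - lo
    if grid.min() < lo - 0.1 * span or grid.max() > hi + 0.1 * span:
        raise ValueError(
            f"grid extends beyond 10% extrapolation of the observed range [{lo}, {hi}]"
        )
    p = fit.proportions_at(grid)  # (S, G, K)
    mean = p.mean(axis=0)
    lo95 = np.quantile(p, 0.025, axis=0)
    hi95 = np.quantile(p, 0.975, axis=0)
    rows = []
    for gi, depth in enumerate(grid):
        for ki, lab in enumerate(fit.labels):
            rows.append(
                {
                    "depth": depth,
                    "source": lab,
                    "mean": mean[gi, ki],
                    "lo95": lo95[gi, ki],
                    "hi95": hi95[gi, ki],
                }
            )
    return pd.DataFrame(rows)


def curve_crossings(curves: pd.DataFrame, source_a: str, source_b: str) -> list[float]:
    """Depths where two sources' mean diet-share curves cross.

    Descriptive only (sign changes of the mean-curve difference with linear
    interpolation); not a changepoint test.
    """
    a = curves[curves["source"] == source_a].sort_values("depth")
    b = curves[curves["source"] == source_b].sort_values("depth")
    if a.empty or b.empty:
        raise ValueError("both sources must appear in the curve table")
    depth = a["depth"].to_numpy()
    diff = a["mean"].to_numpy() - b["mean"].to_numpy()
    out = []
    for i in range(len(diff) - 1):
        if diff[i] == 0.0:
            out.append(float(depth[i]))
        elif diff[i] * diff[i + 1] < 0:
            t = diff[i] / (diff[i] - diff[i + 1])
            out.append(float(depth[i] + t * (depth[i + 1] - depth[i])))
    if diff[-1] == 0.0:
        out.append(float(depth[-1]))
    return out
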