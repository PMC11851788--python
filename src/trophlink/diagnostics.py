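"""MCMC convergence diagnostics: split Gelman-Rubin R-hat and Geweke z.

These are the two checks run on every mixing-model fit, mirroring standard
Bayesian mixing-model practice: R-hat compares between- and within-chain
variance (values near 1 indicate the chains explore the same distribution),
and the Geweke statistic compares the mean of an early window of a single
chain against a late window, standardised by spectral-density-at-zero
standard errors so autocorrelation is accounted for.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import norm


def gelman_rubin(chains, split: bool = True) -> np.ndarray | float:
    """Potential scale reduction factor R-hat.

    Parameters
    ----------
    chains
        Array of shape (n_chains, n_draws) or (n_chains, n_draws, n_params).
    split
        Split each chain into halves first (detects trending chains that a
        plain between/within comparison misses).

    Returns a scalar for 2-d input, an array of length n_params otherwise.
    """
    x = np.asarray(chains, dtype=float)
    scalar = x.ndim == 2
    if scalar:
        x = x[..., None]
    if x.ndim != 3:
        raise ValueError("chains must be (n_chains, n_draws[, n_params])")
    c, s, p = x.shape
    if c < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if split:
        half = s // 2
        if half < 2:
            raise ValueError("chains too short to split")
        x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
        c, s, p = x.shape

    chain_means = x.mean(axis=1)                    # (c, p)
    within = x.var(axis=1, ddof=1).mean(axis=0)     # W, (p,)
    between_over_n = chain_means.var(axis=0, ddof=1)  # B/n, (p,)
    var_plus = (s - 1) / s * within + between_over_n

    rhat = np.empty(p)
    for j in range(p):
        if within[j] == 0:
            rhat[j] = 1.0 if between_over_n[j] == 0 else np.inf
        else:
            rhat[j] = np.sqrt(var_plus[j] / within[j])
    return float(rhat[0]) if scalar else rhat


def spectral_density_at_zero(x: np.ndarray) -> float:
    """Newey-West (Bartlett-weighted) estimate of the spectral density at
    frequency zero, i.e. the long-run variance of the chain segment."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    lag = min(n - 1, max(0, int(4 * (n / 100.0) ** (2.0 / 9.0))))
    acov = np.correlate(x, x, mode="full")[n - 1 : n + lag] / n
    if lag == 0:
        return float(acov[0])
    weights = 1.0 - np.arange(1, lag + 1) / (lag + 1.0)
    return float(acov[0] + 2.0 * np.sum(weights * acov[1:]))


def geweke(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for a single chain.

    Compares the mean of the first ``first`` fraction of the chain with the
    mean of the last ``last`` fraction; under stationarity z ~ N(0, 1).
    """
    x = np.asarray(chain, dtype=float)
    if not (0 < first < 1 and 0 < last < 1 and first + last <= 1):
        raise ValueError("window fractions must be in (0,1) and not overlap")
    n = x.size
    n_a = int(np.floor(first * n))
    n_b = int(np.floor(last * n))
    if n_a < 10 or n_b < 10:
        raise ValueError(f"chain of length {n} too short for Geweke windows")
    if x.max() == x.min():  # constant chain: both window means agree exactly
        return 0.0
    a = x[:n_a]
    b = x[n - n_b :]
    diff = a.mean() - b.mean()
    if diff == 0.0:
        return 0.0
    se2 = spectral_density_at_zero(a) / n_a + spectral_density_at_zero(b) / n_b
    if se2 <= 0:
        return np.inf if diff > 0 else -np.inf
    return float(diff / np.sqrt(se2))


def combined_geweke(chain_draws: np.ndarray) -> np.ndarray:
    """Stouffer-combined Geweke z per parameter across chains.

    ``chain_draws`` has shape (n_chains, n_draws, n_params). The per-chain
    z-scores are each ~N(0,1) under convergence, so their scaled sum is too.
    """
    x = np.asarray(chain_draws, dtype=float)
    c, _, p = x.shape
    z = np.array([[geweke(x[i, :, j]) for j in range(p)] for i in range(c)])
    return z.sum(axis=0) / np.sqrt(c)


def familywise_z_threshold(n_tests: int, alpha: float = 0.05, floor: float = 2.0) -> float:
    """Two-sided Bonferroni |z| threshold across ``n_tests`` comparisons,
    never below ``floor``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return max(floor, float(norm.isf(alpha / 2.0 / n_tests)))
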