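"""Bayesian stable-isotope mixing model for diet proportions.

The model inverts consumer isotope signatures onto a simplex of diet
proportions p over K sources. Each consumer observation x_ij (individual i,
isotope j in (d13c, d15n)) is modelled as

    x_ij ~ Normal( sum_k p_k (mu_kj + tef_kj),
                   sum_k p_k^2 (sigma_kj^2 + tau_kj^2) [+ sigma_res_j^2] )

with a Dirichlet prior on p (flat by default) and, optionally, a per-isotope
residual standard deviation with a half-Cauchy prior. Sampling is random-walk
Metropolis on the ILR transform of p (unconstrained space), with the exact
Jacobian correction so the chain targets the stated posterior over p.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .compositions import helmert_basis
from .datatypes import SourceSummary
from .diagnostics import combined_geweke, familywise_z_threshold, gelman_rubin

__all__ = [
    "MixingProblem",
    "MixingPosterior",
    "DietMatrix",
    "MergeRecord",
    "log_posterior",
    "fit_mixture",
    "merge_sources",
    "build_topology",
    "assemble_diet_matrix",
]

#: central credible-interval levels reported for every proportion
CI_LEVELS = (0.25, 0.50, 0.75, 0.95)


@dataclass
class MixingProblem:
    """Consumer observations plus the sources they may have eaten."""

    consumers: np.ndarray  # (n, 2) = (d13c, d15n) per individual
    sources: list[SourceSummary]
    alpha: np.ndarray | None = None  # Dirichlet prior concentration, default all-ones
    residual_error: bool = True
    residual_scale: float = 1.0  # half-Cauchy scale for the residual SD, per-mil

    def __post_init__(self) -> None:
        self.consumers = np.atleast_2d(np.asarray(self.consumers, dtype=float))
        if self.consumers.shape[1] != 2:
            raise ValueError("consumers must be an (n, 2) array of (d13c, d15n)")
        if not np.all(np.isfinite(self.consumers)):
            raise ValueError("consumer observations must be finite")
        if len(self.sources) < 1:
            raise ValueError("need at least one source")
        if self.alpha is None:
            self.alpha = np.ones(self.n_sources)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (self.n_sources,) or np.any(self.alpha <= 0):
            raise ValueError("alpha must be a positive vector, one entry per source")
        if self.residual_scale <= 0:
            raise ValueError("residual_scale must be > 0")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def n_consumers(self) -> int:
        return self.consumers.shape[0]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sources]

    def shifted_means(self) -> np.ndarray:
        """(K, 2) TEF-corrected source means."""
        return np.array([s.shifted_mu for s in self.sources])

    def pooled_vars(self) -> np.ndarray:
        """(K, 2) source-plus-TEF variances."""
        return np.array([s.pooled_var for s in self.sources])

    def sufficient_stats(self) -> tuple[int, np.ndarray, np.ndarray]:
        """(n, per-isotope mean, per-isotope centered sum of squares).

        The Gaussian likelihood only touches the data through these, which
        keeps the MCMC inner loop O(K) instead of O(nK).
        """
        n = self.n_consumers
        if n == 0:  # no data: the posterior is the prior
            return 0, np.zeros(2), np.zeros(2)
        xbar = self.consumers.mean(axis=0)
        ss = ((self.consumers - xbar) ** 2).sum(axis=0)
        return n, xbar, ss


def _check_simplex(p: np.ndarray, k: int) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (k,):
        raise ValueError(f"p must have shape ({k},), got {p.shape}")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must lie on the simplex (entries >= 0, sum to 1)")
    return p


def log_posterior(p, problem: MixingProblem, residual_sd=None) -> float:
    """Unnormalised log posterior density of the proportion vector.

    ``residual_sd`` is the per-isotope residual SD pair; ``None`` evaluates
    the density with the residual term at zero (the pure mixing likelihood).
    """
    p = _check_simplex(p, problem.n_sources)
    mu = problem.shifted_means()
    var = problem.pooled_vars()
    n, xbar, ss = problem.sufficient_stats()

    res2 = np.zeros(2)
    if residual_sd is not None:
        res2 = np.asarray(residual_sd, dtype=float) ** 2

    m = p @ mu
    v = (p**2) @ var + res2
    if np.any(v <= 0):
        return -np.inf
    loglik = -0.5 * np.sum(n * np.log(2 * np.pi * v) + (ss + n * (xbar - m) ** 2) / v)

    a = problem.alpha
    nonflat = a != 1.0
    if np.any(nonflat & (p == 0.0)):
        return -np.inf if np.any(a[nonflat & (p == 0.0)] > 1.0) else np.inf
    log_prior = float(gammaln(a.sum()) - gammaln(a).sum())
    if np.any(nonflat):
        log_prior += float(np.sum((a[nonflat] - 1.0) * np.log(p[nonflat])))
    return float(loglik + log_prior)


@dataclass
class MixingPosterior:
    """Posterior draws of diet proportions with summaries and diagnostics."""

    labels: list[str]
    draws: np.ndarray  # (n_chains, n_draws, K), every draw on the simplex
    mean: np.ndarray
    sd: np.ndarray
    ci: dict[float, np.ndarray]  # level -> (2, K) lower/upper central bounds
    rhat: np.ndarray
    geweke_z: np.ndarray  # chain-combined z per proportion
    correlation: np.ndarray  # (K, K) posterior proportion correlations
    converged: bool
    acceptance: np.ndarray = field(default_factory=lambda: np.array([]))
    residual_draws: np.ndarray | None = None  # (n_chains, n_draws, 2) SDs

    @property
    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        rows["mean"] = self.mean
        rows["sd"] = self.sd
        for level in CI_LEVELS:
            lo, hi = self.ci[level]
            rows[f"ci{int(level * 100)}_lo"] = lo
            rows[f"ci{int(level * 100)}_hi"] = hi
        rows["rhat"] = self.rhat
        rows["geweke_z"] = self.geweke_z
        return pd.DataFrame(rows, index=pd.Index(self.labels, name="source"))


def _summarise(labels, chain_draws, acceptance, residual=None) -> MixingPosterior:
    pooled = chain_draws.reshape(-1, chain_draws.shape[-1])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=1) if pooled.shape[0] > 1 else np.zeros(pooled.shape[1])
    ci = {}
    for level in CI_LEVELS:
        tail = (1.0 - level) / 2.0
        ci[level] = np.quantile(pooled, [tail, 1.0 - tail], axis=0)
    k = pooled.shape[1]
    if k == 1 or np.any(pooled.std(axis=0) == 0):
        corr = np.eye(k)
    else:
        corr = np.corrcoef(pooled.T)
    if chain_draws.shape[0] >= 2 and np.all(pooled.std(axis=0) > 0):
        rhat = np.atleast_1d(gelman_rubin(chain_draws))
        try:
            gz = combined_geweke(chain_draws)
        except ValueError:  # kept chains too short to diagnose
            gz = np.full(k, np.nan)
    else:  # degenerate (K = 1) posteriors are trivially converged
        rhat = np.ones(k)
        gz = np.zeros(k)
    z_thresh = familywise_z_threshold(k)
    converged = bool(
        np.all(rhat <= 1.1) and not np.any(np.isnan(gz)) and np.all(np.abs(gz) <= z_thresh)
    )
    return MixingPosterior(
        labels=list(labels),
        draws=chain_draws,
        mean=mean,
        sd=sd,
        ci=ci,
        rhat=rhat,
        geweke_z=gz,
        correlation=corr,
        converged=converged,
        acceptance=np.asarray(acceptance),
        residual_draws=residual,
    )


def _run_rw_chain(logpdf, x0, iterations, burn_in, thin, rng, step0=0.3):
    """Adaptive random-walk Metropolis; adaptation only during burn-in.

    The first half of burn-in adapts a scalar step size toward ~30%
    acceptance; the second half additionally learns the empirical proposal
    covariance of the history (Haario-style adaptive Metropolis), which
    handles the strong correlations of near-degenerate mixing posteriors.
    The proposal is frozen before any retained draw, so the kept chain is a
    valid Metropolis sample.
    """
    x = np.array(x0, dtype=float)
    d = x.size
    lp = logpdf(x)
    if not np.isfinite(lp):
        raise RuntimeError("invalid chain initialisation (non-finite log density)")
    step = step0
    chol = np.eye(d)
    history = np.empty((burn_in, d))
    kept = []
    accepted_total = 0
    acc_batch = 0
    batch = 50
    cov_update = max(200, burn_in // 10)
    for t in range(iterations):
        prop = x + step * (chol @ rng.standard_normal(d))
        lpp = logpdf(prop)
        if np.log(rng.random()) < lpp - lp:
            x, lp = prop, lpp
            acc_batch += 1
            accepted_total += 1
        if t < burn_in:
            history[t] = x
            if (t + 1) % batch == 0:
                step *= np.exp(acc_batch / batch - 0.3)
                step = min(max(step, 1e-5), 10.0)
                acc_batch = 0
            if t + 1 >= burn_in // 2 and (t + 1) % cov_update == 0:
                recent = history[(t + 1) // 2 : t + 1]
                cov = np.cov(recent.T) + 1e-8 * np.eye(d)
                try:
                    new_chol = np.linalg.cholesky(cov)
                    # renormalise so the scalar step keeps its meaning
                    scale = np.exp(np.mean(np.log(np.diag(new_chol))))
                    if scale > 0:
                        chol = new_chol / scale
                        step = min(max(step * scale, 1e-5), 10.0)
                except np.linalg.LinAlgError:
                    pass
        elif (t + 1) % batch == 0:
            acc_batch = 0
        if t >= burn_in and (t - burn_in) % thin == 0:
            kept.append(x.copy())
    return np.array(kept), accepted_total / iterations


def fit_mixture(
    problem: MixingProblem,
    *,
    chains: int = 4,
    iterations: int = 20_000,
    burn_in: int | None = None,
    thin: int = 10,
    seed: int = 0,
) -> MixingPosterior:
    """Sample the mixing posterior and return summaries plus diagnostics.

    Runs ``chains`` independent adaptive random-walk Metropolis chains on the
    ILR-transformed proportions (with the residual SDs, when enabled, sampled
    jointly on the log scale). A result whose R-hat exceeds 1.1 or whose
    combined Geweke z fails a familywise 5% check is returned with
    ``converged=False`` rather than raised, so callers can rerun longer.
    """
    if chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    if burn_in is None:
        burn_in = iterations // 2
    if not (0 < burn_in < iterations):
        raise ValueError("need 0 < burn_in < iterations")
    k = problem.n_sources

    n, xbar, ss = problem.sufficient_stats()
    mu = problem.shifted_means()
    var = problem.pooled_vars()
    alpha = problem.alpha
    basis = helmert_basis(k) if k >= 2 else None
    with_res = problem.residual_error
    res_scale = problem.residual_scale
    n_z = k - 1
    log2pi = np.log(2 * np.pi)

    def logpdf(theta: np.ndarray) -> float:
        if n_z:
            y = theta[:n_z] @ basis
            y = y - y.max()
            e = np.exp(y)
            p = e / e.sum()
        else:
            p = np.ones(1)
        if np.any(p == 0.0):
            return -np.inf
        logp = np.log(p)
        res2 = 0.0
        log_prior = float(np.sum(alpha * logp))  # (alpha-1)*log p + ILR Jacobian
        if with_res:
            sig = np.exp(theta[n_z:])
            res2 = sig**2
            # half-Cauchy(res_scale) on sigma, plus log-scale Jacobian
            log_prior += float(np.sum(-np.log1p((sig / res_scale) ** 2) + theta[n_z:]))
        m = p @ mu
        v = (p**2) @ var + res2
        if np.any(v <= 0):
            return -np.inf
        loglik = -0.5 * float(np.sum(n * (log2pi + np.log(v)) + (ss + n * (xbar - m) ** 2) / v))
        return loglik + log_prior

    n_dim = n_z + (2 if with_res else 0)
    if n_dim == 0:
        # single source, no residual term: posterior is the point mass p = 1
        n_kept = (iterations - burn_in + thin - 1) // thin
        draws = np.ones((chains, n_kept, 1))
        return _summarise(problem.labels, draws, np.ones(chains))

    data_sd = problem.consumers.std(axis=0, ddof=0) if n > 1 else np.ones(2)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    chain_p, chain_res, acc = [], [], []
    for cs in seeds:
        rng = np.random.default_rng(cs)
        x0 = np.zeros(n_dim)
        if n_z:
            x0[:n_z] = 0.5 * rng.standard_normal(n_z)
        if with_res:
            x0[n_z:] = np.log(np.maximum(0.5 * data_sd, 0.05)) + 0.3 * rng.standard_normal(2)
        kept, rate = _run_rw_chain(logpdf, x0, iterations, burn_in, thin, rng)
        if n_z:
            y = kept[:, :n_z] @ basis
            y -= y.max(axis=1, keepdims=True)
            e = np.exp(y)
            chain_p.append(e / e.sum(axis=1, keepdims=True))
        else:
            chain_p.append(np.ones((kept.shape[0], 1)))
        if with_res:
            chain_res.append(np.exp(kept[:, n_z:]))
        acc.append(rate)

    draws = np.array(chain_p)
    residual = np.array(chain_res) if with_res else None
    return _summarise(problem.labels, draws, acc, residual)


def build_topology(links, group_of) -> dict[str, list[str]]:
    """Collapse species-level predator->prey pairs to functional-group edges.

    A group-level link exists as soon as one member species of the predator
    group eats one member species of the prey group; duplicates collapse.
    """
    unmapped = sorted(
        {sp for pair in links for sp in pair if sp not in group_of}
    )
    if unmapped:
        raise ValueError(f"species not mapped to any functional group: {unmapped}")
    edges: dict[str, set[str]] = {}
    for pred, prey in links:
        edges.setdefault(group_of[pred], set()).add(group_of[prey])
    return {pred: sorted(prey) for pred, prey in sorted(edges.items())}


@dataclass
class MergeRecord:
    members: tuple[str, ...]
    correlations: dict[tuple[str, str], float]
    new_label: str


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _pool_sources(members: list[SourceSummary], label: str) -> SourceSummary:
    """Moment-matched pooling: combined mean is the unweighted mean of member
    means; combined variance is mean(variances) + variance(means)."""
    mu = np.array([s.mu for s in members])
    sd = np.array([s.sd for s in members])
    tmu = np.array([s.tef_mu for s in members])
    tsd = np.array([s.tef_sd for s in members])
    return SourceSummary(
        label=label,
        mu=mu.mean(axis=0),
        sd=np.sqrt((sd**2).mean(axis=0) + mu.var(axis=0)),
        tef_mu=tmu.mean(axis=0),
        tef_sd=np.sqrt((tsd**2).mean(axis=0) + tmu.var(axis=0)),
    )


def merge_sources(
    posterior: MixingPosterior,
    problem: MixingProblem,
    similar,
    threshold: float = 0.5,
    names: dict[frozenset, str] | None = None,
) -> tuple[MixingProblem, list[MergeRecord]]:
    """Merge source pairs whose posterior proportions are strongly
    anti-/correlated (|r| strictly above ``threshold``) *and* that the user
    has flagged as ecologically similar.

    Ecological similarity cannot be inferred from isotopes, so it is always a
    user-supplied list of label pairs. Transitive chains are resolved with
    union-find. The caller is expected to refit the returned problem under
    the same MCMC settings. Returns the (possibly unchanged) problem and a
    merge log.
    """
    labels = problem.labels
    if posterior.labels != labels:
        raise ValueError("posterior and problem source labels disagree")
    similar_pairs = set()
    for a, b in similar:
        if a not in labels or b not in labels:
            raise ValueError(f"similarity flag ({a!r}, {b!r}) names unknown source")
        if a == b:
            raise ValueError(f"similarity flag pairs a source with itself: {a!r}")
        similar_pairs.add(frozenset((a, b)))
    names = names or {}

    corr = posterior.correlation
    idx = {lab: i for i, lab in enumerate(labels)}
    uf = _UnionFind(labels)
    hit_corr: dict[tuple[str, str], float] = {}
    for pair in similar_pairs:
        a, b = sorted(pair)
        r = float(corr[idx[a], idx[b]])
        if abs(r) > threshold:  # strictly greater; ties stay separate
            uf.union(a, b)
            hit_corr[(a, b)] = r

    clusters: dict[str, list[str]] = {}
    for lab in labels:
        clusters.setdefault(uf.find(lab), []).append(lab)
    if all(len(m) == 1 for m in clusters.values()):
        return problem, []

    new_sources: list[SourceSummary] = []
    records: list[MergeRecord] = []
    seen = set()
    for lab in labels:
        root = uf.find(lab)
        if root in seen:
            continue
        seen.add(root)
        members = clusters[root]
        if len(members) == 1:
            new_sources.append(problem.sources[idx[lab]])
            continue
        new_label = names.get(frozenset(members), "+".join(sorted(members)))
        pooled = _pool_sources([problem.sources[idx[m]] for m in members], new_label)
        new_sources.append(pooled)
        pair_corr = {
            pair: r for pair, r in hit_corr.items() if pair[0] in members and pair[1] in members
        }
        records.append(MergeRecord(tuple(members), pair_corr, new_label))

    merged = MixingProblem(
        consumers=problem.consumers,
        sources=new_sources,
        alpha=None,  # flat Dirichlet over the new, smaller simplex
        residual_error=problem.residual_error,
        residual_scale=problem.residual_scale,
    )
    return merged, records


@dataclass
class DietMatrix:
    """Consumer-by-prey matrix of posterior mean (SD) diet contributions."""

    means: pd.DataFrame
    sds: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        def fmt(m, s):
            return "" if np.isnan(m) else f"{m:.2f}({s:.2f})"

        out = pd.DataFrame(
            [
                [fmt(self.means.iat[i, j], self.sds.iat[i, j]) for j in range(self.means.shape[1])]
                for i in range(self.means.shape[0])
            ],
            index=self.means.index,
            columns=self.means.columns,
        )
        return out

    def row_sums(self) -> pd.Series:
        return self.means.sum(axis=1, skipna=True)

    def write_csv(self, path) -> None:
        self.formatted().to_csv(path, index_label="consumer")


def assemble_diet_matrix(
    posteriors: dict[str, MixingPosterior], topology: dict[str, list[str]]
) -> DietMatrix:
    """Assemble the diet matrix (rows: consumers, columns: prey sources).

    Every consumer group with trophic links must have a posterior; cells
    outside a consumer's source list stay blank (NaN).
    """
    missing = [g for g, prey in topology.items() if prey and g not in posteriors]
    if missing:
        raise ValueError(f"no posterior supplied for consumer group(s): {missing}")
    columns: list[str] = []
    for post in posteriors.values():
        for lab in post.labels:
            if lab not in columns:
                columns.append(lab)
    rows = list(posteriors)
    means = pd.DataFrame(np.nan, index=rows, columns=columns)
    sds = pd.DataFrame(np.nan, index=rows, columns=columns)
    for g, post in posteriors.items():
        means.loc[g, post.labels] = post.mean
        sds.loc[g, post.labels] = post.sd
    sums = means.sum(axis=1, skipna=True)
    bad = sums[(sums - 1.0).abs() > 0.02]
    if not bad.empty:
        raise ValueError(f"diet-matrix rows do not sum to 1 within 0.02: {dict(bad)}")
    return DietMatrix(means=means, sds=sds)
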