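import numpy as np
import pandas as pd
import pytest

from tests._oracles import hand_log_density
from trophlink import (
    MixingProblem,
    SourceSummary,
    assemble_diet_matrix,
    build_topology,
    fit_mixture,
    generate_sources,
    log_posterior,
    merge_sources,
)
from trophlink.mixing import CI_LEVELS, MixingPosterior


def _source(label, mu_c, sd_c, mu_n, sd_n, tef=(1.0, 3.4), tef_sd=(0.4, 0.3)):
    return SourceSummary(
        label, np.array([mu_c, mu_n]), np.array([sd_c, sd_n]), np.array(tef), np.array(tef_sd)
    )


class TestLogPosterior:
    def test_matches_hand_expanded_formula(self):
        src_dicts = [
            dict(mu_c=-21.0, sd_c=0.8, mu_n=4.0, sd_n=0.7, tef_c=1.0, tef_sd_c=0.4, tef_n=3.0, tef_sd_n=0.3),
            dict(mu_c=-16.0, sd_c=0.9, mu_n=10.0, sd_n=0.8, tef_c=1.0, tef_sd_c=0.4, tef_n=2.5, tef_sd_n=0.2),
        ]
        sources = [
            SourceSummary("a", np.array([-21.0, 4.0]), np.array([0.8, 0.7]), np.array([1.0, 3.0]), np.array([0.4, 0.3])),
            SourceSummary("b", np.array([-16.0, 10.0]), np.array([0.9, 0.8]), np.array([1.0, 2.5]), np.array([0.4, 0.2])),
        ]
        problem = MixingProblem(consumers=np.array([[-18.3, 8.1]]), sources=sources, residual_error=False)
        for p1 in (0.2, 0.5, 0.9):
            ours = log_posterior(np.array([p1, 1 - p1]), problem)
            theirs = hand_log_density(p1, -18.3, 8.1, src_dicts)
            assert np.isclose(ours, theirs, atol=1e-10)

    def test_exchangeable_sources_give_symmetric_density(self):
        s = _source("a", -20.0, 1.0, 5.0, 1.0)
        t = _source("b", -16.0, 1.0, 11.0, 1.0)
        # data exactly between the TEF-shifted means
        mid = (s.shifted_mu + t.shifted_mu) / 2.0
        problem = MixingProblem(consumers=mid[None, :], sources=[s, t], residual_error=False)
        for p1 in (0.1, 0.35):
            assert np.isclose(
                log_posterior(np.array([p1, 1 - p1]), problem),
                log_posterior(np.array([1 - p1, p1]), problem),
                atol=1e-10,
            )

    def test_single_source_density_is_constant(self):
        problem = MixingProblem(
            consumers=np.array([[-18.0, 9.0], [-18.5, 9.5]]),
            sources=[_source("only", -19.0, 1.0, 6.0, 1.0)],
            residual_error=False,
        )
        assert np.isfinite(log_posterior(np.array([1.0]), problem))

    def test_off_simplex_rejected(self):
        problem = MixingProblem(
            consumers=np.array([[-18.0, 9.0]]),
            sources=[_source("a", -19.0, 1.0, 6.0, 1.0), _source("b", -17.0, 1.0, 9.0, 1.0)],
        )
        with pytest.raises(ValueError, match="simplex"):
            log_posterior(np.array([0.7, 0.7]), problem)
        with pytest.raises(ValueError, match="simplex"):
            log_posterior(np.array([1.2, -0.2]), problem)


class TestFitMixture:
    def test_degenerate_attribution_to_matching_source(self):
        sources = [
            _source("match", -20.0, 0.05, 5.0, 0.05, tef=(1.0, 3.0), tef_sd=(0.01, 0.01)),
            _source("other", -14.0, 0.05, 11.0, 0.05, tef=(1.0, 3.0), tef_sd=(0.01, 0.01)),
        ]
        rng = np.random.default_rng(0)
        consumers = np.column_stack([rng.normal(-19.0, 0.05, 30), rng.normal(8.0, 0.05, 30)])
        post = fit_mixture(
            MixingProblem(consumers=consumers, sources=sources, residual_error=False),
            chains=4,
            iterations=4000,
            seed=1,
        )
        assert post.mean[post.labels.index("match")] > 0.9

    def test_draws_on_simplex_and_nested_cis(self, triangle_sources):
        rng = np.random.default_rng(3)
        consumers = np.column_stack([rng.normal(-18.0, 1.0, 40), rng.normal(8.0, 1.0, 40)])
        post = fit_mixture(
            MixingProblem(consumers=consumers, sources=triangle_sources),
            chains=4,
            iterations=4000,
            seed=2,
        )
        pooled = post.pooled
        assert np.all(pooled >= 0)
        assert np.allclose(pooled.sum(axis=1), 1.0, atol=1e-10)
        for narrow, wide in zip(CI_LEVELS[:-1], CI_LEVELS[1:]):
            lo_n, hi_n = post.ci[narrow]
            lo_w, hi_w = post.ci[wide]
            assert np.all(lo_w <= lo_n + 1e-12) and np.all(hi_n <= hi_w + 1e-12)

    def test_seeded_runs_are_identical(self, triangle_sources):
        rng = np.random.default_rng(5)
        consumers = np.column_stack([rng.normal(-18.0, 1.0, 20), rng.normal(8.0, 1.0, 20)])
        problem = MixingProblem(consumers=consumers, sources=triangle_sources)
        a = fit_mixture(problem, chains=2, iterations=2000, seed=11)
        b = fit_mixture(problem, chains=2, iterations=2000, seed=11)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_dominates_without_data(self, triangle_sources):
        problem = MixingProblem(
            consumers=np.empty((0, 2)), sources=triangle_sources, residual_error=False
        )
        post = fit_mixture(problem, chains=4, iterations=8000, seed=4)
        # flat Dirichlet prior: each mean is 1/3 up to Monte-Carlo error
        assert np.all(np.abs(post.mean - 1.0 / 3.0) < 0.03)

    def test_single_source_posterior_is_point_mass(self):
        problem = MixingProblem(
            consumers=np.array([[-18.0, 9.0]]),
            sources=[_source("only", -19.0, 1.0, 6.0, 1.0)],
            residual_error=False,
        )
        post = fit_mixture(problem, chains=2, iterations=1000, seed=0)
        assert np.all(post.draws == 1.0)
        assert post.converged

    def test_invalid_mcmc_settings_rejected(self, triangle_sources):
        problem = MixingProblem(consumers=np.array([[-18.0, 9.0]]), sources=triangle_sources)
        with pytest.raises(ValueError, match="chains"):
            fit_mixture(problem, chains=1, iterations=100, seed=0)
        with pytest.raises(ValueError, match="burn_in"):
            fit_mixture(problem, chains=2, iterations=100, burn_in=100, seed=0)


class TestBuildTopology:
    def test_single_species_pair_gives_single_edge(self):
        groups = {"spA": "G1", "spB": "G2"}
        assert build_topology([("spA", "spB")], groups) == {"G1": ["G2"]}

    def test_duplicate_pairs_collapse(self):
        groups = {"spA": "G1", "spB": "G2", "spC": "G2"}
        topo = build_topology([("spA", "spB"), ("spA", "spB"), ("spA", "spC")], groups)
        assert topo == {"G1": ["G2"]}

    def test_empty_links_empty_topology(self):
        assert build_topology([], {}) == {}

    def test_unmapped_species_listed_in_error(self):
        with pytest.raises(ValueError, match="spX"):
            build_topology([("spA", "spX")], {"spA": "G1"})


def _dummy_posterior(labels, corr, means=None):
    k = len(labels)
    means = np.full(k, 1.0 / k) if means is None else np.asarray(means)
    return MixingPosterior(
        labels=list(labels),
        draws=np.tile(means, (2, 10, 1)),
        mean=means,
        sd=np.full(k, 0.05),
        ci={lv: np.vstack([means - 0.1, means + 0.1]) for lv in CI_LEVELS},
        rhat=np.ones(k),
        geweke_z=np.zeros(k),
        correlation=np.asarray(corr, dtype=float),
        converged=True,
    )


class TestMergeSources:
    def _problem(self):
        sources = [
            _source("copepods", -20.29, 0.81, 9.69, 1.88),
            _source("macro_zooplankton", -19.70, 1.41, 9.41, 1.41),
            _source("som", -20.94, 2.14, 3.21, 0.14),
        ]
        return MixingProblem(consumers=np.array([[-18.0, 12.0]]), sources=sources)

    def test_correlated_and_flagged_pair_merges(self):
        problem = self._problem()
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = -0.64
        post = _dummy_posterior(problem.labels, corr)
        merged, log = merge_sources(
            post,
            problem,
            similar=[("copepods", "macro_zooplankton")],
            names={frozenset(("copepods", "macro_zooplankton")): "zooplankton"},
        )
        assert merged.labels == ["zooplankton", "som"]
        assert len(log) == 1 and log[0].new_label == "zooplankton"
        assert log[0].correlations[("copepods", "macro_zooplankton")] == -0.64
        # moment-matched pooling of the member summaries
        z = merged.sources[0]
        assert np.isclose(z.mu[0], (-20.29 + -19.70) / 2)
        expected_var = (0.81**2 + 1.41**2) / 2 + np.var([-20.29, -19.70])
        assert np.isclose(z.sd[0] ** 2, expected_var)

    def test_high_correlation_without_flag_does_not_merge(self):
        problem = self._problem()
        corr = np.eye(3)
        corr[0, 2] = corr[2, 0] = 0.8
        merged, log = merge_sources(_dummy_posterior(problem.labels, corr), problem, similar=[])
        assert merged is problem and log == []

    def test_correlation_at_exactly_threshold_does_not_merge(self):
        problem = self._problem()
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = -0.5
        merged, log = merge_sources(
            _dummy_posterior(problem.labels, corr),
            problem,
            similar=[("copepods", "macro_zooplankton")],
        )
        assert merged is problem and log == []

    def test_transitive_chain_resolved_by_union_find(self):
        problem = self._problem()
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = -0.7
        corr[1, 2] = corr[2, 1] = 0.6
        merged, log = merge_sources(
            _dummy_posterior(problem.labels, corr),
            problem,
            similar=[("copepods", "macro_zooplankton"), ("macro_zooplankton", "som")],
        )
        assert merged.n_sources == 1
        assert set(log[0].members) == {"copepods", "macro_zooplankton", "som"}

    def test_unknown_label_rejected(self):
        problem = self._problem()
        with pytest.raises(ValueError, match="unknown source"):
            merge_sources(
                _dummy_posterior(problem.labels, np.eye(3)), problem, similar=[("copepods", "squid")]
            )
        with pytest.raises(ValueError, match="itself"):
            merge_sources(
                _dummy_posterior(problem.labels, np.eye(3)), problem, similar=[("som", "som")]
            )


class TestDietMatrix:
    def test_single_consumer_single_source_cell(self):
        post = _dummy_posterior(["prey"], np.eye(1), means=np.array([1.0]))
        post.sd = np.array([0.0])
        matrix = assemble_diet_matrix({"pred": post}, {"pred": ["prey"]})
        assert matrix.formatted().loc["pred", "prey"] == "1.00(0.00)"
        assert np.isclose(matrix.row_sums()["pred"], 1.0)

    def test_rows_sum_to_one_within_tolerance(self, triangle_sources):
        rng = np.random.default_rng(1)
        consumers = np.column_stack([rng.normal(-18.0, 1.0, 25), rng.normal(8.5, 1.0, 25)])
        post = fit_mixture(
            MixingProblem(consumers=consumers, sources=triangle_sources),
            chains=2,
            iterations=2000,
            seed=3,
        )
        matrix = assemble_diet_matrix(
            {"fish": post}, {"fish": ["som", "macroalgae", "zooplankton"]}
        )
        assert abs(matrix.row_sums()["fish"] - 1.0) < 0.02

    def test_missing_posterior_rejected(self):
        post = _dummy_posterior(["prey"], np.eye(1), means=np.array([1.0]))
        with pytest.raises(ValueError, match="other_pred"):
            assemble_diet_matrix({"pred": post}, {"pred": ["prey"], "other_pred": ["prey"]})

    def test_blank_cells_for_non_prey(self):
        a = _dummy_posterior(["x", "y"], np.eye(2), means=np.array([0.6, 0.4]))
        b = _dummy_posterior(["y", "z"], np.eye(2), means=np.array([0.3, 0.7]))
        matrix = assemble_diet_matrix({"p1": a, "p2": b}, {"p1": ["x", "y"], "p2": ["y", "z"]})
        fmt = matrix.formatted()
        assert fmt.loc["p1", "z"] == "" and fmt.loc["p2", "x"] == ""


def test_generate_sources_double_as_mixing_input(triangle_sources):
    # the synthetic-data source summaries plug straight into MixingProblem
    problem = MixingProblem(consumers=np.array([[-18.0, 8.0]]), sources=triangle_sources)
    assert problem.n_sources == 3
    assert np.isfinite(log_posterior(np.array([0.2, 0.3, 0.5]), problem))
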