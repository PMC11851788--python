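import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import make_scenario
from trophlink import (
    ConsumerGroupSpec,
    Scenario,
    generate_sources,
    make_stations,
    simulate_baseline_gradient,
    simulate_consumers,
)
from trophlink.synthetic import invert_baseline_gradient
from trophlink import io as tio


class TestGenerateSources:
    def test_values_stored_verbatim(self):
        src = generate_sources([(-19.64, 0.93, 5.62, 0.57)], labels=["phytoplankton"])[0]
        assert src.label == "phytoplankton"
        assert src.mu.tolist() == [-19.64, 5.62]
        assert src.sd.tolist() == [0.93, 0.57]

    def test_identical_specs_identical_summaries(self):
        a = generate_sources([(-20.0, 1.0, 4.0, 0.5)])
        b = generate_sources([(-20.0, 1.0, 4.0, 0.5)])
        assert np.array_equal(a[0].mu, b[0].mu) and np.array_equal(a[0].sd, b[0].sd)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative SD"):
            generate_sources([(-20.0, -0.1, 4.0, 0.5)])

    def test_zero_sd_gives_degenerate_draws(self):
        src = generate_sources([(-20.0, 0.0, 4.0, 0.0)], tef_mu=(1.0, 3.4), tef_sd=(0.0, 0.0))
        ds = simulate_consumers(make_scenario(src, [1.0], n=20, process_sd=(0.0, 0.0)))
        assert np.allclose(ds.samples["d13c"], -19.0, atol=1e-12)
        assert np.allclose(ds.samples["d15n"], 7.4, atol=1e-12)


class TestSimulateConsumers:
    def test_same_seed_is_bit_reproducible(self, triangle_sources):
        sc = make_scenario(triangle_sources, [0.2, 0.3, 0.5], n=40, seed=7)
        a = simulate_consumers(sc)
        b = simulate_consumers(sc)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.stations, b.stations)

    def test_sample_count_and_station_ids(self, triangle_sources):
        sc = Scenario(
            sources=triangle_sources,
            consumers=[
                ConsumerGroupSpec("g1", np.array([0.2, 0.3, 0.5]), n=11),
                ConsumerGroupSpec("g2", np.array([0.6, 0.2, 0.2]), n=7),
            ],
            seed=1,
        )
        ds = simulate_consumers(sc)
        assert len(ds.samples) == 18
        assert set(ds.samples["station_id"]) <= set(ds.stations["station_id"])

    def test_adding_a_group_does_not_perturb_existing_draws(self, triangle_sources):
        base = Scenario(
            sources=triangle_sources,
            consumers=[ConsumerGroupSpec("g1", np.array([0.2, 0.3, 0.5]), n=11)],
            seed=1,
        )
        extended = Scenario(
            sources=triangle_sources,
            consumers=[
                ConsumerGroupSpec("g1", np.array([0.2, 0.3, 0.5]), n=11),
                ConsumerGroupSpec("g2", np.array([0.6, 0.2, 0.2]), n=7),
            ],
            seed=1,
        )
        a = simulate_consumers(base).samples
        b = simulate_consumers(extended).samples
        pd.testing.assert_frame_equal(a, b[b["functional_group"] == "g1"].reset_index(drop=True))

    def test_moments_converge_to_mixture_formula(self, triangle_sources):
        # mean -> sum p_k (mu_k + tef_k); var -> sum p_k^2 (sd_k^2 + tef_sd_k^2) + process^2
        diet = np.array([0.1, 0.4, 0.5])
        ds = simulate_consumers(make_scenario(triangle_sources, diet, n=1000, seed=3, process_sd=(0.4, 0.4)))
        mu = np.array([s.shifted_mu for s in triangle_sources])
        var = np.array([s.pooled_var for s in triangle_sources])
        m_target = diet @ mu
        v_target = (diet**2) @ var + 0.16
        x = ds.samples[["d13c", "d15n"]].to_numpy()
        se_mean = np.sqrt(v_target / 1000)
        assert np.all(np.abs(x.mean(axis=0) - m_target) < 4 * se_mean)
        se_var = v_target * np.sqrt(2.0 / 999)
        assert np.all(np.abs(x.var(axis=0, ddof=1) - v_target) < 4 * se_var)

    def test_reference_mixture_mean_matches_formula(self):
        # suspension-feeder-like scenario built from published summaries:
        # SOM/POM/phytoplankton at p = (0.05, 0.05, 0.90) with the group's
        # proportional TEF; the simulated group mean must match the mixture
        # identity sum_k p_k (mu_k + tef_k)
        from trophlink.datatypes import TefModel
        from trophlink.reference import FUNCTIONAL_GROUPS, reference_source

        row = FUNCTIONAL_GROUPS.loc["benthic_suspension_feeder"]
        tef = TefModel()
        sources = [
            reference_source(g, tef, row["d15n_mean"], row["d15n_sd"])
            for g in ("som", "pom", "phytoplankton")
        ]
        diet = np.array([0.05, 0.05, 0.90])
        ds = simulate_consumers(make_scenario(sources, diet, n=800, seed=13, process_sd=(0.2, 0.2)))
        mu = np.array([s.shifted_mu for s in sources])
        var = np.array([s.pooled_var for s in sources])
        target = diet @ mu
        se = np.sqrt((diet**2) @ var + 0.04) / np.sqrt(800)
        got = ds.samples[["d13c", "d15n"]].mean().to_numpy()
        assert np.all(np.abs(got - target) < 4 * se)

    def test_source_subset_groups(self, triangle_sources):
        sc = Scenario(
            sources=triangle_sources,
            consumers=[
                ConsumerGroupSpec("sub", np.array([0.4, 0.6]), n=50, sources=["som", "zooplankton"])
            ],
            seed=2,
            process_sd=(0.0, 0.0),
        )
        ds = simulate_consumers(sc)
        mu = np.array([triangle_sources[0].shifted_mu, triangle_sources[2].shifted_mu])
        target = np.array([0.4, 0.6]) @ mu
        assert np.all(np.abs(ds.samples[["d13c", "d15n"]].mean().to_numpy() - target) < 0.5)

    def test_invalid_diet_rejected(self, triangle_sources):
        with pytest.raises(ValueError, match="simplex"):
            ConsumerGroupSpec("bad", np.array([0.5, 0.2, 0.2]))
        with pytest.raises(ValueError, match="diet length"):
            simulate_consumers(make_scenario(triangle_sources, [0.5, 0.5]))


@settings(derandomize=True, deadline=None, max_examples=30)
@given(st.lists(st.floats(-3, 3), min_size=2, max_size=2), st.lists(st.floats(-2, 2), min_size=2, max_size=2))
def test_depth_varying_diets_stay_on_simplex(intercept, slope):
    from trophlink.compositions import inverse_ilr

    z = np.array(intercept) + np.linspace(-2, 2, 9)[:, None] * np.array(slope)
    p = inverse_ilr(z)
    assert np.all(p > 0) and np.allclose(p.sum(axis=1), 1.0)


class TestBaselineGradient:
    def _dataset(self, triangle_sources, seed=0):
        return simulate_consumers(make_scenario(triangle_sources, [0.2, 0.3, 0.5], n=30, seed=seed))

    def test_zero_offsets_change_nothing(self, triangle_sources):
        ds = self._dataset(triangle_sources)
        grad = {s: (0.0, 0.0) for s in ds.stations["station_id"]}
        out = simulate_baseline_gradient(ds, grad)
        pd.testing.assert_frame_equal(out.samples, ds.samples)

    def test_single_station_offset_is_exactly_additive(self, triangle_sources):
        ds = self._dataset(triangle_sources)
        st0 = ds.stations["station_id"].iloc[0]
        grad = {s: ((1.0, 0.0) if s == st0 else (0.0, 0.0)) for s in ds.stations["station_id"]}
        out = simulate_baseline_gradient(ds, grad)
        mask = ds.samples["station_id"] == st0
        assert np.allclose(
            out.samples.loc[mask, "d13c"], ds.samples.loc[mask, "d13c"] + 1.0, atol=1e-15
        )
        assert np.allclose(out.samples.loc[~mask, "d13c"], ds.samples.loc[~mask, "d13c"])

    def test_apply_then_invert_recovers_original(self, triangle_sources):
        ds = self._dataset(triangle_sources)
        rng = np.random.default_rng(5)
        grad = {s: tuple(rng.normal(0, 1, 2)) for s in ds.stations["station_id"]}
        out = invert_baseline_gradient(simulate_baseline_gradient(ds, grad))
        assert np.allclose(out.samples["d13c"], ds.samples["d13c"], atol=1e-12)
        assert np.allclose(out.samples["d15n"], ds.samples["d15n"], atol=1e-12)

    def test_missing_station_offset_rejected(self, triangle_sources):
        ds = self._dataset(triangle_sources)
        grad = {s: (1.0, 1.0) for s in ds.stations["station_id"][1:]}
        with pytest.raises(ValueError, match="missing offsets"):
            simulate_baseline_gradient(ds, grad)


class TestStations:
    def test_depths_evenly_spaced_over_range(self):
        stations = make_stations(5, (10.0, 90.0))
        assert np.allclose(stations["depth"], [10, 30, 50, 70, 90])
        assert set(stations.columns) >= {"station_id", "depth", "sstemp", "bottemp", "salinity", "chla"}

    def test_environment_tracks_depth(self):
        stations = make_stations(24, (10.0, 90.0), np.random.default_rng(0))
        assert stations["bottemp"].corr(stations["depth"]) < -0.9
        assert stations["chla"].corr(stations["depth"]) < -0.8
        assert stations["salinity"].corr(stations["depth"]) > 0.9


def test_dataset_write_and_read_roundtrip(tmp_path, triangle_sources):
    ds = simulate_consumers(make_scenario(triangle_sources, [0.2, 0.3, 0.5], n=12, seed=4))
    ds.write(tmp_path)
    samples = tio.read_samples(tmp_path / "samples.csv")
    stations = tio.read_stations(tmp_path / "stations.csv")
    assert len(samples) == 12 and len(stations) == 24
    assert (tmp_path / "truth.json").exists()
    assert np.allclose(samples["d13c"], ds.samples["d13c"])
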