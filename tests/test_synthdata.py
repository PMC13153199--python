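"""Synthetic-data generators: ground-truth structure and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from foulcast import synthdata as sd
from foulcast import varpart as vp
from foulcast import micronet as mn
from foulcast.synthdata import (
    BandSpec,
    CommonalityTarget,
    ScenarioSpec,
    gen_abundance_table,
    gen_eem_set,
    gen_flux_series,
    gen_fouling_dataset,
    gen_ftir_series,
)


class TestScenarioSpec:
    def test_packaged_defaults_cover_all_scenarios(self):
        assert set(sd.SCENARIO_SPECS) == set(sd.SCENARIOS)
        for spec in sd.SCENARIO_SPECS.values():
            assert 0 < spec.final_decline_fraction < 1
            assert spec.initial_flux > 0

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(initial_flux=-1.0), "initial_flux"),
            (dict(final_decline_fraction=1.0), "final_decline_fraction"),
            (dict(decay_timescale=0.0), "decay_timescale"),
            (dict(noise_sd=-0.1), "noise_sd"),
        ],
    )
    def test_invalid_parameters_named_in_error(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            ScenarioSpec(name="Ctrl", **kwargs)


class TestFluxSeries:
    def test_noiseless_ctrl_starts_at_nominal_flux(self):
        spec = ScenarioSpec(name="Ctrl", final_decline_fraction=0.255, noise_sd=0.0)
        log, _ = gen_flux_series(spec, seed=0)
        assert log["flux_lmh"].iloc[0] == pytest.approx(25.0)

    def test_long_time_limit_reaches_plateau(self):
        spec = ScenarioSpec(name="Al", final_decline_fraction=0.493, noise_sd=0.0)
        log, _ = gen_flux_series(spec, duration=200.0, step=1.0, seed=0)
        assert log["flux_lmh"].iloc[-1] == pytest.approx(25.0 * (1 - 0.493), rel=1e-6)

    def test_noiseless_series_satisfies_closed_form_everywhere(self):
        spec = ScenarioSpec(
            name="Fe", final_decline_fraction=0.712, decay_timescale=1.6,
            fluctuation_onset=8.0, noise_sd=0.0,
        )
        log, truth = gen_flux_series(spec, seed=0)
        np.testing.assert_allclose(
            log["flux_lmh"], sd.flux_model(spec, log["time_d"].to_numpy()), rtol=1e-14
        )
        np.testing.assert_allclose(log["flux_lmh"], truth["clean_flux"], rtol=1e-14)

    def test_fe_fluctuation_only_after_onset_and_bounded(self):
        spec = sd.SCENARIO_SPECS["Fe"]
        quiet = ScenarioSpec(
            name="Fe", final_decline_fraction=spec.final_decline_fraction,
            decay_timescale=spec.decay_timescale, noise_sd=0.0,
        )
        noisy = ScenarioSpec(
            name="Fe", final_decline_fraction=spec.final_decline_fraction,
            decay_timescale=spec.decay_timescale, noise_sd=0.0,
            fluctuation_onset=8.0, fluctuation_amplitude=spec.fluctuation_amplitude,
        )
        lq, _ = gen_flux_series(quiet, seed=0)
        ln, _ = gen_flux_series(noisy, seed=0)
        before = lq["time_d"] <= 8.0
        np.testing.assert_allclose(ln["flux_lmh"][before], lq["flux_lmh"][before])
        diff = np.abs(ln["flux_lmh"] - lq["flux_lmh"])
        assert diff.max() <= spec.fluctuation_amplitude + 1e-12
        assert diff.max() > 0

    def test_same_seed_bitwise_identical(self):
        a, _ = gen_flux_series("Fe", seed=11)
        b, _ = gen_flux_series("Fe", seed=11)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(duration=-1.0), "duration"),
        (dict(step=0.0), "step"),
    ])
    def test_invalid_grid_named_in_error(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            gen_flux_series("Ctrl", **kwargs)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            gen_flux_series("Cu")


class TestFtirSeries:
    @pytest.mark.parametrize("scenario,n", [("Fe", 13), ("Ctrl", 11), ("Al", 11)])
    def test_planted_band_counts(self, scenario, n):
        _, truth = gen_ftir_series(scenario, seed=0)
        assert truth["n_bands"] == n

    def test_onset_ranks_are_dense_with_ties(self):
        for scenario in sd.SCENARIOS:
            ranks = sorted(b.onset_rank for b in sd.FTIR_BANDS[scenario])
            assert ranks[0] == 1
            assert set(ranks) == set(range(1, max(ranks) + 1))

    def test_constant_band_zero_noise_time_invariant(self):
        series, _ = gen_ftir_series(
            bands=[BandSpec(center=1500, width=20, profile="constant")], noise_sd=0.0
        )
        for j in range(1, series.n_times):
            np.testing.assert_allclose(series.absorbance[:, j], series.absorbance[:, 0])

    def test_metadata_order_consistent_with_profiles(self):
        # a band with a smaller onset rank reaches half-rise earlier
        _, truth = gen_ftir_series("Fe", seed=0)
        half_time = {}
        t = np.arange(0.0, 20.01, 0.05)
        for b in truth["bands"]:
            p = b.amplitude_profile(t)
            half_time[b.center] = t[np.argmax(p >= 0.5 * p.max())]
        for a in truth["bands"]:
            for b in truth["bands"]:
                if a.onset_rank < b.onset_rank:
                    assert half_time[a.center] < half_time[b.center]

    def test_same_seed_identical(self):
        a, _ = gen_ftir_series("Ctrl", seed=4)
        b, _ = gen_ftir_series("Ctrl", seed=4)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            gen_ftir_series("Mg")

    def test_band_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gen_ftir_series(bands=[BandSpec(center=5000, width=10)])


class TestEemSet:
    def test_sample_count_matches_request(self):
        cube, _ = gen_eem_set("Fe", n_samples=11, seed=0)
        assert cube.n_samples == 11

    def test_intensities_nonnegative_on_stated_grids(self):
        cube, _ = gen_eem_set("Al", seed=1)
        assert cube.ex_axis[0] == 200 and cube.ex_axis[-1] == 450
        assert cube.em_axis[0] == 250 and cube.em_axis[-1] == 550
        assert (cube.intensity >= 0).all()

    def test_fe_window_exceeds_ctrl_noiseless(self):
        fe, _ = gen_eem_set("Fe", sample_scale_sd=0.0, pixel_noise_sd=0.0, seed=0)
        ctrl, _ = gen_eem_set("Ctrl", sample_scale_sd=0.0, pixel_noise_sd=0.0, seed=0)
        win = (fe.em_axis >= 330) & (fe.em_axis <= 450)
        assert fe.intensity[:, win, 0].mean() > ctrl.intensity[:, win, 0].mean()

    def test_same_seed_identical(self):
        a, _ = gen_eem_set("Ctrl", seed=2)
        b, _ = gen_eem_set("Ctrl", seed=2)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            gen_eem_set("Ctrl", n_samples=1)


class TestFoulingDataset:
    def test_population_commonality_matches_targets_exactly(self):
        # analytic fractions of the frozen calibrated weights vs targets
        from foulcast._calibrated import CALIBRATED_WEIGHTS

        for scen, target in sd.COMMONALITY_TARGETS.items():
            W = np.array(CALIBRATED_WEIGHTS[scen]["W"])
            v = np.array(CALIBRATED_WEIGHTS[scen]["v"])
            fracs, r2s = sd.population_commonality(W, v)
            for c in vp.COMPONENTS:
                assert fracs[c] == pytest.approx(getattr(target, c), abs=1e-6)
            assert r2s >= 0.9

    def test_target_fractions_must_sum_to_hundred(self):
        with pytest.raises(ValueError, match="sum to 100"):
            CommonalityTarget(50, 0, 0, 0, 0, 0, 40)

    def test_pure_unique_block_target_makes_y_collinear_with_b(self):
        target = CommonalityTarget(100, 0, 0, 0, 0, 0, 0)
        ds, truth = gen_fouling_dataset(
            target, total_R2=None, n=60, seed=0, column_noise_var=0.0
        )
        W, v = truth["weights"]
        fracs, _ = sd.population_commonality(W, v, column_noise_var=0.0)
        assert fracs["U_B"] == pytest.approx(100.0, abs=1e-6)
        r2 = vp.subset_r2(ds)
        # block B alone explains everything the full model explains, up to
        # the irrelevant predictors' noise fitting at n = 60
        assert r2["B"] == pytest.approx(r2["BIO"], abs=0.02)
        assert r2["B"] > 0.5
        # blocks I and O carry no response information on their own
        # (sample R² of 2 irrelevant predictors at n = 60 stays near p/n)
        assert r2["I"] < 0.15 and r2["O"] < 0.15

    def test_unattainable_total_r2_rejected(self):
        with pytest.raises(ValueError, match="not attainable"):
            gen_fouling_dataset("Fe", total_R2=0.999, n=100, seed=0)

    def test_infeasible_target_errors_name_a_fraction(self):
        bad = CommonalityTarget(-300, 100, 100, 100, 100, 100, -100)
        with pytest.raises(ValueError, match="offending fraction"):
            sd.calibrate_fouling_weights(bad, n_restarts=2)

    def test_same_seed_identical(self):
        a, _ = gen_fouling_dataset("Al", n=60, seed=5)
        b, _ = gen_fouling_dataset("Al", n=60, seed=5)
        pd.testing.assert_series_equal(a.response, b.response)
        for k in a.blocks:
            pd.testing.assert_frame_equal(a.blocks[k], b.blocks[k])

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            gen_fouling_dataset("Fe", n=10, seed=0)


class TestAbundanceTable:
    def test_two_modules_no_connector_planted_graph_disconnected(self):
        _, truth = gen_abundance_table(n_taxa=20, n_modules=2, planted_roles=[], seed=1)
        A = truth["adjacency"]
        names = [f"taxon_{i:03d}" for i in range(20)]
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if truth["membership"][a] != truth["membership"][b]:
                    assert not A[i, j]

    def test_planted_hub_and_connector_structure(self):
        table, truth = gen_abundance_table(seed=0)
        names = list(table.index)
        A = truth["adjacency"]
        g = mn.build_network(table, threshold=truth["edge_threshold"])
        # planted hub touches every member of its module in the planted graph
        hub = truth["hubs"][0]
        hub_mod = truth["membership"][hub]
        members = [t for t in names if truth["membership"][t] == hub_mod
                   and t != hub and t not in truth["connectors"]]
        hi = names.index(hub)
        assert all(A[hi, names.index(t)] for t in members)
        # planted connector reaches all modules in the planted graph
        ci = names.index(truth["connectors"][0])
        nbr_mods = {truth["membership"][names[j]] for j in np.flatnonzero(A[ci])}
        assert nbr_mods == set(range(3))

    def test_planted_graph_roles_classify_as_planted(self):
        import networkx as nx

        table, truth = gen_abundance_table(seed=0)
        names = list(table.index)
        planted = nx.from_numpy_array(truth["adjacency"])
        planted = nx.relabel_nodes(planted, dict(enumerate(names)))
        roles = {r.node: r for r in mn.zi_pi(planted, truth["membership"])}
        for h in truth["hubs"]:
            assert roles[h].role == "module_hub"
        for c in truth["connectors"]:
            assert roles[c].role == "connector"
            assert roles[c].pi == pytest.approx(2.0 / 3.0)

    def test_recovered_hub_and_connector_properties(self):
        table, truth = gen_abundance_table(seed=0)
        g = mn.build_network(table, threshold=truth["edge_threshold"])
        part, _ = mn.detect_modules(g)
        roles = {r.node: r for r in mn.zi_pi(g, part)}
        for h in truth["hubs"]:
            assert roles[h].zi > 2.5
        for c in truth["connectors"]:
            touched = {part[u] for u in g.neighbors(c)}
            assert len(touched) >= 2

    def test_same_seed_identical(self):
        a, _ = gen_abundance_table(seed=9)
        b, _ = gen_abundance_table(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_more_roles_than_taxa_rejected(self):
        roles = [(f"taxon_{i:03d}", "module_hub") for i in range(5)]
        with pytest.raises(ValueError, match="more planted roles"):
            gen_abundance_table(n_taxa=4, n_modules=2, planted_roles=roles, seed=0)

    def test_module_count_bounds_enforced(self):
        with pytest.raises(ValueError, match="n_modules"):
            gen_abundance_table(n_modules=1)
        with pytest.raises(ValueError, match="n_taxa"):
            gen_abundance_table(n_taxa=2, n_modules=3)
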