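"""Ensembles, support entropy, coupling and scenario simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import habsuit as hs
from conftest import toy_records


def cat_model(name="v", si_b=0.5, threshold=0.6):
    return hs.SuitabilityModel(
        hpcs=[hs.CategoricalHPC(name, {"a": 1.0, "b": si_b})], threshold=threshold)


class TestSupportEntropy:
    @pytest.mark.parametrize("p, expected", [
        (0.5, 1.0),          # half support: maximal selection uncertainty
        (0.0, 0.0), (1.0, 0.0),
        (0.25, 0.8112781244591328),
    ])
    def test_binary_entropy_values(self, p, expected):
        assert hs.support_entropy(p) == pytest.approx(expected)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(hs.ConfigurationError):
            hs.support_entropy(1.2)

    @given(st.floats(0.0, 1.0))
    def test_symmetric_about_half_and_maximal_there(self, p):
        h = hs.support_entropy(p)
        assert 0.0 <= h <= 1.0
        assert h == pytest.approx(hs.support_entropy(1.0 - p), abs=1e-12)
        assert h <= 1.0 + 1e-12


class TestEnsembleSupport:
    def test_single_member_support_is_zero_or_one(self):
        ens = hs.EnsembleModel(models=[cat_model("v")], variables=["v", "w"])
        assert ens.support == {"v": 1.0, "w": 0.0}

    def test_support_times_n_models_is_integer(self):
        models = [cat_model("v") for _ in range(3)] + [cat_model("w") for _ in range(7)]
        ens = hs.EnsembleModel(models=models)
        for p in ens.support.values():
            assert (p * ens.n_models) == pytest.approx(round(p * ens.n_models))

    def test_half_support_has_entropy_one(self):
        models = [cat_model("v") for _ in range(5)] + [cat_model("w") for _ in range(5)]
        ens = hs.EnsembleModel(models=models, variables=["v", "w"])
        assert ens.support["v"] == 0.5
        assert ens.entropy["v"] == pytest.approx(1.0)

    def test_build_ensemble_is_reproducible_and_recovers_signal(
            self, complete_pools, fitted_hpcs):
        presences, backgrounds = complete_pools
        kwargs = dict(n_models=8, master_seed=99,
                      ga_config=hs.GAConfig(n_generations=30, stagnation_patience=10))
        a = hs.build_ensemble(presences, backgrounds, fitted_hpcs, **kwargs)
        b = hs.build_ensemble(presences, backgrounds, fitted_hpcs, **kwargs)
        assert [m.to_dict() for m in a.models] == [m.to_dict() for m in b.models]
        assert a.n_models == 8

    def test_save_load_round_trip(self, tmp_path):
        models = [cat_model("v"), cat_model("w", si_b=0.2)]
        ens = hs.EnsembleModel(models=models, seeds=[1, 2])
        ens.save(tmp_path / "ens")
        back = hs.EnsembleModel.load(tmp_path / "ens")
        assert back.n_models == 2
        assert back.support == ens.support
        support_csv = pd.read_csv(tmp_path / "ens" / "support.csv")
        assert set(support_csv.columns) == {"variable", "support_pct", "entropy"}


class TestCoupling:
    def biotic(self, coords):
        df = toy_records({"bio_var": [1.0] * len(coords)})
        df["x"], df["y"] = zip(*coords)
        return df

    def abiotic(self, coords):
        df = toy_records({"abio_var": [2.0] * len(coords)})
        df["x"], df["y"] = zip(*coords)
        return df

    def test_boundary_distance_kept_beyond_excluded(self):
        biotic = self.biotic([(0.0, 0.0)])
        at_radius = hs.couple_datasets(biotic, self.abiotic([(100.0, 0.0)]), 100.0)
        beyond = hs.couple_datasets(biotic, self.abiotic([(100.01, 0.0)]), 100.0)
        assert len(at_radius) == 1
        assert beyond.empty

    def test_identical_coordinates_couple_at_distance_zero(self):
        out = hs.couple_datasets(self.biotic([(5.0, 5.0)]),
                                 self.abiotic([(5.0, 5.0)]))
        assert out["pair_distance_m"].iloc[0] == 0.0
        assert "bio_var" in out.columns and "abio_var" in out.columns

    def test_nearest_partner_wins(self):
        biotic = self.biotic([(30.0, 0.0), (80.0, 0.0)])
        out = hs.couple_datasets(biotic, self.abiotic([(0.0, 0.0)]))
        assert out["pair_distance_m"].iloc[0] == pytest.approx(30.0)

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(3)
        biotic = self.biotic([tuple(c) for c in rng.uniform(0, 1000, (15, 2))])
        abiotic = self.abiotic([tuple(c) for c in rng.uniform(0, 1000, (40, 2))])
        sizes = [len(hs.couple_datasets(biotic, abiotic, r))
                 for r in (25, 50, 100, 200, 400)]
        assert sizes == sorted(sizes)

    def test_missing_coordinates_skipped_with_warning(self):
        abiotic = self.abiotic([(0.0, 0.0), (1.0, 1.0)])
        abiotic.loc[0, "x"] = np.nan
        with pytest.warns(UserWarning, match="without coordinates"):
            out = hs.couple_datasets(self.biotic([(0.0, 0.0)]), abiotic)
        assert len(out) == 1


class TestAggregateScenario:
    def spec(self, name="algae"):
        return hs.VariableSpec(name, "binary", ("0", "1"))

    def test_continuous_median(self):
        from habsuit.ensemble import aggregate_scenario
        spec = hs.VariableSpec("depth", "continuous", (0.0, 30.0))
        out = aggregate_scenario(toy_records({"depth": [10.0, 12.0, 14.0]}), [spec])
        assert out["depth"] == 12.0

    def test_categorical_tie_takes_the_lower_si_class(self):
        from habsuit.ensemble import aggregate_scenario
        # algae 0/1 split: median 0.5; presence of algae has the lower SI
        hpc = hs.CategoricalHPC("algae", {"0": 1.0, "1": 0.3})
        out = aggregate_scenario(toy_records({"algae": ["0", "1"]}),
                                 [self.spec()], hpcs=[hpc])
        assert out["algae"] == "1"
        # flipped preference: absence is now the worst case
        hpc2 = hs.CategoricalHPC("algae", {"0": 0.3, "1": 1.0})
        out2 = aggregate_scenario(toy_records({"algae": ["0", "1"]}),
                                  [self.spec()], hpcs=[hpc2])
        assert out2["algae"] == "0"

    def test_si_tie_falls_back_to_later_declared_class(self):
        from habsuit.ensemble import aggregate_scenario
        hpc = hs.CategoricalHPC("algae", {"0": 1.0, "1": 1.0})
        out = aggregate_scenario(toy_records({"algae": ["0", "1"]}),
                                 [self.spec()], hpcs=[hpc])
        assert out["algae"] == "1"

    def test_single_observation_is_itself(self):
        from habsuit.ensemble import aggregate_scenario
        out = aggregate_scenario(toy_records({"algae": ["1"]}), [self.spec()])
        assert out["algae"] == "1"

    def test_unobserved_variable_stays_missing(self):
        from habsuit.ensemble import aggregate_scenario
        out = aggregate_scenario(toy_records({"algae": [None]}), [self.spec()])
        assert pd.isna(out["algae"])


class TestSimulateEnsemble:
    def scenario(self, values):
        df = toy_records({"v": values})
        return df

    def test_identical_members_have_zero_sd(self):
        ens = hs.EnsembleModel(models=[cat_model("v"), cat_model("v")])
        sims = hs.simulate_ensemble(ens, self.scenario(["a", "b"]))
        assert (sims["sd_hsi"] == 0.0).all()
        assert sims["mean_hsi"].to_list() == pytest.approx([1.0, 0.5])

    def test_single_member_reduces_to_hsi(self):
        model = hs.SuitabilityModel(hpcs=[
            hs.CategoricalHPC("v", {"a": 0.25, "b": 1.0}),
            hs.CategoricalHPC("w", {"a": 1.0}),
        ])
        ens = hs.EnsembleModel(models=[model])
        df = toy_records({"v": ["a"], "w": ["a"]})
        sims = hs.simulate_ensemble(ens, df)
        assert sims["mean_hsi"].iloc[0] == pytest.approx(0.5)
        assert sims["sd_hsi"].iloc[0] == 0.0

    def test_zero_absorption_propagates_to_min_si(self):
        ens = hs.EnsembleModel(models=[cat_model("v", si_b=0.5)])
        sims = hs.simulate_ensemble(ens, self.scenario(["c"]))  # unseen class
        assert sims["mean_hsi"].iloc[0] == 0.0
        assert sims["min_si_v"].iloc[0] == 0.0

    def test_sd_bounded_and_members_counted(self):
        models = [cat_model("v", si_b=0.0), cat_model("v", si_b=1.0)]
        ens = hs.EnsembleModel(models=models)
        sims = hs.simulate_ensemble(ens, self.scenario(["b", "a"]))
        assert (sims["sd_hsi"] <= 0.5 + 1e-12).all()
        assert (sims["n_members_used"] == 2).all()

    def test_unevaluable_site_reported_unsimulated(self):
        ens = hs.EnsembleModel(models=[cat_model("v")])
        df = toy_records({"v": [None]})
        with pytest.warns(UserWarning, match="no ensemble member"):
            sims = hs.simulate_ensemble(ens, df)
        assert np.isnan(sims["mean_hsi"].iloc[0])


class TestCountSuitable:
    def test_direct_count(self):
        sims = pd.DataFrame({"mean_hsi": [0.1, 0.5, 0.9]})
        counts = hs.count_suitable(sims, [0.6])
        assert counts[0.6] == (1, 2)

    def test_all_equal_between_thresholds(self):
        sims = pd.DataFrame({"mean_hsi": [0.7] * 5})
        counts = hs.count_suitable(sims, [0.6, 0.8])
        assert counts[0.6] == (5, 0)
        assert counts[0.8] == (0, 5)

    def test_empty_threshold_list_gives_empty_report(self):
        sims = pd.DataFrame({"mean_hsi": [0.7]})
        assert hs.count_suitable(sims, []) == {}
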