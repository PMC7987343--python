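"""Generator contracts: design layout, richness gradient, planted effects."""

import warnings

import numpy as np
import pandas as pd
import pytest

from microstab.config import FUNCTION_NAMES, SimConfig
from microstab.datatypes import EffectEntry, EffectMap, sample_key
from microstab import simulate


class TestDesign:
    def test_full_factorial_gives_60_mesocosms(self):
        design = simulate.generate_design(SimConfig())
        assert len(design) == 60
        assert design["mesocosm"].is_unique
        counts = design.groupby(["treatment", "origin"], observed=True).size()
        assert (counts == 5).all()

    def test_one_rep_one_origin_gives_one_row_per_treatment(self):
        cfg = SimConfig(n_reps=1, n_origins=1)
        design = simulate.generate_design(cfg)
        assert len(design) == 4
        assert design["treatment"].nunique() == 4

    def test_two_treatments_repeat_each_origin_rep_pair_twice(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = SimConfig(n_treatments=2, richness_retention=(1.0, 0.4))
        design = simulate.generate_design(cfg)
        pair_counts = design.groupby(["origin", "replicate"]).size()
        assert (pair_counts == 2).all()

    def test_treatment_score_is_log2_mesh_with_sterile_at_zero(self):
        design = simulate.generate_design(SimConfig())
        scores = design.drop_duplicates("treatment").set_index("sieve_um")[
            "treatment_score"
        ]
        assert scores[0] == 0.0
        for mesh in (5000, 100, 25):
            assert scores[mesh] == pytest.approx(np.log2(mesh + 1))
        assert scores.loc[[5000, 100, 25, 0]].is_monotonic_decreasing


class TestCommunity:
    def test_sterile_mesocosms_lose_over_half_the_pool(self):
        # retention 0.42 of a 300-taxon pool -> 126 taxa, a 58% loss
        cfg = SimConfig(seed=1, n_taxa_fungi=100, n_taxa_bacteria=200)
        design = simulate.generate_design(cfg)
        comm = simulate.generate_community(design, cfg)
        combined = pd.concat(comm.values(), axis=0)
        sterile = design.loc[design["sieve_um"] == 0, "mesocosm"]
        for meso in sterile:
            col = sample_key(meso, 1)
            n_taxa = int((combined[col] > 0).sum())
            assert n_taxa == round(0.42 * 100) + round(0.42 * 200) == 126
        loss = 1 - 126 / 300
        assert 0.55 <= loss <= 0.60

    def test_full_retention_keeps_entire_pool(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = SimConfig(
                seed=2, richness_retention=(1.0, 1.0, 1.0, 1.0),
                n_taxa_fungi=20, n_taxa_bacteria=30, n_times=2,
            )
        design = simulate.generate_design(cfg)
        comm = simulate.generate_community(design, cfg)
        for table in comm.values():
            assert (table.to_numpy() > 0).all()

    def test_same_seed_gives_identical_tables(self, small_cfg):
        design = simulate.generate_design(small_cfg)
        a = simulate.generate_community(design, small_cfg)
        b = simulate.generate_community(design, small_cfg)
        for group in a:
            pd.testing.assert_frame_equal(a[group], b[group])

    def test_retention_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="richness_retention"):
            SimConfig(richness_retention=(1.0, 0.5))

    def test_expected_richness_declines_along_gradient(self):
        """Averaged over 50 seeds, realized richness strictly decreases
        across the sieve treatments."""
        cfg0 = SimConfig(n_taxa_fungi=20, n_taxa_bacteria=30, n_times=1,
                         n_reps=2)
        design = simulate.generate_design(cfg0)
        means = np.zeros(4)
        for seed in range(50):
            cfg = cfg0.with_seed(seed)
            comm = simulate.generate_community(design, cfg)
            combined = pd.concat(comm.values(), axis=0)
            rich = (combined > 0).sum(axis=0)
            by_treat = design.set_index("mesocosm")["treatment_order"]
            for order in range(4):
                cols = [
                    sample_key(m, 1)
                    for m in by_treat.index[by_treat == order]
                ]
                means[order] += rich[cols].mean()
        assert (np.diff(means) < 0).all()

    def test_rotating_supporter_peaks_at_assigned_time(self):
        cfg = SimConfig(seed=9, n_taxa_fungi=10, n_taxa_bacteria=10,
                        n_supporters_per_function_time=1, peak_boost=2.0)
        design = simulate.generate_design(cfg)
        effects = EffectMap([EffectEntry("F0001", "plant_biomass", 3, 1)])
        comm = simulate.generate_community(design, cfg, effects)
        fungi = comm["fungi"]
        series = np.zeros(cfg.n_times)
        for t in range(1, cfg.n_times + 1):
            cols = [c for c in fungi.columns if c.endswith(f"_T{t}")]
            vals = fungi.loc["F0001", cols]
            series[t - 1] = vals[vals > 0].mean()
        assert np.argmax(series) == 2  # peak at time 3


class TestEffects:
    def test_disjoint_mode_gives_distinct_taxa_per_function(self):
        cfg = SimConfig(seed=3, n_supporters_per_function_time=10)
        em = simulate.assign_taxon_effects(cfg, mode="disjoint")
        assert len(em.taxa()) == 40
        per_function = [
            {e.taxon for e in em.entries if e.function == f} for f in FUNCTION_NAMES
        ]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not per_function[i] & per_function[j]

    def test_identical_mode_shares_one_set(self):
        cfg = SimConfig(seed=3, n_supporters_per_function_time=10)
        em = simulate.assign_taxon_effects(cfg, mode="identical")
        assert len(em.taxa()) == 10

    def test_random_mode_is_reproducible(self, small_cfg):
        a = simulate.assign_taxon_effects(small_cfg)
        b = simulate.assign_taxon_effects(small_cfg)
        assert a.entries == b.entries

    def test_static_mode_reuses_supporters_across_times(self):
        cfg = SimConfig(seed=4, asynchrony_mode="static")
        em = simulate.assign_taxon_effects(cfg)
        for f in FUNCTION_NAMES:
            sets = [set(em.supporters(f, t)) for t in range(1, cfg.n_times + 1)]
            assert all(s == sets[0] for s in sets)


class TestFunctions:
    def test_no_supporters_and_no_noise_gives_exact_baselines(self):
        cfg = SimConfig(seed=5, noise_sd=0.0, n_taxa_fungi=5, n_taxa_bacteria=5,
                        n_times=2)
        design = simulate.generate_design(cfg)
        comm = simulate.generate_community(design, cfg)
        funcs = simulate.generate_functions(comm, EffectMap([]), cfg)
        for f, baseline in cfg.baselines.items():
            vals = funcs.loc[funcs["function"] == f, "value"]
            assert (vals == baseline).all()

    def test_three_positive_supporters_add_three_effects(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = SimConfig(
                seed=6, noise_sd=0.0, effect_size=2.0,
                richness_retention=(1.0, 1.0, 1.0, 1.0),
                n_taxa_fungi=5, n_taxa_bacteria=5, n_times=1,
                baselines={**SimConfig().baselines, "plant_biomass": 10.0},
            )
        design = simulate.generate_design(cfg)
        comm = simulate.generate_community(design, cfg)
        em = EffectMap(
            [EffectEntry(t, "plant_biomass", 1, 1) for t in ("F0001", "F0002", "B0001")]
        )
        funcs = simulate.generate_functions(comm, em, cfg)
        vals = funcs.loc[funcs["function"] == "plant_biomass", "value"]
        assert (vals == 10.0 + 2.0 * 3).all()  # full retention: all present

    def test_unknown_function_name_raises(self, small_cfg):
        design = simulate.generate_design(small_cfg)
        comm = simulate.generate_community(design, small_cfg)
        with pytest.raises(ValueError, match="unknown function"):
            EffectMap([EffectEntry("F0001", "not_a_function", 1, 1)])

    def test_mean_function_value_increases_with_retention(self):
        """Monte-Carlo over 100 seeds: the highest-retention treatment outscores
        the sterile treatment on every function, on average."""
        deltas = np.zeros(4)
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_taxa_fungi=10, n_taxa_bacteria=15,
                            n_supporters_per_function_time=3, n_times=2,
                            n_reps=2)
            ds, _ = simulate.simulate_experiment(cfg)
            merged = ds.functions.merge(ds.design, on="mesocosm")
            top = merged.loc[merged["treatment_order"] == 0]
            sterile = merged.loc[merged["treatment_order"] == 3]
            for i, f in enumerate(FUNCTION_NAMES):
                deltas[i] += (
                    top.loc[top["function"] == f, "value"].mean()
                    - sterile.loc[sterile["function"] == f, "value"].mean()
                )
        assert (deltas > 0).all()


def test_config_loads_from_yaml_and_cli_seed_wins(tmp_path):
    from microstab.config import load_config

    path = tmp_path / "cfg.yaml"
    path.write_text(
        "seed: 5\nn_taxa_fungi: 12\nrichness_retention: [1.0, 0.8, 0.6, 0.4]\n"
    )
    cfg = load_config(path)
    assert cfg.seed == 5 and cfg.n_taxa_fungi == 12
    assert load_config(path, seed=99).seed == 99


def test_duplicate_effect_entries_rejected():
    entry = EffectEntry("F0001", "plant_biomass", 1, 1)
    with pytest.raises(ValueError, match="duplicate"):
        EffectMap([entry, EffectEntry("F0001", "plant_biomass", 1, -1)])


def test_malformed_sample_key_rejected():
    from microstab.datatypes import split_sample_key

    assert split_sample_key("M07_T3") == ("M07", 3)
    with pytest.raises(ValueError):
        split_sample_key("M07-3")


def test_simulated_dataset_round_trips_through_csv(tmp_path, small_dataset):
    from microstab import io

    ds, _ = small_dataset
    paths = simulate.write_dataset(ds, tmp_path)
    loaded = io.load_dataset(
        design=paths["design"],
        functions=paths["functions"],
        abundance={"fungi": paths["fungi"], "bacteria": paths["bacteria"]},
    )
    assert loaded.mesocosms == ds.mesocosms
    assert loaded.times == ds.times
    pd.testing.assert_frame_equal(
        loaded.functions.sort_values(["mesocosm", "time", "function"]).reset_index(drop=True),
        ds.functions.sort_values(["mesocosm", "time", "function"]).reset_index(drop=True),
    )
    for group in ds.abundance:
        # zero-total taxa are dropped on load; none exist in this simulation
        pd.testing.assert_frame_equal(loaded.abundance[group], ds.abundance[group])
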