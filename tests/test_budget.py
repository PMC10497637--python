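"""Colony geometry, scenario classification, and budget aggregation."""

import numpy as np
import pandas as pd
import pytest

from coralcarb import budget as bdg
from coralcarb import synthetic as syn
from coralcarb.budget import ColonyRecord, SpeciesDensityTable, VolumeModelParams


@pytest.fixture
def density_table():
    return SpeciesDensityTable(
        pd.DataFrame(
            {
                "species": ["massive sp", "branching sp", "no-loss sp"],
                "growth_form": ["massive", "branching", "massive"],
                "d_living_g_cm3": [1.5, 1.7, 1.3],
                "d_dead_g_cm3": [1.2, 1.7, 1.3],
                "sctld_susceptible": [True, False, True],
            }
        )
    )


def massive_colony(**kw):
    defaults = dict(species="massive sp", d_max_m=2.0, d_perp_m=2.0, height_m=1.0)
    defaults.update(kw)
    return ColonyRecord(**defaults)


class TestVolumeAndMass:
    def test_elliptical_paraboloid_closed_form(self):
        # d_max = d_perp = 2 m, H = 1 m: r = 1 m, C = pi/2
        assert bdg.colony_volume(massive_colony(), "massive") == pytest.approx(
            np.pi / 2, rel=1e-12
        )

    def test_branching_prism_with_published_correction(self):
        rec = ColonyRecord("b", 1.0, 0.5, 0.4)
        assert bdg.colony_volume(rec, "branching") == pytest.approx(0.0220, abs=5e-5)

    def test_zero_height_means_zero_volume(self):
        rec = massive_colony(height_m=0.0)
        assert bdg.colony_volume(rec, "massive") == 0.0
        assert bdg.colony_volume(rec, "branching") == 0.0

    def test_unknown_growth_form_errors(self):
        with pytest.raises(ValueError, match="growth form"):
            bdg.colony_volume(massive_colony(), "encrusting-unknown")

    def test_mass_unit_conversion(self):
        assert bdg.colony_mass(1.0, 1.5) == 1500.0
        assert bdg.colony_mass(0.0, 2.0) == 0.0
        # 1 cm^3 of aragonite at 2.83 g cm^-3 weighs 2.83 g
        assert bdg.colony_mass(1e-6, 2.83) == pytest.approx(2.83e-3, rel=1e-12)

    def test_negative_dimensions_rejected(self):
        with pytest.raises(ValueError):
            ColonyRecord("x", -1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            ColonyRecord("x", 1.0, 0.5, 0.5, sctld_lesion_pct=120)


class TestClassification:
    def test_small_lesions_stay_alive(self, density_table):
        rec = massive_colony(sctld_lesion_pct=5.0)
        assert bdg.classify_colony(rec, density_table) == "alive_both"

    def test_large_lesions_die_in_post_scenario(self, density_table):
        rec = massive_colony(sctld_lesion_pct=40.0)
        assert bdg.classify_colony(rec, density_table) == "dead_post"

    def test_total_recent_mortality_dies_in_post_scenario(self, density_table):
        rec = massive_colony(recent_mortality_pct=100.0)
        assert bdg.classify_colony(rec, density_table) == "dead_post"

    def test_non_susceptible_species_never_attributed(self, density_table):
        rec = ColonyRecord("branching sp", 1.0, 1.0, 0.5, recent_mortality_pct=100.0)
        assert bdg.classify_colony(rec, density_table) == "alive_both"

    def test_unknown_species_is_named_in_error(self, density_table):
        with pytest.raises(KeyError, match="mystery"):
            bdg.classify_colony(massive_colony(species="mystery"), density_table)


class TestTransectBudget:
    def test_all_alive_means_zero_loss(self, density_table):
        recs = [massive_colony(), massive_colony(d_max_m=1.0, d_perp_m=1.0)]
        res = bdg.transect_budget(recs, density_table)
        assert res["loss_kg_m2"] == 0.0
        assert res["pre_kg_m2"] > 0

    def test_single_dead_colony_hand_computed(self, density_table):
        # C = pi/2 m^3, dD = 0.3 -> loss = -(pi/2)*0.3*1000/10 = -47.12 kg m^-2
        recs = [massive_colony(sctld_lesion_pct=50.0)]
        res = bdg.transect_budget(recs, density_table, transect_area_m2=10.0)
        assert res["loss_kg_m2"] == pytest.approx(-47.12, abs=0.01)

    def test_no_dissolution_species_contributes_zero_loss(self, density_table):
        recs = [massive_colony(species="no-loss sp", sctld_lesion_pct=90.0)]
        res = bdg.transect_budget(recs, density_table)
        assert res["loss_kg_m2"] == 0.0

    def test_empty_transect_warns_and_returns_zeros(self, density_table):
        with pytest.warns(UserWarning, match="empty transect"):
            res = bdg.transect_budget([], density_table)
        assert res == {"pre_kg_m2": 0.0, "post_kg_m2": 0.0, "loss_kg_m2": 0.0}

    def test_post_never_exceeds_pre(self, density_table):
        rng = np.random.default_rng(0)
        recs = [
            massive_colony(
                d_max_m=rng.uniform(0.1, 2), d_perp_m=rng.uniform(0.1, 2),
                height_m=rng.uniform(0.1, 1), sctld_lesion_pct=rng.uniform(0, 100),
            )
            for _ in range(30)
        ]
        res = bdg.transect_budget(recs, density_table)
        assert res["post_kg_m2"] <= res["pre_kg_m2"]


def uniform_transects(loss, n=5, reef="R", pre=20.0):
    return pd.DataFrame(
        {
            "transect": [f"{reef}-T{i}" for i in range(n)],
            "reef": reef,
            "pre_kg_m2": pre,
            "post_kg_m2": pre + loss,
            "loss_kg_m2": loss,
        }
    )


class TestReefScale:
    def test_uniform_loss_over_system_area_reproduces_tonnage(self):
        # -1.33 kg m^-2 over 3,145,967.15 m^2 -> -4184 t
        areas = pd.DataFrame({"reef": ["R"], "area_m2": [3_145_967.15]})
        res = bdg.reef_scale(uniform_transects(-1.33), areas)
        assert res.system["loss_t"] == pytest.approx(-4184.14, abs=0.01)
        assert res.system["mean_loss_kg_m2"] == pytest.approx(-1.33, abs=1e-9)

    def test_two_reef_tonnes_add(self):
        tr = pd.concat(
            [uniform_transects(-0.5, reef="A"), uniform_transects(-1.0, reef="B")],
            ignore_index=True,
        )
        areas = pd.DataFrame({"reef": ["A", "B"], "area_m2": [2000.0, 1000.0]})
        res = bdg.reef_scale(tr, areas)
        assert res.system["loss_t"] == pytest.approx(-0.5 * 2 - 1.0 * 1)

    def test_zero_area_reef_errors(self):
        areas = pd.DataFrame({"reef": ["R"], "area_m2": [0.0]})
        with pytest.raises(ValueError, match="positive area"):
            bdg.reef_scale(uniform_transects(-1.0), areas)

    def test_reef_without_transects_errors(self):
        areas = pd.DataFrame({"reef": ["R", "S"], "area_m2": [100.0, 100.0]})
        with pytest.raises(ValueError, match="no transects"):
            bdg.reef_scale(uniform_transects(-1.0), areas)

    def test_doubling_areas_doubles_tonnes_not_kg_m2(self):
        tr = uniform_transects(-1.0)
        a1 = pd.DataFrame({"reef": ["R"], "area_m2": [1000.0]})
        a2 = pd.DataFrame({"reef": ["R"], "area_m2": [2000.0]})
        r1 = bdg.reef_scale(tr, a1)
        r2 = bdg.reef_scale(tr, a2)
        assert r2.system["loss_t"] == pytest.approx(2 * r1.system["loss_t"])
        assert r2.system["mean_loss_kg_m2"] == pytest.approx(r1.system["mean_loss_kg_m2"])


class TestOracleEquivalence:
    def test_matches_generator_truth_on_seeded_surveys(self):
        for seed in range(5):
            tables, truth = syn.generate_survey(
                syn.SurveySimParams(seed=seed, transects_per_reef=4)
            )
            res = bdg.run_budget(
                tables["survey"], tables["densities"], tables["reef_areas"],
                transects=tables["transects"],
            )
            np.testing.assert_allclose(
                res.transects["loss_kg_m2"], truth.transects["loss_kg_m2"],
                rtol=1e-9, atol=1e-9,
            )
            assert res.system["loss_t"] == pytest.approx(truth.system["loss_t"], rel=1e-9)

    def test_equal_dead_and_living_densities_give_exactly_zero_loss(self):
        species = [
            syn.SpeciesSimSpec("a", 0.6, "massive", 1.5, 1.5, True),
            syn.SpeciesSimSpec("b", 0.4, "branching", 1.7, 1.7, True),
        ]
        tables, truth = syn.generate_survey(
            syn.SurveySimParams(species=species, seed=2, transects_per_reef=3)
        )
        res = bdg.run_budget(
            tables["survey"], tables["densities"], tables["reef_areas"],
            transects=tables["transects"],
        )
        assert (res.transects["loss_kg_m2"] == 0.0).all()
        assert res.system["loss_t"] == 0.0

    def test_raising_dead_density_weakly_shrinks_loss(self):
        def run_with_dd(dd):
            species = [syn.SpeciesSimSpec("a", 1.0, "massive", 1.5, dd, True)]
            tables, _ = syn.generate_survey(
                syn.SurveySimParams(species=species, seed=7, transects_per_reef=3)
            )
            res = bdg.run_budget(
                tables["survey"], tables["densities"], tables["reef_areas"],
                transects=tables["transects"],
            )
            return res.system["loss_t"]

        losses = [run_with_dd(dd) for dd in (1.1, 1.3, 1.5)]
        assert losses[0] < losses[1] < losses[2] == 0.0
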