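import numpy as np
import pandas as pd
import pytest

import traitgrad as tg
from conftest import make_table, random_occurrence_table


class TestDeriveTraits:
    def test_direct_formulas(self):
        raw = pd.DataFrame({
            "plant_id": ["a"], "species": ["sp"], "plot": ["p"],
            "leaf_area_cm2": [10.0], "leaf_mass_g": [0.05],
            "leaf_thickness_mm": [0.2], "root_length_m": [2.0],
            "root_mass_g": [0.01], "root_volume_mm3": [40.0],
            "root_diameter_mm": [0.3],
        })
        out, bad = tg.derive_traits(raw)
        assert bad.empty
        row = out.iloc[0]
        assert row["sla"] == pytest.approx(200.0)
        # volume = 10 cm^2 x 0.2 mm = 200 mm^3; 0.05 g = 50 mg
        assert row["leaf_tissue_density"] == pytest.approx(0.25)
        assert row["srl"] == pytest.approx(200.0)
        assert row["root_tissue_density"] == pytest.approx(0.25)

    def test_nonpositive_mass_flagged(self):
        raw = pd.DataFrame({
            "plant_id": ["a", "b"], "leaf_area_cm2": [10.0, 10.0],
            "leaf_mass_g": [0.05, 0.0],
        })
        out, bad = tg.derive_traits(raw)
        assert len(out) == 1 and len(bad) == 1
        assert "leaf_mass_g" in bad.iloc[0]["reason"]


class TestImputation:
    def test_mean_of_other_plots_at_site(self):
        occ = make_table(
            [("A", "p1", 0.5), ("A", "p2", 0.5), ("A", "p3", 0.5)],
            [("i1", "A", "p1", "s", 1.0), ("i2", "A", "p2", "s", 3.0)],
            [("p1", "s", "h"), ("p2", "s", "h"), ("p3", "s", "h")],
        )
        out, log = tg.impute_missing_traits(occ)
        t = out.tsp("x").set_index("plot")["value"]
        assert t["p3"] == pytest.approx(2.0)
        assert (log["action"] == "imputed").sum() == 1

    def test_identity_when_complete(self, two_plot_table):
        out, log = tg.impute_missing_traits(two_plot_table)
        assert log.empty
        pd.testing.assert_frame_equal(out.occurrences,
                                      two_plot_table.occurrences)

    def test_never_measured_species_dropped(self):
        occ = make_table(
            [("A", "p1", 0.5), ("B", "p1", 0.5)],
            [("i1", "A", "p1", "s", 1.0)],
            [("p1", "s", "h")],
        )
        out, log = tg.impute_missing_traits(occ)
        assert "B" not in out.species
        assert (log["action"] == "dropped_species").any()


class TestTraitGradient:
    def test_worked_example(self, two_plot_table):
        res = tg.trait_gradient_analysis(two_plot_table, "x")
        assert res.plots["p_bar"].to_dict() == pytest.approx(
            {"p1": 3.0, "p2": 2.0})
        sp = res.species
        assert sp.loc["A", "t_bar"] == pytest.approx(2.0)
        assert sp.loc["A", "beta"] == pytest.approx(2.5)
        assert sp.loc["A", "alpha"] == pytest.approx(-0.5)
        assert sp.loc["B", "beta"] == pytest.approx(3.0)
        assert sp.loc["B", "alpha"] == pytest.approx(1.0)

    def test_lone_species_has_zero_alpha(self):
        occ = make_table(
            [("A", "p1", 0.4), ("A", "p2", 0.8)],
            [("i1", "A", "p1", "s", 1.5), ("i2", "A", "p2", "s", 2.5)],
            [("p1", "s", "h"), ("p2", "s", "h")],
        )
        sp = tg.trait_gradient_analysis(occ, "x").species
        assert sp.loc["A", "alpha"] == pytest.approx(0.0, abs=1e-12)
        assert sp.loc["A", "beta"] == pytest.approx(sp.loc["A", "t_bar"])

    @pytest.mark.parametrize("seed", range(20))
    def test_identity_and_weighted_mean_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        occ = random_occurrence_table(rng)
        res = tg.trait_gradient_analysis(occ, "x")
        assert res.check_identity(tol=1e-10) <= 1e-10
        # per plot, abundance-weighted deviations from p_bar vanish
        d = occ.occurrences.merge(occ.tsp("x"), on=["species", "plot"])
        d["p_bar"] = d["plot"].map(res.plots["p_bar"])
        resid = (d["abundance"] * (d["value"] - d["p_bar"])).groupby(
            d["plot"]).sum()
        assert resid.abs().max() < 1e-10

    def test_record_order_invariance(self):
        rng = np.random.default_rng(5)
        occ = random_occurrence_table(rng)
        shuffled = occ.copy()
        shuffled.occurrences = shuffled.occurrences.sample(
            frac=1, random_state=1).reset_index(drop=True)
        shuffled.plants = shuffled.plants.sample(
            frac=1, random_state=2).reset_index(drop=True)
        a = tg.trait_gradient_analysis(occ, "x")
        b = tg.trait_gradient_analysis(shuffled, "x")
        pd.testing.assert_frame_equal(a.species, b.species)
        pd.testing.assert_frame_equal(a.plots, b.plots)


class TestIntraspecificSlope:
    def _table(self, points, extra_species=True):
        """One focal species measured in len(points) plots; a partner
        species per plot tunes the plot mean to the requested x value."""
        occ_rows, plant_rows, plot_rows = [], [], []
        for i, (x, y) in enumerate(points):
            p = f"p{i}"
            # partner abundance 1, focal abundance 1 -> p_bar = (y+partner)/2
            partner = 2 * x - y
            occ_rows += [("F", p, 1.0), (f"Z{i}", p, 1.0)]
            plant_rows += [(f"f{i}", "F", p, "s", y),
                           (f"z{i}", f"Z{i}", p, "s", partner)]
            plot_rows.append((p, "s", "h"))
        return make_table(occ_rows, plant_rows, plot_rows)

    def test_constant_trait_gives_zero_slope(self):
        occ = self._table([(1.0, 2.0), (2.0, 2.0), (3.0, 2.0)])
        slopes, _ = tg.intraspecific_slope(occ, "x")
        assert slopes["F"] == pytest.approx(0.0, abs=1e-12)

    def test_tracking_the_gradient_gives_slope_one(self):
        occ = self._table([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        slopes, _ = tg.intraspecific_slope(occ, "x")
        assert slopes["F"] == pytest.approx(1.0)

    def test_hand_ols_slope_two(self):
        occ = self._table([(1.0, 1.0), (2.0, 3.0), (3.0, 5.0)])
        slopes, _ = tg.intraspecific_slope(occ, "x")
        assert slopes["F"] == pytest.approx(2.0)

    def test_too_few_plots_excluded(self):
        occ = self._table([(1.0, 1.0), (2.0, 3.0)])
        slopes, log = tg.intraspecific_slope(occ, "x", min_plots=3)
        assert "F" not in slopes.index
        assert (log["reason"] == "too_few_plots").any()

    def test_flat_gradient_excluded(self):
        occ = self._table([(2.0, 1.0), (2.0, 3.0), (2.0, 5.0)])
        slopes, log = tg.intraspecific_slope(occ, "x")
        assert "F" not in slopes.index
        assert (log["reason"] == "no_gradient_variance").any()


class TestBsTest:
    def test_symmetric_slopes_about_one(self):
        out = tg.test_bs([0.0, 2.0, 1.0, 1.0])
        assert out["mean"] == pytest.approx(1.0)
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["P"] == pytest.approx(1.0)
        assert out["df"] == 3

    def test_far_from_one_is_significant(self):
        rng = np.random.default_rng(0)
        out = tg.test_bs(rng.normal(0.0, 0.01, size=30))
        assert out["P"] < 1e-3

    def test_single_slope_rejected(self):
        with pytest.raises(ValueError):
            tg.test_bs([1.0])


class TestVariancePartition:
    def test_hand_sum_of_squares(self):
        occ = make_table(
            [("A", "p1", 1.0), ("B", "p1", 1.0),
             ("C", "p2", 1.0), ("D", "p2", 1.0)],
            [("1", "A", "p1", "s", 0.0), ("2", "B", "p1", "s", 2.0),
             ("3", "C", "p2", "s", 4.0), ("4", "D", "p2", "s", 6.0)],
            [("p1", "s", "h"), ("p2", "s", "h")],
        )
        vp = tg.variance_partition(occ, "x")
        assert vp["fraction_among_plots"] == pytest.approx(0.8)
        assert vp["fraction_within_plots"] == pytest.approx(0.2)

    def test_equal_plot_means_give_zero_among(self):
        occ = make_table(
            [("A", "p1", 1.0), ("B", "p1", 1.0),
             ("A", "p2", 1.0), ("B", "p2", 1.0)],
            [("1", "A", "p1", "s", 0.0), ("2", "B", "p1", "s", 2.0),
             ("3", "A", "p2", "s", 0.0), ("4", "B", "p2", "s", 2.0)],
            [("p1", "s", "h"), ("p2", "s", "h")],
        )
        vp = tg.variance_partition(occ, "x")
        assert vp["fraction_among_plots"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_fractions_bounded_and_complementary(self, seed):
        occ = random_occurrence_table(np.random.default_rng(seed))
        vp = tg.variance_partition(occ, "x")
        for v in vp.values():
            assert 0.0 <= v <= 1.0
        assert vp["fraction_among_plots"] + vp["fraction_within_plots"] == \
            pytest.approx(1.0)
        assert vp["fraction_among_species"] + vp["fraction_within_species"] \
            == pytest.approx(1.0)


class TestComponentR2:
    def test_constant_beta_gives_alpha_r2_one(self):
        res = tg.TraitGradientResult(
            trait="x",
            species=pd.DataFrame({
                "t_bar": [1.0, 2.0, 4.0], "beta": [0.5, 0.5, 0.5],
                "alpha": [0.5, 1.5, 3.5]}, index=["a", "b", "c"]),
            plots=pd.DataFrame())
        r2 = tg.component_r2(res)
        assert r2["r2_alpha"] == pytest.approx(1.0)
        assert r2.get("r2_beta_degenerate") is True

    def test_constant_alpha_gives_beta_r2_one(self):
        res = tg.TraitGradientResult(
            trait="x",
            species=pd.DataFrame({
                "t_bar": [1.0, 2.0, 4.0], "beta": [0.9, 1.9, 3.9],
                "alpha": [0.1, 0.1, 0.1]}, index=["a", "b", "c"]),
            plots=pd.DataFrame())
        r2 = tg.component_r2(res)
        assert r2["r2_beta"] == pytest.approx(1.0)


class TestLoadTables:
    def test_percent_abundance_and_log10(self, tmp_path):
        comm = tmp_path / "c.csv"
        comm.write_text("plot,species,abundance\np1,A,50\np1,B,100\n")
        traits = tmp_path / "t.csv"
        traits.write_text(
            "plant_id,species,plot,site,x\ni1,A,p1,s,100\ni2,B,p1,s,10\n")
        occ = tg.load_tables(comm, traits)
        assert occ.occurrences["abundance"].tolist() == [0.5, 1.0]
        assert sorted(occ.plants["x"]) == pytest.approx([1.0, 2.0])

    def test_nonpositive_trait_rejected(self, tmp_path):
        comm = tmp_path / "c.csv"
        comm.write_text("plot,species,abundance\np1,A,0.5\n")
        traits = tmp_path / "t.csv"
        traits.write_text("plant_id,species,plot,site,x\ni1,A,p1,s,-3\n")
        with pytest.raises(ValueError):
            tg.load_tables(comm, traits)
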