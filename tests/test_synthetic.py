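"""Ground-truth landscapes, selection simulation, fixtures."""

import numpy as np
import pytest

from amynuc.constants import AB42
from amynuc.library_design import Mutation, enumerate_variants, paper_designs
from amynuc.synthetic import (
    AtomSpec,
    GroundTruthLandscape,
    ResidueSpec,
    build_pdb,
    generate_fixture_structure,
    generate_stability_table,
    sample_landscape,
    serpentine_fixture,
    simulate_selection,
)
from amynuc.structure import distance_matrix, parse_structure


@pytest.fixture()
def cterm_design(designs):
    return designs["cterm"]


class TestLandscapeSampling:
    def test_zero_density_means_no_couplings(self, cterm_design):
        land = sample_landscape(cterm_design, coupling_density=0.0, seed=0)
        assert land.couplings == {}

    def test_same_seed_identical(self, cterm_design):
        a = sample_landscape(cterm_design, coupling_density=0.2, seed=5)
        b = sample_landscape(cterm_design, coupling_density=0.2, seed=5)
        assert a.first_order == b.first_order
        assert a.couplings == b.couplings

    def test_coupling_density_binomial(self, designs):
        # 40 co-mutable pairs x 16 mutation combos = 640 candidate couplings
        land = sample_landscape(
            [designs["comb1"], designs["comb2"]], coupling_density=0.1, seed=3
        )
        n = len(land.couplings)
        # binomial(640, 0.1): mean 64, sd ~7.6; allow 4 sd
        assert 64 - 31 <= n <= 64 + 31

    def test_sign_split_roughly_matches_mixture(self, designs):
        land = sample_landscape(designs["shallow"], coupling_density=0, seed=11)
        vals = np.array(list(land.first_order.values()))
        frac_pos = np.mean(vals > 0.1)
        assert 0.6 < frac_pos < 0.85  # majority destabilizing


class TestGrowthRateMap:
    def test_wt_is_zero(self):
        land = GroundTruthLandscape({"I41M": 1.0})
        assert land.growth_rate(()) == 0.0

    def test_saturation_at_lower_bound(self):
        land = GroundTruthLandscape({"I41M": 50.0}, sigmoid=(-4.0, 0.0, 1.0))
        gr = land.growth_rate((Mutation(41, "I", "M"),))
        # centered lower asymptote: L - g(0) = -4 - (-2) = -2
        assert gr == pytest.approx(-2.0, abs=1e-6)

    def test_additivity_without_coupling(self):
        land = GroundTruthLandscape({"I41M": 0.7, "A42T": -0.3})
        phi = land.trait((Mutation(41, "I", "M"), Mutation(42, "A", "T")))
        assert phi == pytest.approx(0.4)

    def test_coupling_contributes_once(self):
        land = GroundTruthLandscape(
            {"I41M": 0.7, "A42T": -0.3}, {("I41M", "A42T"): 1.0}
        )
        phi = land.trait((Mutation(41, "I", "M"), Mutation(42, "A", "T")))
        assert phi == pytest.approx(1.4)

    def test_unknown_mutation_rejected(self):
        land = GroundTruthLandscape({"I41M": 0.7})
        with pytest.raises(KeyError, match="V40L"):
            land.growth_rate((Mutation(40, "V", "L"),))

    def test_monotone_decreasing(self):
        land = GroundTruthLandscape({"I41M": 0.5, "A42T": 2.0})
        g1 = land.growth_rate((Mutation(41, "I", "M"),))
        g2 = land.growth_rate((Mutation(42, "A", "T"),))
        assert g2 < g1 < 0


class TestSelectionSimulation:
    def test_deterministic_given_seed(self, cterm_design):
        land = sample_landscape(cterm_design, 0.0, seed=0)
        variants = enumerate_variants(cterm_design, 1, include_wt=True)[:50]
        a = simulate_selection(land, variants, depth=10_000, seed=9)
        b = simulate_selection(land, variants, depth=10_000, seed=9)
        assert a.equals(b)

    def test_depth_conserved_per_pool(self, cterm_design):
        land = sample_landscape(cterm_design, 0.0, seed=0)
        variants = enumerate_variants(cterm_design, 1, include_wt=True)[:50]
        depth = 25_000
        counts = simulate_selection(land, variants, depth=depth, replicates=3, seed=4)
        for r in (1, 2, 3):
            assert counts[f"input{r}"].sum() == depth
            assert counts[f"output{r}"].sum() == depth

    def test_equal_growth_rates_keep_frequencies(self):
        land = GroundTruthLandscape({"I41M": 0.0, "A42T": 0.0})
        variants = enumerate_variants(
            paper_designs()["cterm"], 0, include_wt=True
        )
        counts = simulate_selection(land, variants, depth=200_000, seed=2)
        # single variant: all reads in both pools
        assert counts["input1"].iloc[0] == counts["output1"].iloc[0] == 200_000

    def test_log_ratio_tracks_truth_at_depth(self, cterm_design):
        land = sample_landscape(cterm_design, 0.0, seed=1)
        variants = enumerate_variants(cterm_design, 1, include_wt=True)
        counts = simulate_selection(land, variants, depth=10**6, seed=7)
        wt = counts.index[counts["variant"] == "WT"][0]
        lr = np.log(
            (counts["output1"] + 0.5) / (counts["input1"] + 0.5)
        )
        est = lr - lr[wt]
        mask = counts["variant"] != "WT"
        r = np.corrcoef(est[mask], counts.loc[mask, "true_gr"])[0, 1]
        assert r > 0.99

    def test_rejects_nonpositive_depth(self, cterm_design):
        land = sample_landscape(cterm_design, 0.0, seed=0)
        with pytest.raises(ValueError, match="depth"):
            simulate_selection(land, [], depth=0)


class TestStabilityTable:
    def test_perfect_correlation_gives_unit_ratio_in_region(self):
        ddg = {"I41M": 2.0, "V40L": 3.0, "F19L": 1.5}
        tab = generate_stability_table(
            ddg, structures=(("S1", 4),), region=(29, 42), correlation=1.0, seed=0
        )
        in_region = tab[tab["mutation"].isin(["I41M", "V40L"])]
        assert np.allclose(
            in_region["assembly_ddg"] / in_region["n_chains"],
            [2.0, 3.0],
        )

    def test_reproducible(self):
        ddg = {"I41M": 2.0}
        a = generate_stability_table(ddg, seed=5)
        b = generate_stability_table(ddg, seed=5)
        assert a.equals(b)


class TestFixtureStructures:
    def test_two_residue_distance_by_construction(self):
        residues = [
            ResidueSpec("A", 1, "A", (AtomSpec("CB", "C", (0.0, 0.0, 0.0)),)),
            ResidueSpec("A", 2, "A", (AtomSpec("CB", "C", (3.0, 4.0, 0.0)),)),
        ]
        pdb = build_pdb(residues)
        model = parse_structure(pdb, chains=["A"])
        dm = distance_matrix(model, "monomer", "A")
        assert dm.get(1, 2) == pytest.approx(5.0, abs=1e-3)

    def test_glycine_gets_calpha_only(self):
        pdb = serpentine_fixture(AB42)
        model = parse_structure(pdb, chains=["A"])
        gly = model.chain("A")[33]  # G33
        assert gly.sidechain.shape == (1, 3)

    def test_coordinates_roundtrip(self):
        residues = [
            ResidueSpec("A", 7, "L", (AtomSpec("CB", "C", (1.234, -5.678, 9.012)),)),
        ]
        model = parse_structure(build_pdb(residues), chains=["A"])
        np.testing.assert_allclose(
            model.chain("A")[7].sidechain[0], [1.234, -5.678, 9.012], atol=1e-3
        )

    def test_dimer_mode_computable_on_stacked_chains(self):
        pdb = serpentine_fixture(AB42, chains=("A", "B"), chain_offset=10.0)
        model = parse_structure(pdb)
        dm = distance_matrix(model, "dimer", chain_pair=("A", "B"))
        assert len(dm.positions) == 42
        assert (dm.values > 0).all()

    def test_malformed_spec_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            build_pdb([ResidueSpec("A", 1, "A", ())])
        with pytest.raises(ValueError, match="duplicate"):
            build_pdb(
                [
                    ResidueSpec("A", 1, "A", (AtomSpec("CB", "C", (0, 0, 0)),)),
                    ResidueSpec("A", 1, "G", (AtomSpec("CA", "C", (1, 1, 1)),)),
                ]
            )

    def test_explicit_ca_coords_mode(self):
        pdb = generate_fixture_structure(
            sequence=AB42, ca_coords={1: (0.0, 0.0, 0.0), 42: (20.0, 0.0, 0.0)}
        )
        model = parse_structure(pdb, chains=["A"])
        assert set(model.chain("A")) == {1, 42}
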