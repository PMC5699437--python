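"""Generator properties: trees, traits, masking, sites, communities, rasters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beediv import diversity as dv
from beediv import synthetic as syn
from beediv._util import child_seeds


class TestSimulateTree:
    def test_tip_count_labels_and_ultrametricity(self):
        tree, pool = syn.simulate_tree(17, seed=5)
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert len(tips) == 17 == len(pool)
        assert sorted(tips) == sorted(pool["species_id"])
        assert syn.is_ultrametric(tree, tol=1e-8)
        assert pool["species_id"].is_unique
        assert pool[["genus", "family"]].notna().all().all()

    def test_two_tip_tree_is_cherry_with_half_cophenetic_equal_height(self):
        tree, _ = syn.simulate_tree(2, seed=3)
        height = syn.tree_height(tree)
        d = dv.phylo_distances(tree)
        # half the cophenetic distance between the only two tips is the
        # depth of their common ancestor (the root), i.e. the tree height
        pdm = tree.phylogenetic_distance_matrix()
        taxa = [lf.taxon for lf in tree.leaf_node_iter()]
        assert pdm.patristic_distance(*taxa) / 2 == pytest.approx(height, rel=1e-9)
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_birth_death_tree_ultrametric_with_extinction(self):
        tree, _ = syn.simulate_tree(50, birth=1.0, death=0.5, seed=7)
        depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-8
        assert all(e.length > 0 for e in tree.edges() if e.tail_node is not None)

    def test_nonviable_rates_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_tree(10, birth=1.0, death=1.0, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_tree(1, seed=0)

    def test_seeded_determinism(self):
        t1, p1 = syn.simulate_tree(12, seed=9)
        t2, p2 = syn.simulate_tree(12, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        pd.testing.assert_frame_equal(p1, p2)

    def test_genera_are_clades(self):
        tree, pool = syn.simulate_tree(40, seed=11)
        for genus, grp in pool.groupby("genus"):
            taxa = [tree.taxon_namespace.get_taxon(s) for s in grp["species_id"]]
            if len(taxa) == 1:
                continue
            mrca = tree.mrca(taxa=taxa)
            clade = {lf.taxon.label for lf in mrca.leaf_iter()}
            assert clade == set(grp["species_id"])


class TestSimulateTraits:
    def test_zero_rate_brownian_returns_root_value(self, small_system):
        tree, _, _ = small_system
        specs = [
            syn.TraitSpec("flat", "continuous", rate=0.0, root=7.5),
            syn.TraitSpec("cat", "categorical", rate=0.1, levels=("a", "b")),
        ]
        traits = syn.simulate_traits(tree, specs, seed=0)
        assert np.allclose(traits["flat"], 7.5)

    def test_empty_spec_rejected(self, small_system):
        tree, _, _ = small_system
        with pytest.raises(ValueError):
            syn.simulate_traits(tree, [], seed=0)

    def test_star_tree_tips_are_independent(self):
        """On a star phylogeny Brownian tip values are i.i.d.: the mean
        cross-tip sample correlation over replicates is ~0."""
        n = 10
        nwk = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        reps = np.stack(
            [
                syn.simulate_traits(
                    tree, [syn.TraitSpec("x", "continuous", rate=1.0)], seed=s
                )["x"].to_numpy()
                for s in range(400)
            ]
        )
        c = np.corrcoef(reps, rowvar=False)
        off = c[~np.eye(n, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_phylogenetic_signal_sisters_closer_than_random(self, balanced_tree_32):
        """Sister tips share almost the whole Brownian path, so their mean
        squared difference is far below that of random tip pairs."""
        rngpairs = np.random.default_rng(0)
        sister_msd, random_msd = [], []
        for s in range(100):
            x = syn.simulate_traits(
                balanced_tree_32, [syn.TraitSpec("x", "continuous", rate=1.0)], seed=s
            )["x"]
            v = x.to_numpy()
            sister_msd.append(np.mean((v[0::2] - v[1::2]) ** 2))
            i, j = rngpairs.integers(0, 32, 16), rngpairs.integers(0, 32, 16)
            ok = i != j
            random_msd.append(np.mean((v[i[ok]] - v[j[ok]]) ** 2))
        assert np.mean(sister_msd) < np.mean(random_msd)


class TestMaskTraits:
    def test_paper_scale_masking_counts(self, ):
        """11.7% partial and 4.1% total of 317 species gives 37 and 13."""
        idx = pd.Index([f"s{i}" for i in range(317)], name="species_id")
        traits = pd.DataFrame(
            {"a": np.arange(317.0), "b": pd.Series(["x", "y"] * 159)[:317].astype(object)},
            index=idx,
        )
        masked, mask = syn.mask_traits(traits, 0.117, 0.041, seed=1)
        per_species = mask.sum(axis=1)
        assert (per_species == traits.shape[1]).sum() == 13
        assert ((per_species >= 1) & (per_species < traits.shape[1])).sum() == 37

    def test_zero_fractions_change_nothing(self, small_system):
        _, _, traits = small_system
        masked, mask = syn.mask_traits(traits, 0.0, 0.0, seed=1)
        assert not mask.any().any()
        pd.testing.assert_frame_equal(masked, traits)

    def test_seeded_mask_reproducible(self, small_system):
        _, _, traits = small_system
        _, m1 = syn.mask_traits(traits, 0.5, 0.0, seed=42)
        _, m2 = syn.mask_traits(traits, 0.5, 0.0, seed=42)
        pd.testing.assert_frame_equal(m1, m2)

    def test_invalid_fractions_rejected(self, small_system):
        _, _, traits = small_system
        with pytest.raises(ValueError):
            syn.mask_traits(traits, 0.8, 0.5, seed=0)
        with pytest.raises(ValueError):
            syn.mask_traits(traits, -0.1, 0.0, seed=0)


class TestSimulateSites:
    def test_single_class_mix(self):
        mix = {k: 0.0 for k in syn.LAND_USE_LEVELS}
        mix["seminatural"] = 1.0
        sites = syn.simulate_sites(3, 10, landuse_mix=mix, seed=0)
        assert (sites["land_use"] == "seminatural").all()

    def test_shape_and_nesting(self):
        sites = syn.simulate_sites(10, 20, seed=1)
        assert len(sites) == 200
        assert sites["study_id"].nunique() == 10
        assert (sites["effort"] > 0).all()
        assert (sites["hpd"] >= 0).all()
        # blocks of five sites nested within studies
        blocks_per_study = sites.groupby("study_id")["block_id"].nunique()
        assert (blocks_per_study == math.ceil(20 / 5)).all()

    def test_realized_mix_within_binomial_error(self):
        sites = syn.simulate_sites(30, 40, seed=2)
        n = len(sites)
        mix = syn.default_landuse_mix()
        for level, p in mix.items():
            k = int((sites["land_use"] == level).sum())
            assert stats.binomtest(k, n, p).pvalue > 1e-4

    def test_unnormalized_mix_rejected(self):
        mix = {k: 1.0 for k in syn.LAND_USE_LEVELS}
        with pytest.raises(ValueError):
            syn.simulate_sites(2, 5, landuse_mix=mix, seed=0)


class TestSimulateCommunities:
    def test_null_effects_leave_land_uses_indistinguishable(self, small_system):
        """With all injected effects zero, mean ln E_SD must not differ
        between pasture and semi-natural sites (two-sided test, alpha 0.01,
        over a large multi-study network)."""
        tree, pool, traits = small_system
        truth = syn.GroundTruth(
            lu_effects_sd={k: 0.0 for k in syn.LAND_USE_LEVELS},
            hpd_slopes={k: 0.0 for k in syn.LAND_USE_LEVELS},
            sd_study=0.0,
            sd_block=0.0,
        )
        sites = syn.simulate_sites(200, 6, seed=21)
        comm = syn.simulate_communities(sites, pool, tree, traits, truth, seed=22)
        div = dv.site_diversity(comm)
        ln_e = np.log(div.set_index("site_id")["E_sd"])
        lu = sites.set_index("site_id")["land_use"]
        a = ln_e[lu == "pasture"]
        b = ln_e[lu == "seminatural"]
        assert stats.ttest_ind(a, b).pvalue > 0.01

    def test_injected_pasture_effect_recovered(self, small_system):
        """The −0.39 log-scale pasture contrast is recovered within two
        standard errors at 500 sites."""
        from beediv.models import ModelSpec, fit_lmm, prepare_model_frame

        tree, pool, traits = small_system
        sites = syn.simulate_sites(10, 50, seed=31)
        comm = syn.simulate_communities(sites, pool, tree, traits, seed=32)
        div = dv.site_diversity(dv.effort_correct(comm, sites))
        data, centring = prepare_model_frame(sites, div)
        fit = fit_lmm(data, ModelSpec("ln_E_sd", ("land_use",)), "ML", centring)
        est, se = fit.params["land_use[T.pasture]"], fit.bse["land_use[T.pasture]"]
        assert abs(est - (-0.39)) <= 2 * se

    def test_expected_richness_one_gives_monoculture(self, small_system):
        tree, pool, traits = small_system
        truth = syn.GroundTruth(
            lu_effects_sd={k: 0.0 for k in syn.LAND_USE_LEVELS},
            baseline_ln_e_sd=0.0,
            sd_study=0.0,
            sd_block=0.0,
            sd_resid=0.0,
        )
        sites = syn.simulate_sites(2, 5, seed=41)
        comm = syn.simulate_communities(sites, pool, tree, traits, truth, seed=42)
        div = dv.site_diversity(comm)
        assert np.allclose(div["E_sd"], 1.0)
        assert (comm.groupby("site_id").size() == 1).all()

    def test_missing_level_in_truth_rejected(self, small_system):
        tree, pool, traits = small_system
        with pytest.raises(ValueError):
            syn.GroundTruth(lu_effects_sd={"seminatural": 0.0})


class TestSimulateRasters:
    def test_fractions_sum_to_one(self):
        stack = syn.simulate_rasters((15, 20), 4, seed=3)
        total = sum(stack.fractions().values())
        assert np.allclose(total, 1.0, atol=1e-9)
        assert all((v >= 0).all() for v in stack.fractions().values())

    def test_country_count_and_subregions(self):
        stack = syn.simulate_rasters((20, 20), 3, seed=4)
        assert len(np.unique(stack.layers["country_id"])) == 3
        assert set(np.unique(stack.layers["subregion_id"])) <= {1.0, 2.0, 3.0, 4.0}

    def test_seeded_rerun_bit_identical(self):
        s1 = syn.simulate_rasters((10, 10), 2, seed=5)
        s2 = syn.simulate_rasters((10, 10), 2, seed=5)
        for name in s1.layers:
            assert np.array_equal(s1.layers[name], s2.layers[name])

    def test_bad_extent_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_rasters((0, 10), 2, seed=0)
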