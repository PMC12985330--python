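"""Synthetic-data generators: determinism, calibration, ground truth."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from chromascape import landscape, simulate
from chromascape.colours import COLOURS
from chromascape.errors import InvalidParameterError
from chromascape.phylo import phylo_correlation, rooted_clades, tip_labels
from chromascape.simulate import (
    DEFAULT_COLOUR_MEAN_PCT,
    SyntheticScenario,
    gen_colour_table,
    gen_communities,
    gen_inequality_scenario,
    gen_landscape,
    gen_phylogeny,
    gen_tree_set,
)


class TestColourTable:
    def test_profiles_sum_to_100(self):
        table = gen_colour_table(50, seed=1)
        np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)
        assert (table.to_numpy() >= 0).all()

    def test_uniform_concentration_profiles_sum_exactly(self):
        table = gen_colour_table(20, concentration=np.ones(10), seed=2)
        np.testing.assert_allclose(table.sum(axis=1), 100.0, atol=1e-9)

    def test_deterministic_under_seed(self):
        a = gen_colour_table(30, seed=5)
        b = gen_colour_table(30, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = gen_colour_table(30, seed=6)
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_default_mean_recovers_survey_colour_shares(self):
        """Sample mean over 10,000 species within 3 MC SE of the target."""
        n = 10_000
        table = gen_colour_table(n, seed=3)
        alpha = simulate.default_concentration()
        a0 = alpha.sum()
        mean_target = 100 * alpha / a0
        var = (
            100**2 * alpha * (a0 - alpha) / (a0**2 * (a0 + 1))
        )  # Dirichlet marginal variance
        se = np.sqrt(var / n)
        sample_mean = table[list(COLOURS)].mean(axis=0).to_numpy()
        np.testing.assert_array_less(np.abs(sample_mean - mean_target), 3 * se)
        # the Dirichlet mean is proportional to the default colour shares
        np.testing.assert_allclose(
            mean_target,
            100 * DEFAULT_COLOUR_MEAN_PCT / DEFAULT_COLOUR_MEAN_PCT.sum(),
            atol=1e-9,
        )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_colour_table(5, concentration=np.zeros(10), seed=0)


class TestPhylogenyGen:
    def test_two_species_cherry_equal_depths(self):
        tree = gen_phylogeny(2, seed=1)
        corr = phylo_correlation(tree)
        assert corr.shape == (2, 2)

    def test_tip_labels_match_requested_species(self):
        tree = gen_phylogeny(50, seed=4)
        assert sorted(tip_labels(tree)) == simulate.species_ids(50)

    @pytest.mark.parametrize("n,seed", [(5, 0), (20, 1), (50, 2)])
    def test_ultrametric_with_positive_branches(self, n, seed):
        tree = gen_phylogeny(n, seed=seed)
        depths = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                assert node.edge.length > 0
                depths[node] = depths[node.parent_node] + node.edge.length
        tip_depths = [depths[l] for l in tree.leaf_node_iter()]
        np.testing.assert_allclose(tip_depths, tip_depths[0], rtol=1e-9)

    def test_invalid_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_phylogeny(1, seed=0)


class TestTreeSet:
    def test_counts_and_shared_topology(self):
        trees = gen_tree_set(8, [(1, 10)], seed=0)
        assert len(trees) == 10
        clade_sets = [frozenset(rooted_clades(t)) for t in trees]
        assert all(cs == clade_sets[0] for cs in clade_sets)

    def test_clade_frequencies_match_mixture(self):
        trees = gen_tree_set(6, [(1, 7), (2, 3)], seed=0)
        assert len(trees) == 10
        counts = Counter()
        for t in trees:
            counts.update(rooted_clades(t))
        a_only = frozenset(rooted_clades(trees[0])) - frozenset(
            rooted_clades(trees[-1])
        )
        b_only = frozenset(rooted_clades(trees[-1])) - frozenset(
            rooted_clades(trees[0])
        )
        assert a_only and b_only  # topologies actually differ
        assert all(counts[c] == 7 for c in a_only)
        assert all(counts[c] == 3 for c in b_only)

    def test_empty_and_bad_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_tree_set(5, [], seed=0)
        with pytest.raises(InvalidParameterError):
            gen_tree_set(5, [(1, 0)], seed=0)


class TestLandscape:
    def test_pure_cropland_mix_dominates_everywhere(self):
        sc = SyntheticScenario(seed=1, n_sites=10, habitat_mix={"croplands": 1.0})
        patches, _, truth = gen_landscape(sc)
        for site, site_patches in patches.items():
            comp = landscape.buffer_composition(site_patches)
            assert comp.pct["croplands"] >= 60.0
            assert truth.site_habitat[site] == "croplands"

    def test_patch_union_area_matches_disc(self):
        sc = SyntheticScenario(seed=2, n_sites=5)
        patches, _, _ = gen_landscape(sc)
        disc_area = np.pi * 200.0**2
        for site_patches in patches.values():
            total = sum(p.geometry.area for p in site_patches)
            assert total == pytest.approx(disc_area, rel=0.01)

    def test_true_label_recoverable_by_ruleset(self):
        sc = SyntheticScenario(seed=3, n_sites=40)
        patches, _, truth = gen_landscape(sc)
        hits = sum(
            landscape.buffer_composition(ps).habitat == truth.site_habitat[site]
            for site, ps in patches.items()
        )
        assert hits / len(patches) >= 0.9

    def test_deterministic_under_seed(self):
        sc = SyntheticScenario(seed=4, n_sites=4)
        a, coords_a, _ = gen_landscape(sc)
        b, coords_b, _ = gen_landscape(sc)
        pd.testing.assert_frame_equal(coords_a, coords_b)
        for site in a:
            assert [p.geometry.wkt for p in a[site]] == [
                p.geometry.wkt for p in b[site]
            ]

    def test_bad_cell_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_landscape(SyntheticScenario(seed=0, n_sites=1), cell_size=0)


class TestCommunities:
    def _inputs(self, n_species=30, seed=0):
        table = gen_colour_table(n_species, seed=seed)
        tree = gen_phylogeny(n_species, seed=seed)
        return table, tree

    def test_zero_affinity_occupancy_independent_of_habitat(self):
        table, tree = self._inputs()
        sc = SyntheticScenario(
            seed=1, n_species=30, n_sites=2000, affinity_strength=0.0
        )
        labels = {
            s: h
            for s, h in zip(
                simulate.site_ids(2000),
                np.random.default_rng(0).choice(
                    list(sc.habitat_mix), 2000, p=list(sc.habitat_mix.values())
                ),
            )
        }
        community, truth = gen_communities(table, tree, labels, sc)
        rates = community.groupby(pd.Series(labels)).mean()
        # per-species occupancy should not differ across habitats beyond
        # binomial noise; compare the grand rates per habitat
        habitat_rates = rates.mean(axis=1)
        assert habitat_rates.max() - habitat_rates.min() < 0.05

    def test_strong_affinity_boosts_matched_species(self):
        table, tree = self._inputs()
        sc = SyntheticScenario(
            seed=2, n_species=30, n_sites=2000, affinity_strength=4.0
        )
        rng = np.random.default_rng(1)
        labels = dict(
            zip(
                simulate.site_ids(2000),
                rng.choice(list(sc.habitat_mix), 2000, p=list(sc.habitat_mix.values())),
            )
        )
        community, truth = gen_communities(table, tree, labels, sc)
        label_series = pd.Series(labels)
        matched, unmatched = [], []
        for sp, aff in truth.species_affinity.items():
            in_home = community.loc[label_series == aff, sp].mean()
            away = community.loc[label_series != aff, sp].mean()
            matched.append(in_home)
            unmatched.append(away)
        assert np.mean(matched) > np.mean(unmatched) + 0.2

    def test_mean_richness_close_to_target(self):
        table, tree = self._inputs(n_species=60, seed=5)
        sc = SyntheticScenario(
            seed=5, n_species=60, n_sites=1000, richness_target=15.0
        )
        rng = np.random.default_rng(2)
        labels = dict(
            zip(
                simulate.site_ids(1000),
                rng.choice(list(sc.habitat_mix), 1000, p=list(sc.habitat_mix.values())),
            )
        )
        community, _ = gen_communities(table, tree, labels, sc)
        assert community.sum(axis=1).mean() == pytest.approx(15.0, rel=0.10)

    def test_every_site_has_at_least_two_species(self):
        table, tree = self._inputs(n_species=10, seed=6)
        sc = SyntheticScenario(
            seed=6, n_species=10, n_sites=300, richness_target=2.0
        )
        labels = {s: "croplands" for s in simulate.site_ids(300)}
        community, _ = gen_communities(table, tree, labels, sc)
        assert (community.sum(axis=1) >= 2).all()

    def test_low_richness_target_rejected(self):
        table, tree = self._inputs(n_species=10, seed=7)
        sc = SyntheticScenario(seed=7, n_species=10, n_sites=5, richness_target=5)
        sc.richness_target = 1.0
        with pytest.raises(InvalidParameterError):
            gen_communities(table, tree, {"site00001": "croplands"}, sc)

    def test_mismatched_species_sets_rejected(self):
        table = gen_colour_table(10, seed=8)
        tree = gen_phylogeny(12, seed=8)
        sc = SyntheticScenario(seed=8, n_species=10, n_sites=5, richness_target=5)
        with pytest.raises(InvalidParameterError):
            gen_communities(table, tree, {"site00001": "croplands"}, sc)


class TestInequalityScenario:
    def test_noiseless_limit_recovers_coefficients(self):
        from chromascape import models

        sc = SyntheticScenario(seed=1, n_sites=2000, noise_sd=1e-10)
        data, truth = gen_inequality_scenario(sc)
        spec = models.ModelSpec(
            response="gini",
            predictors=models.INEQUALITY_PREDICTORS,
            habitat=None,
        )
        res = models.fit_colour_glm(data, spec)
        for pred in simulate.DIRECT_PREDICTORS:
            planted = truth.planted_coefficients[pred]
            if planted == 0.0:
                assert abs(res.terms.loc[pred, "estimate"]) < 1e-9
            else:
                assert res.terms.loc[pred, "estimate"] == pytest.approx(
                    planted, rel=1e-6
                )

    def test_coefficient_bias_shrinks_with_sample_size(self):
        from chromascape import models

        biases = {}
        for n in (200, 2000):
            errs = []
            for seed in range(30):
                sc = SyntheticScenario(seed=seed, n_sites=n)
                data, truth = gen_inequality_scenario(sc)
                spec = models.ModelSpec(
                    response="gini",
                    predictors=models.INEQUALITY_PREDICTORS,
                    habitat=None,
                )
                res = models.fit_colour_glm(data, spec)
                errs.append(
                    res.terms.loc["psv", "estimate"]
                    - truth.planted_coefficients["psv"]
                )
            biases[n] = np.abs(np.mean(errs))
        assert biases[2000] < biases[200] + 0.01

    def test_missing_planted_coefficient_rejected(self):
        sc = SyntheticScenario(seed=0, n_sites=10)
        del sc.planted_coefficients["psv"]
        with pytest.raises(InvalidParameterError):
            gen_inequality_scenario(sc)

    def test_deterministic_under_seed(self):
        a, _ = gen_inequality_scenario(SyntheticScenario(seed=9, n_sites=50))
        b, _ = gen_inequality_scenario(SyntheticScenario(seed=9, n_sites=50))
        pd.testing.assert_frame_equal(a, b)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 1},
            {"n_sites": 0},
            {"habitat_mix": {"croplands": 0.5}},
            {"habitat_mix": {"lunar": 1.0}},
            {"affinity_strength": -1.0},
            {"noise_sd": 0.0},
            {"colour_concentration": np.zeros(10)},
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            SyntheticScenario(seed=0, **kwargs)
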