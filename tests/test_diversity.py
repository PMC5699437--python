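"""Rao's quadratic entropy, distance constructions and effective numbers."""

import numpy as np
import pandas as pd
import pytest

from beediv import diversity as dv
from tests.conftest import toy_tree


def brute_force_rao(p, d):
    """Independent oracle: the explicit double sum of Eq. Q = Σ d_ij p_i p_j."""
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += d[i, j] * p[i] * p[j]
    return q


class TestEffortCorrect:
    @staticmethod
    def _tables(efforts):
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(len(efforts))],
                "study_id": "st1",
                "effort": efforts,
            }
        )
        comm = pd.DataFrame(
            {"site_id": [f"s{i}" for i in range(len(efforts))], "species_id": "spA", "abundance": 10.0}
        )
        return sites, comm

    def test_linear_scaling_to_study_maximum(self):
        sites, comm = self._tables([1.0, 2.0, 5.0])
        out = dv.effort_correct(comm, sites)
        assert out["abundance"].tolist() == [50.0, 25.0, 10.0]

    def test_equal_effort_study_unchanged(self):
        sites, comm = self._tables([3.0, 3.0, 3.0])
        out = dv.effort_correct(comm, sites)
        assert out["abundance"].tolist() == [10.0, 10.0, 10.0]

    def test_correction_is_within_study_only(self):
        sites = pd.DataFrame(
            {
                "site_id": ["a", "b"],
                "study_id": ["st1", "st2"],
                "effort": [1.0, 10.0],
            }
        )
        comm = pd.DataFrame({"site_id": ["a", "b"], "species_id": "sp", "abundance": [5.0, 5.0]})
        out = dv.effort_correct(comm, sites)
        # each site is already at its own study's maximum effort
        assert out["abundance"].tolist() == [5.0, 5.0]

    def test_unknown_site_and_zero_effort_rejected(self):
        sites, comm = self._tables([1.0, 0.0, 2.0])
        with pytest.raises(ValueError):
            dv.effort_correct(comm, sites)
        with pytest.raises(KeyError):
            dv.effort_correct(
                pd.DataFrame({"site_id": ["zz"], "species_id": ["s"], "abundance": [1.0]}),
                sites,
            )


class TestSpeciesDistances:
    def test_unit_offdiagonal(self):
        d = dv.species_distances(["a", "b", "c"])
        assert d.matrix.shape == (3, 3)
        assert d.matrix.sum() == 6  # six off-diagonal ones
        assert np.all(np.diag(d.matrix) == 0)

    def test_single_species(self):
        d = dv.species_distances(["only"])
        assert d.matrix.shape == (1, 1) and d.matrix[0, 0] == 0

    def test_rao_equals_gini_simpson(self):
        p = np.array([0.5, 0.3, 0.2])
        d = dv.species_distances(["a", "b", "c"])
        assert dv.rao_q(p, d) == pytest.approx(1 - np.sum(p**2), abs=1e-12)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            dv.species_distances(["a", "a"])


class TestGowerDistances:
    def test_single_categorical_mismatch_of_two_traits(self):
        traits = pd.DataFrame(
            {"size": [1.0, 1.0], "nest": pd.array(["ground", "cavity"], dtype=object)},
            index=["a", "b"],
        )
        # zero-range continuous trait is excluded with a warning, leaving
        # only the categorical mismatch => raw 1.0; with both informative:
        with pytest.warns(UserWarning):
            d = dv.gower_distances(traits)
        traits2 = pd.DataFrame(
            {"size": [0.0, 1.0], "nest": pd.array(["ground", "ground"], dtype=object)},
            index=["a", "b"],
        )
        d2 = dv.gower_distances(traits2)
        # one of two equally weighted traits differs maximally: raw 0.5
        assert d2.matrix[0, 1] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_identical_rows_distance_zero(self):
        traits = pd.DataFrame(
            {"x": [2.0, 2.0, 5.0], "c": pd.array(["u", "u", "v"], dtype=object)},
            index=["a", "b", "c"],
        )
        d = dv.gower_distances(traits)
        assert d.matrix[0, 1] == 0.0

    def test_opposite_extremes_distance_one(self):
        traits = pd.DataFrame(
            {"x": [0.0, 1.0], "y": [10.0, -3.0], "c": pd.array(["u", "v"], dtype=object)},
            index=["a", "b"],
        )
        d = dv.gower_distances(traits)
        assert d.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_sqrt_corrected_matrix_is_euclidean_embeddable(self):
        """The doubly centred −D²/2 Gram matrix of the corrected Gower
        distances has no meaningfully negative eigenvalue."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            traits = pd.DataFrame(
                {
                    "a": rng.normal(size=10),
                    "b": rng.normal(size=10),
                    "c": pd.array(rng.choice(["x", "y", "z"], 10), dtype=object),
                },
                index=[f"s{i}" for i in range(10)],
            )
            d = dv.gower_distances(traits).matrix
            j = np.eye(10) - np.ones((10, 10)) / 10
            gram = -0.5 * j @ (d**2) @ j
            assert np.linalg.eigvalsh(gram).min() > -1e-8


class TestPhyloDistances:
    def test_toy_tree_half_cophenetic_rescaled(self):
        tree = toy_tree("((A:1,B:1):1,C:2);")
        d = dv.phylo_distances(tree, ["A", "B", "C"])
        # cophenetic(A,B)=2 -> half 1; cophenetic(A,C)=4 -> half 2; after
        # rescaling by the maximum: 0.5 and 1.0
        assert d.matrix[0, 1] == pytest.approx(0.5)
        assert d.matrix[0, 2] == pytest.approx(1.0)
        assert d.matrix[1, 2] == pytest.approx(1.0)
        assert np.all(np.diag(d.matrix) == 0)

    def test_root_spanning_pairs_hit_one_on_ultrametric_tree(self):
        tree = toy_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        d = dv.phylo_distances(tree, ["A", "B", "C", "D"])
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            assert d.matrix[i, j] == pytest.approx(1.0)

    def test_missing_species_rejected(self):
        tree = toy_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError):
            dv.phylo_distances(tree, ["A", "Z"])


class TestRaoQAndEffectiveNumber:
    def test_two_species_even_split(self):
        assert dv.rao_q(np.array([0.5, 0.5]), np.array([[0, 1], [1, 0]])) == pytest.approx(0.5)

    def test_single_species_zero_entropy(self):
        assert dv.rao_q(np.array([1.0]), np.zeros((1, 1))) == 0.0

    def test_three_species_gini_simpson_brute_force(self):
        p = np.array([0.5, 0.3, 0.2])
        d = dv.species_distances(["a", "b", "c"]).matrix
        assert dv.rao_q(p, d) == pytest.approx(0.62, abs=1e-12)
        assert dv.rao_q(p, d) == pytest.approx(brute_force_rao(p, d), abs=1e-15)

    @pytest.mark.parametrize("q,e", [(0.5, 2.0), (0.0, 1.0), (0.62, 1 / 0.38)])
    def test_effective_number_values(self, q, e):
        assert dv.effective_number(q) == pytest.approx(e, rel=1e-9)

    def test_effective_number_rejects_q_at_or_above_one(self):
        with pytest.raises(ValueError):
            dv.effective_number(1.0)

    def test_misaligned_and_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dv.rao_q(np.array([0.5, 0.5]), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            dv.rao_q(np.array([-0.5, 1.5]), np.zeros((2, 2)))


class TestSiteDiversity:
    def test_equally_abundant_fully_distinct_species(self):
        n = 6
        comm = pd.DataFrame(
            {"site_id": "s1", "species_id": [f"sp{i}" for i in range(n)], "abundance": 1.0}
        )
        div = dv.site_diversity(comm)
        assert div["E_sd"].iloc[0] == pytest.approx(n, rel=1e-9)

    def test_all_unit_functional_distances_collapse_to_sd(self):
        comm = pd.DataFrame(
            {"site_id": "s1", "species_id": ["a", "b", "c"], "abundance": [3.0, 2.0, 1.0]}
        )
        traits = pd.DataFrame(
            {"c": pd.array(["x", "y", "z"], dtype=object)}, index=["a", "b", "c"]
        )
        div = dv.site_diversity(comm, traits=traits)
        assert div["E_fd"].iloc[0] == pytest.approx(div["E_sd"].iloc[0], rel=1e-9)

    def test_identical_trees_average_equals_single_tree(self):
        tree = toy_tree("((A:1,B:1):1,C:2);")
        comm = pd.DataFrame(
            {"site_id": "s1", "species_id": ["A", "B", "C"], "abundance": [1.0, 1.0, 2.0]}
        )
        one = dv.site_diversity(comm, trees=[tree])
        many = dv.site_diversity(comm, trees=[toy_tree("((A:1,B:1):1,C:2);") for _ in range(5)])
        assert many["Q_pd"].iloc[0] == pytest.approx(one["Q_pd"].iloc[0], abs=1e-12)

    def test_species_missing_from_traits_rejected(self):
        comm = pd.DataFrame({"site_id": "s1", "species_id": ["a", "b"], "abundance": 1.0})
        traits = pd.DataFrame({"x": [1.0]}, index=["a"])
        with pytest.raises(KeyError):
            dv.site_diversity(comm, traits=traits)


class TestRaoInvariants:
    """Structural properties of the quadratic entropy."""

    @staticmethod
    def _random_community(rng, n):
        p = rng.dirichlet(np.ones(n))
        d = rng.uniform(0, 1, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return p, d

    def test_vectorized_matches_double_loop(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p, d = self._random_community(rng, int(rng.integers(2, 12)))
            assert dv.rao_q(p, d) == pytest.approx(brute_force_rao(p, d), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p, d = self._random_community(rng, 8)
        perm = rng.permutation(8)
        assert dv.rao_q(p[perm], d[np.ix_(perm, perm)]) == pytest.approx(
            dv.rao_q(p, d), abs=1e-12
        )

    def test_zero_abundance_padding_is_neutral(self):
        rng = np.random.default_rng(6)
        p, d = self._random_community(rng, 5)
        p_pad = np.concatenate([p, [0.0, 0.0]])
        d_pad = np.zeros((7, 7))
        d_pad[:5, :5] = d
        d_pad[5:, :] = d_pad[:, 5:] = 0.5
        np.fill_diagonal(d_pad, 0)
        assert dv.rao_q(p_pad, d_pad) == pytest.approx(dv.rao_q(p, d), abs=1e-12)

    def test_distance_scaling_scales_q_linearly(self):
        rng = np.random.default_rng(8)
        p, d = self._random_community(rng, 6)
        q = dv.rao_q(p, d)
        for c in (0.25, 0.5, 1.0):
            assert dv.rao_q(p, c * d) == pytest.approx(c * q, abs=1e-12)

    def test_effective_number_bounds_per_facet(self, small_system, site_network):
        tree, pool, traits = small_system
        sites, comm = site_network
        div = dv.site_diversity(comm, traits=traits, trees=[tree])
        richness = comm[comm["abundance"] > 0].groupby("site_id")["species_id"].nunique()
        merged = div.set_index("site_id").join(richness.rename("S"))
        assert (merged["E_sd"] >= 1 - 1e-9).all()
        assert (merged["E_sd"] <= merged["S"] + 1e-9).all()
        assert (merged["E_fd"] <= merged["E_sd"] + 1e-9).all()
        assert (merged["E_pd"] <= merged["E_sd"] + 1e-9).all()
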