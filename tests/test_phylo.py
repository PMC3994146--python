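import numpy as np
import pytest

from chipsip.errors import ParameterError, ValidationError
from chipsip.io import read_tree
from chipsip.phylo import (TreeIndex, ancestral_states, fitch_score,
                           plot_null_histogram, reshuffle_null, signal_pvalues,
                           test_all_guilds as run_guild_tests, test_guild_character as run_guild_character)
from chipsip.simulate import assign_guilds, simulate_tree

from helpers_parsimony import brute_force_score, enumerate_unrooted_newicks


class TestFitchScore:
    def test_single_split(self):
        tree = read_tree("((A,B),(C,D));")
        assert fitch_score(tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_constant_character(self):
        tree = read_tree("((A,B),(C,D));")
        assert fitch_score(tree, {l: 1 for l in "ABCD"}) == 0

    def test_discordant_split_needs_two_changes(self):
        tree = read_tree("((A,C),(B,D));")
        assert fitch_score(tree, {"A": 1, "B": 1, "C": 0, "D": 0}) == 2

    def test_three_states(self):
        tree = read_tree("((A,B),(C,D),(E,F));")
        states = {"A": 0, "B": 0, "C": 1, "D": 1, "E": 2, "F": 2}
        assert fitch_score(tree, states) == 2
        assert brute_force_score(tree, states) == 2

    def test_missing_leaf_state_errors_or_excludes(self):
        tree = read_tree("((A,B),(C,D));")
        with pytest.raises(ValidationError, match="without a character state"):
            fitch_score(tree, {"A": 1, "B": 0, "C": 0})
        assert fitch_score(tree, {"A": 1, "B": 0, "C": 0},
                           missing="exclude") == 1

    def test_multifurcation_matches_brute_force(self):
        # polytomy where naive pairwise intersection over-counts
        tree = read_tree("(A,B,C,(D,E));")
        states = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0}
        assert fitch_score(tree, states) == brute_force_score(tree, states)

    def test_matches_brute_force_on_random_trees(self, rng):
        for n in (8, 12):
            for _ in range(5):
                tree = simulate_tree(n, rng=rng)
                labels = [l.taxon.label for l in tree.leaf_node_iter()]
                states = {l: int(s) for l, s in
                          zip(labels, rng.integers(0, 2, n))}
                assert fitch_score(tree, states) == brute_force_score(tree, states)

    def test_rooting_invariance(self, rng):
        tree = simulate_tree(20, rng=rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        states = {l: int(s) for l, s in zip(labels, rng.integers(0, 3, 20))}
        base = fitch_score(tree, states)
        for node in list(tree.preorder_internal_node_iter())[1:4]:
            clone = tree.clone(depth=1)
            target = clone.find_node(lambda n: n.edge and n.parent_node
                                     and len(n.leaf_nodes()) == 2)
            clone.reroot_at_edge(target.edge, update_bipartitions=False)
            assert fitch_score(clone, states) == base

    def test_binary_score_bounded_by_minority_count(self, rng):
        tree = simulate_tree(30, rng=rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        for _ in range(10):
            vec = rng.integers(0, 2, 30)
            if vec.min() == vec.max():
                continue
            states = {l: int(s) for l, s in zip(labels, vec)}
            score = fitch_score(tree, states)
            assert 1 <= score <= min(vec.sum(), 30 - vec.sum())


class TestReshuffleNull:
    def test_constant_character_null_is_zero(self):
        tree = read_tree("((A,B),(C,D));")
        null = reshuffle_null(tree, {l: 1 for l in "ABCD"}, n_reshuffles=1,
                              rng_seed=0)
        assert null.tolist() == [0]

    def test_scores_within_bounds(self, rng):
        tree = simulate_tree(24, rng=rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        states = {l: (1 if i < 8 else 0) for i, l in enumerate(labels)}
        null = reshuffle_null(tree, states, n_reshuffles=200, rng_seed=1)
        assert null.min() >= 1 and null.max() <= 8

    def test_seed_reproducibility(self):
        tree = simulate_tree(20, rng_seed=7)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        states = {l: (i % 2) for i, l in enumerate(labels)}
        a = reshuffle_null(tree, states, n_reshuffles=100, rng_seed=42)
        b = reshuffle_null(tree, states, n_reshuffles=100, rng_seed=42)
        assert (a == b).all()
        c = reshuffle_null(tree, states, n_reshuffles=100, rng_seed=43)
        assert not (a == c).all()

    def test_mean_matches_large_resampling_oracle(self):
        """Null mean on a balanced 32-leaf tree vs an independent estimate.

        The oracle shuffles leaf states with numpy directly and scores each
        shuffle with the brute-force-verified scorer, at 20x the sample
        size; the two means must agree within Monte-Carlo error.
        """
        newick = "(" + ",".join(
            "((t%da,t%db),(t%dc,t%dd))" % (i, i, i, i) for i in range(8)
        ) + ");"
        tree = read_tree(newick)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        states = {l: (1 if i < 8 else 0) for i, l in enumerate(labels)}
        null = reshuffle_null(tree, states, n_reshuffles=2000, rng_seed=0)

        oracle_rng = np.random.default_rng(123)
        index, vec = TreeIndex.from_states(tree, states)
        perms = oracle_rng.permuted(np.tile(vec, (40_000, 1)), axis=1)
        oracle_scores = index.score_matrix(perms.T)
        se = np.sqrt(null.var() / null.size + oracle_scores.var() / oracle_scores.size)
        assert abs(null.mean() - oracle_scores.mean()) < 4 * se


class TestSignalPvalues:
    def test_observed_below_all_null(self):
        pv = signal_pvalues(1, np.full(1000, 10))
        assert pv["p_empirical"] == pytest.approx(1 / 1001)

    def test_observed_at_median(self, rng):
        null = rng.integers(5, 15, 999)
        pv = signal_pvalues(int(np.median(null)), null)
        assert 0.3 < pv["p_empirical"] < 0.7

    def test_zero_variance_null_ftest_undefined(self):
        pv = signal_pvalues(3, np.full(100, 5))
        assert np.isnan(pv["p_ftest"])
        assert 0 <= pv["p_empirical"] <= 1

    def test_empty_null_rejected(self):
        with pytest.raises(ParameterError):
            signal_pvalues(1, np.array([]))

    def test_ftest_small_for_extreme_observation(self, rng):
        null = rng.normal(20, 2, 1000).round()
        pv = signal_pvalues(2, null)
        assert pv["p_ftest"] < 0.05
        assert pv["p_empirical"] < 0.05


class TestAncestralStates:
    def test_constant_character(self):
        tree = read_tree("((A,B),(C,D));")
        rec = ancestral_states(tree, {l: 1 for l in "ABCD"})
        internal = [n for n in rec.node_states if not n.is_leaf()]
        assert all(rec.node_states[n] == 1 for n in internal)
        assert rec.score == 0 and rec.changes() == 0

    def test_single_split_partitions_at_one_edge(self):
        tree = read_tree("((A,B),(C,D));")
        rec = ancestral_states(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert rec.changes() == rec.score == 1

    def test_achieves_brute_force_minimum(self, rng):
        for newick in ["((A,B),((C,D),(E,F)));", "((A,(B,C)),(D,(E,F)));"]:
            tree = read_tree(newick)
            for _ in range(20):
                vec = rng.integers(0, 2, 6)
                states = {l: int(s) for l, s in zip("ABCDEF", vec)}
                rec = ancestral_states(tree, states)
                assert rec.changes() == brute_force_score(tree, states)
                assert rec.score == rec.changes()


class TestGuildCharacterTests:
    def test_constant_guild_skipped(self):
        tree = simulate_tree(10, rng_seed=0)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        guild_of = {l: "COPIOTROPH" for l in labels}
        with pytest.warns(UserWarning, match="skipped"):
            assert run_guild_tests(tree, guild_of, n_reshuffles=10) == {}

    def test_clade_seeded_trait_detected(self):
        tree = simulate_tree(60, rng_seed=3)
        truths = assign_guilds(tree, proportions=(0.5, 0.25, 0.25),
                               clustering_mode="clade_seeded", rng_seed=3)
        guild_of = {t.taxon_id: t.guild for t in truths}
        results = run_guild_tests(tree, guild_of, n_reshuffles=500, rng_seed=3)
        assert results  # at least one testable guild
        for char in results.values():
            assert char.p_empirical < 0.05
            assert char.observed_score < char.null_mean

    def test_taxa_missing_from_tree_reported(self):
        tree = read_tree("((A,B),(C,(D,E)));")
        members = ["A", "B", "Z"]
        universe = ["A", "B", "C", "D", "E", "Z"]
        char = run_guild_character(tree, members, universe, guild="g",
                                    n_reshuffles=50, rng_seed=0)
        assert char.excluded_taxa == ("Z",)
        assert char.n_leaves == 5

    def test_histogram_plot_written(self, tmp_path):
        tree = simulate_tree(30, rng_seed=1)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        guild_of = {l: ("A" if i < 10 else "B") for i, l in enumerate(labels)}
        results = run_guild_tests(tree, guild_of, n_reshuffles=100, rng_seed=1)
        path = tmp_path / "null.svg"
        plot_null_histogram(results["A"], str(path))
        assert path.stat().st_size > 0
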