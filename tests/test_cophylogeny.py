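"""Tree I/O, midpoint rooting, congruence mapping and the codivergence test."""

import itertools

import numpy as np
import pytest

from paleofoam import fixtures
from paleofoam.cophylogeny import (
    NewickError,
    codivergence_test,
    extract_branch_pairs,
    leaf_labels,
    map_congruent_branches,
    midpoint_root,
    parse_newick,
    write_newick,
)
from paleofoam.simulate import simulate_codivergence

import pandas as pd


class TestNewickIO:
    def test_round_trip(self):
        text = "((A:1,B:2):0.5,C:3);"
        tree = parse_newick(text)
        assert sorted(leaf_labels(tree)) == ["A", "B", "C"]
        again = parse_newick(write_newick(tree))
        assert sorted(leaf_labels(again)) == ["A", "B", "C"]

    def test_branch_lengths_preserved_to_10_digits(self):
        text = "((A:1.234567891,B:2):0.5000000001,C:3);"
        out = write_newick(parse_newick(text))
        assert "1.234567891" in out
        assert "0.5000000001" in out

    def test_polytomy_preserved(self):
        tree = parse_newick("(A:1,B:1,C:1);")
        assert len(tree.seed_node.child_nodes()) == 3

    def test_malformed_raises(self):
        with pytest.raises(NewickError):
            parse_newick("((A:1,B:2;")

    def test_duplicate_labels_raise(self):
        with pytest.raises(NewickError, match="duplicate"):
            parse_newick("(A:1,A:2);")


def tree_diameter_brute_force(tree) -> float:
    """All-pairs leaf path oracle via the phylogenetic distance matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    return max(
        pdm.patristic_distance(a, b) for a, b in itertools.combinations(taxa, 2)
    )


def total_length(tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


class TestMidpointRoot:
    def test_star_tree_roots_on_longest_edge(self):
        rooted = midpoint_root(parse_newick("(A:1,B:3,C:1);"))
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in rooted.leaf_node_iter()
        }
        assert depths["A"] == pytest.approx(2)
        assert depths["B"] == pytest.approx(2)

    def test_idempotent(self):
        tree = parse_newick("((A:1,B:2):0.5,(C:1.5,D:0.5):1);")
        once = midpoint_root(tree)
        twice = midpoint_root(once)
        d1 = {l.taxon.label: l.distance_from_root() for l in once.leaf_node_iter()}
        d2 = {l.taxon.label: l.distance_from_root() for l in twice.leaf_node_iter()}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], rel=1e-9)

    def test_max_depth_is_half_diameter_on_random_trees(self, rng):
        import dendropy

        for seed in range(5):
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=10,
                rng=__import__("random").Random(seed),
            )
            diameter = tree_diameter_brute_force(tree)
            rooted = midpoint_root(tree)
            max_depth = max(
                l.distance_from_root() for l in rooted.leaf_node_iter()
            )
            assert max_depth == pytest.approx(diameter / 2, rel=1e-9)

    def test_conserves_total_branch_length(self):
        tree = parse_newick("((A:1,B:2):0.5,(C:1.5,D:0.5):1);")
        before = total_length(tree)
        assert total_length(midpoint_root(tree)) == pytest.approx(before, rel=1e-9)

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            midpoint_root(parse_newick("((A,B),C);"))


HOST5 = "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"
VIRUS5_SAME = "((((a:.1,b:.1):.1,c:.2):.1,d:.3):.1,e:.4);"
VIRUS5_SWAP = "((((a:.1,c:.1):.1,b:.2):.1,d:.3):.1,e:.4);"
MAP5 = {"a": "A", "b": "B", "c": "C", "d": "D", "e": "E"}


class TestCongruence:
    def test_identical_topologies_full_bijection(self):
        res = map_congruent_branches(
            parse_newick(HOST5), parse_newick(VIRUS5_SAME), MAP5
        )
        assert res.congruent
        assert len(res.branch_map) == 8  # 2n-2 for rooted binary, n=5

    def test_tip_swap_reports_discordant_clades(self):
        res = map_congruent_branches(
            parse_newick(HOST5), parse_newick(VIRUS5_SWAP), MAP5
        )
        assert not res.congruent
        assert frozenset({"A", "B"}) in res.host_only
        assert frozenset({"A", "C"}) in res.virus_only

    def test_symmetric_under_inverse_map(self):
        host, virus = parse_newick(HOST5), parse_newick(VIRUS5_SAME)
        inv = {h: v for v, h in MAP5.items()}
        assert map_congruent_branches(host, virus, MAP5).congruent
        assert map_congruent_branches(virus, host, inv).congruent
        virus_bad = parse_newick(VIRUS5_SWAP)
        assert not map_congruent_branches(host, virus_bad, MAP5).congruent
        assert not map_congruent_branches(virus_bad, host, inv).congruent

    def test_non_bijective_map_rejected(self):
        bad = dict(MAP5, a="B")
        with pytest.raises(ValueError, match="bijection"):
            map_congruent_branches(parse_newick(HOST5), parse_newick(VIRUS5_SAME), bad)

    def test_mismatched_polytomy_fails(self):
        host = parse_newick("((A:1,B:1):1,C:2);")
        virus = parse_newick("(a:1,b:1,c:1);")
        res = map_congruent_branches(host, virus, {"a": "A", "b": "B", "c": "C"})
        assert not res.congruent

    def test_packaged_host_fixture_congruent_with_simulated_virus(self):
        host = fixtures.host_tree()
        virus, _ = simulate_codivergence(
            host, viral_rate=1.5e-9, seed=1, tip_map=fixtures.tip_map()
        )
        res = map_congruent_branches(host, virus, fixtures.tip_map())
        assert res.congruent
        assert len(res.branch_map) == 10  # 6 hosts -> 2n-2 branches


class TestExtractBranchPairs:
    def test_five_leaf_pair_gives_eight_rows(self):
        host, virus = parse_newick(HOST5), parse_newick(VIRUS5_SAME)
        res = map_congruent_branches(host, virus, MAP5)
        pairs = extract_branch_pairs(res, host, virus)
        assert len(pairs) == 8
        assert pairs["is_external"].sum() == 5

    def test_degenerate_all_zero_durations_flagged(self):
        host = parse_newick("((A:0,B:0):0,C:0);")
        virus = parse_newick("((a:.1,b:.1):.1,c:.2);")
        res = map_congruent_branches(host, virus, {"a": "A", "b": "B", "c": "C"})
        pairs = extract_branch_pairs(res, host, virus)
        assert (pairs["host_duration"] == 0).all()
        assert pairs.attrs.get("degenerate")

    def test_stale_mapping_rejected(self):
        host, virus = parse_newick(HOST5), parse_newick(VIRUS5_SAME)
        res = map_congruent_branches(host, virus, MAP5)
        other = parse_newick(HOST5)
        with pytest.raises(ValueError, match="stale"):
            extract_branch_pairs(res, other, virus)


def ols_normal_equations(x, y):
    """Independent least-squares oracle from the normal equations."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    return beta[1], beta[0], 1 - ss_res / ss_tot


def make_pairs(x, y):
    return pd.DataFrame(
        {
            "branch_id": [str(i) for i in range(len(x))],
            "host_duration": x,
            "virus_length": y,
            "is_external": [True] * len(x),
        }
    )


class TestCodivergenceTest:
    def test_exact_linear_relationship(self):
        fit = codivergence_test(make_pairs([10, 20, 30], [0.01, 0.02, 0.03]))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.001)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        fit = codivergence_test(make_pairs(x, y))
        slope, intercept, r2 = ols_normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)
        assert fit.n_branches == 4

    def test_permutation_p_small_for_strong_signal(self):
        x = np.arange(1.0, 11.0)
        y = 0.002 * x + 0.001
        fit = codivergence_test(make_pairs(x, y), n_permutations=999, seed=5)
        assert fit.permutation_p == pytest.approx(1 / 1000)

    def test_null_gives_large_permutation_p(self, rng):
        x = np.arange(1.0, 13.0)
        ps = []
        for seed in range(10):
            y = rng.permutation(x) * 0.001  # no association with x
            fit = codivergence_test(make_pairs(x, y), n_permutations=200, seed=seed)
            ps.append(fit.permutation_p)
        assert np.mean(ps) > 0.2  # roughly uniform, not concentrated at 0

    def test_r2_invariant_under_axis_rescaling(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([0.1, 0.25, 0.28, 0.5])
        base = codivergence_test(make_pairs(x, y))
        scaled = codivergence_test(make_pairs(x * 100, y))
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-10)
        assert scaled.slope == pytest.approx(base.slope / 100, rel=1e-10)
        scaled_y = codivergence_test(make_pairs(x, y * 7))
        assert scaled_y.r_squared == pytest.approx(base.r_squared, rel=1e-10)

    def test_permutation_and_analytic_p_agree_in_rank_order(self, rng):
        # effect sizes far enough apart that both p-values must order them
        x = np.arange(1.0, 21.0)
        analytic, permuted = [], []
        for i, noise in enumerate([0.001, 0.05, 2.0]):
            y = 0.01 * x + rng.normal(0, noise, size=len(x))
            fit = codivergence_test(make_pairs(x, y), n_permutations=500, seed=i)
            analytic.append(fit.p_value)
            permuted.append(fit.permutation_p)
        assert analytic == sorted(analytic)
        assert permuted == sorted(permuted)

    def test_through_origin_flag(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 0.01 * x
        fit = codivergence_test(make_pairs(x, y), through_origin=True)
        assert fit.intercept == 0.0
        assert fit.slope == pytest.approx(0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 branch"):
            codivergence_test(make_pairs([1, 2], [0.1, 0.2]))
        with pytest.raises(ValueError, match="variance"):
            codivergence_test(make_pairs([5, 5, 5], [0.1, 0.2, 0.3]))
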