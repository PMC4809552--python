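"""Phylogenetic engine: parsing, transition matrices, pruning, simulation,
branch-scale fitting, grafting and ancestral reconstruction."""

import numpy as np
import pytest
import scipy.linalg

from accelscan.alignment import MultipleAlignment
from accelscan.phylo import (
    NewickError,
    SubstitutionModel,
    alignment_loglik,
    decode_codes,
    fit_branch_scale,
    graft_leaf,
    parse_newick,
    prune_leaf,
    prune_loglik,
    reconstruct_ancestor,
    simulate_leaf_codes,
)

from conftest import canonical_form, enumeration_loglik, random_tree


class TestParseNewick:
    @pytest.mark.parametrize("text,n_leaves", [
        ("(A:0.1,B:0.1):0;", 2),
        ("((A:0.1,B:0.2):0.05,C:0.3):0;", 3),
        ("(((a:0.01,b:0.02)ab:0.3,c:0.5)abc:0.1,(d:0.2,e:0.25)de:0.15);", 5),
    ])
    def test_round_trip(self, text, n_leaves):
        tree = parse_newick(text)
        assert len(tree.leaf_names) == n_leaves
        again = parse_newick(tree.to_newick())
        assert canonical_form(tree) == canonical_form(again)

    def test_two_leaf_lengths(self):
        tree = parse_newick("(A:0.1,B:0.1):0;")
        assert tree.length[tree.index("A")] == pytest.approx(0.1)
        assert tree.length[tree.index("B")] == pytest.approx(0.1)

    def test_internal_edge_length(self):
        tree = parse_newick("((A:0.1,B:0.2)ab:0.05,C:0.3):0;")
        assert tree.length[tree.index("ab")] == pytest.approx(0.05)

    def test_duplicate_leaf_error_names_token(self):
        with pytest.raises(NewickError, match="A"):
            parse_newick("(A:0.1,A:0.2);")

    def test_malformed(self):
        with pytest.raises(NewickError):
            parse_newick("((A:0.1,B:0.2;")


class TestTransitionMatrix:
    def test_identity_at_zero(self, jc, hky):
        for m in (jc, hky):
            assert np.abs(m.transition_matrix(0.0) - np.eye(4)).max() < 1e-12

    def test_stationary_limit(self, jc):
        P = jc.transition_matrix(100.0)
        assert np.allclose(P, 0.25, atol=1e-10)

    def test_jc_closed_form(self, jc):
        P = jc.transition_matrix(0.3)
        diag = 0.25 + 0.75 * np.exp(-4.0 / 3.0 * 0.3)
        assert np.allclose(np.diag(P), diag, atol=1e-12)
        assert np.abs(P - scipy.linalg.expm(jc.Q * 0.3)).max() < 1e-10

    def test_hky_matches_expm(self, hky):
        for t in (0.01, 0.2, 1.5):
            assert np.abs(hky.transition_matrix(t)
                          - scipy.linalg.expm(hky.Q * t)).max() < 1e-10

    def test_rows_sum_to_one(self, hky):
        for t in (0.0, 0.05, 0.7, 3.0):
            assert np.allclose(hky.transition_matrix(t).sum(axis=1), 1.0,
                               atol=1e-12)

    @pytest.mark.parametrize("s,t", [(0.1, 0.2), (0.05, 1.3), (0.4, 0.4)])
    def test_chapman_kolmogorov(self, hky, s, t):
        Ps, Pt, Pst = (hky.transition_matrix(x) for x in (s, t, s + t))
        assert np.abs(Ps @ Pt - Pst).max() < 1e-10

    def test_negative_branch_rejected(self, jc):
        with pytest.raises(ValueError):
            jc.transition_matrix(-0.1)

    def test_model_invariants(self, hky):
        assert np.allclose(hky.Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(hky.pi @ hky.Q, 0.0, atol=1e-12)  # stationarity
        assert np.isclose(-(hky.pi * np.diag(hky.Q)).sum(), 1.0)  # unit rate


class TestPruneLoglik:
    def test_zero_branches_force_shared_state(self, jc):
        tree = parse_newick("(A:0.0,B:0.0);")
        lnl = prune_loglik(tree, jc, {"A": "A", "B": "A"})
        assert lnl == pytest.approx(np.log(0.25), abs=1e-12)

    def test_all_missing_gives_loglik_zero(self, jc):
        tree = parse_newick("((A:0.1,B:0.2)ab:0.05,C:0.3);")
        assert prune_loglik(tree, jc, {"A": "-", "B": "N", "C": "-"}) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, hky):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            tree = random_tree(rng, n)
            column = {name: "ACGT-N"[rng.integers(0, 6)]
                      for name in tree.leaf_names}
            got = prune_loglik(tree, hky, column)
            want = enumeration_loglik(tree, hky, column)
            if np.isfinite(want):
                assert got == pytest.approx(want, rel=1e-10)

    def test_leaf_order_invariance(self, jc):
        t1 = parse_newick("((A:0.1,B:0.2)x:0.05,C:0.3);")
        t2 = parse_newick("(C:0.3,(B:0.2,A:0.1)x:0.05);")
        col = {"A": "A", "B": "C", "C": "G"}
        assert prune_loglik(t1, jc, col) == pytest.approx(
            prune_loglik(t2, jc, col), rel=1e-12)

    def test_reroot_along_zero_length_edge(self, hky):
        # same unrooted tree, root slid along the internal edge
        t1 = parse_newick("((A:0.1,B:0.2)u:0.0,(C:0.3,D:0.15)v:0.05);")
        t2 = parse_newick("((A:0.1,B:0.2)u:0.05,(C:0.3,D:0.15)v:0.0);")
        col = {"A": "A", "B": "G", "C": "T", "D": "T"}
        assert prune_loglik(t1, hky, col) == pytest.approx(
            prune_loglik(t2, hky, col), rel=1e-10)

    def test_strict_mode_requires_all_leaves(self, jc):
        tree = parse_newick("((A:0.1,B:0.2)x:0.05,C:0.3);")
        with pytest.raises(KeyError, match="C"):
            prune_loglik(tree, jc, {"A": "A", "B": "C"}, strict=True)


class TestSimulate:
    def test_zero_branches_copy_root(self, jc):
        tree = parse_newick("((A:0.0,B:0.0)x:0.0,C:0.0);")
        codes = simulate_leaf_codes(tree, jc, 200, 5)
        assert np.array_equal(codes["A"], codes["B"])
        assert np.array_equal(codes["A"], codes["C"])

    def test_fixed_seed_reproducible(self, hky, eight_leaf_tree):
        a = simulate_leaf_codes(eight_leaf_tree, hky, 500, 42)
        b = simulate_leaf_codes(eight_leaf_tree, hky, 500, 42)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_pairwise_identity_matches_closed_form(self, jc):
        # two leaves at total path 0.6: P(same) under the substitution model
        tree = parse_newick("(A:0.3,B:0.3);")
        n = 10_000
        codes = simulate_leaf_codes(tree, jc, n, 11)
        observed = float((codes["A"] == codes["B"]).mean())
        P = jc.transition_matrix(0.6)
        expected = float((jc.pi * np.diag(P)).sum())
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se


class TestFitBranchScale:
    def test_boundary_mass_under_null(self, hky, eight_leaf_tree):
        """With no acceleration the constrained MLE should pin at the bound
        in roughly half of replicates (>= 40% expected)."""
        rng = np.random.default_rng(3)
        at_bound = 0
        reps = 200
        for _ in range(reps):
            codes = simulate_leaf_codes(eight_leaf_tree, hky, 500, rng)
            lam, _ = fit_branch_scale(eight_leaf_tree, hky, codes, "stem")
            at_bound += lam == 1.0
        assert at_bound / reps >= 0.40

    def test_recovers_planted_scale(self, hky, eight_leaf_tree):
        """Reduced-replicate smoke check of parameter recovery (the full
        multi-lambda version runs in the acceptance suite)."""
        rng = np.random.default_rng(4)
        lams = []
        for _ in range(20):
            codes = simulate_leaf_codes(eight_leaf_tree, hky, 2000, rng,
                                        scales={"stem": 4.0})
            lam, _ = fit_branch_scale(eight_leaf_tree, hky, codes, "stem")
            lams.append(lam)
        assert 3.0 <= float(np.median(lams)) <= 5.3

    def test_all_missing_flat_likelihood_ties_to_bound(self, jc, eight_leaf_tree):
        codes = {name: np.full(50, 4, dtype=np.uint8)
                 for name in eight_leaf_tree.leaf_names}
        lam, lnl = fit_branch_scale(eight_leaf_tree, jc, codes, "stem")
        assert lam == 1.0
        assert lnl == pytest.approx(0.0, abs=1e-9)

    def test_maximum_beats_grid(self, hky, eight_leaf_tree):
        codes = simulate_leaf_codes(eight_leaf_tree, hky, 800, 9,
                                    scales={"stem": 6.0})
        lam, lnl = fit_branch_scale(eight_leaf_tree, hky, codes, "stem")
        for trial in (1.0, 2.0, 4.0, 8.0, 16.0, 50.0):
            assert lnl >= alignment_loglik(eight_leaf_tree, hky, codes,
                                           scales={"stem": trial}) - 1e-8

    def test_unknown_branch(self, jc, eight_leaf_tree):
        with pytest.raises(KeyError):
            fit_branch_scale(eight_leaf_tree, jc,
                             {"f1": np.zeros(5, dtype=np.uint8)}, "nope")


class TestGraftLeaf:
    def test_split_arithmetic(self):
        tree = parse_newick("((A:0.2,B:0.1)ab:0.05,C:0.3);")
        new = graft_leaf(tree, "A", "A2", stem_fraction=0.5, new_branch_length=0.07)
        assert new.length[new.index("A")] == pytest.approx(0.1)
        parent = int(new.parent[new.index("A")])
        assert new.length[parent] == pytest.approx(0.1)
        assert new.length[new.index("A2")] == pytest.approx(0.07)

    def test_zero_length_graft_duplicates_sister(self, hky):
        tree = parse_newick("((A:0.2,B:0.1)ab:0.05,C:0.3);")
        new = graft_leaf(tree, "A", "A2", stem_fraction=0.0, new_branch_length=0.0)
        col = {"A": "G", "B": "C", "C": "T"}
        base = prune_loglik(tree, hky, col)
        dup = prune_loglik(new, hky, {**col, "A2": "G"})
        assert dup == pytest.approx(base, rel=1e-10)

    def test_graft_then_prune_round_trip(self):
        tree = parse_newick("((A:0.2,B:0.1)ab:0.05,C:0.3);")
        new = graft_leaf(tree, "B", "B2", stem_fraction=0.4, new_branch_length=0.2)
        restored = prune_leaf(new, "B2")
        assert canonical_form(restored) == canonical_form(tree)

    def test_name_collision_and_unknown_sister(self):
        tree = parse_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError):
            graft_leaf(tree, "A", "B", 0.5, 0.1)
        with pytest.raises(KeyError):
            graft_leaf(tree, "Z", "C", 0.5, 0.1)


class TestReconstructAncestor:
    def test_short_branches_recover_shared_base(self, jc):
        tree = parse_newick("((A:1e-8,B:1e-8)ab:1e-8,C:1e-8);")
        codes = {s: np.array([1], dtype=np.uint8) for s in "ABC"}  # all 'C'
        seq, post = reconstruct_ancestor(tree, jc, codes, "ab")
        assert seq == "C"
        assert post[0, 1] >= 0.999

    def test_all_missing_site_reports_n(self, jc):
        tree = parse_newick("((A:0.1,B:0.1)ab:0.1,C:0.1);")
        codes = {"A": np.array([4, 0], dtype=np.uint8),
                 "B": np.array([4, 0], dtype=np.uint8),
                 "C": np.array([4, 0], dtype=np.uint8)}
        seq, post = reconstruct_ancestor(tree, jc, codes, "ab")
        assert seq[0] == "N"
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_posterior_matches_enumeration_bayes(self, hky):
        """Marginal posterior at an internal node equals brute-force Bayes
        over all ancestral assignments on a 4-leaf tree with column A,A,G,G."""
        import itertools
        tree = parse_newick("((A:0.1,B:0.15)ab:0.2,(C:0.12,D:0.3)cd:0.25);")
        obs = {"A": 0, "B": 0, "C": 2, "D": 2}
        codes = {s: np.array([v], dtype=np.uint8) for s, v in obs.items()}
        _, post = reconstruct_ancestor(tree, hky, codes, "ab")

        internal = ["ab", "cd"]
        root = tree.names[tree.root]
        P = {n: hky.transition_matrix(float(tree.length[tree.index(n)]))
             for n in ["A", "B", "C", "D", "ab", "cd"]}
        joint = np.zeros(4)
        for rt, ab, cd in itertools.product(range(4), repeat=3):
            p = hky.pi[rt] * P["ab"][rt, ab] * P["cd"][rt, cd]
            p *= P["A"][ab, 0] * P["B"][ab, 0] * P["C"][cd, 2] * P["D"][cd, 2]
            joint[ab] += p
        want = joint / joint.sum()
        assert np.allclose(post[0], want, atol=1e-10)

    def test_leaf_target_rejected(self, jc):
        tree = parse_newick("(A:0.1,B:0.2);")
        with pytest.raises(ValueError):
            reconstruct_ancestor(tree, jc,
                                 {"A": np.array([0], dtype=np.uint8)}, "A")
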