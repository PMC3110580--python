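import numpy as np
import pytest

import traitgrad as tg
from traitgrad.comparative import ZERO_LENGTH_FLOOR


def brute_force_contrasts(tree, trait):
    """Independent oracle: literal recursive pruning on a cloned tree."""
    work = tree.copy()
    values = {id(t): float(trait[t.label]) for t in work.tips()}
    lengths = {id(n): max(n.length, ZERO_LENGTH_FLOOR)
               for n in work.preorder() if n is not work.root}
    out = []
    for node in work.postorder():
        if node.is_tip:
            continue
        (i, j) = node.children
        bi, bj = lengths[id(i)], lengths[id(j)]
        xi, xj = values[id(i)], values[id(j)]
        out.append(((xi - xj), np.sqrt(bi + bj)))
        values[id(node)] = (xi / bi + xj / bj) / (1 / bi + 1 / bj)
        extra = bi * bj / (bi + bj)
        if node is not work.root:
            lengths[id(node)] = lengths[id(node)] + extra
    return out


def brute_force_k(tree, trait):
    """Independent oracle: Blomberg's K by explicit matrix inversion."""
    C = tg.phylo_covariance(tree)
    labels = list(C.index)
    Cm = C.to_numpy()
    Ci = np.linalg.inv(Cm)
    one = np.ones(len(labels))
    x = np.array([trait[l] for l in labels])
    n = len(labels)
    a = one @ Ci @ x / (one @ Ci @ one)
    mse0 = (x - a) @ (x - a) / (n - 1)
    mse = (x - a) @ Ci @ (x - a) / (n - 1)
    expected = (np.trace(Cm) - n / (one @ Ci @ one)) / (n - 1)
    return (mse0 / mse) / expected


class TestContrasts:
    def test_two_tip_standardized_value(self):
        t = tg.read_newick("(A:1,B:1);")
        cs = tg.independent_contrasts(t, {"A": 0.0, "B": 2.0})
        assert cs.n == 1
        assert abs(cs.standardized[0]) == pytest.approx(np.sqrt(2.0))

    def test_hand_pruned_three_tips(self):
        t = tg.read_newick("((A:1,B:1):1,C:1);")
        cs = tg.independent_contrasts(t, {"A": 1.0, "B": 3.0, "C": 6.0})
        std = sorted(np.round(cs.standardized, 10))
        # node AB: (1-3)/sqrt(2); root: (2-6)/sqrt(1.5+1)
        assert std == pytest.approx(
            sorted([-2 / np.sqrt(2), -4 / np.sqrt(2.5)]))

    def test_constant_trait_gives_zero_contrasts(self):
        t = tg.simulate_tree(10, seed=1)
        cs = tg.independent_contrasts(
            t, {s: 3.14 for s in t.tip_labels})
        assert np.allclose(cs.standardized, 0.0)

    @pytest.mark.parametrize("n_tips", [4, 5, 6, 7, 8])
    def test_matches_brute_force_pruning(self, n_tips):
        for seed in range(10):
            tree = tg.simulate_tree(n_tips, seed=100 * n_tips + seed)
            rng = np.random.default_rng(seed)
            trait = {s: rng.normal() for s in tree.tip_labels}
            cs = tg.independent_contrasts(tree, trait)
            got = sorted(zip(np.round(cs.contrasts, 9),
                             np.round(cs.sds, 9)))
            want = sorted((round(c, 9), round(s, 9))
                          for c, s in brute_force_contrasts(tree, trait))
            assert got == pytest.approx(want)

    def test_tip_trait_mismatch_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            tg.independent_contrasts(three_tip_tree, {"A": 1.0, "B": 2.0})

    def test_count_is_tips_minus_one(self):
        star = tg.resolve_polytomies(
            tg.read_newick("(A:1,B:1,C:1,D:1,E:1);"), seed=0)
        cs = tg.independent_contrasts(
            star, dict(zip("ABCDE", [1.0, 2.0, 3.0, 4.0, 5.0])))
        assert cs.n == 4


class TestDiagnostics:
    def test_equal_sds_not_applicable(self):
        t = tg.resolve_polytomies(tg.read_newick("(A:1,B:1,C:1,D:1);"),
                                  seed=0)
        cs = tg.independent_contrasts(
            t, {"A": 1.0, "B": 2.0, "C": 4.0, "D": 0.5})
        # force identical SDs to trigger the degenerate branch
        cs.sds = np.full_like(cs.sds, 1.0)
        out = tg.contrast_diagnostics(cs)
        assert out["applicable"] is False

    def test_sign_flip_invariance(self):
        tree = tg.simulate_tree(16, seed=3)
        rng = np.random.default_rng(3)
        trait = {s: rng.normal() for s in tree.tip_labels}
        flipped = {s: -v for s, v in trait.items()}
        a = tg.contrast_diagnostics(tg.independent_contrasts(tree, trait))
        b = tg.contrast_diagnostics(tg.independent_contrasts(tree, flipped))
        assert a["r"] == pytest.approx(b["r"])

    def test_bm_on_true_lengths_is_uncorrelated_on_average(self):
        tree = tg.simulate_tree(64, seed=11)
        rs = []
        for rep in range(100):
            trait = tg.simulate_bm_traits(tree, 1.0, seed=rep)
            rs.append(tg.contrast_diagnostics(
                tg.independent_contrasts(tree, trait))["r"])
        assert abs(np.mean(rs)) < 0.05


class TestCorrelations:
    def test_identical_variables(self):
        x = {f"s{i}": float(i) for i in range(10)}
        out = tg.correlation_ahistorical(x, x)
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 10

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        x = {f"s{i}": rng.normal() for i in range(10_000)}
        y = {f"s{i}": rng.normal() for i in range(10_000)}
        assert abs(tg.correlation_ahistorical(x, y)["r"]) < 0.03

    def test_pic_proportional_contrasts(self):
        tree = tg.simulate_tree(12, seed=2)
        rng = np.random.default_rng(2)
        x = {s: rng.normal() for s in tree.tip_labels}
        y = {s: 2.0 * v for s, v in x.items()}
        cx = tg.independent_contrasts(tree, x)
        cy = tg.independent_contrasts(tree, y)
        out = tg.correlation_pic(cx, cy)
        assert out["r"] == pytest.approx(1.0)
        assert out["df"] == 10

    def test_through_origin_hand_value(self):
        cs = tg.ContrastSet(node_ids=["a", "b", "c"],
                            contrasts=np.array([1.0, -2.0, 3.0]),
                            sds=np.ones(3), tip_labels=[])
        cs2 = tg.ContrastSet(node_ids=["a", "b", "c"],
                             contrasts=np.array([2.0, -4.0, 5.0]),
                             sds=np.ones(3), tip_labels=[])
        # r = 25 / sqrt(14 * 45) = 0.996025...
        out = tg.correlation_pic(cs, cs2)
        assert out["r"] == pytest.approx(25 / np.sqrt(14 * 45), abs=1e-12)

    def test_joint_sign_flip_invariance(self):
        tree = tg.simulate_tree(10, seed=9)
        rng = np.random.default_rng(9)
        cx = tg.independent_contrasts(
            tree, {s: rng.normal() for s in tree.tip_labels})
        cy = tg.independent_contrasts(
            tree, {s: rng.normal() for s in tree.tip_labels})
        r0 = tg.correlation_pic(cx, cy)["r"]
        k = 3
        cx.contrasts[k] *= -1
        cy.contrasts[k] *= -1
        assert tg.correlation_pic(cx, cy)["r"] == pytest.approx(r0)

    def test_star_tree_pic_equals_centered_pearson(self):
        rng = np.random.default_rng(21)
        labels = [f"s{i}" for i in range(20)]
        star = tg.resolve_polytomies(
            tg.read_newick("(" + ",".join(f"{l}:1" for l in labels) + ");"),
            seed=5)
        x = {l: rng.normal() for l in labels}
        y = {l: 0.5 * x[l] + rng.normal() for l in labels}
        pic = tg.correlation_pic(tg.independent_contrasts(star, x),
                                 tg.independent_contrasts(star, y))["r"]
        ahist = tg.correlation_ahistorical(x, y)["r"]
        assert pic == pytest.approx(ahist, abs=1e-6)


class TestBlombergK:
    def test_star_phylogeny_k_is_one(self):
        star = tg.read_newick("(A:1,B:1,C:1,D:1,E:3);")
        # equal branch lengths make it a proper star
        star = tg.set_equal_branch_lengths(star)
        trait = {"A": 0.3, "B": -1.0, "C": 2.0, "D": 0.1, "E": 5.0}
        assert tg.blomberg_k(star, trait) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_tips", [4, 6, 8])
    def test_matches_matrix_oracle(self, n_tips):
        for seed in range(10):
            tree = tg.simulate_tree(n_tips, seed=seed)
            trait = tg.simulate_bm_traits(tree, 1.0, seed=1000 + seed)
            assert tg.blomberg_k(tree, trait) == pytest.approx(
                brute_force_k(tree, trait), abs=1e-8)

    def test_shuffling_lowers_k_below_bm(self):
        tree = tg.simulate_tree(32, seed=5)
        rng = np.random.default_rng(5)
        lower = 0
        for rep in range(100):
            trait = tg.simulate_bm_traits(tree, 1.0, seed=rep)
            k_bm = tg.blomberg_k(tree, trait)
            labels = list(trait)
            vals = rng.permutation(list(trait.values()))
            k_shuf = tg.blomberg_k(tree, dict(zip(labels, vals)))
            lower += k_shuf < k_bm
        assert lower >= 90


class TestSignalTest:
    def test_p_value_lower_bound_and_determinism(self):
        tree = tg.simulate_tree(24, seed=8)
        trait = tg.simulate_bm_traits(tree, 1.0, seed=8)
        a = tg.signal_test(tree, trait, n_perm=99, seed=42)
        b = tg.signal_test(tree, trait, n_perm=99, seed=42)
        assert a.P == b.P
        assert a.P >= 1 / 100
        assert a.K == pytest.approx(tg.blomberg_k(tree, trait))

    def test_strong_signal_gives_min_p(self):
        # trait = tip depth ordering on a ladder tree: maximal signal
        tree = tg.simulate_tree(32, seed=13)
        trait = tg.simulate_bm_traits(tree, 1.0, seed=2)
        # amplify signal: use exact BM with no noise on a deep tree
        res = tg.signal_test(tree, trait, n_perm=199, seed=0)
        assert res.P <= 0.05

    def test_nperm_validation(self):
        tree = tg.simulate_tree(5, seed=0)
        with pytest.raises(ValueError):
            tg.signal_test(tree, {s: 1.0 for s in tree.tip_labels},
                           n_perm=0)
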