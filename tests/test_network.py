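import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from regmodnet import (
    DiscretizedStates,
    ExpressionMatrix,
    Module,
    ModuleNetwork,
    NetworkParams,
    SplitQuery,
    best_split,
    build_tree,
    discretize_matrix,
    discretize_tf,
    fit_leaf,
    fit_module_network,
    gaussian_log_density,
    gene_log_likelihood,
    reassign_genes,
    split_log_likelihood,
)
from regmodnet.network import LOG_SQRT_2PI
from regmodnet.serialize import network_to_dict
from regmodnet.simulate import generate_planted_network


def _log(rows, genes=None, conds=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    conds = conds or [f"c{j}" for j in range(rows.shape[1])]
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=conds), "log")


def _states(rows, tfs=None, conds=None):
    rows = np.asarray(rows)
    tfs = tfs or [f"tf{i}" for i in range(rows.shape[0])]
    conds = conds or [f"c{j}" for j in range(rows.shape[1])]
    return DiscretizedStates(pd.DataFrame(rows, index=tfs, columns=conds).astype(np.int8))


class TestDiscretize:
    def test_constant_row_all_normal(self):
        assert discretize_tf(np.full(6, 3.0)).tolist() == [0] * 6

    def test_hand_computed_zscores_on_five_elements(self):
        # [0,0,0,0,5]: mean 1, population sd 2 -> z = [-.5,-.5,-.5,-.5,2]
        assert discretize_tf(np.array([0.0, 0, 0, 0, 5])).tolist() == [0, 0, 0, 0, 1]

    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=3, max_size=20))
    def test_negation_swaps_high_and_low(self, vals):
        row = np.asarray(vals)
        a = discretize_tf(row)
        b = discretize_tf(-row)
        assert np.array_equal(b, -a)

    def test_matrix_discretization_requires_log_scale(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"]), "counts"
        )
        with pytest.raises(ValueError, match="log"):
            discretize_matrix(m, ["g"])


class TestGaussianLogDensity:
    def test_closed_form_at_mean(self):
        assert gaussian_log_density(0.0, 0.0, 1.0) == pytest.approx(-0.9189385, abs=1e-6)

    def test_closed_form_one_sigma_out(self):
        assert gaussian_log_density(1.0, 0.0, 1.0) == pytest.approx(-1.4189385, abs=1e-6)

    def test_doubling_sigma_lowers_peak_by_ln2(self):
        a = gaussian_log_density(0.0, 0.0, 1.0)
        b = gaussian_log_density(0.0, 0.0, 2.0)
        assert a - b == pytest.approx(math.log(2.0))

    def test_sigma_below_floor_clamped(self):
        a = gaussian_log_density(0.3, 0.3, 1e-12, sigma_floor=0.01)
        b = gaussian_log_density(0.3, 0.3, 0.01, sigma_floor=0.01)
        assert a == b


class TestFitLeaf:
    def test_degenerate_variance_hits_floor(self):
        mu, sigma = fit_leaf([1.0, 1.0, 1.0], sigma_floor=0.01)
        assert mu == 1.0
        assert sigma == 0.01

    def test_two_point_population_sd(self):
        mu, sigma = fit_leaf([0.0, 2.0])
        assert (mu, sigma) == (1.0, 1.0)

    def test_matches_mean_sd_formula_oracle(self):
        vals = [0.3, 1.7, -0.4, 2.2, 0.9, -1.1]
        mu, sigma = fit_leaf(vals)
        n = len(vals)
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / n)
        assert mu == pytest.approx(mean)
        assert sigma == pytest.approx(sd)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            fit_leaf([])


class TestSplitLogLikelihood:
    def test_single_gene_four_conditions_matches_logpdf_sum_oracle(self):
        m = _log([[1.0, 2.0, 10.0, 12.0]])
        part = (["c0", "c1"], ["c2", "c3"])
        got = split_log_likelihood(["g0"], m, part)
        expected = 0.0
        for conds in part:
            vals = m.data.loc["g0", conds].to_numpy()
            mu, sd = vals.mean(), max(vals.std(), 0.01)
            expected += stats.norm.logpdf(vals, mu, sd).sum()
        assert got == pytest.approx(expected)

    def test_perfect_separation_sits_at_sigma_floor_maximum(self):
        m = _log([[0.0, 0.0, 5.0, 5.0], [0.0, 0.0, 5.0, 5.0]])
        got = split_log_likelihood(["g0", "g1"], m, (["c0", "c1"], ["c2", "c3"]))
        # each side: 4 values exactly at the mean, sigma floored
        expected = 2 * (-4 * (LOG_SQRT_2PI + math.log(0.01)))
        assert got == pytest.approx(expected)

    def test_true_two_state_structure_beats_merged_leaf(self):
        m = _log([[0.0, 0.1, 8.0, 8.1], [0.1, 0.0, 8.1, 8.0]])
        genes = ["g0", "g1"]
        split = split_log_likelihood(genes, m, (["c0", "c1"], ["c2", "c3"]))
        vals = m.values.ravel()
        mu, sd = vals.mean(), vals.std()
        merged = stats.norm.logpdf(vals, mu, sd).sum()
        assert split > merged


def _brute_force_best_split(genes, m, conds, cand_tfs, states, params):
    """Exhaustive enumeration over every (TF, high/low) query."""
    best, best_ll = None, -math.inf
    leaf_vals = m.data.loc[genes, conds].to_numpy().ravel()
    mu, sd = leaf_vals.mean(), max(leaf_vals.std(), params.sigma_floor)
    leaf_ll = stats.norm.logpdf(leaf_vals, mu, sd).sum()
    for tf in sorted(cand_tfs):
        for qstate, target in (("high", 1), ("low", -1)):
            yes = [c for c in conds if states.states.loc[tf, c] == target]
            no = [c for c in conds if c not in set(yes)]
            if len(yes) < params.min_leaf_conditions or len(no) < params.min_leaf_conditions:
                continue
            ll = 0.0
            for side in (yes, no):
                vals = m.data.loc[genes, side].to_numpy().ravel()
                mu_s, sd_s = vals.mean(), max(vals.std(), params.sigma_floor)
                ll += stats.norm.logpdf(vals, mu_s, sd_s).sum()
            if ll > best_ll:
                best, best_ll = SplitQuery(tf, qstate), ll
    if best is None or best_ll <= leaf_ll + params.epsilon_gain:
        return None
    return best


class TestBestSplit:
    params = NetworkParams()

    def test_perfect_split_dominates(self):
        m = _log([[0.0, 0.0, 9.0, 9.0, 9.0, 0.0]])
        states = _states([[1, 1, 0, 0, 0, 1], [0, 1, 0, 1, 0, 1]], tfs=["tfA", "tfB"])
        q = best_split(["g0"], m, m.condition_ids, ["tfA", "tfB"], states)
        assert q == SplitQuery("tfA", "high")

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n_tf, n_cond, n_gene = 3, 8, 6
            m = _log(rng.normal(0, 2, size=(n_gene, n_cond)))
            states = _states(rng.choice([-1, 0, 1], size=(n_tf, n_cond)))
            cands = list(states.tf_ids)
            got = best_split(m.gene_ids, m, m.condition_ids, cands, states, self.params)
            want = _brute_force_best_split(
                m.gene_ids, m, m.condition_ids, cands, states, self.params
            )
            assert got == want

    def test_exact_tie_resolved_lexicographically(self):
        # two TFs with identical state patterns -> identical likelihoods
        m = _log([[0.0, 0.0, 7.0, 7.0]])
        states = _states([[1, 1, 0, 0], [1, 1, 0, 0]], tfs=["tfB", "tfA"])
        q = best_split(["g0"], m, m.condition_ids, ["tfA", "tfB"], states)
        assert q == SplitQuery("tfA", "high")

    def test_none_when_no_feasible_improvement(self):
        rng = np.random.default_rng(0)
        m = _log(rng.normal(0, 0.01, size=(2, 4)) + 5.0)
        states = _states([[1, 0, 0, 0]])  # 'high' side has 1 < min_leaf conditions
        q = best_split(m.gene_ids, m, m.condition_ids, ["tf0"], states)
        assert q is None


class TestBuildTree:
    def test_no_improving_tf_yields_single_leaf(self):
        rng = np.random.default_rng(4)
        m = _log(rng.normal(3.0, 0.05, size=(3, 6)))
        states = _states([[0, 0, 0, 0, 0, 0]])
        tree = build_tree(m.gene_ids, m, ["tf0"], states)
        assert tree.depth() == 0
        assert len(tree.leaves()) == 1
        assert tree.leaves()[0].condition_ids == tuple(m.condition_ids)

    def test_max_depth_one_gives_at_most_two_leaves(self, small_ds):
        genes = [g for g, mm in small_ds.truth_assignment.items() if mm == 0]
        tree = build_tree(
            genes, small_ds.matrix, small_ds.tf_ids, small_ds.tf_states,
            NetworkParams(max_depth=1),
        )
        assert len(tree.leaves()) <= 2

    def test_recovers_planted_depth2_condition_hierarchy(self):
        hits = 0
        for seed in range(5):
            ds = generate_planted_network(
                n_modules=1, genes_per_module=12, n_background_genes=0,
                n_conditions=16, n_tfs=6, depth=2, seed=seed,
            )
            tree = build_tree(
                ds.module_gene_ids, ds.matrix, ds.regulator_tf_ids, ds.tf_states,
                NetworkParams(max_depth=2),
            )
            hits += tree.condition_hierarchy() == ds.truth_trees[0].condition_hierarchy()
        assert hits >= 4

    def test_no_tf_repeats_on_a_path(self, small_ds):
        genes = [g for g, mm in small_ds.truth_assignment.items() if mm == 1]
        tree = build_tree(genes, small_ds.matrix, small_ds.tf_ids, small_ds.tf_states)

        def check(node, used):
            if node.is_leaf:
                return
            assert node.query.tf_id not in used
            check(node.yes, used | {node.query.tf_id})
            check(node.no, used | {node.query.tf_id})

        check(tree.root, set())


class TestGeneLogLikelihood:
    def test_gene_at_all_leaf_means_closed_form(self):
        # profile exactly at every leaf mean with unit sigmas:
        # each condition contributes ln(1/sqrt(2*pi))
        from regmodnet.network import LeafModel, RegulatoryTree, SplitQuery, TreeNode

        tree = RegulatoryTree(
            TreeNode(
                query=SplitQuery("tfX", "high"),
                yes=TreeNode(leaf=LeafModel(("c0", "c1"), 3.0, 1.0)),
                no=TreeNode(leaf=LeafModel(("c2", "c3", "c4"), -1.0, 1.0)),
            ),
            ("c0", "c1", "c2", "c3", "c4"),
        )
        row = pd.Series({"c0": 3.0, "c1": 3.0, "c2": -1.0, "c3": -1.0, "c4": -1.0})
        assert gene_log_likelihood(row, tree) == pytest.approx(-0.9189385 * 5, abs=1e-5)

    def test_four_condition_toy_matches_logpdf_oracle(self):
        from regmodnet.network import LeafModel, RegulatoryTree, SplitQuery, TreeNode

        tree = RegulatoryTree(
            TreeNode(
                query=SplitQuery("tfX", "high"),
                yes=TreeNode(leaf=LeafModel(("c0", "c1"), 1.0, 0.5)),
                no=TreeNode(leaf=LeafModel(("c2", "c3"), 4.0, 2.0)),
            ),
            ("c0", "c1", "c2", "c3"),
        )
        row = pd.Series({"c0": 0.7, "c1": 1.4, "c2": 3.0, "c3": 6.0})
        expected = (
            stats.norm.logpdf([0.7, 1.4], 1.0, 0.5).sum()
            + stats.norm.logpdf([3.0, 6.0], 4.0, 2.0).sum()
        )
        assert gene_log_likelihood(row, tree) == pytest.approx(expected)

    def test_constant_offset_quadratic_penalty(self):
        from regmodnet.network import LeafModel, RegulatoryTree, TreeNode

        conds = tuple(f"c{i}" for i in range(5))
        tree = RegulatoryTree(TreeNode(leaf=LeafModel(conds, 2.0, 1.0)), conds)
        base = pd.Series(2.0, index=list(conds))
        c = 1.7
        drop = gene_log_likelihood(base, tree) - gene_log_likelihood(base + c, tree)
        assert drop == pytest.approx(5 * c**2 / 2)


class TestReassign:
    def _two_module_net(self, m):
        from regmodnet.network import LeafModel, RegulatoryTree, TreeNode

        conds = tuple(m.condition_ids)
        tree_a = RegulatoryTree(TreeNode(leaf=LeafModel(conds, 0.0, 1.0)), conds)
        tree_b = RegulatoryTree(TreeNode(leaf=LeafModel(conds, 10.0, 1.0)), conds)
        mods = [Module(tuple(m.gene_ids), tree_a), Module((), tree_b)]
        return ModuleNetwork(mods, {g: 0 for g in m.gene_ids})

    def test_genes_move_to_nearest_leaf_model(self):
        m = _log([[0.1, -0.2, 0.0], [9.8, 10.1, 10.0]])
        net = self._two_module_net(m)
        out = reassign_genes(net, m)
        assert out.assignment == {"g0": 0, "g1": 1}

    def test_identical_trees_tie_break_to_module_zero(self):
        m = _log([[1.0, 2.0], [3.0, 4.0]])
        from regmodnet.network import LeafModel, RegulatoryTree, TreeNode

        conds = tuple(m.condition_ids)
        tree = RegulatoryTree(TreeNode(leaf=LeafModel(conds, 2.0, 1.0)), conds)
        net = ModuleNetwork(
            [Module(("g0",), tree), Module(("g1",), tree)], {"g0": 0, "g1": 1}
        )
        out = reassign_genes(net, m)
        assert set(out.assignment.values()) == {0}
        assert len(out.modules) == 1  # empty module dropped

    def test_single_gene_single_module_identity(self):
        m = _log([[1.0, 2.0]])
        from regmodnet.network import LeafModel, RegulatoryTree, TreeNode

        conds = tuple(m.condition_ids)
        tree = RegulatoryTree(TreeNode(leaf=LeafModel(conds, 1.5, 1.0)), conds)
        net = ModuleNetwork([Module(("g0",), tree)], {"g0": 0})
        assert reassign_genes(net, m).assignment == {"g0": 0}

    def test_sampled_gene_returns_home_in_most_draws(self, small_ds, fit_params):
        # draw profiles from module 0's planted leaf Gaussians; they should
        # be assigned to the module whose fitted tree matches that structure
        net = fit_module_network(
            small_ds.matrix, small_ds.tf_ids, 5, seed=0, params=fit_params
        )
        truth0 = [g for g, mm in small_ds.truth_assignment.items() if mm == 0]
        counts = {}
        for g in truth0:
            counts[net.assignment[g]] = counts.get(net.assignment[g], 0) + 1
        home = max(counts, key=counts.get)
        tree = small_ds.truth_trees[0]
        rng = np.random.default_rng(42)
        hits = 0
        n_draw = 100
        for _ in range(n_draw):
            row = np.empty(small_ds.matrix.n_conditions)
            pos = {c: i for i, c in enumerate(small_ds.matrix.condition_ids)}
            for leaf in tree.leaves():
                for c in leaf.condition_ids:
                    row[pos[c]] = rng.normal(leaf.mu, leaf.sigma)
            lls = [
                gene_log_likelihood(pd.Series(row, index=small_ds.matrix.condition_ids), mod.tree)
                for mod in net.modules
            ]
            hits += int(np.argmax(lls)) == home
        assert hits >= 95


class TestFitModuleNetwork:
    def test_trace_monotone_and_fixed_point(self, small_ds, fit_params):
        net = fit_module_network(small_ds.matrix, small_ds.tf_ids, 4, seed=1, params=fit_params)
        tr = net.total_log_likelihood_trace
        assert all(b >= a - 1e-6 for a, b in zip(tr, tr[1:]))
        assert net.iterations_run <= 50
        # fixed point: one more reassignment changes nothing
        again = reassign_genes(net, small_ds.matrix)
        assert again.assignment == net.assignment

    def test_no_tf_structure_converges_to_flat_trees(self):
        rng = np.random.default_rng(8)
        m = _log(rng.normal(0, 1, size=(20, 10)))
        states_rows = np.zeros((2, 10), dtype=int)
        # TFs exist but are always 'normal': no feasible split
        net = fit_module_network(m, [], 3, seed=0)
        assert all(mod.tree.depth() == 0 for mod in net.modules)

    def test_deterministic_bit_identical(self, small_ds, fit_params):
        a = fit_module_network(small_ds.matrix, small_ds.tf_ids, 4, seed=3, params=fit_params)
        b = fit_module_network(small_ds.matrix, small_ds.tf_ids, 4, seed=3, params=fit_params)
        assert network_to_dict(a) == network_to_dict(b)

    def test_partition_covers_all_genes_exactly_once(self, small_ds, fit_params):
        net = fit_module_network(small_ds.matrix, small_ds.tf_ids, 4, seed=2, params=fit_params)
        seen = [g for mod in net.modules for g in mod.genes]
        assert sorted(seen) == sorted(small_ds.matrix.gene_ids)
        for g, idx in net.assignment.items():
            assert g in net.modules[idx].genes

    def test_member_tf_not_its_own_regulator(self, small_ds, fit_params):
        net = fit_module_network(small_ds.matrix, small_ds.tf_ids, 4, seed=5, params=fit_params)
        for mod in net.modules:
            assert not (mod.tree.regulators() & set(mod.genes))
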