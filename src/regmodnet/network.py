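"""Regulatory module network inference.

A regulatory module couples a set of co-expressed genes with a binary
decision tree over transcription-factor (TF) activity states.  Each internal
tree node queries whether a TF is highly (+1) or lowly (−1) expressed in a
condition; the leaves partition the experimental conditions, and the pooled
log-expression of the module's genes within a leaf is modeled as a Gaussian
N(μ_k, σ_k).  Inference alternates two coordinate-ascent steps from a
K-means start:

1. tree construction — greedy likelihood-maximizing splits per module;
2. gene reassignment — each gene moves to the tree under which its profile
   is most likely.

Both steps never decrease the total data log-likelihood, so the iteration
terminates at an assignment fixed point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import kmeans_cluster
from .matrix import SCALE_LOG, ExpressionMatrix

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

HIGH = "high"
LOW = "low"


@dataclass
class NetworkParams:
    """Tunable knobs of the inference engine (all in log-expression units
    where dimensional).

    z_hi / z_lo
        Per-TF z-score cutoffs for the {−1, 0, +1} activity discretization.
    sigma_floor
        Lower bound on leaf standard deviations; prevents infinite
        likelihood on degenerate (constant) leaves.
    min_leaf_conditions
        A split is feasible only if both sides keep at least this many
        conditions.
    epsilon_gain
        Minimum log-likelihood improvement for accepting a split.
    max_depth
        Maximum number of query levels on any root-to-leaf path.
    exclude_member_tfs
        If true, a TF assigned to a module as a target cannot serve as a
        regulator in that module's own tree.
    """

    z_hi: float = 1.0
    z_lo: float = -1.0
    sigma_floor: float = 0.01
    min_leaf_conditions: int = 2
    epsilon_gain: float = 1e-6
    max_depth: int = 3
    exclude_member_tfs: bool = True
    kmeans_restarts: int = 10


# ---------------------------------------------------------------------------
# TF state discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedStates:
    """TF × condition activity states over {−1, 0, +1}."""

    states: pd.DataFrame  # index: tf ids, columns: condition ids, int8

    def __post_init__(self) -> None:
        vals = self.states.to_numpy()
        if vals.size and not np.isin(vals, (-1, 0, 1)).all():
            raise ValueError("states must lie in {-1, 0, 1}")

    @property
    def tf_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.states.columns)

    def row(self, tf_id: str) -> np.ndarray:
        return self.states.loc[tf_id].to_numpy()


def discretize_tf(expr_row: np.ndarray, z_hi: float = 1.0, z_lo: float = -1.0) -> np.ndarray:
    """Map a log-expression profile to {−1, 0, +1} by its own z-scores.

    +1 where z >= z_hi, −1 where z <= z_lo, 0 otherwise; a constant profile
    (zero variance) is entirely "normal" (all 0).
    """
    row = np.asarray(expr_row, dtype=float)
    sd = row.std()
    states = np.zeros(row.shape, dtype=np.int8)
    if sd == 0:
        return states
    z = (row - row.mean()) / sd
    states[z >= z_hi] = 1
    states[z <= z_lo] = -1
    return states


def discretize_matrix(
    m: ExpressionMatrix, tf_ids: Sequence[str], z_hi: float = 1.0, z_lo: float = -1.0
) -> DiscretizedStates:
    """Discretize the rows of ``tf_ids`` (must be genes of ``m``)."""
    if m.scale_tag != SCALE_LOG:
        raise ValueError("discretize_matrix expects a log-scale matrix")
    missing = [t for t in tf_ids if t not in m.data.index]
    if missing:
        raise ValueError(f"TFs absent from matrix: {missing[:5]}")
    rows = {t: discretize_tf(m.row(t), z_hi, z_lo) for t in tf_ids}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=m.condition_ids)
    return DiscretizedStates(df.astype(np.int8))


# ---------------------------------------------------------------------------
# Tree structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class SplitQuery:
    """A yes/no question on a TF's state: yes ⇔ state == +1 ('high') or
    state == −1 ('low')."""

    tf_id: str
    query_state: str  # HIGH or LOW

    def __post_init__(self) -> None:
        if self.query_state not in (HIGH, LOW):
            raise ValueError(f"query_state must be 'high' or 'low'")

    @property
    def target(self) -> int:
        return 1 if self.query_state == HIGH else -1


@dataclass
class LeafModel:
    """A condition subset S_k with pooled Gaussian parameters (μ_k, σ_k)."""

    condition_ids: tuple[str, ...]
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.condition_ids:
            raise ValueError("leaf condition subset must be nonempty")
        if self.sigma <= 0:
            raise ValueError("leaf sigma must be positive")


@dataclass
class TreeNode:
    query: SplitQuery | None = None
    yes: "TreeNode | None" = None
    no: "TreeNode | None" = None
    leaf: LeafModel | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None


@dataclass
class RegulatoryTree:
    """Binary TF-query tree whose leaves partition the conditions."""

    root: TreeNode
    condition_ids: tuple[str, ...]

    def leaves(self) -> list[LeafModel]:
        out: list[LeafModel] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.leaf)
            else:
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out

    def leaf_for(self) -> dict[str, LeafModel]:
        mapping: dict[str, LeafModel] = {}
        for leaf in self.leaves():
            for c in leaf.condition_ids:
                if c in mapping:
                    raise ValueError(f"condition {c!r} reached by two leaves")
                mapping[c] = leaf
        return mapping

    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(d(node.yes), d(node.no))

        return d(self.root)

    def regulators(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.add(node.query.tf_id)
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return frozenset(out)

    def topology(self):
        """Nested-tuple structural signature (queries only, no parameters)."""

        def sig(node: TreeNode):
            if node.is_leaf:
                return ("leaf",)
            return (node.query.tf_id, node.query.query_state, sig(node.yes), sig(node.no))

        return sig(self.root)

    def condition_hierarchy(self):
        """The nested condition partition the tree induces, as unordered
        frozensets.  Two trees with this signature equal are observationally
        equivalent: regulator labels are unidentifiable whenever two TFs
        share a state pattern on the relevant conditions."""

        def sig(node: TreeNode):
            if node.is_leaf:
                return frozenset(node.leaf.condition_ids)
            return frozenset((sig(node.yes), sig(node.no)))

        return sig(self.root)


@dataclass
class Module:
    """A gene set plus the regulatory tree predicted to control it."""

    genes: tuple[str, ...]
    tree: RegulatoryTree


@dataclass
class ModuleNetwork:
    modules: list[Module]
    assignment: dict[str, int]
    iterations_run: int = 0
    total_log_likelihood_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        trace = self.total_log_likelihood_trace
        for prev, cur in zip(trace, trace[1:]):
            if cur < prev - 1e-6:
                raise ValueError("log-likelihood trace must be non-decreasing")

    def partition(self) -> list[frozenset[str]]:
        return [frozenset(mod.genes) for mod in self.modules]


# ---------------------------------------------------------------------------
# Gaussian machinery
# ---------------------------------------------------------------------------

def gaussian_log_density(x, mu: float, sigma: float, sigma_floor: float = 0.01):
    """ln N(x; μ, σ).  σ below the floor is clamped (degenerate-leaf guard)."""
    sigma = max(float(sigma), sigma_floor)
    x = np.asarray(x, dtype=float)
    out = -LOG_SQRT_2PI - math.log(sigma) - (x - mu) ** 2 / (2.0 * sigma**2)
    return float(out) if out.ndim == 0 else out


def fit_leaf(values: Iterable[float], sigma_floor: float = 0.01) -> tuple[float, float]:
    """ML Gaussian fit of pooled leaf values: (mean, floored population sd)."""
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot fit a leaf on an empty value pool")
    mu = float(vals.mean())
    sigma = max(float(vals.std()), sigma_floor)
    return mu, sigma


def _pooled_ll(vals: np.ndarray, sigma_floor: float) -> tuple[float, float, float]:
    """(μ, σ, total log-likelihood incl. the −½ln2π constant) of a pool."""
    n = vals.size
    mu = float(vals.mean())
    sigma = max(float(vals.std()), sigma_floor)
    ss = float(((vals - mu) ** 2).sum())
    ll = -n * (LOG_SQRT_2PI + math.log(sigma)) - ss / (2.0 * sigma**2)
    return mu, sigma, ll


def split_log_likelihood(
    module_genes: Sequence[str],
    m: ExpressionMatrix,
    partition: tuple[Sequence[str], Sequence[str]],
    sigma_floor: float = 0.01,
) -> float:
    """Total pooled Gaussian log-likelihood of a two-way condition split.

    Each side's (μ, σ) is fit on the pooled values of all module genes in
    that side's conditions; the likelihood is the product over both sides of
    every gene × condition density (sum of logs here).
    """
    yes_conds, no_conds = partition
    total = 0.0
    for conds in (yes_conds, no_conds):
        sub = m.data.loc[list(module_genes), list(conds)].to_numpy(dtype=float)
        total += _pooled_ll(sub.ravel(), sigma_floor)[2]
    return total


# ---------------------------------------------------------------------------
# Greedy tree construction
# ---------------------------------------------------------------------------

def _enumerate_splits(
    X: np.ndarray,
    cond_idx: np.ndarray,
    states_mat: np.ndarray,
    cand_order: list[tuple[str, int]],
    params: NetworkParams,
):
    """Yield (query, yes_idx, no_idx, split_ll) for every feasible query.

    ``cand_order`` lists (tf_id, row-position-in-states) sorted by tf_id, so
    iteration order realizes the lexicographic (tf_id, query_state)
    tie-break — 'high' precedes 'low'.
    """
    for tf_id, tf_pos in cand_order:
        tf_states = states_mat[tf_pos, cond_idx]
        for query_state, target in ((HIGH, 1), (LOW, -1)):
            yes_mask = tf_states == target
            n_yes = int(yes_mask.sum())
            n_no = cond_idx.size - n_yes
            if n_yes < params.min_leaf_conditions or n_no < params.min_leaf_conditions:
                continue
            yes_idx = cond_idx[yes_mask]
            no_idx = cond_idx[~yes_mask]
            ll = (
                _pooled_ll(X[:, yes_idx].ravel(), params.sigma_floor)[2]
                + _pooled_ll(X[:, no_idx].ravel(), params.sigma_floor)[2]
            )
            yield SplitQuery(tf_id, query_state), yes_idx, no_idx, ll


def best_split(
    module_genes: Sequence[str],
    m: ExpressionMatrix,
    conditions: Sequence[str],
    candidate_tfs: Sequence[str],
    states: DiscretizedStates,
    params: NetworkParams | None = None,
) -> SplitQuery | None:
    """The feasible (TF, high/low) query maximizing the split likelihood.

    Returns None when no feasible query beats the unsplit leaf by more than
    ``epsilon_gain``.  Exact likelihood ties go to the lexicographically
    smaller (tf_id, query_state).
    """
    params = params or NetworkParams()
    if not candidate_tfs:
        return None
    X = m.data.loc[list(module_genes)].to_numpy(dtype=float)
    col_pos = {c: i for i, c in enumerate(m.condition_ids)}
    cond_idx = np.array([col_pos[c] for c in conditions], dtype=int)
    states_mat = states.states.reindex(columns=m.condition_ids).to_numpy()
    tf_pos = {t: i for i, t in enumerate(states.tf_ids)}
    cand_order = [(t, tf_pos[t]) for t in sorted(set(candidate_tfs))]
    leaf_ll = _pooled_ll(X[:, cond_idx].ravel(), params.sigma_floor)[2]
    best = None
    best_ll = -math.inf
    for query, _, _, ll in _enumerate_splits(X, cond_idx, states_mat, cand_order, params):
        if ll > best_ll:
            best, best_ll = query, ll
    if best is None or best_ll <= leaf_ll + params.epsilon_gain:
        return None
    return best


def build_tree(
    module_genes: Sequence[str],
    m: ExpressionMatrix,
    candidate_tfs: Sequence[str],
    states: DiscretizedStates,
    params: NetworkParams | None = None,
) -> RegulatoryTree:
    """Greedy recursive construction of a module's regulatory tree.

    Splitting stops at ``max_depth``, when a side would fall below
    ``min_leaf_conditions``, or when no query improves the pooled leaf
    likelihood by more than ``epsilon_gain``.  No TF repeats along a
    root-to-leaf path.
    """
    params = params or NetworkParams()
    if not module_genes:
        raise ValueError("cannot build a tree for an empty module")
    genes = list(module_genes)
    X = m.data.loc[genes].to_numpy(dtype=float)
    all_conds = list(m.condition_ids)
    states_mat = states.states.reindex(columns=all_conds).to_numpy()
    tf_pos = {t: i for i, t in enumerate(states.tf_ids)}
    cands = sorted(set(candidate_tfs) & set(states.tf_ids))

    def grow(cond_idx: np.ndarray, depth: int, used: frozenset[str]) -> TreeNode:
        mu, sigma, leaf_ll = _pooled_ll(X[:, cond_idx].ravel(), params.sigma_floor)
        leaf = LeafModel(tuple(all_conds[i] for i in cond_idx), mu, sigma)
        if depth >= params.max_depth or cond_idx.size < 2 * params.min_leaf_conditions:
            return TreeNode(leaf=leaf)
        cand_order = [(t, tf_pos[t]) for t in cands if t not in used]
        best = None
        best_ll = -math.inf
        for query, yes_idx, no_idx, ll in _enumerate_splits(
            X, cond_idx, states_mat, cand_order, params
        ):
            if ll > best_ll:
                best, best_ll = (query, yes_idx, no_idx), ll
        if best is None or best_ll <= leaf_ll + params.epsilon_gain:
            return TreeNode(leaf=leaf)
        query, yes_idx, no_idx = best
        used2 = used | {query.tf_id}
        return TreeNode(
            query=query,
            yes=grow(yes_idx, depth + 1, used2),
            no=grow(no_idx, depth + 1, used2),
        )

    root = grow(np.arange(len(all_conds)), 0, frozenset())
    return RegulatoryTree(root, tuple(all_conds))


def refit_tree(
    tree: RegulatoryTree,
    module_genes: Sequence[str],
    m: ExpressionMatrix,
    sigma_floor: float = 0.01,
) -> RegulatoryTree:
    """Keep a tree's topology/condition partition; refit leaf (μ, σ) on the
    pooled values of the given genes."""
    genes = list(module_genes)

    def walk(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            sub = m.data.loc[genes, list(node.leaf.condition_ids)].to_numpy(dtype=float)
            mu, sigma = fit_leaf(sub.ravel(), sigma_floor)
            return TreeNode(leaf=LeafModel(node.leaf.condition_ids, mu, sigma))
        return TreeNode(query=node.query, yes=walk(node.yes), no=walk(node.no))

    return RegulatoryTree(walk(tree.root), tree.condition_ids)


# ---------------------------------------------------------------------------
# Likelihood evaluation and reassignment
# ---------------------------------------------------------------------------

def _compiled_leaves(tree: RegulatoryTree, condition_ids: Sequence[str]):
    col_pos = {c: i for i, c in enumerate(condition_ids)}
    out = []
    for leaf in tree.leaves():
        idx = np.array([col_pos[c] for c in leaf.condition_ids], dtype=int)
        out.append((idx, leaf.mu, leaf.sigma))
    return out


def gene_log_likelihood(gene_row, tree: RegulatoryTree) -> float:
    """Σ_conditions ln N(x_j; μ_leaf(j), σ_leaf(j)) for one gene profile.

    ``gene_row`` is a pandas Series indexed by condition id, or an array
    aligned with the tree's condition order.
    """
    if isinstance(gene_row, pd.Series):
        row = gene_row.reindex(list(tree.condition_ids)).to_numpy(dtype=float)
    else:
        row = np.asarray(gene_row, dtype=float)
        if row.size != len(tree.condition_ids):
            raise ValueError("gene_row length does not match tree conditions")
    total = 0.0
    for idx, mu, sigma in _compiled_leaves(tree, tree.condition_ids):
        vals = row[idx]
        total += float(
            -vals.size * (LOG_SQRT_2PI + math.log(sigma))
            - ((vals - mu) ** 2).sum() / (2.0 * sigma**2)
        )
    return total


def _ll_matrix(m: ExpressionMatrix, trees: Sequence[RegulatoryTree]) -> np.ndarray:
    """Genes × trees log-likelihood matrix (vectorized over genes)."""
    X = m.values.astype(float)
    out = np.zeros((X.shape[0], len(trees)))
    for j, tree in enumerate(trees):
        acc = np.zeros(X.shape[0])
        for idx, mu, sigma in _compiled_leaves(tree, m.condition_ids):
            sub = X[:, idx]
            acc += (
                -idx.size * (LOG_SQRT_2PI + math.log(sigma))
                - ((sub - mu) ** 2).sum(axis=1) / (2.0 * sigma**2)
            )
        out[:, j] = acc
    return out


def reassign_genes(network: ModuleNetwork, m: ExpressionMatrix) -> ModuleNetwork:
    """Move every gene to the argmax-likelihood tree (ties → lowest module
    index); empty modules are dropped."""
    if not network.modules:
        raise ValueError("network has no modules")
    ll = _ll_matrix(m, [mod.tree for mod in network.modules])
    labels = np.argmax(ll, axis=1)
    assignment = {g: int(l) for g, l in zip(m.gene_ids, labels)}
    return _compact(network.modules, assignment, m,
                    network.iterations_run, network.total_log_likelihood_trace)


def _compact(
    modules: Sequence[Module],
    assignment: Mapping[str, int],
    m: ExpressionMatrix,
    iterations: int,
    trace: Sequence[float],
) -> ModuleNetwork:
    """Rebuild module gene sets from an assignment, dropping empty modules."""
    member: dict[int, list[str]] = {}
    for g in m.gene_ids:
        member.setdefault(assignment[g], []).append(g)
    keep = [i for i in range(len(modules)) if member.get(i)]
    remap = {old: new for new, old in enumerate(keep)}
    new_modules = [Module(tuple(member[i]), modules[i].tree) for i in keep]
    new_assignment = {g: remap[assignment[g]] for g in m.gene_ids}
    return ModuleNetwork(new_modules, new_assignment, iterations, list(trace))


def fit_module_network(
    m: ExpressionMatrix,
    tfs: Sequence[str],
    K: int,
    seed: int,
    max_iter: int = 50,
    params: NetworkParams | None = None,
) -> ModuleNetwork:
    """Full inference: K-means start, then alternate tree construction and
    gene reassignment to an assignment fixed point.

    ``tfs`` are the candidate regulators (typically the differentially
    expressed TFs); their rows must be present in ``m`` so their states can
    be discretized.  The total-log-likelihood trace is recorded after every
    half-step and is guaranteed non-decreasing: the tree step keeps the
    previous topology (leaf parameters refit) whenever the fresh greedy tree
    would score lower on the module's current genes.
    """
    params = params or NetworkParams()
    if m.scale_tag != SCALE_LOG:
        raise ValueError("fit_module_network expects a log-scale matrix")
    tfs = sorted(set(tfs))
    states = discretize_matrix(m, tfs, params.z_hi, params.z_lo)
    clustering = kmeans_cluster(m, K, seed, n_init=params.kmeans_restarts)
    assignment = dict(clustering.assignment)
    member: dict[int, list[str]] = {}
    for g in m.gene_ids:
        member.setdefault(assignment[g], []).append(g)
    keep = sorted(member)
    remap = {old: new for new, old in enumerate(keep)}
    assignment = {g: remap[assignment[g]] for g in m.gene_ids}
    gene_sets: list[tuple[str, ...]] = [tuple(member[i]) for i in keep]
    prev_trees: list[RegulatoryTree | None] = [None] * len(gene_sets)
    trace: list[float] = []
    iterations = 0

    for _ in range(max_iter):
        iterations += 1
        trees: list[RegulatoryTree] = []
        total = 0.0
        for genes, prev in zip(gene_sets, prev_trees):
            gene_set = set(genes)
            cands = [t for t in tfs if not (params.exclude_member_tfs and t in gene_set)]
            tree = build_tree(genes, m, cands, states, params)
            sub = m.subset(genes=list(genes))
            ll_new = float(_ll_matrix(sub, [tree]).sum())
            if prev is not None:
                refit = refit_tree(prev, genes, m, params.sigma_floor)
                ll_old = float(_ll_matrix(sub, [refit]).sum())
                if ll_old > ll_new:
                    tree, ll_new = refit, ll_old
            trees.append(tree)
            total += ll_new
        trace.append(total)

        ll = _ll_matrix(m, trees)
        labels = np.argmax(ll, axis=1)
        new_assignment = {g: int(l) for g, l in zip(m.gene_ids, labels)}
        trace.append(float(ll.max(axis=1).sum()))

        net = _compact(
            [Module(gs, t) for gs, t in zip(gene_sets, trees)],
            new_assignment, m, iterations, trace,
        )
        converged = net.assignment == assignment and len(net.modules) == len(gene_sets)
        assignment = net.assignment
        gene_sets = [mod.genes for mod in net.modules]
        prev_trees = [mod.tree for mod in net.modules]
        if converged:
            break

    if len(gene_sets) == 1:
        warnings.warn("all genes collapsed into a single module")
    return ModuleNetwork(
        [Module(gs, t) for gs, t in zip(gene_sets, prev_trees)],
        assignment, iterations, trace,
    )
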