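"""Synthetic module-structured expression data with planted ground truth.

The generator emulates the structure the inference model assumes: a panel of
TF genes whose discretized states drive, through random binary query trees,
condition-partition-specific Gaussian expression of module genes, plus
unstructured background genes.  TF rows participate in the matrix as
ordinary genes so the member-TF exclusion path is exercised.  Leaf means are
laid out hierarchically along the planted tree (path-bit binary code times
the separation), so adjacent leaves differ by at least
``leaf_mean_separation`` and the root split carries the widest gap — the
regime in which greedy likelihood search is expected to recover the planted
topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import SCALE_COUNTS, SCALE_LOG, ExpressionMatrix
from .network import (
    HIGH,
    LOW,
    DiscretizedStates,
    LeafModel,
    RegulatoryTree,
    SplitQuery,
    TreeNode,
    discretize_tf,
)

_MIN_LEAF = 2  # conditions per planted leaf


@dataclass
class SyntheticDataset:
    """A planted module network: expression matrix plus full ground truth."""

    matrix: ExpressionMatrix               # log scale
    truth_assignment: dict[str, int]       # module genes only
    truth_trees: list[RegulatoryTree]
    tf_states: DiscretizedStates
    params: dict
    counts: ExpressionMatrix | None = None
    de_truth: frozenset[str] = frozenset()

    @property
    def module_gene_ids(self) -> list[str]:
        return list(self.truth_assignment)

    @property
    def tf_ids(self) -> list[str]:
        """All TF rows (planted regulator pool plus decoys)."""
        return self.tf_states.tf_ids

    @property
    def regulator_tf_ids(self) -> list[str]:
        return [t for t in self.tf_states.tf_ids if not t.startswith("DTF")]

    @property
    def decoy_tf_ids(self) -> list[str]:
        return [t for t in self.tf_states.tf_ids if t.startswith("DTF")]

    @property
    def background_gene_ids(self) -> list[str]:
        planted = set(self.truth_assignment) | set(self.tf_ids)
        return [g for g in self.matrix.gene_ids if g not in planted]


def _tf_profile(rng: np.random.Generator, n_conditions: int) -> np.ndarray:
    """A TF log-expression profile with clear high/normal/low tiers.

    Levels are drawn per condition (≈¼ high, ½ normal, ¼ low), with at
    least two conditions forced into each tail so the z-score
    discretization always yields both +1 and −1 states.
    """
    levels = rng.choice([-1, 0, 1], size=n_conditions, p=[0.25, 0.5, 0.25])
    for target in (-1, 1):
        short = 2 - int((levels == target).sum())
        if short > 0:
            pool = np.nonzero(levels == 0)[0]
            pick = rng.choice(pool, size=short, replace=False)
            levels[pick] = target
    return 2.0 + 2.0 * levels + rng.normal(0.0, 0.05, size=n_conditions)


def _random_topology(
    rng: np.random.Generator,
    states: np.ndarray,           # tf × condition
    tf_ids: Sequence[str],
    depth: int,
    n_conditions: int,
    max_tries: int = 200,
):
    """A random full binary query tree of the given depth whose every leaf
    keeps >= _MIN_LEAF conditions.  Returns (nested query structure,
    leaf condition-index lists in left-to-right order)."""

    def grow(cond_idx: np.ndarray, d: int, used: frozenset[str]):
        if d == 0:
            return ("leaf",), [cond_idx]
        need = (2 ** (d - 1)) * _MIN_LEAF
        options = []
        for tf_i in range(len(tf_ids)):
            if tf_ids[tf_i] in used:
                continue
            for state_name, target in ((HIGH, 1), (LOW, -1)):
                mask = states[tf_i, cond_idx] == target
                if need <= mask.sum() and need <= (~mask).sum():
                    options.append((tf_i, state_name, mask))
        if not options:
            return None
        rng.shuffle(options)
        for tf_i, state_name, mask in options:
            used2 = used | {tf_ids[tf_i]}
            yes = grow(cond_idx[mask], d - 1, used2)
            if yes is None:
                continue
            no = grow(cond_idx[~mask], d - 1, used2)
            if no is None:
                continue
            sig = (tf_ids[tf_i], state_name, yes[0], no[0])
            return sig, yes[1] + no[1]
        return None

    for _ in range(max_tries):
        result = grow(np.arange(n_conditions), depth, frozenset())
        if result is not None:
            return result
    raise ValueError(
        f"could not plant a depth-{depth} tree on {n_conditions} conditions "
        f"with the drawn TF states"
    )


def _build_truth_tree(sig, leaf_idx_lists, leaf_means, condition_ids, leaf_sigma, sigma_floor=0.01):
    leaf_iter = iter(zip(leaf_idx_lists, leaf_means))

    def build(node_sig) -> TreeNode:
        if node_sig == ("leaf",):
            idx, mean = next(leaf_iter)
            conds = tuple(condition_ids[i] for i in idx)
            return TreeNode(leaf=LeafModel(conds, float(mean), max(leaf_sigma, sigma_floor)))
        tf_id, state_name, yes_sig, no_sig = node_sig
        return TreeNode(
            query=SplitQuery(tf_id, state_name),
            yes=build(yes_sig),
            no=build(no_sig),
        )

    return RegulatoryTree(build(sig), tuple(condition_ids))


def generate_planted_network(
    n_modules: int = 5,
    genes_per_module: int = 30,
    n_background_genes: int = 30,
    n_conditions: int = 20,
    n_tfs: int = 12,
    leaf_mean_separation: float = 4.0,
    leaf_sigma: float = 0.5,
    depth: int = 2,
    seed: int = 7,
    z_hi: float = 1.0,
    z_lo: float = -1.0,
    n_decoy_tfs: int = 0,
) -> SyntheticDataset:
    """Generate a planted module network on the log-expression scale.

    Defaults give 5 modules × 30 genes over 20 conditions with
    leaf-mean separation 4 and leaf noise σ = 0.5 (separation/σ = 8), 12 TF
    rows and 30 unstructured background genes.  ``n_decoy_tfs`` adds TF
    rows that regulate nothing (the "non-differentially expressed TF" pool
    for stability experiments).  Regeneration with the same parameters is
    bit-identical.
    """
    if n_conditions < (2**depth) * _MIN_LEAF:
        raise ValueError(
            f"{n_conditions} conditions cannot host a depth-{depth} tree "
            f"({2**depth} leaves x {_MIN_LEAF} conditions minimum)"
        )
    params = dict(
        n_modules=n_modules, genes_per_module=genes_per_module,
        n_background_genes=n_background_genes, n_conditions=n_conditions,
        n_tfs=n_tfs, leaf_mean_separation=leaf_mean_separation,
        leaf_sigma=leaf_sigma, depth=depth, seed=seed, z_hi=z_hi, z_lo=z_lo,
        n_decoy_tfs=n_decoy_tfs,
    )
    rng = np.random.default_rng(seed)
    condition_ids = [f"C{i+1:02d}" for i in range(n_conditions)]
    tf_ids = [f"TF{i+1:02d}" for i in range(n_tfs)]
    decoy_ids = [f"DTF{i+1:02d}" for i in range(n_decoy_tfs)]

    all_tf_ids = tf_ids + decoy_ids
    tf_rows = np.vstack([_tf_profile(rng, n_conditions) for _ in all_tf_ids])
    state_rows = np.vstack([discretize_tf(r, z_hi, z_lo) for r in tf_rows])
    states = DiscretizedStates(
        pd.DataFrame(state_rows, index=all_tf_ids, columns=condition_ids).astype(np.int8)
    )

    gene_rows: dict[str, np.ndarray] = {}
    truth_assignment: dict[str, int] = {}
    truth_trees: list[RegulatoryTree] = []
    for mod in range(n_modules):
        sig, leaf_idx_lists = _random_topology(
            rng, state_rows[: len(tf_ids)], tf_ids, depth, n_conditions
        )
        # hierarchical leaf means: path-bit binary code x separation
        n_leaves = len(leaf_idx_lists)
        offset = float(rng.uniform(0.0, leaf_mean_separation))
        sign = float(rng.choice([-1.0, 1.0]))
        leaf_means = [offset + sign * leaf_mean_separation * i for i in range(n_leaves)]
        truth_trees.append(
            _build_truth_tree(sig, leaf_idx_lists, leaf_means, condition_ids, leaf_sigma)
        )
        mean_by_cond = np.empty(n_conditions)
        for idx, mean in zip(leaf_idx_lists, leaf_means):
            mean_by_cond[idx] = mean
        for g in range(genes_per_module):
            gid = f"M{mod+1}_G{g+1:03d}"
            if leaf_sigma > 0:
                row = mean_by_cond + rng.normal(0.0, leaf_sigma, size=n_conditions)
            else:
                row = mean_by_cond.copy()
            gene_rows[gid] = row
            truth_assignment[gid] = mod

    # background: structureless genes at heterogeneous constitutive levels
    # spanning the planted dynamic range (no TF-conditioned pattern)
    all_means = [l.mu for t in truth_trees for l in t.leaves()]
    lo = min(all_means) if all_means else 0.0
    hi = max(all_means) if all_means else 1.0
    bg_noise = max(leaf_sigma, 0.25)
    for b in range(n_background_genes):
        gid = f"BG{b+1:03d}"
        level = rng.uniform(lo, hi)
        gene_rows[gid] = level + rng.normal(0.0, bg_noise, size=n_conditions)

    for tf, row in zip(all_tf_ids, tf_rows):
        gene_rows[tf] = row

    matrix = ExpressionMatrix(
        pd.DataFrame.from_dict(gene_rows, orient="index", columns=condition_ids),
        SCALE_LOG,
    )
    return SyntheticDataset(matrix, truth_assignment, truth_trees, states, params)


def generate_counts(
    dataset: SyntheticDataset,
    library_size: int = 1_000_000,
    seed: int = 0,
    group_a: Sequence[str] | None = None,
    group_b: Sequence[str] | None = None,
    de_genes: Sequence[str] | None = None,
    shift_factor: float | Sequence[float] = 1.0,
) -> tuple[ExpressionMatrix, frozenset[str]]:
    """Poisson read counts whose rates track exp(log-expression).

    Conditions split into two groups (default: first half vs second half).
    ``de_genes`` get their group-A rates multiplied by ``shift_factor``
    (scalar or per-gene); genes with a factor ≠ 1 form the returned DE truth
    set.  Columns are scaled so each condition's expected total equals
    ``library_size``.  An over-dispersion hook can replace the count draw by
    subclassing; Poisson matches the stand-in binomial DE test.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    m = dataset.matrix
    conds = m.condition_ids
    if group_a is None or group_b is None:
        half = len(conds) // 2
        group_a = conds[:half]
        group_b = conds[half:]
    de_genes = list(de_genes) if de_genes is not None else []
    if np.isscalar(shift_factor):
        factors = {g: float(shift_factor) for g in de_genes}
    else:
        if len(shift_factor) != len(de_genes):
            raise ValueError("per-gene shift_factor length must match de_genes")
        factors = {g: float(f) for g, f in zip(de_genes, shift_factor)}
    rng = np.random.default_rng(seed)
    rates = np.exp(m.values.astype(float))
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    a_cols = [i for i, c in enumerate(conds) if c in set(group_a)]
    for g, f in factors.items():
        rates[gene_pos[g], a_cols] *= f
    col_tot = rates.sum(axis=0)
    rates = rates / col_tot[None, :] * library_size
    counts = rng.poisson(rates).astype(float)
    cm = ExpressionMatrix(
        pd.DataFrame(counts, index=m.gene_ids, columns=conds), SCALE_COUNTS
    )
    truth = frozenset(g for g, f in factors.items() if f != 1.0)
    return cm, truth


def regenerate(params: dict) -> SyntheticDataset:
    """Rebuild a dataset from its stored generator parameters (bit-exact)."""
    return generate_planted_network(**params)
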