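"""Module evaluation: permutation null model, Rand index, stability checks.

The per-condition module score is the reduced Gaussian log-likelihood

    log p_j = sum_i [ -(x_ij - mu_k)^2 / (2 sigma_k^2) - ln sigma_k ]

summed over the module's genes i, where leaf k is the tree leaf containing
condition j; the constant -(1/2) ln 2π per term is dropped.  The null model
keeps a fitted tree's condition partition fixed, draws random gene sets of
the same size, refits the leaf Gaussians, and recomputes the mean score —
"random genes, same topology".
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .deg import Comparison, run_comparison, select_degs
from .matrix import ExpressionMatrix
from .network import (
    Module,
    ModuleNetwork,
    NetworkParams,
    fit_leaf,
    fit_module_network,
)


@dataclass
class ConditionScore:
    condition_id: str
    log_p: float


@dataclass
class NullDistribution:
    """Mean log_p of ``n_reps`` random same-size gene draws on a fixed tree."""

    n_reps: int
    values: np.ndarray  # per-rep mean log_p
    observed: float

    def __post_init__(self) -> None:
        if len(self.values) != self.n_reps:
            raise ValueError("per-rep value count must equal n_reps")

    @property
    def summary(self) -> dict[str, float]:
        return {
            "null_mean": float(self.values.mean()),
            "null_sd": float(self.values.std()),
            "null_min": float(self.values.min()),
            "null_max": float(self.values.max()),
            "observed": self.observed,
        }

    def to_tsv(self, path) -> None:
        pd.DataFrame({"rep": np.arange(self.n_reps), "mean_log_p": self.values}).to_csv(
            path, sep="\t", index=False
        )

    def histogram(self, bins: int = 30) -> pd.DataFrame:
        """Density-normalized histogram export (area 1)."""
        span = np.ptp(self.values)
        scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
        if span <= bins * np.spacing(scale):  # degenerate null, e.g. universe == module
            v = float(self.values[0])
            density, edges = np.histogram(self.values, bins=1, range=(v - 0.5, v + 0.5), density=True)
        else:
            density, edges = np.histogram(self.values, bins=bins, density=True)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
        )


def _leaf_partition(module: Module) -> list[tuple[str, ...]]:
    return [leaf.condition_ids for leaf in module.tree.leaves()]


def _score_genes(
    m: ExpressionMatrix,
    genes: Sequence[str],
    partition: Sequence[tuple[str, ...]],
    leaf_params: Sequence[tuple[float, float]],
) -> dict[str, float]:
    """log_p per condition for the given genes under given leaf parameters."""
    X = m.data.loc[list(genes)]
    out: dict[str, float] = {}
    for conds, (mu, sigma) in zip(partition, leaf_params):
        sub = X[list(conds)].to_numpy(dtype=float)
        scores = -((sub - mu) ** 2).sum(axis=0) / (2.0 * sigma**2) - len(genes) * math.log(sigma)
        for c, s in zip(conds, scores):
            out[c] = float(s)
    return out


def module_log_p(
    module: Module, m: ExpressionMatrix
) -> tuple[list[ConditionScore], float]:
    """Per-condition scores and their mean for a fitted module."""
    partition = _leaf_partition(module)
    leaf_params = [(l.mu, l.sigma) for l in module.tree.leaves()]
    scores = _score_genes(m, module.genes, partition, leaf_params)
    ordered = [ConditionScore(c, scores[c]) for c in module.tree.condition_ids]
    mean = float(np.mean([s.log_p for s in ordered]))
    return ordered, mean


def random_null(
    module: Module,
    m: ExpressionMatrix,
    universe: Iterable[str],
    n_reps: int = 1000,
    seed: int = 0,
    sigma_floor: float = 0.01,
) -> NullDistribution:
    """Null distribution of mean log_p over random same-size gene draws.

    Each rep samples ``len(module.genes)`` genes without replacement from
    the universe, refits each leaf's (μ, σ) on the drawn genes' pooled
    values over the leaf's conditions (fixed partition), and records the
    mean per-condition score.
    """
    universe = sorted(set(universe))
    size = len(module.genes)
    if len(universe) < size:
        raise ValueError(
            f"universe ({len(universe)} genes) smaller than module ({size})"
        )
    partition = _leaf_partition(module)
    rng = np.random.default_rng(seed)
    _, observed = module_log_p(module, m)
    values = np.empty(n_reps)
    for rep in range(n_reps):
        draw = list(rng.choice(universe, size=size, replace=False))
        leaf_params = []
        for conds in partition:
            pool = m.data.loc[draw, list(conds)].to_numpy(dtype=float).ravel()
            leaf_params.append(fit_leaf(pool, sigma_floor))
        scores = _score_genes(m, draw, partition, leaf_params)
        values[rep] = float(np.mean(list(scores.values())))
    return NullDistribution(n_reps, values, observed)


# ---------------------------------------------------------------------------
# Rand index
# ---------------------------------------------------------------------------

@dataclass
class RandIndexReport:
    a: int  # together in both
    b: int  # apart in both
    c: int  # together in X, apart in Y
    d: int  # apart in X, together in Y

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def R(self) -> float:
        total = self.a + self.b + self.c + self.d
        if total == 0:
            raise ValueError("Rand index undefined for fewer than 2 elements")
        return (self.a + self.b) / total


def _labels(partition) -> dict[Hashable, int]:
    if isinstance(partition, Mapping):
        uniq = {v: i for i, v in enumerate(dict.fromkeys(partition.values()))}
        return {k: uniq[v] for k, v in partition.items()}
    labels: dict[Hashable, int] = {}
    for i, group in enumerate(partition):
        for el in group:
            if el in labels:
                raise ValueError(f"element {el!r} appears in two groups")
            labels[el] = i
    return labels


def rand_index(X, Y) -> RandIndexReport:
    """Pair-counting Rand agreement R = (a+b)/(a+b+c+d) of two partitions.

    Partitions may be given as collections of groups or as element → label
    mappings; both must cover the same element set of size ≥ 2.
    """
    lx, ly = _labels(X), _labels(Y)
    if set(lx) != set(ly):
        raise ValueError("partitions cover different element sets")
    elements = sorted(lx, key=repr)
    if len(elements) < 2:
        raise ValueError("Rand index needs at least 2 elements")
    ax = np.array([lx[e] for e in elements])
    ay = np.array([ly[e] for e in elements])
    same_x = ax[:, None] == ax[None, :]
    same_y = ay[:, None] == ay[None, :]
    iu = np.triu_indices(len(elements), k=1)
    sx, sy = same_x[iu], same_y[iu]
    a = int((sx & sy).sum())
    b = int((~sx & ~sy).sum())
    c = int((sx & ~sy).sum())
    d = int((~sx & sy).sum())
    return RandIndexReport(a, b, c, d)


# ---------------------------------------------------------------------------
# Stability under non-DE TF injection
# ---------------------------------------------------------------------------

def _relation_pairs(network: ModuleNetwork):
    """Co-membership pair sets: gene–gene, TF–TF (co-regulating a module),
    TF–target."""
    gene_gene: set[frozenset] = set()
    tf_tf: set[frozenset] = set()
    tf_target: set[tuple] = set()
    for mod in network.modules:
        genes = sorted(mod.genes)
        for g1, g2 in itertools.combinations(genes, 2):
            gene_gene.add(frozenset((g1, g2)))
        regs = sorted(mod.tree.regulators())
        for t1, t2 in itertools.combinations(regs, 2):
            tf_tf.add(frozenset((t1, t2)))
        for t in regs:
            for g in genes:
                tf_target.add((t, g))
    return gene_gene, tf_tf, tf_target


def _pairset_agreement(pairs_x: set, pairs_y: set, universe_pairs: int) -> tuple[int, int]:
    """(agreements, total) where agreement = pair predicted together in both
    or in neither run."""
    a = len(pairs_x & pairs_y)
    b = universe_pairs - len(pairs_x | pairs_y)
    return a + b, universe_pairs


def relation_rand_indices(
    net_x: ModuleNetwork, net_y: ModuleNetwork
) -> dict[str, float]:
    """Rand-style agreement of predicted relations between two runs.

    Gene–gene pairs use all genes shared by the runs; TF–TF and TF–target
    pairs are restricted to the TFs appearing as regulators in both runs.
    """
    genes_x = set(net_x.assignment)
    genes_y = set(net_y.assignment)
    shared_genes = sorted(genes_x & genes_y)
    gx, tx, tgx = _relation_pairs(net_x)
    gy, ty, tgy = _relation_pairs(net_y)
    tfs_x = set().union(*(mod.tree.regulators() for mod in net_x.modules)) if net_x.modules else set()
    tfs_y = set().union(*(mod.tree.regulators() for mod in net_y.modules)) if net_y.modules else set()
    shared_tfs = sorted(tfs_x & tfs_y)

    def restrict(pairs, keep):
        return {p for p in pairs if all(el in keep for el in p)}

    keep_g = set(shared_genes)
    keep_t = set(shared_tfs)
    counts = {}
    n_gene_pairs = len(shared_genes) * (len(shared_genes) - 1) // 2
    counts["gene_gene"] = _pairset_agreement(
        restrict(gx, keep_g), restrict(gy, keep_g), n_gene_pairs
    )
    n_tf_pairs = len(shared_tfs) * (len(shared_tfs) - 1) // 2
    counts["tf_tf"] = _pairset_agreement(
        restrict(tx, keep_t), restrict(ty, keep_t), n_tf_pairs
    )
    n_tg_pairs = len(shared_tfs) * len(shared_genes)
    tgx_r = {p for p in tgx if p[0] in keep_t and p[1] in keep_g}
    tgy_r = {p for p in tgy if p[0] in keep_t and p[1] in keep_g}
    counts["tf_target"] = _pairset_agreement(tgx_r, tgy_r, n_tg_pairs)

    out: dict[str, float] = {}
    agree_all = total_all = 0
    for key, (agree, total) in counts.items():
        out[key] = agree / total if total else 1.0
        agree_all += agree
        total_all += total
    out["combined"] = agree_all / total_all if total_all else 1.0
    return out


def tf_injection_stability(
    m: ExpressionMatrix,
    deg_tfs: Sequence[str],
    non_deg_tfs: Sequence[str],
    fractions: Sequence[float],
    K: int,
    seed: int,
    params: NetworkParams | None = None,
    max_iter: int = 50,
) -> dict[float, dict[str, float]]:
    """Refit the network with a share of non-DE TFs added to the candidate
    list and compare predicted relations against the 0% baseline.

    Each fraction selects round(f · |non_deg_tfs|) extra TFs (a fraction
    exceeding the pool is capped with a warning).  Fraction 0 compares the
    baseline with itself and is exactly 1.0 by determinism.
    """
    non_deg_tfs = sorted(set(non_deg_tfs))
    baseline = fit_module_network(m, deg_tfs, K, seed, max_iter=max_iter, params=params)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(non_deg_tfs))
    out: dict[float, dict[str, float]] = {}
    for frac in fractions:
        f = float(frac)
        if f < 0:
            raise ValueError("fractions must be non-negative")
        if f > 1:
            warnings.warn(f"fraction {f} exceeds available non-DE TFs; capped at 1.0")
            f = 1.0
        n_extra = int(round(f * len(non_deg_tfs)))
        extra = order[:n_extra]
        if n_extra == 0:
            net = fit_module_network(m, deg_tfs, K, seed, max_iter=max_iter, params=params)
        else:
            net = fit_module_network(
                m, list(deg_tfs) + extra, K, seed, max_iter=max_iter, params=params
            )
        out[float(frac)] = relation_rand_indices(baseline, net)
    return out


# ---------------------------------------------------------------------------
# DEG-threshold robustness
# ---------------------------------------------------------------------------

def threshold_robustness(
    m: ExpressionMatrix,
    counts: ExpressionMatrix,
    comparisons: Sequence[Comparison],
    thresholds: tuple[float, float],
    K: int,
    seed: int,
    params: NetworkParams | None = None,
    tfs: Sequence[str] | None = None,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Fit networks on DEG sets at two adjusted-p cutoffs and report, for
    each stricter-cutoff module, its best-matching looser-cutoff module.

    Columns: strict_module, strict_size, loose_module, jaccard, containment
    (|S∩L|/|S|).  With the stand-in DE test and BH adjustment the stricter
    DEG set is nested in the looser one.
    """
    lo, hi = sorted(thresholds)
    tfs = sorted(set(tfs)) if tfs is not None else []
    nets = {}
    for cutoff in (lo, hi):
        results = [run_comparison(counts, c, threshold=cutoff) for c in comparisons]
        selected = select_degs(results, mode="overlap")
        if not selected:
            raise ValueError(f"no DEGs selected at cutoff {cutoff}")
        wanted = set(selected) | set(tfs)
        keep = [g for g in m.gene_ids if g in wanted]
        sub = m.subset(genes=keep)
        k_eff = min(K, sub.n_genes)
        nets[cutoff] = fit_module_network(
            sub, [t for t in tfs if t in wanted and t in set(keep)], k_eff, seed,
            max_iter=max_iter, params=params,
        )
    strict_net, loose_net = nets[lo], nets[hi]
    rows = []
    for i, smod in enumerate(strict_net.modules):
        s = set(smod.genes)
        best_j, best_cont, best_idx = -1.0, 0.0, -1
        for j, lmod in enumerate(loose_net.modules):
            l = set(lmod.genes)
            jac = len(s & l) / len(s | l)
            if jac > best_j:
                best_j, best_idx = jac, j
                best_cont = len(s & l) / len(s)
        rows.append((i, len(s), best_idx, best_j, best_cont))
    return pd.DataFrame(
        rows,
        columns=["strict_module", "strict_size", "loose_module", "jaccard", "containment"],
    )
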