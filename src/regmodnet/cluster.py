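"""Initial K-means co-expression clustering and choice of cluster count K.

K is picked from the tradeoff between average within-cluster correlation and
average cluster size: as K grows, clusters become tighter but smaller.  The
"knee" of the correlation curve — the K of maximum discrete curvature — is
taken as the automatic choice; callers may always override it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .matrix import SCALE_LOG, ExpressionMatrix


@dataclass
class Clustering:
    """A hard partition of genes plus its summary statistics."""

    assignment: dict[str, int]
    K: int
    avg_corr: float = float("nan")
    avg_size: float = float("nan")
    zero_variance_genes: frozenset[str] = frozenset()

    def members(self, k: int) -> list[str]:
        return [g for g, c in self.assignment.items() if c == k]

    def as_sets(self) -> list[frozenset[str]]:
        return [
            frozenset(self.members(k)) for k in range(self.K)
        ]


def kmeans_cluster(m: ExpressionMatrix, K: int, seed: int, n_init: int = 10) -> Clustering:
    """Lloyd K-means on log-expression row vectors (Euclidean distance).

    ``n_init`` random restarts keep the best-inertia solution; fixed seed
    gives a deterministic result.
    """
    if m.scale_tag != SCALE_LOG:
        raise ValueError("kmeans_cluster expects a log-scale matrix")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m.n_genes:
        raise ValueError(f"K={K} exceeds gene count {m.n_genes}")
    X = m.values.astype(float)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed, tol=1e-6)
    labels = km.fit_predict(X)
    assignment = {g: int(l) for g, l in zip(m.gene_ids, labels)}
    clustering = Clustering(assignment, K)
    clustering.avg_corr, clustering.avg_size = cluster_stats(m, clustering)
    return clustering


def _pairwise_mean_corr(rows: np.ndarray, zero_var: np.ndarray) -> float:
    """Mean pairwise Pearson r among rows; pairs touching a zero-variance
    row contribute 0 by convention."""
    n = rows.shape[0]
    if n == 1:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    iu = np.triu_indices(n, k=1)
    return float(corr[iu].mean())


def cluster_stats(m: ExpressionMatrix, clustering: Clustering) -> tuple[float, float]:
    """(avg_corr, avg_size): cluster-mean of pairwise Pearson r, and n/K.

    Size-1 clusters contribute correlation 1.0; zero-variance rows give
    correlation 0 with every partner and are flagged on the clustering.
    """
    missing = [g for g in clustering.assignment if g not in m.data.index]
    if missing:
        raise ValueError(f"clustering refers to genes absent from matrix: {missing[:5]}")
    X = m.data.loc[list(clustering.assignment)].to_numpy(dtype=float)
    genes = list(clustering.assignment)
    labels = np.array([clustering.assignment[g] for g in genes])
    row_var = X.var(axis=1)
    zero_var_all = row_var == 0
    clustering.zero_variance_genes = frozenset(
        g for g, z in zip(genes, zero_var_all) if z
    )
    per_cluster = []
    for k in range(clustering.K):
        idx = np.nonzero(labels == k)[0]
        if idx.size == 0:
            continue
        per_cluster.append(_pairwise_mean_corr(X[idx], zero_var_all[idx]))
    avg_corr = float(np.mean(per_cluster)) if per_cluster else float("nan")
    avg_size = len(genes) / clustering.K
    return avg_corr, avg_size


@dataclass
class KSelection:
    """Chosen K plus the full (K, avg_corr, avg_size) curve."""

    chosen_k: int
    curve: pd.DataFrame  # columns: K, avg_corr, avg_size
    fallback: bool = False

    def to_tsv(self, path) -> None:
        self.curve.to_csv(path, sep="\t", index=False)


# avg_corr spread below which the data are treated as structureless
_FLAT_CURVE_SPAN = 0.05


def select_k(
    m: ExpressionMatrix,
    k_range: tuple[int, int],
    seed: int,
    n_init: int = 10,
) -> KSelection:
    """Scan K over ``k_range`` (inclusive) and pick the curvature knee.

    The knee is the point of maximum distance between the normalized
    avg_corr curve and the chord joining its endpoints (kneedle criterion):
    the K where correlation gains flatten into the plateau.  A window
    narrower than 3 leaves the knee undefined: the midpoint is returned
    with a warning.  A flat curve (structureless data) falls back to the
    smallest K with a warning.
    """
    lo, hi = k_range
    if lo < 2 or hi > m.n_genes or lo > hi:
        raise ValueError(f"k_range {k_range} outside [2, {m.n_genes}]")
    ks = list(range(lo, hi + 1))
    rows = []
    for k in ks:
        c = kmeans_cluster(m, k, seed, n_init=n_init)
        rows.append((k, c.avg_corr, c.avg_size))
    curve = pd.DataFrame(rows, columns=["K", "avg_corr", "avg_size"])
    if len(ks) < 3:
        warnings.warn("k_range narrower than 3: knee undefined, using midpoint")
        return KSelection(ks[len(ks) // 2], curve, fallback=True)
    corr = curve["avg_corr"].to_numpy()
    if np.ptp(corr) < _FLAT_CURVE_SPAN:
        warnings.warn("flat correlation curve: no cluster structure, using smallest K")
        return KSelection(ks[0], curve, fallback=True)
    # kneedle: farthest point of the normalized curve above its chord
    x = (np.asarray(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    y = (corr - corr.min()) / np.ptp(corr)
    knee = int(np.argmax(y - x))
    return KSelection(ks[knee], curve)
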