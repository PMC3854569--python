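"""Differential-expression gene (DEG) selection.

Negative-binomial DE machinery (edgeR/DEGseq) is deliberately out of scope:
real analyses import their adjusted p-values via :func:`import_deg_table`.
A self-contained stand-in test is provided for synthetic counts: a two-sided
exact binomial test on a gene's pooled counts across the two groups against
the library-size proportion.  It is a replicate-free pooled test, documented
as a stand-in, not a reimplementation of edgeR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import SCALE_COUNTS, ExpressionMatrix

DEFAULT_THRESHOLD = 0.05  # edgeR-style adjusted-p cutoff
DEGSEQ_DEFAULT_THRESHOLD = 0.001  # DEGseq's default cutoff


@dataclass
class Comparison:
    """A two-group contrast (e.g. inoculated vs mock at one time point)."""

    name: str
    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        self.group_a = frozenset(self.group_a)
        self.group_b = frozenset(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError(f"comparison {self.name!r}: empty group")
        if self.group_a & self.group_b:
            raise ValueError(f"comparison {self.name!r}: groups overlap")


@dataclass
class DEGResult:
    """Per-comparison DE outcome: raw and adjusted p-values plus selection."""

    comparison: str
    p_raw: pd.Series
    p_adj: pd.Series
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for s in (self.p_raw, self.p_adj):
            vals = s.to_numpy(dtype=float)
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValueError("p-values must lie in [0, 1]")

    @property
    def selected(self) -> frozenset[str]:
        # inclusive threshold: p <= cutoff selects the gene
        mask = self.p_adj <= self.threshold
        return frozenset(self.p_adj.index[mask])


def de_test(counts: ExpressionMatrix, comparison: Comparison) -> pd.Series:
    """Stand-in DE test: exact two-sided binomial on pooled group counts.

    For each gene, its pooled count in group A out of its total pooled count
    is tested against the null proportion libA / (libA + libB).  Genes with
    zero total count get p = 1 (no-signal convention).
    """
    if counts.scale_tag != SCALE_COUNTS:
        raise ValueError("de_test expects a counts-scale matrix")
    cond = set(counts.condition_ids)
    for grp, label in ((comparison.group_a, "a"), (comparison.group_b, "b")):
        missing = grp - cond
        if missing:
            raise ValueError(
                f"comparison {comparison.name!r}: group_{label} conditions "
                f"absent from matrix: {sorted(missing)[:5]}"
            )
    a_cols = [c for c in counts.condition_ids if c in comparison.group_a]
    b_cols = [c for c in counts.condition_ids if c in comparison.group_b]
    a_counts = counts.data[a_cols].sum(axis=1).round().astype(int)
    b_counts = counts.data[b_cols].sum(axis=1).round().astype(int)
    lib_a = float(a_counts.sum())
    lib_b = float(b_counts.sum())
    if lib_a + lib_b == 0:
        return pd.Series(1.0, index=counts.gene_ids, name=comparison.name)
    p0 = lib_a / (lib_a + lib_b)
    pvals = np.ones(counts.n_genes)
    for i, (xa, xb) in enumerate(zip(a_counts.to_numpy(), b_counts.to_numpy())):
        total = xa + xb
        if total == 0:
            continue
        pvals[i] = stats.binomtest(int(xa), int(total), p0).pvalue
    return pd.Series(pvals, index=counts.gene_ids, name=comparison.name)


def adjust_pvalues(p: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    if isinstance(p, pd.Series):
        arr = p.to_numpy(dtype=float)
    else:
        arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return p.copy() if isinstance(p, pd.Series) else arr
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adj, index=p.index, name=p.name)
    return adj


def run_comparison(
    counts: ExpressionMatrix,
    comparison: Comparison,
    threshold: float = DEFAULT_THRESHOLD,
) -> DEGResult:
    """Stand-in test + BH adjustment for one comparison."""
    raw = de_test(counts, comparison)
    adj = adjust_pvalues(raw)
    return DEGResult(comparison.name, raw, adj, threshold)


def select_degs(
    results: Sequence[DEGResult],
    mode: Literal["per_group", "overlap", "union"] = "overlap",
):
    """Combine per-comparison selections.

    ``per_group`` returns a dict of each comparison's selected set;
    ``overlap`` the intersection across comparisons; ``union`` their union.
    """
    if not results:
        raise ValueError("select_degs requires at least one DEGResult")
    if mode == "per_group":
        return {r.comparison: r.selected for r in results}
    sets = [r.selected for r in results]
    if mode == "overlap":
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    if mode == "union":
        out = frozenset()
        for s in sets:
            out = out | s
        return out
    raise ValueError(f"unknown mode {mode!r}")


def import_deg_table(
    path: str | Path,
    comparison: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> DEGResult:
    """Import an external DE table (gene_id <tab> adjusted p), e.g. edgeR output.

    The adjusted p is used for both raw and adjusted slots.  A header line is
    tolerated if its second field is non-numeric.
    """
    path = Path(path)
    genes: list[str] = []
    ps: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                p = float(parts[1])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric p-value {parts[1]!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{path}:{lineno}: p-value {p} outside [0, 1]")
            genes.append(parts[0])
            ps.append(p)
    if len(set(genes)) != len(genes):
        raise ValueError(f"{path}: duplicate gene ids in DEG table")
    series = pd.Series(ps, index=genes, dtype=float)
    name = comparison if comparison is not None else path.stem
    return DEGResult(name, series.copy(), series, threshold)
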