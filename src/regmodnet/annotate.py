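"""Module annotation: GO-term enrichment and nodulin motif scanning.

Enrichment is a one-sided hypergeometric upper-tail test of a GO term's
frequency in a module against a background gene universe.  The motif scan
counts exact (overlapping) occurrences of the two putative nodulin consensus
sequences NODCON1GM (AAAGAT) and NODCON2GM (CTCTT) in promoter regions,
taken as the 500 bp upstream of each gene's start codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

NODULIN_MOTIFS = {"NODCON1GM": "AAAGAT", "NODCON2GM": "CTCTT"}
DEFAULT_UPSTREAM_LENGTH = 500
DEFAULT_ENRICHMENT_CUTOFF = 0.01

_ONTOLOGIES = ("P", "F", "C")


@dataclass(frozen=True)
class GoAnnotation:
    """One gene → GO term link, with sub-ontology P/F/C."""

    gene_id: str
    go_id: str
    ontology: str
    term: str = ""

    def __post_init__(self) -> None:
        if self.ontology not in _ONTOLOGIES:
            raise ValueError(f"ontology must be one of {_ONTOLOGIES}")


def load_annotations(path: str | Path) -> list[GoAnnotation]:
    """Read a GO annotation TSV: gene_id, go_id, ontology[, term]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = list(df.columns)
    out = []
    for _, rec in df.iterrows():
        term = str(rec[cols[3]]) if len(cols) > 3 else ""
        out.append(GoAnnotation(str(rec[cols[0]]), str(rec[cols[1]]), str(rec[cols[2]]), term))
    return out


@dataclass
class EnrichmentRow:
    go_id: str
    term: str
    ontology: str
    k: int      # module genes carrying the term
    K_bg: int   # background genes carrying the term
    n: int      # module size (annotated genes)
    N: int      # background size
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.k > min(self.K_bg, self.n):
            raise ValueError("k cannot exceed min(K_bg, n)")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def enrichment_test(
    module_genes: Iterable[str],
    annotations: Sequence[GoAnnotation],
    background: Iterable[str] | None = None,
    cutoff: float = DEFAULT_ENRICHMENT_CUTOFF,
    bh_correct: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment for every GO term in the module.

    The background defaults to all annotated genes; it must contain the
    module.  Raw p-values are reported (matching the published tables); BH
    adjustment is opt-in via ``bh_correct``.
    """
    ann_by_gene: dict[str, set[tuple[str, str, str]]] = {}
    for a in annotations:
        ann_by_gene.setdefault(a.gene_id, set()).add((a.go_id, a.ontology, a.term))
    if background is None:
        background = ann_by_gene.keys()
    bg = sorted(set(background))
    if not bg:
        raise ValueError("empty background universe")
    module = sorted(set(module_genes))
    stray = set(module) - set(bg)
    if stray:
        raise ValueError(f"module genes outside background: {sorted(stray)[:5]}")
    N = len(bg)
    n = len(module)
    term_bg: dict[tuple[str, str, str], int] = {}
    term_mod: dict[tuple[str, str, str], int] = {}
    mod_set = set(module)
    for g in bg:
        for key in ann_by_gene.get(g, ()):
            term_bg[key] = term_bg.get(key, 0) + 1
            if g in mod_set:
                term_mod[key] = term_mod.get(key, 0) + 1
    rows = []
    for key in sorted(term_mod):
        go_id, ontology, term = key
        k = term_mod[key]
        K_bg = term_bg[key]
        # P(X >= k) for X ~ Hypergeom(N, K_bg, n)
        p = float(stats.hypergeom.sf(k - 1, N, K_bg, n))
        p = min(p, 1.0)
        rows.append(EnrichmentRow(go_id, term, ontology, k, K_bg, n, N, p, p < cutoff))
    if bh_correct and rows:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r.p_value = float(q)
            r.significant = q < cutoff
    rows.sort(key=lambda r: (r.p_value, r.go_id))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.go_id, r.term, r.ontology, r.k, r.K_bg, r.n, r.N, r.p_value, r.significant)
            for r in rows
        ],
        columns=["go_id", "term", "ontology", "k", "K_bg", "n", "N", "p_value", "significant"],
    )


# ---------------------------------------------------------------------------
# Upstream extraction
# ---------------------------------------------------------------------------

def extract_upstream(
    genome: str | Path | Mapping[str, str],
    features: str | Path,
    length: int = DEFAULT_UPSTREAM_LENGTH,
    feature_type: str = "gene",
) -> dict[str, str]:
    """Extract each gene's upstream promoter window from genome + GFF3.

    For a forward-strand gene starting at 1-based position s the window is
    [max(1, s − length), s − 1]; for a reverse-strand gene ending at e it is
    the reverse complement of [e + 1, e + length].  Windows are truncated at
    contig ends; genes on contigs absent from the genome are skipped with a
    warning.  Coordinates follow GFF3 (1-based, inclusive); returned
    sequences are uppercase 5'→3' relative to the gene.
    """
    if isinstance(genome, Mapping):
        contigs = {k: str(v).upper() for k, v in genome.items()}
    else:
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")
        }
    db = gffutils.create_db(
        str(features), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, str] = {}
    for feat in db.features_of_type(feature_type, order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        contig = contigs.get(feat.seqid)
        if contig is None:
            warnings.warn(f"gene {gene_id!r}: contig {feat.seqid!r} absent from genome; skipped")
            continue
        if feat.strand == "-":
            start = feat.end + 1                    # 1-based
            end = min(len(contig), feat.end + length)
            if start > end:
                out[gene_id] = ""
                continue
            window = contig[start - 1 : end]
            out[gene_id] = str(Seq(window).reverse_complement())
        else:
            end = feat.start - 1
            start = max(1, feat.start - length)
            if start > end:
                out[gene_id] = ""
                continue
            out[gene_id] = contig[start - 1 : end]
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Nodulin motif scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    strand: str   # '+' or '-'
    offset: int   # 0-based position in the upstream sequence


def _count_overlapping(seq: str, pattern: str) -> list[int]:
    hits = []
    start = seq.find(pattern)
    while start != -1:
        hits.append(start)
        start = seq.find(pattern, start + 1)
    return hits


def scan_nodulin_motifs(
    upstream: Mapping[str, str] | str | Path,
    scan_reverse: bool = False,
    motifs: Mapping[str, str] = NODULIN_MOTIFS,
) -> list[MotifHit]:
    """All (overlapping) exact occurrences of the nodulin motifs, per record.

    Sequences are uppercase-normalized; IUPAC ambiguity codes never match.
    The optional reverse scan searches each motif's reverse complement on
    the stored strand and reports it as strand '-'.
    """
    if not isinstance(upstream, Mapping):
        upstream = read_fasta(upstream)
    hits: list[MotifHit] = []
    for gene_id in upstream:
        seq = str(upstream[gene_id]).upper()
        for name, pattern in motifs.items():
            for off in _count_overlapping(seq, pattern.upper()):
                hits.append(MotifHit(gene_id, name, "+", off))
            if scan_reverse:
                rc = str(Seq(pattern.upper()).reverse_complement())
                for off in _count_overlapping(seq, rc):
                    hits.append(MotifHit(gene_id, name, "-", off))
    return hits


def motif_summary(
    hits: Sequence[MotifHit],
    assignment: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene (and, given a module assignment, per-module) hit counts."""
    rows = [(h.gene_id, h.motif, h.strand, h.offset) for h in hits]
    df = pd.DataFrame(rows, columns=["gene_id", "motif", "strand", "offset"])
    if df.empty:
        counts = pd.DataFrame(columns=["gene_id", "motif", "count"])
    else:
        counts = (
            df.groupby(["gene_id", "motif"]).size().reset_index(name="count")
        )
    if assignment is not None and not counts.empty:
        counts["module"] = counts["gene_id"].map(assignment)
    return counts
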