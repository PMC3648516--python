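"""Hypergeometric GO/KEGG term enrichment of DEG sets.

For a universe of N annotated ortholog genes of which n are differentially
expressed, a term annotating M universe genes and m DEGs is scored by the
upper-tail hypergeometric probability

    p = P(X >= m) = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N,n).

Terms annotating fewer than five universe genes are filtered out before
testing, and a term is flagged enriched when p <= 0.05 (no multiplicity
correction across terms; a BH column is available for users who want one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .diff_expression import bh_fdr

DEFAULT_MIN_TERM_SIZE = 5
DEFAULT_ALPHA = 0.05


@dataclass
class TermAnnotation:
    term_id: str
    description: str = ""
    category: str = ""
    level: int | None = None
    genes: set[str] = field(default_factory=set)


AnnotationMap = dict  # term_id -> TermAnnotation


@dataclass
class EnrichmentRecord:
    term_id: str
    description: str
    category: str
    level: int | None
    m: int  # DEGs annotated to the term
    M: int  # universe genes annotated to the term
    n: int  # DEGs with any annotation
    N: int  # universe genes with any annotation
    p_value: float
    enriched: bool
    fdr: float | None = None


def hypergeom_upper_tail(m: int, M: int, n: int, N: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N genes, M marked, n drawn)."""
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(
            f"inconsistent hypergeometric parameters m={m}, M={M}, n={n}, N={N}"
        )
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich(
    deg_genes: set[str],
    annotation: Mapping[str, TermAnnotation],
    universe: set[str],
    *,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    alpha: float = DEFAULT_ALPHA,
    category: str | None = None,
    add_fdr: bool = True,
) -> list[EnrichmentRecord]:
    """Score every sufficiently large term for DEG over-representation.

    ``universe`` is the full ortholog-gene set; ``deg_genes`` must be a
    subset of it.  N and n count only genes carrying at least one annotation
    (optionally restricted to one ``category``, e.g. a single GO namespace).
    Terms with fewer than ``min_term_size`` annotated universe genes are
    excluded before testing.  Output is sorted by ascending p, ties broken
    by term identifier.
    """
    if not deg_genes <= universe:
        extra = sorted(deg_genes - universe)
        raise ValueError(f"DEG genes outside the universe: {extra[:5]}")
    terms = [
        t for t in annotation.values() if category is None or t.category == category
    ]
    annotated_universe: set[str] = set()
    for t in terms:
        annotated_universe |= t.genes & universe
    if not annotated_universe:
        raise ValueError("no universe gene carries an annotation in this category")
    N = len(annotated_universe)
    n = len(deg_genes & annotated_universe)
    records: list[EnrichmentRecord] = []
    for t in sorted(terms, key=lambda t: t.term_id):
        term_universe = t.genes & universe
        M = len(term_universe)
        if M < min_term_size:
            continue
        m = len(term_universe & deg_genes)
        p = hypergeom_upper_tail(m, M, n, N)
        records.append(
            EnrichmentRecord(
                term_id=t.term_id,
                description=t.description,
                category=t.category,
                level=t.level,
                m=m,
                M=M,
                n=n,
                N=N,
                p_value=p,
                enriched=(p <= alpha and M >= min_term_size),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.term_id))
    if add_fdr and records:
        qs = bh_fdr([r.p_value for r in records])
        for r, q in zip(records, qs):
            r.fdr = float(q)
    return records


def load_annotation_gmt(
    path: str | Path, *, category: str = "", metadata: Mapping[str, tuple] | None = None
) -> AnnotationMap:
    """Parse a GMT-like TSV: term_id, description, then one gene per field.

    ``metadata`` optionally maps term_id to ``(category, level)`` as read by
    :func:`load_term_metadata`.
    """
    out: AnnotationMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected term, description, genes...")
            term_id, description = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise ValueError(f"line {lineno}: term {term_id!r} has no genes")
            cat, level = category, None
            if metadata and term_id in metadata:
                cat, level = metadata[term_id]
            out[term_id] = TermAnnotation(
                term_id=term_id,
                description=description,
                category=cat,
                level=level,
                genes=genes,
            )
    return out


def load_term_metadata(path: str | Path) -> dict[str, tuple[str, int | None]]:
    """Read optional term metadata TSV: term_id, category, level."""
    out: dict[str, tuple[str, int | None]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            term_id = fields[0]
            cat = fields[1] if len(fields) > 1 else ""
            level = int(fields[2]) if len(fields) > 2 and fields[2] else None
            out[term_id] = (cat, level)
    return out


def write_enrichment_table(
    records: Iterable[EnrichmentRecord], path: str | Path, header: str | None = None
) -> None:
    """TSV mirroring the usual enrichment-table layout (term, level,
    description, DEG count, gene count, p-value)."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "term_id\tcategory\tlevel\tdescription\tn_degs\tn_genes\t"
            "p_value\tfdr\tenriched\n"
        )
        for r in records:
            level = "" if r.level is None else str(r.level)
            fdr = "" if r.fdr is None else f"{r.fdr:.6g}"
            fh.write(
                f"{r.term_id}\t{r.category}\t{level}\t{r.description}\t"
                f"{r.m}\t{r.M}\t{r.p_value:.6g}\t{fdr}\t{str(r.enriched).lower()}\n"
            )
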