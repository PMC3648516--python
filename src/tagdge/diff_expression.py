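"""Exact two-library differential-expression testing for tag counts.

Replicate-free DGE libraries are compared with the Audic–Claverie exact
statistic: given a tag (gene) count ``x`` in a library of ``n1`` total tags,
the count ``y`` in a second library of ``n2`` tags follows

    P(y | x) = (n2/n1)^y * (x+y)! / ( x! * y! * (1 + n2/n1)^(x+y+1) ),

a negative-binomial distribution with ``x+1`` successes and success
probability ``n1/(n1+n2)``.  The two-sided p-value doubles the smaller tail
and caps at 1.  Tails are evaluated through the regularized incomplete beta
function, which is exact and stable at library sizes of millions of tags.

Genes are called differentially expressed when the Benjamini–Hochberg FDR
falls below 0.001 and the normalized |log2 ratio| is at least 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betainc
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_THRESHOLD = 1e-3
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class DEGRecord:
    """One gene's two-species comparison."""

    gene_id: str
    species_a: str
    species_b: str
    x: int  # count in A
    y: int  # count in B
    n1: int  # total clean tags of A
    n2: int  # total clean tags of B
    log2_ratio: float  # A over B, normalized
    p_value: float
    fdr: float
    status: str  # "up", "down" or "ns"


def exact_tag_test(x, y, n1, n2):
    """Two-sided Audic–Claverie p-value for counts x (library n1) and y (n2).

    Accepts scalars or numpy arrays for ``x`` and ``y``; returns the same
    shape.  ``p = min(1, 2 * min(P(Y<=y|x), P(Y>=y|x)))`` with both tails
    including the observed count.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    p1 = n1 / (n1 + n2)
    xf = x.astype(float)
    yf = y.astype(float)
    # P(Y <= y | x): CDF of NB(x+1 successes, p1) at y.
    lower = betainc(xf + 1.0, yf + 1.0, p1)
    # P(Y >= y | x) = 1 - CDF(y-1), via the complement identity for y >= 1.
    upper = np.where(yf > 0, betainc(np.maximum(yf, 1.0), xf + 1.0, 1.0 - p1), 1.0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return float(p) if p.ndim == 0 else p


def audic_claverie_pmf(y, x, n1, n2):
    """P(y | x) mass of the conditional tag-count distribution (vectorized)."""
    from scipy.special import gammaln

    y = np.asarray(y, dtype=float)
    r = n2 / n1
    logp = (
        y * np.log(r)
        + gammaln(x + y + 1.0)
        - gammaln(x + 1.0)
        - gammaln(y + 1.0)
        - (x + y + 1.0) * np.log1p(r)
    )
    return np.exp(logp)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def log2_ratio(x, y, n1, n2, pseudocount: float = 0.0):
    """log2 of the normalized count ratio, second library over first.

    ``log2( ((y + c) / n2) / ((x + c) / n1) )`` with pseudocount ``c``.
    A zero count requires a positive pseudocount (the ratio is undefined
    otherwise).  Vectorized over ``x`` and ``y``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if pseudocount == 0 and (np.any(x == 0) or np.any(y == 0)):
        raise ValueError("zero count with zero pseudocount: ratio undefined")
    out = np.log2(((y + pseudocount) / n2) / ((x + pseudocount) / n1))
    return float(out) if out.ndim == 0 else out


def classify(
    fdr: float,
    lfc: float,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> str:
    """DEG status from adjusted p and log2 ratio.

    The FDR cut is strict (``fdr < threshold``); the fold-change cut is
    inclusive (``|lfc| >= threshold``).
    """
    if fdr < fdr_threshold and lfc >= lfc_threshold:
        return "up"
    if fdr < fdr_threshold and lfc <= -lfc_threshold:
        return "down"
    return "ns"


def call_degs(
    table,
    libs,
    comparison: tuple[str, str],
    *,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DEGRecord]:
    """Call differentially expressed genes between two species.

    ``table`` is an ortholog table with per-species counts filled and
    ``libs`` maps species label to its clean :class:`~tagdge.tag_library.TagLibrary`
    (the source of the library totals).  The reported ``log2_ratio`` is
    species A over species B ("A vs B"), so ``up`` means higher expression
    in A.  The FDR cut is strict (<) and the fold-change cut inclusive (>=).
    """
    a, b = comparison
    if a not in libs or b not in libs:
        missing = [s for s in comparison if s not in libs]
        raise KeyError(f"comparison species missing from libraries: {missing}")
    n1 = libs[a].total
    n2 = libs[b].total
    genes = table.genes
    x = np.array([g.count_per_species[a] for g in genes], dtype=np.int64)
    y = np.array([g.count_per_species[b] for g in genes], dtype=np.int64)
    p = np.atleast_1d(exact_tag_test(x, y, n1, n2))
    q = bh_fdr(p)
    # orientation: A over B -> feed (x=count_b, y=count_a) to the B-over-A primitive
    lfc = np.atleast_1d(log2_ratio(y, x, n2, n1, pseudocount=pseudocount))
    records = []
    for i, g in enumerate(genes):
        status = classify(q[i], lfc[i], fdr_threshold, lfc_threshold)
        records.append(
            DEGRecord(
                gene_id=g.gene_id,
                species_a=a,
                species_b=b,
                x=int(x[i]),
                y=int(y[i]),
                n1=n1,
                n2=n2,
                log2_ratio=float(lfc[i]),
                p_value=float(p[i]),
                fdr=float(q[i]),
                status=status,
            )
        )
    return records


def deg_summary(records: Sequence[DEGRecord]) -> dict[str, int]:
    """Up/down/total tallies for one comparison."""
    up = sum(1 for r in records if r.status == "up")
    down = sum(1 for r in records if r.status == "down")
    return {"up": up, "down": down, "total_degs": up + down, "n_genes": len(records)}


def write_deg_table(records: Sequence[DEGRecord], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "gene_id\tspecies_a\tspecies_b\tcount_a\tcount_b\ttpm_a\ttpm_b\t"
            "log2_ratio\tp_value\tfdr\tstatus\n"
        )
        for r in sorted(records, key=lambda r: r.gene_id):
            tpm_a = r.x * 1e6 / r.n1
            tpm_b = r.y * 1e6 / r.n2
            fh.write(
                f"{r.gene_id}\t{r.species_a}\t{r.species_b}\t{r.x}\t{r.y}\t"
                f"{tpm_a:.4f}\t{tpm_b:.4f}\t{r.log2_ratio:.4f}\t"
                f"{r.p_value:.6g}\t{r.fdr:.6g}\t{r.status}\n"
            )
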