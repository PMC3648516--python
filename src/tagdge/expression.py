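"""Expression-level utilities: TPM, expression binning and qPCR comparison."""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite
from pathlib import Path
from typing import Iterable, Sequence

SCALE = 1_000_000
DEFAULT_BIN_EDGES = (5.0, 50.0)
BIN_LABELS = ("low", "mid", "high")


def tpm(count: int, total_clean: int) -> float:
    """Tags per million: ``count * 1e6 / total_clean``.

    ``total_clean`` is the library's total clean-tag mass and must be
    positive.
    """
    if total_clean <= 0:
        raise ValueError("total_clean must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    return count * SCALE / total_clean


def bin_expression(
    tpm_value: float, edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> str:
    """Assign a TPM value to an expression category.

    With the default edges ``(5, 50)`` the categories are ``low`` = [0, 5),
    ``mid`` = [5, 50] and ``high`` = (50, inf), honouring the conventions
    "low is TPM<5" and "high is TPM>50": both edge values land in ``mid``.
    """
    lo, hi = edges
    if lo >= hi:
        raise ValueError("edges must be ascending")
    if tpm_value < 0 or not isfinite(tpm_value):
        raise ValueError(f"TPM must be finite and nonnegative, got {tpm_value}")
    if tpm_value < lo:
        return BIN_LABELS[0]
    if tpm_value > hi:
        return BIN_LABELS[2]
    return BIN_LABELS[1]


def expression_category_fractions(
    tpm_values: Iterable[float], edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> dict[str, float]:
    """Fraction of genes per low/mid/high expression category."""
    counts = dict.fromkeys(BIN_LABELS, 0)
    n = 0
    for value in tpm_values:
        counts[bin_expression(value, edges)] += 1
        n += 1
    if n == 0:
        return dict.fromkeys(BIN_LABELS, 0.0)
    return {label: counts[label] / n for label in BIN_LABELS}


@dataclass(frozen=True)
class QpcrMeasurement:
    """Averaged threshold cycles for one gene in one sample.

    ``ct_reference`` is the endogenous control (beta-actin) CT measured in
    parallel.
    """

    gene_id: str
    species: str
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for value in (self.ct_target, self.ct_reference):
            if not (isfinite(value) and value > 0):
                raise ValueError(f"CT values must be positive and finite, got {value}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def relative_expression_ddct(a: QpcrMeasurement, b: QpcrMeasurement) -> float:
    """Relative expression of a gene in sample *a* versus sample *b*.

    The comparative-CT (2^-ddCT) method: dCT = CT_target - CT_reference per
    sample, ddCT = dCT_a - dCT_b, result 2^-ddCT.  Equals 1 when the
    normalized cycles agree; reciprocal under swapping a and b.
    """
    if a.gene_id != b.gene_id:
        raise ValueError(f"gene mismatch: {a.gene_id!r} vs {b.gene_id!r}")
    return 2.0 ** -(a.delta_ct - b.delta_ct)


def direction_concordance(
    pairs: Iterable[tuple[float, float]]
) -> tuple[int, int]:
    """Count fold-change direction agreement between two assays.

    Each pair is (log2 ratio from tag counting, log2 ratio from qPCR); a
    pair is concordant iff both values are nonzero and share the sign.
    Returns ``(n_concordant, n_total)``.
    """
    n_conc = n_tot = 0
    for dge, qpcr in pairs:
        if not (isfinite(dge) and isfinite(qpcr)):
            raise ValueError("log2 ratios must be finite")
        n_tot += 1
        if dge * qpcr > 0:
            n_conc += 1
    return n_conc, n_tot


def load_qpcr_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read qPCR measurements from TSV: gene_id, species, ct_target, ct_reference."""
    out: list[QpcrMeasurement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 fields")
            if lineno == 1:
                try:
                    float(fields[2])
                except ValueError:
                    continue  # header
            out.append(
                QpcrMeasurement(fields[0], fields[1], float(fields[2]), float(fields[3]))
            )
    return out
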