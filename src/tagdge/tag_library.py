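"""Per-species tag-count libraries: loading, cleaning and abundance summaries.

A tag library is the table of distinct 21-bp tags observed in one species'
DGE sequencing run with their copy numbers.  Cleaning removes malformed tags
and all copy-number-1 tags (singletons are treated as probable sequencing
errors); the post-cleaning total is the library size used as the denominator
of TPM and as the library total of the exact count test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .tag_reference import is_valid_tag

logger = logging.getLogger(__name__)


@dataclass
class TagLibrary:
    """Distinct-tag copy numbers for one species."""

    species_label: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        """Total tag mass (sum of copy numbers)."""
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        """Number of distinct tags."""
        return len(self.counts)

    def tag_set(self) -> set[str]:
        return set(self.counts)


class TagTableError(ValueError):
    """Raised for malformed rows in a tag-count table (strict mode)."""


def _parse_row(line: str, lineno: int) -> tuple[str, int]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 2:
        raise TagTableError(f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}")
    tag, count_str = fields[0].strip().upper(), fields[1].strip()
    try:
        count = int(count_str)
    except ValueError:
        raise TagTableError(f"line {lineno}: non-integer count {count_str!r}") from None
    if count <= 0:
        raise TagTableError(f"line {lineno}: non-positive count {count}")
    if not is_valid_tag(tag):
        raise TagTableError(f"line {lineno}: invalid tag {tag!r} (need CATG-prefixed ACGT 21-mer)")
    return tag, count


def load_tag_counts(
    path: str | Path, species_label: str | None = None, *, strict: bool = True
) -> TagLibrary:
    """Load a raw tag library from a two-column TSV (tag, count).

    A header line is auto-detected by a non-integer second field on the first
    row.  With ``strict=True`` (default) any malformed row raises
    :class:`TagTableError`; otherwise malformed rows are skipped with a log
    message.  Duplicate tags have their counts summed.
    """
    label = species_label if species_label is not None else Path(path).stem
    counts: dict[str, int] = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                tag, count = _parse_row(line, lineno)
            except TagTableError as err:
                if first_data_line:
                    # header line: second field is not an integer
                    first_data_line = False
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) == 2 and not fields[1].strip().lstrip("-").isdigit():
                        continue
                if strict:
                    raise
                logger.warning("%s: skipping %s", path, err)
                continue
            first_data_line = False
            counts[tag] = counts.get(tag, 0) + count
    return TagLibrary(species_label=label, counts=counts)


def clean_tags(raw: TagLibrary) -> TagLibrary:
    """Remove singleton (copy-number-1) and malformed tags; recompute totals.

    Idempotent: cleaning a clean library returns an equal library.
    """
    kept = {
        tag: count
        for tag, count in raw.counts.items()
        if count >= 2 and is_valid_tag(tag)
    }
    return TagLibrary(species_label=raw.species_label, counts=kept)


def tag_abundance_distribution(
    lib: TagLibrary, bin_edges: Sequence[int]
) -> np.ndarray:
    """Distinct-tag counts per copy-number bin.

    Bins are half-open ``[e0, e1), [e1, e2), ..., [e_last, inf)``; every
    distinct tag falls in exactly one bin, so the histogram sums to the
    number of distinct tags.  All copy numbers must be >= the first edge.
    """
    edges = list(bin_edges)
    if not edges:
        raise ValueError("bin_edges must be nonempty")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly ascending")
    counts = np.fromiter(lib.counts.values(), dtype=np.int64, count=lib.distinct)
    if counts.size and counts.min() < edges[0]:
        raise ValueError(
            f"copy number {counts.min()} below first bin edge {edges[0]}"
        )
    hist, _ = np.histogram(counts, bins=edges + [np.inf])
    return hist


def write_tag_counts(lib: TagLibrary, path: str | Path, header: str | None = None) -> None:
    """Write a tag library as a two-column TSV, tags sorted for determinism."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("tag\tcount\n")
        for tag in sorted(lib.counts):
            fh.write(f"{tag}\t{lib.counts[tag]}\n")
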