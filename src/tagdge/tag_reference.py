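"""In-silico tag reference databases for DGE tag profiling.

SAGE-like digital gene expression (DGE) libraries count 21-bp tags that start
at an NlaIII recognition site (``CATG``) and extend 17 nt downstream, the
distance at which MmeI cuts.  To interpret observed tags, each species'
transcriptome assembly is turned into an index of *all possible* CATG+17-nt
tags it contains, mapping every such 21-mer to the transcripts carrying it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import reverse_complement

ANCHOR = "CATG"
TAG_LENGTH = 21
_VALID_CHARS = frozenset("ACGT")


def is_valid_tag(tag: str) -> bool:
    """True iff *tag* is a 21-mer starting with CATG over the A/C/G/T alphabet."""
    return (
        len(tag) == TAG_LENGTH
        and tag.startswith(ANCHOR)
        and set(tag) <= _VALID_CHARS
    )


def iter_tags(sequence: str) -> Iterator[tuple[int, str]]:
    """Yield ``(position, tag)`` for every CATG-anchored 21-mer in *sequence*.

    Every CATG occurrence followed by at least 17 characters yields a
    candidate; candidates containing non-ACGT characters (ambiguity codes)
    are dropped.  Overlapping sites each yield their own tag.
    """
    seq = sequence.upper()
    start = seq.find(ANCHOR)
    while start != -1:
        window = seq[start : start + TAG_LENGTH]
        if len(window) == TAG_LENGTH and set(window) <= _VALID_CHARS:
            yield start, window
        start = seq.find(ANCHOR, start + 1)


@dataclass
class TagReferenceIndex:
    """Map from CATG-anchored 21-mer tags to the transcripts containing them."""

    species_label: str
    tag_to_transcripts: dict[str, set[str]] = field(default_factory=dict)
    n_transcripts: int = 0

    def __len__(self) -> int:
        return len(self.tag_to_transcripts)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tag_to_transcripts

    def lookup(self, tag: str) -> set[str]:
        """Transcripts carrying *tag* (empty set if absent)."""
        return self.tag_to_transcripts.get(tag, set())


def _coerce_records(transcripts) -> Iterator[tuple[str, str]]:
    for rec in transcripts:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            yield str(rec.id), str(rec.seq)
        else:
            name, seq = rec
            yield str(name), str(seq)


def build_tag_index(
    transcripts: Iterable,
    species_label: str,
    *,
    antisense: bool = False,
    three_prime_most: bool = False,
) -> TagReferenceIndex:
    """Build the reference index of all possible CATG+17-nt tags.

    Parameters
    ----------
    transcripts
        Iterable of Bio.SeqRecord objects or ``(identifier, sequence)`` pairs.
        Identifiers must be unique.
    species_label
        Name attached to the index (e.g. ``"MED"``).
    antisense
        Also index tags from the reverse-complement strand.  Off by default:
        DGE tags derive from oriented cDNA.
    three_prime_most
        Classic-SAGE emulation: keep only the 3'-most valid tag per transcript
        (per strand) instead of every site.

    Raises
    ------
    ValueError
        If two transcripts share an identifier.
    """
    index = TagReferenceIndex(species_label=species_label)
    seen: set[str] = set()
    for name, seq in _coerce_records(transcripts):
        if name in seen:
            raise ValueError(f"duplicate transcript identifier: {name!r}")
        seen.add(name)
        strands = [seq] if not antisense else [seq, reverse_complement(seq.upper())]
        for strand_seq in strands:
            tags = [tag for _, tag in iter_tags(strand_seq)]
            if three_prime_most and tags:
                tags = tags[-1:]
            for tag in tags:
                index.tag_to_transcripts.setdefault(tag, set()).add(name)
    index.n_transcripts = len(seen)
    return index


def read_fasta(path: str | Path) -> list:
    """Read a (wrapped or unwrapped) multi-record FASTA file."""
    return list(SeqIO.parse(str(path), "fasta"))


def build_tag_index_from_fasta(path: str | Path, species_label: str, **kwargs) -> TagReferenceIndex:
    return build_tag_index(read_fasta(path), species_label, **kwargs)


def write_index_tsv(index: TagReferenceIndex, path: str | Path) -> None:
    """Serialize the index as TSV: tag, comma-separated sorted transcript IDs."""
    with open(path, "w") as fh:
        fh.write("tag\ttranscripts\n")
        for tag in sorted(index.tag_to_transcripts):
            fh.write(f"{tag}\t{','.join(sorted(index.tag_to_transcripts[tag]))}\n")
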