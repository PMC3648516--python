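"""Cross-species ortholog assignment by exact common-tag mapping.

Tags observed in *all* compared libraries ("common tags") are evidence of an
orthologous transcript.  Each common tag is resolved against the species'
tag-reference databases in a fixed priority order: the first database that
contains the tag decides its fate — a single-transcript hit assigns the tag
to that transcript (gene), a multi-transcript hit marks it ambiguous and it
is discarded, and a tag absent from every database stays unmatched.  Exact
string matching only; no mismatches are allowed.  Tags resolving to the same
transcript merge into one ortholog gene whose per-species expression is the
sum of its member tags' counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .tag_library import TagLibrary
from .tag_reference import TagReferenceIndex


@dataclass
class OrthologGene:
    """One ortholog: a transcript plus the unambiguous common tags hitting it."""

    gene_id: str
    source_db: str
    member_tags: set[str]
    count_per_species: dict[str, int] = field(default_factory=dict)
    tpm_per_species: dict[str, float] = field(default_factory=dict)


@dataclass
class OrthologTable:
    genes: list[OrthologGene]
    unmatched_tags: set[str]
    ambiguous_tags: set[str]
    db_order: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def assigned_tags(self) -> set[str]:
        out: set[str] = set()
        for g in self.genes:
            out |= g.member_tags
        return out


def common_tags(libs: Sequence[TagLibrary]) -> set[str]:
    """Exact intersection of distinct tags across two or more libraries."""
    if len(libs) < 2:
        raise ValueError("need at least two libraries to intersect")
    tags = libs[0].tag_set()
    for lib in libs[1:]:
        tags &= lib.tag_set()
    return tags


def assign_orthologs(
    common: Iterable[str],
    indexes: Sequence[TagReferenceIndex],
    *,
    joint_ambiguity: bool = False,
) -> OrthologTable:
    """Partition common tags into ortholog genes, ambiguous and unmatched sets.

    ``indexes`` is the priority-ordered list of reference databases (the
    first is tried first; only tags it lacks fall through to the next).
    With ``joint_ambiguity=True`` a tag hitting more than one transcript in
    *any* database is discarded before assignment, instead of judging
    ambiguity only in the first database containing the tag.
    """
    if not indexes:
        raise ValueError("empty reference index list")
    genes: dict[tuple[str, str], OrthologGene] = {}
    unmatched: set[str] = set()
    ambiguous: set[str] = set()
    for tag in sorted(set(common)):
        if joint_ambiguity and any(len(idx.lookup(tag)) > 1 for idx in indexes):
            ambiguous.add(tag)
            continue
        for idx in indexes:
            hits = idx.lookup(tag)
            if not hits:
                continue
            if len(hits) > 1:
                ambiguous.add(tag)
            else:
                (gene_id,) = hits
                key = (idx.species_label, gene_id)
                gene = genes.get(key)
                if gene is None:
                    gene = OrthologGene(
                        gene_id=gene_id, source_db=idx.species_label, member_tags=set()
                    )
                    genes[key] = gene
                gene.member_tags.add(tag)
            break
        else:
            unmatched.add(tag)
    gene_list = sorted(genes.values(), key=lambda g: (g.source_db, g.gene_id))
    ids = [g.gene_id for g in gene_list]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"gene identifiers collide across databases: {dup[:5]}")
    return OrthologTable(
        genes=gene_list,
        unmatched_tags=unmatched,
        ambiguous_tags=ambiguous,
        db_order=[idx.species_label for idx in indexes],
    )


def gene_counts(
    table: OrthologTable, libs: Mapping[str, TagLibrary]
) -> OrthologTable:
    """Fill per-species counts and TPM by summing member-tag copy numbers.

    Every species' TPM denominator is that library's total clean-tag mass.
    Common tags exist in every library by construction; a missing species
    raises ``KeyError``.
    """
    from .expression import tpm

    totals = {label: lib.total for label, lib in libs.items()}
    for gene in table.genes:
        for label, lib in libs.items():
            count = sum(lib.counts.get(t, 0) for t in gene.member_tags)
            gene.count_per_species[label] = count
            gene.tpm_per_species[label] = tpm(count, totals[label])
    return table


def write_ortholog_table(
    table: OrthologTable, path: str | Path, header: str | None = None
) -> None:
    species = sorted({s for g in table.genes for s in g.count_per_species})
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        cols = ["gene_id", "source_db", "n_tags", "tags"]
        cols += [f"count_{s}" for s in species] + [f"tpm_{s}" for s in species]
        fh.write("\t".join(cols) + "\n")
        for g in table.genes:
            row = [g.gene_id, g.source_db, str(len(g.member_tags)), ",".join(sorted(g.member_tags))]
            row += [str(g.count_per_species.get(s, 0)) for s in species]
            row += [f"{g.tpm_per_species.get(s, 0.0):.4f}" for s in species]
            fh.write("\t".join(row) + "\n")


def write_tag_set(tags: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tag in sorted(tags):
            fh.write(tag + "\n")
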