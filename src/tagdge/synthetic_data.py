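"""Synthetic three-species DGE study generator with known ground truth.

Emulates the statistical structure the tag pipeline assumes: three divergent
transcriptomes sharing one ortholog per gene (sequences drift from a common
ancestor by per-site substitution), CATG-anchored 21-bp tags, deep tag
libraries sampled multinomially from a ground-truth expression vector with
planted between-species fold changes, and singleton sequencing-error tags
that the cleaning step must remove.  Every artifact is reproducible from the
config seed, and a truth table records per-gene TPM, planted effects and
differential-expression flags so that sensitivity and empirical FDR can be
scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np

from .enrichment import AnnotationMap, TermAnnotation
from .tag_library import TagLibrary
from .tag_reference import ANCHOR, TAG_LENGTH, iter_tags

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_SPECIES = ("MED", "MEAM1", "AsiaII3")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for the generator.

    Defaults emulate a desk-scale version of a three-species whitefly DGE
    study: ~10^6 tags per library (the study itself sequenced ~6x10^6),
    broad log-normal expression, a modest planted-DE fraction with 4-fold
    effects, and a few percent of library mass emitted as singleton error
    tags.
    """

    n_genes: int = 1500
    gene_length: tuple[int, int] = (400, 1200)
    species: tuple[str, ...] = DEFAULT_SPECIES
    divergence: float = 0.02  # expected per-pair substitutions per site
    library_depth: int = 1_000_000
    de_fraction: float = 0.15
    effect_log2: float = 2.0
    singleton_noise_rate: float = 0.05
    expression_sigma: float = 1.5  # log-normal sd of true expression
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.library_depth <= 0:
            raise ValueError("n_genes and library_depth must be positive")
        for p in (self.divergence, self.de_fraction, self.singleton_noise_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.divergence > 0.3:
            raise ValueError("divergence above 0.3 is not supported")
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        lo, hi = self.gene_length
        if lo < TAG_LENGTH or hi < lo:
            raise ValueError("gene_length range invalid")

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        return list(combinations(self.species, 2))


@dataclass
class TruthTable:
    """Ground truth: per-gene true TPM, planted effects and DE flags."""

    gene_ids: list[str]
    species: tuple[str, ...]
    tpm: dict[str, np.ndarray]  # species -> true TPM per gene (sums to 1e6)
    multiplier_log2: dict[str, np.ndarray]  # species -> planted log2 multiplier
    field_names = ("gene_ids", "species", "tpm", "multiplier_log2")

    def planted_log2(self, a: str, b: str) -> np.ndarray:
        """Planted log2 effect of each gene for comparison a-over-b."""
        return self.multiplier_log2[a] - self.multiplier_log2[b]

    def is_de(self, a: str, b: str) -> np.ndarray:
        return self.planted_log2(a, b) != 0.0

    def true_log2(self, a: str, b: str) -> np.ndarray:
        """Realized log2 TPM ratio a-over-b (renormalization included)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.tpm[a] / self.tpm[b])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cols = ["gene_id"]
            cols += [f"tpm_{s}" for s in self.species]
            cols += [f"log2mult_{s}" for s in self.species]
            fh.write("\t".join(cols) + "\n")
            for i, gid in enumerate(self.gene_ids):
                row = [gid]
                row += [f"{self.tpm[s][i]:.6f}" for s in self.species]
                row += [f"{self.multiplier_log2[s][i]:g}" for s in self.species]
                fh.write("\t".join(row) + "\n")


def transcript_id(gene_id: str, species: str) -> str:
    return f"{gene_id}.{species}"


def gene_of_transcript(tid: str) -> str:
    """Invert :func:`transcript_id` (gene ids contain no dot)."""
    return tid.split(".", 1)[0]


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


_ANCHOR_CODES = np.array([1, 0, 3, 2], dtype=np.uint8)  # C A T G


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(codes.size) < rate
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        out[mask] = (out[mask] + shift) % 4
    return out


def _ensure_taggable(codes: np.ndarray, anchor_pos: int) -> np.ndarray:
    """Re-inject a CATG site at ``anchor_pos`` if the sequence lost all tags."""
    if any(True for _ in iter_tags(_decode(codes))):
        return codes
    out = codes.copy()
    out[anchor_pos : anchor_pos + 4] = _ANCHOR_CODES
    return out


def simulate_transcriptomes(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[tuple[str, str]]], dict[str, dict[str, str]]]:
    """Generate one transcript per gene per species plus the orthology map.

    Ancestral sequences carry at least one CATG site with >=17 nt downstream;
    each species copy substitutes sites independently at half the configured
    pairwise divergence, so substitutions fall inside tag windows naturally
    and some genes lose cross-species common tags.  A species copy that loses
    every valid tag has its anchor site restored so every transcript stays
    taggable.

    Returns ``(transcriptomes, orthology)`` where ``transcriptomes`` maps
    species to a list of ``(transcript_id, sequence)`` and ``orthology`` maps
    gene id to its per-species transcript ids.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    per_species_rate = cfg.divergence / 2.0
    lo, hi = cfg.gene_length
    transcriptomes: dict[str, list[tuple[str, str]]] = {s: [] for s in cfg.species}
    orthology: dict[str, dict[str, str]] = {}
    for i in range(cfg.n_genes):
        gid = f"g{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, length)
        anchor_pos = int(rng.integers(0, length - TAG_LENGTH + 1))
        ancestor[anchor_pos : anchor_pos + 4] = _ANCHOR_CODES
        orthology[gid] = {}
        for sp in cfg.species:
            codes = _mutate(rng, ancestor, per_species_rate)
            codes = _ensure_taggable(codes, anchor_pos)
            tid = transcript_id(gid, sp)
            transcriptomes[sp].append((tid, _decode(codes)))
            orthology[gid][sp] = tid
    return transcriptomes, orthology


def make_truth(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> TruthTable:
    """Draw true expression and plant between-species fold changes.

    Base expression is log-normal across genes.  A ``de_fraction`` of genes
    each get a single perturbed species (chosen uniformly, sign uniform) whose
    expression is multiplied by ``2**effect_log2``; the per-species vectors
    are then renormalized to TPM (sum 1e6).  One perturbed species makes the
    gene differentially expressed in the two comparisons involving it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    base = rng.lognormal(mean=0.0, sigma=cfg.expression_sigma, size=n)
    mult_log2 = {s: np.zeros(n) for s in cfg.species}
    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    which_species = rng.integers(0, len(cfg.species), size=n_de)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    for j, g in enumerate(de_idx):
        sp = cfg.species[which_species[j]]
        mult_log2[sp][g] = signs[j] * cfg.effect_log2
    tpm = {}
    for s in cfg.species:
        expr = base * 2.0 ** mult_log2[s]
        tpm[s] = expr / expr.sum() * 1e6
    return TruthTable(
        gene_ids=gene_ids, species=cfg.species, tpm=tpm, multiplier_log2=mult_log2
    )


def _transcript_tags(seq: str) -> list[str]:
    return sorted({tag for _, tag in iter_tags(seq)})


def _random_error_tag(rng: np.random.Generator) -> str:
    return ANCHOR + _decode(rng.integers(0, 4, size=TAG_LENGTH - 4, dtype=np.uint8))


def _reference_sites(
    transcriptomes: Mapping[str, list[tuple[str, str]]],
    gene_ids: list[str],
    species: tuple[str, ...],
) -> dict[str, list[int]]:
    """Homologous restriction-site positions per gene.

    Species copies contain no indels, so a tag start position is comparable
    across species; the reference site set of a gene is the union over
    species of positions yielding a valid tag.
    """
    seq_of = {
        sp: {gene_of_transcript(tid): seq for tid, seq in transcriptomes[sp]}
        for sp in species
    }
    sites: dict[str, set[int]] = {g: set() for g in gene_ids}
    for sp in species:
        for gid in gene_ids:
            for pos, _ in iter_tags(seq_of[sp][gid]):
                sites[gid].add(pos)
    return {g: sorted(ps) for g, ps in sites.items()}


def _valid_window(seq: str, pos: int) -> str | None:
    window = seq[pos : pos + TAG_LENGTH]
    from .tag_reference import is_valid_tag

    return window if is_valid_tag(window) else None


def simulate_tag_libraries(
    transcriptomes: Mapping[str, list[tuple[str, str]]],
    truth: TruthTable,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, TagLibrary]:
    """Sample raw per-species tag libraries from the truth expression.

    Tag mass is allocated per homologous restriction site: every reference
    site of a gene (a position valid in at least one species) carries an
    equal share ``TPM_gene / n_sites`` of the gene's expression, identical
    in every species.  A species samples only its intact sites, so
    homologous tags have the same expected abundance everywhere while sites
    destroyed by divergence lose their share (their tags drop out of the
    common-tag set).  Per species, ``library_depth * (1 -
    singleton_noise_rate)`` tags are drawn multinomially over intact sites;
    the remaining mass is emitted as unique random CATG 21-mers with copy
    number 1 (sequencing-error surrogates removed by cleaning).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sites = _reference_sites(transcriptomes, truth.gene_ids, cfg.species)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    libraries: dict[str, TagLibrary] = {}
    for sp in cfg.species:
        seq_of = {gene_of_transcript(tid): seq for tid, seq in transcriptomes[sp]}
        item_tags: list[str] = []
        item_weights: list[float] = []
        for gid in truth.gene_ids:
            ref = sites[gid]
            if not ref:
                continue
            share = truth.tpm[sp][gene_index[gid]] / len(ref)
            for pos in ref:
                tag = _valid_window(seq_of[gid], pos)
                if tag is not None:
                    item_tags.append(tag)
                    item_weights.append(share)
        weights = np.asarray(item_weights)
        probs = weights / weights.sum()
        n_noise = int(round(cfg.library_depth * cfg.singleton_noise_rate))
        n_signal = cfg.library_depth - n_noise
        draws = rng.multinomial(n_signal, probs)
        counts: dict[str, int] = {}
        for tag, c in zip(item_tags, draws):
            if c:
                counts[tag] = counts.get(tag, 0) + int(c)
        injected = 0
        while injected < n_noise:
            tag = _random_error_tag(rng)
            if tag in counts:
                continue
            counts[tag] = 1
            injected += 1
        libraries[sp] = TagLibrary(species_label=sp, counts=counts)
    return libraries


def make_annotation_map(
    gene_ids: list[str],
    rng: np.random.Generator,
    *,
    n_terms: int = 60,
    size_range: tuple[int, int] = (3, 80),
    category: str = "synthetic_function",
    planted: Mapping[str, set[str]] | None = None,
) -> AnnotationMap:
    """Randomly group genes into terms of sizes 3-80 (GMT-style map).

    ``planted`` optionally adds terms with prescribed gene sets (e.g. terms
    deliberately packed with DE genes, for enrichment power checks).
    """
    lo, hi = size_range
    out: AnnotationMap = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(gene_ids))
        genes = set(rng.choice(gene_ids, size=size, replace=False).tolist())
        term_id = f"TERM:{t:04d}"
        out[term_id] = TermAnnotation(
            term_id=term_id,
            description=f"synthetic term {t}",
            category=category,
            genes=genes,
        )
    if planted:
        for term_id, genes in planted.items():
            out[term_id] = TermAnnotation(
                term_id=term_id,
                description="planted term",
                category=category,
                genes=set(genes),
            )
    return out


def simulate_qpcr_panel(
    truth: TruthTable,
    comparison: tuple[str, str],
    gene_indices: np.ndarray,
    rng: np.random.Generator,
    *,
    ct_noise_sd: float = 0.25,
    ct_reference: float = 15.0,
) -> list[tuple]:
    """Synthesize qPCR CT measurements whose ddCT encodes the true ratio.

    Returns a list of ``(QpcrMeasurement_a, QpcrMeasurement_b)`` pairs with
    Gaussian CT noise, for concordance checks against tag-count ratios.
    """
    from .expression import QpcrMeasurement

    a, b = comparison
    pairs = []
    for i in gene_indices:
        gid = truth.gene_ids[int(i)]
        log2_ratio = float(truth.true_log2(a, b)[int(i)])
        # dCT difference of -log2_ratio makes 2^-ddCT equal the true ratio
        ct_a = 25.0 - log2_ratio / 2.0 + rng.normal(0.0, ct_noise_sd)
        ct_b = 25.0 + log2_ratio / 2.0 + rng.normal(0.0, ct_noise_sd)
        ref_a = ct_reference + rng.normal(0.0, ct_noise_sd)
        ref_b = ct_reference + rng.normal(0.0, ct_noise_sd)
        pairs.append(
            (
                QpcrMeasurement(gid, a, ct_a, ref_a),
                QpcrMeasurement(gid, b, ct_b, ref_b),
            )
        )
    return pairs


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulated study produces."""

    config: SyntheticConfig
    transcriptomes: dict[str, list[tuple[str, str]]]
    orthology: dict[str, dict[str, str]]
    truth: TruthTable
    libraries: dict[str, TagLibrary]
    annotation: AnnotationMap


def simulate_study(cfg: SyntheticConfig) -> SyntheticStudy:
    """Run the full generator with independent substreams per artifact."""
    seq = np.random.SeedSequence(cfg.seed)
    rng_tx, rng_truth, rng_libs, rng_annot = (
        np.random.default_rng(s) for s in seq.spawn(4)
    )
    transcriptomes, orthology = simulate_transcriptomes(cfg, rng_tx)
    truth = make_truth(cfg, rng_truth)
    libraries = simulate_tag_libraries(transcriptomes, truth, cfg, rng_libs)
    annotation = make_annotation_map(truth.gene_ids, rng_annot)
    return SyntheticStudy(
        config=cfg,
        transcriptomes=transcriptomes,
        orthology=orthology,
        truth=truth,
        libraries=libraries,
        annotation=annotation,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, tag TSVs, annotation GMT and truth TSV for a study."""
    from .tag_library import write_tag_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    seed_note = f"seed={study.config.seed}"
    for sp in study.config.species:
        fasta = outdir / f"{sp}.transcripts.fasta"
        with open(fasta, "w") as fh:
            for tid, seq in study.transcriptomes[sp]:
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths[f"fasta_{sp}"] = fasta
        tsv = outdir / f"{sp}.tags.tsv"
        write_tag_counts(study.libraries[sp], tsv, header=seed_note)
        paths[f"tags_{sp}"] = tsv
    gmt = outdir / "annotation.gmt.tsv"
    with open(gmt, "w") as fh:
        for term_id in sorted(study.annotation):
            t = study.annotation[term_id]
            fh.write("\t".join([t.term_id, t.description] + sorted(t.genes)) + "\n")
    paths["annotation"] = gmt
    truth_tsv = outdir / "truth.tsv"
    study.truth.write_tsv(truth_tsv)
    paths["truth"] = truth_tsv
    return paths
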