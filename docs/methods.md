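# Methods

## Tag model

A DGE tag is the 21-mer beginning at an NlaIII recognition site (`CATG`)
and extending 17 nt downstream, the distance at which MmeI cuts. The
reference index of a transcriptome contains *every* such 21-mer — each
`CATG` occurrence with at least 17 following nucleotides yields a tag, so
overlapping sites each contribute and a transcript can carry several tags.
Candidate windows containing IUPAC ambiguity codes invalidate only that tag,
never the transcript. Indexing is sense-strand only by default, since DGE
tags derive from oriented cDNA; an `antisense` flag indexes both strands,
and a `three_prime_most` flag emulates classic SAGE (one tag per transcript
per strand). Matching everywhere is exact string equality — no mismatches,
so a single substitution inside a tag window removes that tag from
consideration rather than mis-assigning it.

## Library cleaning

The pipeline starts from tag-count tables (tag, copy number), the form in
which DGE libraries are deposited; read-level adaptor/quality processing is
upstream of this artifact and out of scope. Cleaning removes malformed rows
and every tag with copy number 1: a singleton is more likely a sequencing
error than a real transcript observation, and the exact test downstream is
anyway powerless at count 1. Cleaning is idempotent, and the clean totals
are the library sizes *n₁*, *n₂* used by the exact test and the TPM
denominator. (A "mapped-tags" TPM denominator can be substituted via the
ortholog table if preferred; clean-total is the default because "per million
tags" refers to the library, not to the mapped subset.)

## Common-tag orthology

Distinct clean tags present in all libraries are intersected, and each
common tag is resolved against the species reference indexes in a fixed
priority order (default: the configured species order). The first database
containing the tag decides its fate:

- exactly one transcript → the tag is assigned to that transcript (gene);
- multiple transcripts → the tag is discarded as ambiguous, with no
  fall-through to later databases;
- absent from every database → unmatched.

The three outcomes partition the common-tag set, an invariant asserted in
the tests. Tags resolving to the same transcript merge into one ortholog
gene whose per-species count is the sum over its member tags; gene identity
across databases is by representative hit only (no sequence-similarity
joining — the references are unigene-style assemblies). Judging ambiguity
in the first containing database is the default because a tag that is unique
where it is first seen has an unambiguous best interpretation; a stricter
`joint_ambiguity` mode discards tags multi-mapping in *any* database before
assignment, for users who prefer ambiguity to be a global property.

## Differential expression

With a single library per species there are no replicates, so dispersion
models are not identifiable; the appropriate test is the exact conditional
one. Given count *x* in a library of *n₁* total tags, the count *y* in a
library of *n₂* tags follows

    P(y | x) = (n₂/n₁)^y (x+y)! / ( x! y! (1+n₂/n₁)^(x+y+1) ),

the negative-binomial distribution with x+1 successes and success
probability n₁/(n₁+n₂). Tails are evaluated through the regularized
incomplete beta function (the NB CDF identity), which is exact, stable at
counts of 10⁴–10⁵ and O(1) per gene; the test suite verifies agreement with
direct term-by-term summation of the mass to 10⁻¹⁰ over the full count grid
up to 200 and checks that the mass sums to 1 to 10⁻⁹.

The two-sided p-value doubles the smaller of P(Y ≤ y) and P(Y ≥ y) (both
tails include the observed count) and caps at 1. Two consequences worth
knowing: at x = y and n₁ = n₂ the lower tail is exactly ½, so p = 1; and
the construction is *not* exactly symmetric under swapping the conditioning
library — (x, n₁) ↔ (y, n₂) can change p by tens of percent at small
counts, a known property of conditional two-sided tests. Conclusions at the
stringent threshold used here are insensitive to the orientation; the
pipeline always conditions on the first-named species of a comparison.

Multiplicity is handled by Benjamini–Hochberg step-up (delegated to
statsmodels and oracle-checked against a naive implementation). The DEG
rule is FDR < 0.001 (strict) and |log₂ ratio| ≥ 1 (inclusive), the ratio
being normalized count of the first species over the second, with a
pseudocount of 1 tag added to both counts before normalization whenever
needed (zero counts otherwise have an undefined ratio; 1 tag is the
smallest observable unit and keeps extreme fold changes finite). The
pseudocount is configurable and recorded in output headers.

## Enrichment

For a DEG set, N and n count universe genes and DEG genes carrying at least
one annotation (per category when categories are present — GO namespaces
are tested separately, since mixing namespaces would inflate N with genes
that could never be drawn for the term). A term annotating M universe genes
and m DEGs gets the hypergeometric upper tail p = P(X ≥ m) (the sum running
over i < m is subtracted from 1). Terms with M < 5 are filtered before
testing — tiny terms produce unstable, uninterpretable p-values — and
p ≤ 0.05 (inclusive) flags enrichment. No multiplicity correction is
applied to the enrichment p-values themselves, matching common practice for
these screening tables; a BH-adjusted column is emitted alongside for users
who want it. Output is sorted by ascending p with term-id tie-breaking so
reruns are byte-identical.

## qPCR comparison

Relative expression by the comparative-CT method: ΔCT = CT_target −
CT_reference per sample (reference gene β-actin), ΔΔCT across samples,
relative expression 2^−ΔΔCT. Direction concordance between tag-based and
qPCR log₂ ratios counts a pair concordant iff both are nonzero with equal
sign; zeros count as discordant, which is the conservative choice.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes:

- **Transcriptomes.** One ancestor per gene (uniform random sequence,
  length uniform in 400–1200 nt, one guaranteed `CATG` site with ≥17 nt
  downstream); each species copy substitutes each site independently at
  divergence/2 per site, giving the configured expected pairwise divergence
  (default 0.02 — congeneric-cryptic-species scale for transcribed
  sequence). Substitutions fall inside tag windows naturally, so a fraction
  of genes predicted by (1 − d/2)^(3·21) per window lose their cross-species
  common tags and exercise the fallback mapping; a species copy that loses
  every tag has its anchor site restored so all transcripts stay taggable.
- **Expression truth.** Gene expression is log-normal (σ = 1.5, a typical
  breadth for bulk transcriptomes that still leaves >95 % of genes
  detectable at the default depth). A `de_fraction` (default 0.15) of genes
  each get one species (uniform) perturbed by ±`effect_log2` (default 2);
  per-species vectors are renormalized to TPM summing to 10⁶, so realized
  ratios include the small compositional shift that renormalization
  creates, exactly as in real libraries.
- **Tag sampling.** Tag mass is allocated per homologous restriction site:
  every reference site of a gene (a position valid in ≥1 species — species
  copies have no indels, so positions are comparable) carries an equal
  share TPM/n_sites of the gene's expression, *identical in every species*.
  A species samples multinomially over its intact sites only. This makes
  homologous tags unbiased expression estimators across species — the
  assumption the common-tag method itself rests on — while sites destroyed
  by divergence genuinely lose their mass. Library depth defaults to 10⁶
  tags (the motivating study sequenced ~6×10⁶; 10⁶ keeps simulations in
  seconds while leaving median per-gene counts in the hundreds, deep enough
  for the planted 4-fold effects to be comfortably testable).
- **Noise.** `singleton_noise_rate` (default 0.05) of library mass is
  emitted as unique random `CATG` 21-mers with copy number 1 — the error
  model the singleton filter is designed for. No quality scores, indels or
  paralog families are modelled.
- **Annotations.** Terms of size 3–80 sampled uniformly from the gene set,
  optionally with planted DE-packed terms for power checks.

Randomness is a single seed expanded into independent substreams per
artifact (sequences, truth, libraries, annotations); a fixed seed gives
byte-identical outputs, including file serializations.

What passing on synthetic data does *not* show: robustness to paralogous
tag collisions (real assemblies share tags between gene-family members far
more often than random sequence does), to assembly fragmentation (one gene
split over several unigenes), or to non-uniform tag formation along the
transcript (3′ bias of the protocol). These affect the orthology step more
than the statistics.

## Problem sizes and numerical choices

End-to-end checks run at 1,000–1,500 genes and 10⁶ tags per library — at
these sizes the full pipeline completes in a few seconds while per-gene
counts match the statistical regime of the motivating study. Oracle
comparisons use exact rational arithmetic (hypergeometric, N ≤ 25), direct
mass summation (exact test, counts ≤ 200, tolerance 10⁻¹⁰), and naive
reimplementations (BH step-up, substring scans). Expression bins follow
[0,5), [5,50], (50,∞) so that "TPM < 5" and "TPM > 50" both read literally;
values exactly at an edge land in the middle bin. Degenerate inputs have
defined behaviour: empty transcript sets and empty libraries are legal and
propagate as empty results; zero library totals, non-permutation database
orders, and DEG genes outside the enrichment universe raise errors naming
the offending value.

## Known limitations

- One library per species: between-colony biological variation is
  unidentifiable, and the exact test's p-values quantify sampling error
  only. Calls are "differences between these libraries", not population
  claims.
- Exact matching means a SNP in a tag window silently removes the gene from
  the common-tag set; divergence therefore biases the ortholog set toward
  conserved 21-mers.
- The two-sided p depends on which library is conditioned on (see above).
- Enrichment p-values are screening statistics without cross-term
  correction; treat the table order, not the absolute values, as the
  signal.
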