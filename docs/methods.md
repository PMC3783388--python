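# Methods

This note records the models, numerical choices and limitations behind
`yrscan`. It documents how results are computed, not what they are: every
number the package reports is produced at run time by the code described
here.

## Element model

A YR retrotransposon is modeled as a *core* — the genomic envelope of
merged, strand-consistent protein-domain hits — plus optional
terminal-repeat evidence that extends the element to its *outer
interval*. Two architectures are recognized:

* **DIRS**: inverted terminal repeats (the left terminus equals the
  reverse complement of the right), an optional internal complementary
  region (ICR), and a coding core of RT, RH, MT and YR.
* **Ngaro**: split direct repeats ordered A1–core–B1–A2–B2, a coding core
  of RT, RH and YR (never MT), with the YR ORF optionally shifted +1
  relative to RT–RH.

Decayed copies are first-class citizens: stops translate to `*` and stay
in the peptide (scored −8 per aligned stop so a single interruption does
not split a domain), codons containing N translate to `X` (scored 0, so
ambiguity neither creates nor destroys hits), and an element is emitted
as long as one diagnostic domain is detectable.

## Domain scanning

Scanning profiles are position score matrices. The packaged set scores
column *i* of a consensus peptide as the BLOSUM62 row of the consensus
residue; profiles built from member sets (``build_profile_from_members``)
use per-column log-odds `ln((count_a + 1) / ((n + 1)·bg_a))` with a
uniform background of 1/20, dropping columns that are more than half
gaps. HMMER3 ASCII profiles are imported by converting match-state
emissions to log-odds against the uniform background; insert states are
not modeled — gaps use two per-profile affine constants (open −11,
extend −1). This is deliberate: the scanner needs profile *scanning*, not
full plan7 decoding, and its fidelity is tested against a full-matrix
dynamic-programming oracle rather than against HMMER bit scores.

The local alignment is exact affine-gap Smith–Waterman, vectorized along
the peptide axis (the insertion state reduces to a running-maximum scan
per profile row, so no per-cell Python loop exists). Hit extraction is
greedy from the best score with aligned-region masking; candidate regions
found by the forward pass are re-solved in windows whose size is derived
from an upper bound on alignment extent, so windowing never changes the
result. All packaged profile scores are integers, making the arithmetic
exact in float64.

**Significance.** The paper-style tool E-values are replaced by a
self-contained empirical null: the maximum profile score over
composition-preserving shuffles of the scanned peptide, with
`p = (1 + #{null ≥ score}) / (n_shuffles + 1)`. The pipeline default is
p ≤ 0.01 at 199 shuffles. Two engineering choices keep this affordable at
genome scale, both recorded in `RunConfig`: the null for a
(record, profile) pair is computed once on a 2,000-residue
composition-preserving subsample of the longest frame peptide and shared
by all hits of that pair, and the shuffles are scored in one batched
forward pass (shuffles concatenated with separator runs longer than any
profitable gap, so per-shuffle maxima are provably identical to scoring
them separately). The per-profile reporting threshold — a quarter of the
consensus self-score, clamped at 40 — sits far above the shuffled
background of megabase-scale scans while keeping half-length decayed
fragments detectable; it, not the p-value, is what controls false
positives on element-free sequence (the acceptance run checks zero
detections on an element-free megabase).

**Merging.** Same-strand hits within 3,000 nt chain into cores (single
linkage). The gap default reflects the few-kb span of a three-to-four
domain core; it is configurable. Within a core, same-class hits with
>50% reciprocal overlap keep only the best score (ties: longer alignment,
then leftmost). Cores whose retained hits span more than one frame are
flagged `has_frameshift`. The RT/RH parity report counts RT- and
RH-bearing cores and flags RH-without-RT cores as candidates for profile
insensitivity; it never deletes elements, and rebuilding a custom RT
profile from clustered representatives is left to the user
(`build_profile_from_members`).

## Repeat detection

Repeats are modeled as **ungapped** copies. Candidate diagonals come from
exact k-mer seeds (k = 13); on each seeded diagonal the optimal interval
— maximizing `matches − 3·mismatches` subject to length ≥ 20 and identity
≥ 0.80 — is found exactly by an offline sweep (ends processed in
increasing order of the identity-feasibility potential while starts are
activated into a position-indexed segment tree, making each query a
range-minimum). Identity feasibility is compared in scaled-integer
arithmetic, so there are no float boundary effects, and on seeded
diagonals the result provably equals exhaustive substring-pair
enumeration — the acceptance suite checks this against an
all-pairs oracle.

Two scoring choices matter for boundary precision. A pure match count
keeps growing through random flank (a quarter of random positions match),
so the objective charges mismatches −3: extension into flank then has
negative drift and the optimum sits at the copy edges. Score ties are
broken toward the *shortest* interval, because an equal-score longer
interval only adds break-even flank noise; chance matches directly
adjacent to a copy can still extend a boundary by a few bases, which is
why recovery is specified within ±5 nt rather than exactly. k = 13 was
chosen so that i.i.d. 2 kb flanks yield a qualifying spurious pair in
under 5% of trials (at k = 11 a chance seed extends to a qualifying
20 nt/80% window roughly 17% of the time); planted repeats at ≥80%
pairwise identity still seed reliably.

The ITR search compares the left flank with the reverse complement of the
right flank (flank 2,000 nt); the split-direct search pairs the left
flank with a 2×flank downstream window (A pair) and the downstream window
with itself (B pair, copies non-overlapping by construction), keeps the
best A and B candidates, and requires start(B1) < start(A2) < start(B2).
Repeat copies may reach at most 30 nt into the core envelope, preventing
coding sequence from doubling as "repeat". Minus-strand cores are handled
by running the plus-strand logic on the reverse complement of the region
and mapping coordinates back. The ICR search (min length 15) is evidence
only; no classification decision reads it.

## Classification

Superfamily uses a decision ladder ordered by diagnostic value:

1. MT domain present → DIRS (MT is unique to DIRS);
2. ITR found → DIRS;
3. split direct repeats found → Ngaro;
4. otherwise a vote by the affinity tags (DIRS-specific / Ngaro-like /
   generic, generic abstains) of the best hit per domain class;
5. ties, all-generic, or contradictions (MT together with split direct
   repeats) → `undetermined`, with the full evidence trail recorded.

Completeness: `complete` requires the superfamily's full domain set,
every hit covering ≥ 0.8 of its profile, and the full repeat structure;
`remnant` is every hit under 0.5 coverage or a single surviving domain
class; everything else is `truncated`. The 0.8/0.5 cutoffs are declared
package defaults — the completeness classes are qualitative in origin and
carry no published thresholds. An `undetermined` element can never be
`complete` (it has no architecture to complete).

Clades (Ngaro 1–4) and DIRS lineages (A/B) are assigned by summing, over
the available RT/RH/YR hit peptides, the best local alignment score of
per-clade motif profiles; the winner needs a relative margin
`(best − second)/best ≥ 0.05`, otherwise `unassigned`. The margin guards
against shared motifs between clades; the packaged motifs are synthetic
stand-ins (see below), so clade assignment quality is validated on
synthetic constructions only.

## Families, similarity graph, tree

Family clustering is greedy and incremental: concatenated best-hit
peptides (RT, RH, YR, MT order) are sorted by length descending (ties:
lexicographic id) and each joins the first representative with global
identity ≥ 0.60, else founds a cluster. Identity is defined as identical
positions in a minimum-edit-distance global alignment divided by the
shorter length (the CD-HIT convention for the denominator; the alignment
itself is computed by edlib). A shared-word lower bound (word length 4)
pre-filters pairs; it is a true bound, so filtering never changes the
partition — the acceptance suite compares against an unfiltered
all-pairs oracle.

The similarity graph aligns all representative pairs locally (BLOSUM62,
−11/−1) and converts scores to p-values by a Gumbel fit
(method of moments) to a 50-shuffle null of the shorter sequence; edges
keep p ≤ 1e-06, and group identity is connected-component membership.
The 2D force-directed layout (edge attraction ∝ −log10 p, inverse-square
repulsion, decaying step) is for visualization only.

The representative tree intentionally replaces maximum-likelihood
inference with a distance method: per-domain progressive alignments
(k-mer-distance UPGMA guide tree; profile–profile global alignment with
BLOSUM62 expected scores) are trimmed column-wise (gap fraction > 0.05
removed — a gap-fraction approximation of strict conservation-based
trimming), concatenated with all-gap padding for missing domains (so
incomplete elements stay in the tree), converted to Poisson-corrected
distances over mutually ungapped columns, and summarized by Saitou–Nei
neighbor joining (Q criterion, smallest-index tie-break, negative branch
lengths clamped to zero with a warning). MT is excluded from the tree
because it exists only in DIRS and would encode superfamily membership
directly. Outgroup rooting places the root at the midpoint of the branch
separating a monophyletic outgroup and errors otherwise. The claims this
stage supports — DIRS/Ngaro separation, clade structure — are testable at
distance level; NJ's exact recovery on additive matrices is verified by
simulation and cross-checked against scikit-bio's implementation.

## Synthetic data: what it emulates and what it does not

The generator plants elements following the two architectures with
seeded reverse-translation of packaged domain peptides, exact repeat
copies, optional +1 YR frameshift, optional ICR, and decay applied in a
fixed order: substitutions (uniform per-base rate μ) → truncation (a
fraction removed from one end) → whole-domain deletion. Truth records
carry post-decay coordinates, surviving-domain peptides, and a
"retained" flag per domain (≥60% of its length surviving — the
denominator used for recall on degraded genomes). Background is i.i.d.
at a configurable GC (default 0.45, a typical fungal value); insertions
are separated by ≥4,000 nt of background so that distinct insertions
stay distinct under hit chaining, or nested inside an earlier element
with configurable probability.

The packaged seeds are synthetic: a random generic consensus per domain,
superfamily variants at ~70% identity to it, and clade/lineage variants
carrying a 20-residue diagnostic motif. They are internally consistent
with the packaged scanning profiles, which is exactly what the offline
tests require — and no more. Passing tests therefore demonstrate the
machinery (detection, boundary resolution, classification logic,
clustering, tree separation) under controlled decay; they do not
demonstrate sensitivity of any particular curated profile on real
genomes, realistic fungal base composition (isochores, repeat-induced
point mutation), insertion-age structure, or the behavior of
Pfam/CDD-scale profile libraries. Real runs should supply curated HMMER3
profiles.

Default study conditions used by the acceptance computations: a clean
genome with 20 elements (10 DIRS across both lineages, 10 Ngaro across
all four clades, random strands, every other Ngaro YR frameshifted) in
~0.5 Mb; a degraded genome with 200 elements at μ = 0.10 and 30%
truncation probability (truncation fraction uniform on 0.1–0.6) in
~1.4 Mb; and 1 Mb of element-free background. These sizes exercise every
code path at full method fidelity; nothing in the method depends on
genome size beyond linear cost.

## Numerical and determinism notes

* All stochastic steps (shuffle nulls, graph p-values, layout,
  simulation) take explicit seeds; the pipeline derives stage seeds from
  one master seed, and reruns are byte-identical apart from timestamps.
* Score arithmetic in the scanner is integer-valued float64 (exact);
  repeat identity constraints use per-mille integer arithmetic; identity
  thresholds in clustering are compared with a 1e-9 tolerance.
* Tie-breaks are fixed everywhere (documented per module) so that equal
  inputs yield equal outputs across platforms.
* Degenerate inputs: records shorter than 3 nt translate to empty
  peptides with a warning; a peptide pair with no mutually ungapped
  columns, or a Poisson distance at p = 1, is an error rather than a
  silent infinity; an all-gap trimmed alignment is an error.

## Known limitations

* Repeat copies are modeled ungapped; indel-containing repeat copies are
  found only insofar as a qualifying ungapped sub-interval exists.
* The split-direct search keeps one best A and one best B candidate per
  search; pathological layouts where the globally best combination
  requires a suboptimal per-pair candidate can be missed.
* Only the best-scoring repeat architecture is attached per core; an
  element genuinely carrying both signals resolves by score, with
  conflicts surfacing through the MT/split-direct contradiction rule.
* The similarity graph is quadratic in the number of representatives; the
  pipeline therefore builds it on family representatives, not all copies.
* Nested insertions are supported by the generator, but the annotator
  merges same-strand nested copies into one core when their hits chain
  within the merge gap; opposite-strand nesting resolves into separate
  elements.
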