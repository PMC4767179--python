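# Methods

## Distances and gap policies

All distances are uncorrected *p*-distances: mismatches divided by compared
sites between two equal-length aligned rows. Two gap policies are
implemented and recorded in every `DistanceMatrix`: *pairwise deletion*
(default; columns with a gap or ambiguity code in either row of a pair are
skipped for that pair) and *complete deletion* (columns with a gap or
ambiguity in any row are removed once for the whole alignment). Ambiguity
codes (N and partial IUPAC codes) are excluded from compared sites rather
than counted as mismatches. Percent identity uses the same site-exclusion
convention (plus terminal-gap trimming), so identity and *p*-distance are
exact complements on the compared sites; an `all_columns` policy (gap
columns count as mismatches) is available for comparison with tools that
report alignment-wide identity. Under pairwise deletion *p* is not a
metric; only symmetry and the [0, 1] range are guaranteed.

## Barcode gap and thresholds

Per species: `max_intra` (undefined for singletons, which are flagged and
treated as 0 in the gap predicate) and `min_inter` (minimum distance from
any member to any other species' member). A marker's threshold is the
minimum of `min_inter` over the full reference sampling — equivalently the
minimum over per-genus thresholds — and the species-level comparison is
strict (`d < t`): a query exactly at the threshold is *not* species-level.
Singletons contribute `min_inter` to threshold derivation because real
reference samplings contain singletons. Genus-restricted thresholds
(always ≥ the pooled threshold) implement the rescue rule for queries whose
hit falls in a well-sampled genus; generalising what was a one-strain,
ad-hoc decision in practice, the fallback is applied only when explicitly
enabled and only to hits whose genus has a supplied genus threshold.

The bridge from database identity reports to distances is
`d = (100 − identity)/100`. Printed identities are integers, so this is a
≤ 0.005 approximation of the underlying alignment distance; worked-example
comparisons use half-up integer rounding for percentages, and reported
distances use three decimals (comma and point decimal separators are both
parsed).

## Decision roadmap

Markers are tried in priority order (nuITS2 → nuITS1 → *rbc*L). For each
marker: (a) exhaustive global-alignment best-hit search over the local
reference FASTA (ties broken by coverage then lexicographic hit id, and
flagged); threshold test with optional genus fallback; (b) for nuITS2, CBC
counting against the hit structure — one or more full CBCs demote the call;
(c) accepted-name check. Final ranks: **species** (all steps pass),
**genus** (distance passes but a CBC is present — the hit is a close
congener of a distinct species), **unassigned** (threshold failed
everywhere, or the assigned name is not accepted). Hemi-CBCs never block a
species call: the worked example itself contains species-level rows with
hemi-CBCs. Every decision carries an ordered rationale chain.

## ITS2 structures and CBC counting

Structures are nested (pseudoknot-free) pair sets in dot-bracket notation.
CBCs are evaluated on *shared* pairs — pairs present in both structures
after mapping to a common global alignment — and only where both columns
are ungapped and both base pairs are canonical (A·T/U, G·C, G·T/U wobble):
both sides differing is a CBC, exactly one a hemi-CBC. Gapped and
non-canonical shared pairs are skipped and reported separately, so
cbc + hemi + unchanged equals the evaluated pair count. Counting is
symmetric in its two inputs.

Externally predicted structures (Vienna files) are the recommended input
for biological data. Two desk-scale surrogates are provided and clearly
labelled as such: a Nussinov base-pair-maximisation folder (deterministic
traceback: pairing preferred over bifurcation, smallest partner index;
minimum hairpin loop 3) in place of thermodynamic folding, and
alignment-based homology transfer (template pairs kept when both positions
map to target residues) in place of database-driven structure modelling.
Published CBC counts obtained with thermodynamic folding and
structure-aware alignment are method-sensitive; the packaged worked example
therefore carries its CBC counts as data, and the counting machinery is
validated by injection round-trips (structures built with (k, m) changes
return exactly (k, m)).

## Amplicon geometry and ITS annotation

In-silico PCR matches degenerate primers by IUPAC set intersection (both
primer and template may be ambiguous; inosine matches anything) with a
configurable mismatch budget, forward on the given strand and reverse as
its reverse complement; the leftmost forward site is paired with the
rightmost compatible reverse site, multiple forward sites are flagged, and
absence of a site pair is a result, not an exception. Coordinates are
0-based half-open internally and 1-based in reports, with the reported
length defined as (reverse 3′-end position − forward 5′-start position) —
the convention under which the 192→657 *rbc*L primer pair yields the
printed 465.

The ITS1–5.8S–ITS2 amplicon is split by locating the 5.8S gene between two
conserved flanking motifs (defaults CGATGAAGAACGCAGC and GAATTGCAGAATTC,
≤ 1 degenerate mismatch each, accepted 5.8S length 100–200 nt); ITS1 and
ITS2 are the flanks, and the three spans partition the amplicon. This is a
deliberate simplification of profile-HMM annotation: accuracy is validated
on synthetic amplicons only, and records without a motif pair are flagged
unannotatable and skipped rather than guessed.

## Trees

Neighbor joining is the Saitou–Nei agglomeration on the *p*-distance
matrix with a deterministic tie-break (first minimal Q in row/col scan
order); negative branch-length estimates are clamped to zero (with a
warning above numerical noise), and the unrooted tree is stored with a
trifurcating root (2n − 3 edges). NJ is exact on additive matrices, which
the tests exploit as an oracle. Bootstrap support resamples alignment
columns with replacement under a seeded generator; support is the fraction
of replicate NJ trees containing each split of the full-data tree.
Monophyly is the unrooted split test (a set is monophyletic iff its
complement is). Model-based likelihood trees are out of scope; NJ with
bootstrap is the package's clade-confirmation surrogate, and monophyly
claims are exercised on synthetic data.

## Synthetic data generator

The generator emulates curated per-genus reference samplings: clusters of
conspecific sequences separated by a clean barcode gap, plus query strains
at known distances. Design goals were *exactness* and *determinism* rather
than evolutionary realism. Each species owns a private, disjoint block of
`inter/2 × L` columns where its ancestor differs from a shared root; any
two species ancestors therefore differ at exactly `inter × L` sites.
Members mutate `intra/2 × L` positions inside their own block — positions
disjoint between members, replacement bases differing from both the
ancestor and the root — so realised max<sub>intra</sub> = `intra` and
min<sub>inter</sub> = `inter` exactly, and the derived threshold equals
`inter`. Genus membership is a label (genus roots coincide with the global
root): at the default study-scale conditions (20 species, `inter` = 0.10,
L = 1000) the species blocks fill the sequence, and distance-based
conclusions do not depend on between-genus excess divergence. Defaults
(intra 0.01, inter 0.10, L = 1000) mirror the magnitudes seen in the
curated Chlorella/Desmodesmus reference ranges (intraspecific ≈ 0–0.02,
interspecific minima ≈ 0.015–0.076).

Substitution-only mutation keeps realised distances analytically forced
(`mutate_sequence` substitutes exactly `round(d × L)` distinct positions);
an indel-free design also means the generator's output is its own
alignment. What the generator does **not** emulate: indels and alignment
uncertainty, rate heterogeneity and multiple hits (no model correction is
needed at these divergences), unbalanced sampling, mislabelled references,
and paralogy. Passing tests therefore demonstrate correctness of the
inference chain under clean-gap conditions, not robustness to noisy real
databases — the worked example and the accession workflow cover the
real-data side.

Structure-pair generation folds a base sequence and rewrites chosen pairs
with canonicity-preserving substitutions on both sides (CBC) or one side
(hemi-CBC), giving exact injected counts.

The identification experiment sweeps query distances and thresholds and
reports correct/false/unassigned rates, illustrating the central trade-off:
a threshold at the interspecific minimum never mis-assigns but leaves
divergent queries unassigned, while permissive thresholds assign everything
at the cost of errors.

## Numerical choices and degenerate inputs

Alignment scoring defaults to match +1 / mismatch −1 / gap −2 (linear),
with a deterministic traceback (substitution > gap in first sequence > gap
in second); the row recurrence is computed as an exact prefix scan. The
center-star aligner ("once a gap, always a gap") is a fixture aligner for
synthetic/toy data; real analyses should supply externally aligned FASTA.
Empty FASTA files, duplicate ids, non-IUPAC characters, all-gap rows,
pairs with no comparable sites, single-species gap analyses and sub-3-taxon
NJ are rejected with specific errors; per-record pipeline failures are
logged and skipped without aborting the batch. All stochastic components
(generator, bootstrap, experiment) are seeded and reproduce byte-identical
outputs under identical configuration.

## Problem sizes

The shipped tests and the acceptance script run the study-scale synthetic
conditions (20 species × 2 sequences × 1000 nt, multiple seeds), oracle
checks at exhaustive-enumeration scale (alignments ≤ 6 nt, foldings ≤ 12
nt, trees ≤ 8 taxa), and bootstrap checks at a few hundred replicates —
sizes chosen so the full suite completes in well under a minute while every
oracle remains genuinely exhaustive.

## Known limitations

- CBC counts from surrogate folding will not generally match counts
  obtained with thermodynamic folding plus curated structural alignments.
- The identity→distance bridge quantises at 1% for printed identities.
- The accession-dependent statistics (reference distance ranges, genotype
  counts, nucleotide diversities) require downloading and aligning the
  original GenBank sets; alignment parameters and the gap policy used for
  the published figures are not uniquely determined, so reproduction is
  best-effort and both settings are recorded in the workflow output.
- The genus-fallback rule generalises a single-case decision; it is off by
  default in the library API and explicit in reports when used.
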