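# Methods

This note documents the statistical and algorithmic choices behind each
stage, the synthetic-data generators and their calibration, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## SSR mining

An SSR locus is a *maximal perfect* tandem repeat of a *primitive*
1–6 bp unit (a unit is primitive if it is not itself a power of a
shorter string). The scanner finds, for each unit length u, maximal
runs of the periodicity predicate s[i] = s[i+u] and reports a run as a
locus when its full-unit repeat count reaches the threshold for u.
Primitivity of the observed unit guarantees each tract is reported
exactly once, at its shortest unit: any longer-unit representation of
the same pure power has a non-primitive unit and is skipped.

Defaults (repeat counts, unitless): mono ≥ 10, di ≥ 6, tri/tetra/penta/
hexa ≥ 5 — the thresholds conventionally used in MISA-style mining.
Compound or interrupted repeats are never merged; only perfect simple
tracts are reported. Lowercase (soft-masked) bases are uppercased
before scanning; `N` breaks tracts; any other non-ACGT character is a
format error.

Motif classes collapse the 2u rotation/strand variants of a unit:
X = the lexicographic minimum over all cyclic rotations of the unit and
of its reverse complement, label = `X/revcomp(X)`. Palindromic classes
(`AT/AT`, `CG/CG`) are legal; note that CG is its own reverse
complement, so its class label is `CG/CG`.

Coordinates are 0-based half-open in memory and 1-based inclusive in
exported tables (GFF-style). *Mean interlocus distance* is defined as
assembly length divided by locus count (bp per locus), not the mean of
adjacent gaps — the definition consistent with genome-scale summaries
of this kind.

Correctness is checked against an independent brute-force scanner that
tests every (start, unit) pair, on random sequences and on synthetic
genomes with planted tracts.

## Genotypes and the band matrix

Accessions are dikaryotic, so a cell holds an unordered set of at most
two allele sizes (integer bp; capillary sizing is treated as exact, no
±1 bp fuzzy merging). An empty set is missing data. The band matrix
expands calls to one 0/1 column per observed (marker, allele size)
pair, ordered by marker display order then ascending size; a column
exists iff at least one accession carries the band, so the column count
equals the total observed allele count ΣNa. Whole-cell missingness is
tracked separately from genuine band absence.

## Diversity statistics

Frequencies are *band-based*: each distinct band an accession carries
contributes one count, and missing cells are excluded from the
denominator (no imputation). This matches presence/absence band
scoring; it does not weight homozygous-like single-band calls twice.

For frequencies p₁…p_k:

- Ne = 1/Σp², He = 1 − Σp² (plain Nei gene diversity, *not* the
  2N/(2N−1) unbiased variant — the plain estimator is what makes the
  identity He = 1 − 1/Ne hold exactly, and published per-locus tables
  of this kind satisfy it to 3 decimals),
- I = −Σp ln p in natural logarithm,
- PIC = 1 − Σp² − Σ_{j<k} 2p_j²p_k², computed via
  Σ_{j<k}2p_j²p_k² = (Σp²)² − Σp⁴.

Provable invariants under these definitions, tested on arbitrary
frequency vectors: PIC ≤ He, Ne ≤ Na, I ≤ ln Na, He = 1 − 1/Ne.
The report table mirrors the conventional layout: one row per locus,
a totals row (column sums) and a means row (totals / locus count),
displayed at 3 decimals (Na mean at 2).

## Similarity and clustering

Similarity is the simple matching coefficient on band columns —
agreements include shared absences, the usual convention for dominant-
style scoring — and distance is 1 − S. Columns of markers missing in
either member of a pair are excluded pairwise (pairwise-complete rather
than dropping accessions); a pair with no comparable columns is an
error.

UPGMA is implemented directly rather than delegated, because two
details are part of the contract and are implementation-defined in
library routines: (a) the tie rule — among equally close pairs, merge
the pair whose (smallest leaf label, largest leaf label) is
lexicographically least, making trees deterministic under any input
order; (b) the height convention — a node's height is the size-weighted
average distance at the merge, *not* halved, so a dendrogram drawn on
1 − S can be read directly in similarity units and a cut at similarity
s separates clusters merging above height 1 − s. SciPy's average
linkage serves as an independent oracle for the cophenetic distances in
tests. Groups from a cut are numbered by first-accession input order.
Newick branch lengths are parent height minus child height, so leaf
depths are equal (ultrametric).

## Core selection

The maximization (M) strategy is a deterministic greedy cover: pick the
accession adding the most uncovered allele classes; break ties toward
the larger total band count, then input order; stop at 100 % coverage.
The published "advanced M" heuristic of PowerCore is not fully
specified in the literature; this greedy formulation shares its
objective (full class retention with minimal redundancy) and carries
the classical set-cover guarantee — at most (1 + ln max-support) times
the optimal cover — which the tests verify against exhaustive
enumeration on small instances. If a `target_size` beyond the cover is
requested, further picks maximize the running within-core Shannon
index summed over markers (band-count frequencies within the core);
a target below the cover size returns the full cover with a warning.

Quantitative traits, when supplied, are discretized into quartile
classes and appended as extra coverage columns, so phenotype classes
are retained alongside alleles. The random-subset baseline reports
Monte-Carlo mean coverage of uniform subsets at a given size under a
fixed seed.

## Molecular identity codes

The payload is `fingerprint-traitcode-suppcode`: the fingerprint is the
accession's band row as a raw "0"/"1" string (human-readable; identity
of fingerprints is identity of band rows, there is no hashing), the
trait and supplementary codes concatenate single- or few-character
codes from a user-supplied code book (shipped default: fruiting-body
color; origin region; cultivation type). The concrete field order and
separators are this package's documented convention, configurable via
the code book. Duplicate detection partitions accessions by identical
fingerprint (or payload); fingerprint-identical groups whose metadata
codes still differ are flagged, since such accessions are separable
only through metadata.

For 2D-barcode use, a 2-character base-36 checksum of the character sum
(mod 36²) is appended after a distinct separator (`~`), keeping the raw
payload recoverable. The default capacity limit (2953 characters) is
the byte-mode capacity of the largest QR symbol; oversize payloads get
an error suggesting the provided base-36 fingerprint compaction.
Barcode image rendering is deliberately out of scope — the payload
string is the deliverable.

## Synthetic-data generators

**Genomes.** Background bases are drawn i.i.d. at a configurable GC
content; planted tracts are stamped in, flank bases are fixed so the
periodic run cannot extend past the planted span, and the whole
background is rejection-resampled until mining reports exactly the
planted catalog (accidental above-threshold background tracts at these
thresholds are rare, so a handful of attempts suffice). Planted tracts
must be non-overlapping, clear of the sequence ends, and at or above
threshold.

**Populations.** Defaults are the study conditions the package is
shaped around: 57 accessions, 15 loci with allele counts
[5,9,5,6,7,4,9,8,11,10,7,9,17,5,3] (ΣNa = 115), 5 near-equal groups,
within-group similarity 0.90 and between-group similarity 0.72, chosen
so a cut at 0.76 separates the groups and the similarity range
resembles the 0.70–1.00 span typical of such panels.

The generative model: each locus gets a ladder of allele sizes and a
Dirichlet-drawn weight vector (concentration `allele_freq_prior`,
default 1.0). Each group carries a consensus allele *pair* per locus;
an accession copies its group's consensus slot by slot, replacing a
slot with a weight-distributed random allele with mutation probability
m. Expected band-presence probabilities, and from them the expected
simple-matching agreement between any two accessions, have closed
forms under this model; m is solved from the within-group target by
bisection on that closed form. Between-group divergence comes from a
subset of *discriminating loci* at which each group receives its own
consensus pair, dealt from a per-locus shuffled allele ladder in a
per-locus random group order (so which groups happen to share an
allele varies across loci instead of repeating systematically). The
subset is chosen by a greedy subset-sum over the closed-form
between-group agreement deficits to hit the between-group target; the
mutation rate and the subset are alternated twice since each slightly
moves the other. Unattainable targets raise a calibration error rather
than silently missing.

Because band columns exist only for observed alleles, every allele is
guaranteed present: after (optional) missingness is applied, uncovered
alleles are patched into accessions, preferring single-band cells
(addition) over replacing bands that are carried elsewhere. The stored
truth (group labels, per-group band presence probabilities and their
normalized band frequencies, the calibrated m, the discriminating
loci) refers to the pre-patch model; the patch moves at most a few
bands per locus.

What the generator does *not* emulate: PCR stutter, null alleles,
size-calling noise, linkage between loci, and within-group pedigree
structure. Passing tests therefore demonstrate correctness of the
estimators and algorithms under a clean band-scoring model, not
robustness to genotyping artifacts.

**Traits.** Color counts are fixed quotas (round(n·18/57) white, the
rest brown). With group labels supplied, members of the largest group
are colored white with a configurable correlation before the remaining
quota is spread at random — emulating a color-linked subcluster.
Remaining fields are drawn from the code book's levels, so encoding is
closed by construction.

All generators are deterministic given (spec, seed): one NumPy
`default_rng` stream, consumed in a fixed order.

## Problem sizes and tolerances

The test suite runs entirely on synthetic data generated at run time:
populations of 57×15 (500×15 for the frequency-recovery check, which
asserts a 0.05 tolerance on band frequencies), genomes of 2–10 kb,
brute-force scanner equivalence on sequences ≤ 400 bp, exhaustive
set-cover oracles on ≤ 12 accessions, and 20 seeds for the planted-
group-recovery property (ARI = 1 required in ≥ 19 of 20, since a group
pair can land near the cut by chance). Empirical similarity
calibration is asserted at ±0.03 around the targets; the closed-form
expectations are exact for the within-group level and within the
subset-sum granularity (< 0.01) for the between-group level.

## Known limitations

- Band-based frequencies treat a single-band cell as one observation,
  so allele frequencies are frequencies *of bands among carriers*, not
  gametic frequencies; all downstream statistics inherit this
  convention (deliberately, to match band scoring).
- The greedy cover is optimal only up to the logarithmic set-cover
  bound; a data set could exist where the true minimum core is smaller.
- Simple matching weights shared absences as agreement; with very
  sparse band matrices this inflates similarity between allele-poor
  accessions.
- The pairwise-complete missing-data rule can make the similarity
  matrix non-Euclidean in extreme missingness; UPGMA still runs but
  cophenetic distortion grows.
- Trait quartile discretization uses empirical quantiles and drops
  duplicate bin edges, so fewer than four classes can result for
  heavily tied traits.
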