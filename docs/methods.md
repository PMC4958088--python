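# Methods

## Problem setting

Clonal cultivars are vegetatively propagated, so every plant of a cultivar
carries the same multilocus genotype. Fingerprinting therefore reduces to
choosing a marker panel whose genotypes jointly separate all cultivars of
interest, and organising the comparison so that routine identification needs
as few assays as possible. SSR markers with long-core motifs (3–6 bp repeat
units) are used because their alleles separate cleanly on capillary
electrophoresis; alleles are scored as fragment sizes in bp.

## Data model

A genotype call is an unordered multiset of 2 or 3 allele sizes — the
packaged tea survey contains five triploid calls (cultivars 4 and 18); all
others are diploid. Calls are canonicalised to ascending order, and equality
is multiset equality, so `292/268` and `268/292` are the same call. Missing
cells are a hard error rather than an NA state: the survey table is
complete, and in transcription-heavy workflows a silent missing-data policy
hides mistakes.

## Marker statistics

Allele frequencies at a locus count every allele copy: 2 per diploid call,
3 per triploid call. This is the only counting rule that uses all observed
data without imputing a hidden fourth state; it also means the frequency
denominator varies by locus in mixed-ploidy tables (e.g. 132 vs 135
observations over 66 cultivars).

* PID = 2(Σp²)² − Σp⁴. This equals the exhaustive sum over unordered
  Hardy–Weinberg genotypes of P(g)², which the tests verify by brute-force
  enumeration for up to 6 alleles.
* PIC = 1 − Σp² − Σ_{i<j} 2p²ᵢp²ⱼ (Botstein form; the statistic PowerMarker
  reports). PIC < 1 − Σp² (expected heterozygosity) for any polymorphic
  locus.
* Ho counts an individual as heterozygous when its call has ≥2 distinct
  alleles; a triploid call with two distinct alleles is heterozygous.
* Panel-wide PID is the product of per-locus PIDs, assuming independently
  segregating loci — reasonable here because the panel spreads over 15
  linkage groups.

All frequency math runs in double precision; rounding to 3 decimals happens
only in the CSV writer.

### Printed statistics vs recomputation

Recomputing the per-locus statistics of the packaged survey from its printed
genotypes does not reproduce every printed third-decimal value (e.g. Ho at
TM442: printed 0.485, direct count 0.500) or even every NA/NG count (the
triploid calls and two singleton alleles inflate direct counts at four of
the six core markers). The published statistics were evidently computed from
a scoring of the data not fully recoverable from the printed genotype table.
The package therefore treats the printed statistics table as an *input* for
panel arithmetic (products, means, selection) and exposes
`compare_with_reference` as a diagnostic that reports the deltas rather than
hiding them. One printed value, the TM369 PID of 8.58 × 10⁻⁷, is formally
inconsistent with the PID formula for any 10-allele locus; it is preserved
verbatim because the published panel-wide product (1.42 × 10⁻³²) requires
it, and it is flagged in the fixture's provenance header.

## Core-marker selection

Criteria: PID < `pid_max` and PIC > `pic_min` (strict), NA ≤ `na_max` and
NG ≤ `ng_max` (non-strict). Defaults: 0.198 / 0.5 / 5 / 10. The PID ceiling
default is the *published* panel average, kept literal rather than
recomputed: the arithmetic mean of the printed PID column is ≈0.192, and
using it would exclude TM442 (PID 0.192) from its own panel. Callers who
want the recomputed mean pass `panel_mean_pid(stats)` explicitly. Survivors
are ordered by descending PID (ties by name) — the order the identification
diagram consumes.

Descending PID puts the *least* discriminating marker first. That is the
stated construction convention of the source methodology and is implemented
literally, without per-node optimal marker re-selection; a per-group
best-marker chooser (entropy/Gini style) is explicitly out of scope.

## Distances and clustering

Cultivars are individuals, not populations, so population-level distance
formulas operate on individual allele profiles: shares of 1/2 (or 1/3)
per allele copy. The default metric is Nei's standard genetic distance with
sums pooled across loci, D = −ln(J_xy / √(J_xx·J_yy)); an allele-sharing
distance 1 − mean_loci Σ_a min(x_a, y_a) is selectable. Legacy toolchains do
not always record which Nei variant they applied, so no claim is made about
reproducing any particular published tree topology or cluster cut; the
packaged data's 0.25-height cut is a demonstration, not a validated result.
Profiles with zero allele overlap have infinite Nei distance in theory; the
ratio is clipped at the smallest positive double, giving a large finite
distance (~708) instead of overflow.

UPGMA is scipy's average-linkage clustering; its merge order is
deterministic, so repeated runs are bit-for-bit identical. The Newick writer
assigns each merge half of the height difference per side, so leaf-to-root
path lengths equal half the root height; tests parse the output back with
dendropy and compare patristic against cophenetic distances.

## The identification diagram

`build_cid` splits the cultivar set by genotype at the first marker of a
fixed global order, recursing with the next marker into every group of ≥2
cultivars. Groups that remain unsplit by a marker still consume it (a
single-branch node), which keeps the invariant that a cultivar's depth
equals the first marker index at which its genotype prefix is unique.
Cultivars still sharing all panel genotypes end as *flagged unresolved
leaves* — a first-class outcome meaning "the panel needs another marker",
never an error. Branch keys are exact canonical genotypes; serialisation
orders branches by genotype string so JSON/DOT output is deterministic.

`identify` is lazy: it requires only the genotypes on the traversed path and
raises a named error when the sample lacks the marker at the current node.
`add_cultivar` routes a new cultivar down the tree, re-splitting any leaf it
collides with using the remaining markers; the result is provably identical
to rebuilding from scratch on the extended table, and tests assert this
equivalence on randomised synthetic extensions.

## Synthetic populations

`simulate_table` draws, per individual and locus, 2 allele copies i.i.d.
from the locus frequency vector — 3 with probability `triploid_fraction` —
independently across loci. This emulates exactly the structure the analytic
formulas assume: Hardy–Weinberg proportions, independent loci, known
frequencies, occasional triploids treated purely as 3-allele observations
(no meiotic model, no linkage, no genotyping error, no null alleles).
Passing Monte-Carlo tests therefore validates the formulas and the tree
machinery, not the biological realism of any real survey.

`empirical_match_probability` is the PID oracle: the exact fraction of
unordered individual pairs identical at all named loci, computed by grouping
identical multilocus genotypes (algebraically equal to the O(n²) pair scan).
Tests check agreement with analytic PID within 4 standard errors at
n = 20,000, using n/2 as the effective independent-pair count — conservative
relative to the true U-statistic variance.

## Problem sizes and numerical choices

Test and acceptance runs use the packaged 66 × 6 table, Monte-Carlo
populations of 10,000–20,000 individuals for frequency/PID recovery, and
100 random 12-individual tables for decision-tree invariants; the whole
suite runs in a few seconds on one core. Frequency-vector validation uses a
1e-12 tolerance on Σp = 1; ultrametricity allows 1e-9 slack on merge-height
monotonicity; selection thresholds are compared with exact floating-point
inequalities, matching their strict/non-strict definitions.

## Known limitations

* Allele sizes are taken as exact integers; binning of raw fragment sizes
  is upstream and out of scope.
* The CID assumes error-free genotyping; probabilistic identification under
  scoring error is not modelled.
* No optimal-subset search over marker panels is attempted; selection is
  threshold-based as defined.
* The Nei-distance variant behind the packaged survey's published tree is
  unknown; both provided metrics are plausible, neither is asserted.
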