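# Methods

`fgscreen` implements a forward-genomics screen: it asks which
protein-coding genes have decayed preferentially in species that
independently evolved a phenotype — here, poor vision — and maps the
inferred loss events onto the species tree.  This note documents the
model, the statistics, the synthetic-data generator that the test suite
and benchmark run on, and the numerical and design choices that were
genuinely open.

## Reading-frame intactness

A gene in a query species is represented by a codon-aware pairwise
alignment against a reference coding sequence.  Five lesion classes are
called from the alignment:

- **frameshifting indels** — a maximal run of gap columns whose net
  inserted-minus-deleted length is not a multiple of 3, snapped to the
  codon containing the first affected base (a compound indel with net
  length 0 mod 3 is *not* an event);
- **premature stops** — TAA/TAG/TGA read in the reference frame at any
  codon before the terminal one (the terminal stop, or a stop created at
  the final codon, is never premature);
- **splice-site lesions** — a donor dinucleotide outside {GT, GC} (GC
  donors occur in a small minority of real introns and are tolerated by
  default; a strict-GT mode is available) or an acceptor other than AG,
  anchored at the boundary codon of the adjacent exon;
- **exon deletions** — an exon aligned entirely to gaps while flanking
  sequence is present;
- **gene deletions** — all exons absent with the locus present.

Codons without aligned query sequence (assembly gaps, written `N`) are
*missing data*: they are never called as mutations, but they do
interrupt intact stretches and reduce the present fraction.  All
coordinates are 0-based, half-open, in codon units.

**%intact** is the maximum percentage of the reading frame free of
lesions and assembly gaps: breakpoints are the codon spans of all
mutations plus all runs of absent codons, and the statistic is
100 × (longest clean codon run) / L.  A mutation-free, fully present
gene scores 100; a whole-gene deletion scores 0.  Because breakpoint
codons themselves count as non-intact, two point lesions at codons 200
and 700 of a 1000-codon gene give 49.9 (clean stretch 201–699), not 50.

Species-level status uses fixed thresholds: **missing** when less than
50% of the coding sequence is present in the assembly, otherwise
**lost** below 60 %intact, **intact** at or above 90, **uncertain**
between.  A transcript-level classifier is also provided that inspects
only the central 80% of the CDS (window `[ceil(0.1L), floor(0.9L))`):
lesions confined to the outer 10% at either end do not trigger a
`potentially_lost` call, and under-50%-present transcripts are
`missing`.

## Phenotype and lineages

Species are labelled foreground (poor vision) either by thresholding
visual acuity — cycles per degree; default threshold 1, strict `<` —
or by a molecular signature (at least five lost genes from a
user-supplied marker set).  Functionally blind species without
measurements must be explicitly flagged `assumed_zero` in the input;
the code never infers blindness.  Where both behavioural and anatomical
estimates exist, the input table is expected to carry the behavioural
one (it is the more accurate measurement); the package does not
re-derive acuity from eye anatomy.

"Independent lineages" are operationalised as the maximal monophyletic
clades whose leaves are all foreground.  Each such clade is compatible
with a single ancestral transition to the poor-vision state, so it
counts once toward convergence.  This partition is invariant under leaf
reordering and tree rotation, and its size equals the number of
foreground species exactly on a star tree.

## The association screen

Genes are first filtered: a gene is dropped if its %intact is missing
for more than 50% of foreground or more than 50% of background species,
or if its non-missing values are all identical (no variation can carry
an association).  For each retained gene the response y (%intact per
species) is regressed on the binary foreground indicator x by
generalized least squares with the Brownian-motion covariance
V_ij = shared root-to-tip path length of species i and j, the standard
phylogenetic regression.  Species with missing y are dropped gene-wise
and the tree is pruned per gene; genes sharing a missingness pattern
share one Cholesky factorisation of V.  No Pagel's λ or other
covariance scaling is estimated — plain Brownian V, a deliberate
simplification.  The response is raw %intact, untransformed.

The test is one-sided (alternative: slope < 0) because the screen
targets genes *preferentially lost* in foreground; a two-sided switch
exists.  p-values use the t distribution with n − 2 degrees of freedom.
Degenerate fits (constant response, singular covariance) report
slope 0, p = 1, flagged, rather than raising.  Benjamini–Hochberg
q-values are computed over exactly the post-filter gene universe, and a
**candidate** must satisfy q < 0.05 *and* be lost in at least three
foreground lineages (a lineage counts if any of its species is lost,
i.e. %intact < 60).  Results are ranked by (q, p, gene id) so output is
reproducible under ties.  A control screen reruns the identical
machinery with a substituted foreground (e.g. high-acuity sister
species).

A continuous-phenotype mode (regressing on log10 acuity) is available
but off by default; the primary screen is binary.

## Loss mapping

Gene loss is treated as irreversible (Dollo parsimony): the
minimum-event reconstruction places one loss on the stem of every
maximal clade whose informative leaves are all lost.  Missing-status
leaves are uninformative — they neither create nor destroy events — so
assembly gaps cannot inflate or deflate the count.  This greedy
maximal-clade placement provably attains the Dollo minimum; the test
suite verifies it against exhaustive enumeration of all labelings on
200 random trees of up to 8 leaves.

Independently of status data, identical lesions — same kind at the same
codon — observed in all informative leaves of a clade are assigned to
that clade's stem branch as likely ancestral events.  Matching is exact;
same-kind lesions one codon apart are reported separately as "possibly
shared" for manual review and never auto-merged, since alignment jitter
and recurrent mutation cannot be distinguished automatically.

## Enrichment

Candidate over-representation in user-supplied GMT gene sets uses
Fisher's exact test on the 2×2 table over the post-filter universe —
one-sided (hypergeometric upper tail) by default, two-sided available —
with BH correction across sets.  No ontology is bundled, so results
never depend on a database version.

## The synthetic-data generator

The generator produces the study conditions the screen assumes, so that
every stage is testable end to end without downloads.

- **Tree**: pure-birth (Yule) with birth rate 1, conditioned on n
  extant species, scaled to a root-to-tip height of 100 time units —
  roughly the age of the placental radiation in millions of years, so
  rates read naturally as per-lineage per My.  The birth process stops
  at the n-th split, which leaves the youngest cherry with zero-length
  tips; all pendant edges are therefore extended by one exponential
  waiting time (rate n × birth rate), preserving ultrametricity and
  keeping the Brownian covariance positive definite.  The draw is
  conditioned on admitting the requested foreground configuration
  (fresh draws up to 20 attempts).
- **Phenotype**: 7 disjoint foreground clades with sizes (3, 2, 1, 1,
  1, 1, 1) — ten species, mirroring the screen's study design of four
  subterranean singletons, one echolocating bat clade and two rodent
  lineages.  Only clades whose stem originates at least 20% of the tree
  height above the present are eligible (`min_age_frac = 0.2`).  This
  matters: relaxed selection needs time to leave lesions, and a
  foreground species on a near-zero pendant branch would carry an
  essentially intact gene while the GLS contrast weights it heavily
  (its tight background sister makes it the most precise comparison);
  without the age floor, benchmark sensitivity collapses on some tree
  draws.  Real poor-vision lineages are tens of millions of years old,
  so the floor is also the realistic choice.  Foreground acuity is
  drawn uniformly from (0.05, 0.9), background log-uniformly from
  (1.1, 60), so thresholding at 1 recovers the intended labels exactly.
- **Gene histories**: lesions arrive as a Poisson process per branch.
  All genes receive background noise at λ_bg = 2 × 10⁻⁴ per My (0.02
  expected lesions per root-to-tip path — rare noise, standing in for
  both genuine fixed lesions and residual alignment artifacts).
  Associated genes additionally receive λ_fg = 0.13 per My on every
  branch within foreground lineages, stem included; λ_fg is calibrated
  so that each foreground species of an associated gene is lost
  (%intact < 60) with probability ≈ 0.8 (measured 0.79).  Lesions on
  internal branches are inherited by all descendants, so shared
  ancestral mutations arise naturally.  Kinds are drawn as frameshift
  deletion 0.30, insertion 0.20, premature stop 0.35, splice 0.10, exon
  deletion 0.05; positions are uniform over codons and unique within a
  gene, so implanted sets round-trip exactly through alignment
  rendering and detection.
- **Alignments**: a random reference CDS (ATG start, no internal stop,
  single terminal stop, default 300 codons in 8 exons) is rendered per
  gene, and each species' query carries exactly its lesion list.  The
  detector run on these alignments is checked against the implanted
  truth — the generator is the detector's oracle.
- **Randomness**: one config seed feeds named, CRC-keyed substreams
  (tree, phenotype, acuity, one per gene), so any single gene is
  reproducible in isolation.

What the generator does *not* emulate: substitution processes (queries
are reference copies plus lesions), dN/dS or selection-intensity
signals, alignment error, paralog confusion, or assembly gaps under the
default settings (absent regions can be injected explicitly).  Passing
benchmarks therefore demonstrate the statistical machinery under the
model's own assumptions, not robustness to real-data artifacts.

## Benchmark results computed by the suite

Under the default configuration (49 species, 7 foreground lineages,
2,000 genes, 20 associated), averaged over 20 seeds: sensitivity for
associated genes lost in ≥3 lineages is 1.0 and the false-discovery
proportion among flagged candidates is 0.0; with no associated genes
the screen flags nothing.  `scripts/acceptance.py` recomputes these at
run time.

## Known limitation: finite-sample p-value calibration

The PGLS p-values are exact for Gaussian responses — simulating
Brownian traits on the same trees and phenotype assignments, the
empirical type-I error at α = 0.05 is 0.046–0.048.  The lesion process,
however, is a compound-Poisson jump process pushed through a bounded
nonlinearity, and a retained null gene typically carries only one or
two lesion events.  Conditional on the realized tree and foreground
placement, the null p-value distribution is therefore not uniform: a
single chance lesion inside a foreground lineage *is* a strong negative
association, and where the lineages sit relative to short branches
decides whether the test runs conservative or anti-conservative.
Measured across configurations, the fraction of null p-values below
0.05 ranges from ~0.00 to ~0.14 depending on the tree draw and noise
level, and does not concentrate at 0.05 even with many genes, because
all genes share one configuration.  The dedicated calibration test in
`tests/test_acceptance.py` states the nominal 3-binomial-SE band and
fails under the default configuration; it is kept failing deliberately
as an honest record of this property rather than being loosened.  What
*does* hold, and what the screen's validity actually rests on, is
control at the decision level: BH plus the convergence filter yields
zero false candidates across all tested null configurations, and FDP ≤
0.1 in the benchmark.  Rank-based or permutation p-values would fix
calibration but are outside the present scope, which follows the cited
GLS formulation.
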