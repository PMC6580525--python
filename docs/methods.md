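# Methods

This note documents the models implemented in `retrosite`, the reasoning
behind the tunable defaults, what the simulators do and do not emulate, and
the numerical conventions that make results reproducible.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; conversion to 1-based
inclusive happens only at the presentation layer.  Tracks and calls are
strand-agnostic; strand is retained on each mate only where orientation
matters (breakpoint refinement, orientation-normalising collected mates,
assembly).  Mate pairs are consumed in forward/reverse ("innie")
orientation, i.e. after junction processing of a long-insert library; the
raw outward-facing chemistry is not modelled.

## Signal tracks

Five per-window (default 500 bp) integer count tracks are computed from the
mate pairs of one sample:

- **SHORT_INSERT** — both mates on one chromosome with outer span below the
  expected insert range; every window between the mates is incremented,
  because element-spanning pairs localise the insertion interior.
- **DISCORDANT** — inter-chromosomal pairs or spans above the expected
  range; the window of each mate's leftmost aligned base is incremented.
- **ORPHAN** — exactly one mappable mate; the mapped mate's window is
  incremented.
- **CLIPPED** — a mapped mate with mapped fraction ≤ 1 − `min_clipped_fraction`
  (default 0.2); its anchor window is incremented.
- **DEPTH** — every window overlapped by each mate's aligned bases.

Counts are raw integers (no smoothing, no normalisation), which keeps the
tracks exact, order-invariant and directly testable; all aggregation
happens in the caller.  Mates with mapping quality below `min_mapq`
(default 20) are demoted to unmapped rather than dropped, because the
orphan signal depends on one-mapped/one-unmapped pairs.  Duplicate template
names count once; identical coordinates under distinct names all count.

The expected insert model defaults to an 8 kbp library: range 5,000–12,000
bp, mean 8,000, sd 1,500 (~19% CV, consistent with long-insert library
practice; the sd only matters to the simulator — the caller uses the range).

## Insertion caller

Per window, a track votes when its raw count reaches its threshold;
windows with at least `min_tracks_agreeing` votes merge into a call when
separated by at most `merge_gap_windows`.  Defaults were calibrated with
the built-in simulator at the tuning conditions (1 Mbp reference, 8 kbp
insertion, 20× physical coverage, 125 bp reads, 0.1% substitution errors):

| parameter | default | rationale |
|---|---|---|
| `window_size` | 500 bp | breakpoint localisation well below one insert length |
| `threshold_short_insert` | 2 | background is ~0 for a truncated insert distribution |
| `threshold_discordant` | 3 | guards against stray re-mappings in real data |
| `threshold_orphan` | 2 | the dominant insertion signal at low read coverage |
| `threshold_clipped` | 2 | junction pile-ups only |
| `threshold_depth` | disabled | see below |
| `min_tracks_agreeing` | 1 | see below |
| `merge_gap_windows` | 24 (12 kbp) | bridges the two breakpoint flanks of one insertion |

Two defaults deserve explanation.  At 20× *physical* coverage of an 8 kbp
library the sequence coverage is only ~0.6×, so the per-window expectation
of every junction-local signal is below one: for a cell prevalence *p*,
roughly 40·*p* orphan anchors spread over ±8 kbp around the insertion,
~1.2·*p* element-spanning short-insert pairs, and under one clipped read.
Only the orphan track is individually reliable, and requiring two or more
tracks to agree fails at every prevalence under these conditions.  The
caller therefore accepts single-track windows by default — consistent with
a deliberately permissive first step whose false positives are resolved by
the assembly/classification stage — and merges voting windows at insert
scale so the two flanks form one call.  Specificity is retained because
the short-insert/discordant/orphan/clipped backgrounds are structurally
zero for a concordant library; on insertion-free simulations the caller
emits exactly zero calls.  The DEPTH track is computed and reported as
evidence but does not vote by default: at ~0.6× read coverage, per-window
depth is Poisson with mean ≈ 3, and any deviation threshold either never
fires or fires on sampling noise.  With deep paired-end data a user can
set `threshold_depth` to enable it.

Each call receives a refined breakpoint: the median clipped-read junction
position when clipped evidence exists, otherwise the midpoint between the
innermost forward-strand orphan anchor end and the innermost reverse-strand
anchor start (forward anchors lie left of the insertion, reverse anchors
right of it, in an innie library).  Detection in the sensitivity sweep is
scored on this estimate (falling back to the call-interval midpoint),
because the midpoint of an insert-scale voting plateau fluctuates by more
than the 1 kbp tolerance the tuning targets.

Raising `min_tracks_agreeing` never increases the number of calls
(monotonicity), and identical inputs produce identical call lists
(ties between same-coordinate calls order by evidence descending).

## Mate-pair simulator

Cell prevalence is modelled per fragment: each of
`physical_coverage × reference_length / mean_insert` fragments derives from
the carrier haplotype with probability *p*, else from the reference.
Fragment lengths are truncated normal within the expected range; two
`read_length` reads are taken from the fragment ends; substitution errors
are i.i.d. (default 0.1%, no indels — indel errors drive none of the
tracks).  Reads carry their true placement, and an "oracle aligner" maps
each read at the reference coordinates of its dominant reference-derived
block: fully inside a novel insertion → unmapped; straddling a junction →
partially mapped with clip side recorded; fewer than 32 reference-derived
bases (~a mapper seed) → unmapped.  The oracle path makes simulation
experiments deterministic and mapper-free; production input is a real
mapper's coordinate-sorted SAM/BAM.

What the simulator does **not** emulate: mapping ambiguity in repeats,
chimeric fragments, PCR duplicates, quality-dependent errors, indel errors,
diploid genotypes, GC bias.  Passing the simulation suite therefore
demonstrates the logic of the pipeline under clean mapping, not robustness
to the full error structure of real libraries; the mapq demotion, duplicate
handling and per-track thresholds exist for that reality but are exercised
only lightly by the tests.

The tuning sweep (40–100% prevalence in 5% steps, ≥ 20 replicates per
level) reports the detection rate of a planted 8 kbp insertion with a 1 kbp
breakpoint tolerance.  With default caller settings the minimum prevalence
with ≥ 90% detection lands at 45–55% depending on the seed; problem sizes
(1 Mbp reference, 20 replicates) were chosen so the full sweep completes in
minutes while keeping ≥ 20 Bernoulli trials per grid cell.

## Assembly and classification

The assembler is greedy overlap-layout: repeatedly merge the pair of
sequences with the longest suffix–prefix overlap ≥ `min_overlap` (30) at
identity ≥ `min_identity` (0.95), trying all four distinct orientation
pairings, until no merge remains.  Candidate overlaps are anchored on exact
occurrences of the leading `min_overlap`-mer (seed-and-extend), so an error
inside the seed can hide an overlap — acceptable at sub-percent error
rates.  Ties break deterministically (longest overlap, then insertion
order); contigs are reported longest-first.  On error-free tiling reads the
assembler reconstructs the planted sequence exactly, and
reverse-complementing all input reads reverse-complements the output.

Classification aligns each contig locally against every panel sequence on
both strands with fixed affine scoring (match +1, mismatch −2, gap open −4,
gap extend −1); identity is identities over alignment columns.  Hits
require ≥ 100 aligned bp at ≥ 0.80 identity and rank by
identity × aligned length.  Both the contig bases outside the matched
region and the *panel entry's* bases outside it are retained as candidate
host flanks: a database entry for a polymorphic insertion typically carries
the host context around the element, and confirmation consists of aligning
any flank (≥ 50 bp at ≥ 0.95 identity) to the reference within the call
interval ± `flank_bp`.  Verdict precedence per call is
human > endogenous retrovirus > retrovirus > unresolved, with a
human-category best hit short-circuiting before the retrovirus pass so
human structural variation is never reported as a virus.

Allele reconstruction at a known locus assembles the non-anchored mates of
pairs anchored in the locus flanks, orients the contig by edit distance,
aligns it to the reference allele (banded edit-distance alignment; global
when lengths are within 10%, infix otherwise) and reports substitutions as
(position, reference base, observed base).  Coverage below 95% of the
allele flags the result partial.

## HERV-K k-mer genotyper

`T` is built per locus as the canonical k-mers (lexicographic min of k-mer
and reverse complement, k = 25 by default, rolling 2-bit encoding) present
in the locus's alleles, minus all k-mers of the reference genome with every
in-reference locus masked, minus all k-mers of other loci's alleles.  A
k-mer whose every allele occurrence lies inside an LTR annotation goes to
the LTR-only partition; all others — including LTR/internal junction
k-mers — are internal, so junction k-mers correctly witness the proviral
interior (they vanish in a solo LTR).  Loci with empty `T` are flagged
unusable.  `n` counts distinct observed members of `T` (presence, not
occurrences): the ratio semantics are the proportion of unique k-mers
matched exactly, and any polymorphism or read error inside a k-mer excludes
it, so each substitution lowers `n` by at most k.

State calling uses partition ratios with thresholds of 0.5: internal ratio
≥ 0.5 → provirus; else LTR ratio ≥ 0.5 → solo LTR; else absence.  The 0.5
default is a reconstruction (half the unique k-mers observed is well above
any plausible noise floor and tolerant of one divergent allele); an empty
partition produces a call from the remaining partition plus a warning.
`n/T` is pooled over all alleles at a locus.  Loci on the Y chromosome or
in expanding centromeric arrays are handled by simply excluding them from
the locus panel.

The independent mate-pair path calls the same states from read placement:
for a locus whose reference allele is the provirus, read occupancy of the
proviral interior implies provirus, occupancy confined to the 5′ LTR
implies solo LTR, and an empty locus implies absence (occupancy threshold
0.2, safely below the ~46% covered fraction expected even at 0.6× read
coverage and far above the zero of a deleted interior).  For loci absent
from the reference, orphan mates anchored within one insert length of the
pre-integration site are located on the provirus allele by exact substring
search (edit-distance fallback); any mate touching the interior implies
provirus, LTR-only mates imply solo LTR (≥ 3 reads either way), no anchored
mates imply absence.  `anchor_discovery` generalises the same idea
genome-wide by clustering (10 kbp window, ≥ 3 anchors) the mates of reads
matching a full-length HERV-K sequence, to catch insertions at loci not in
the panel.

The cohort concordance experiment (5 individuals × 8 loci, uniform random
states) uses error-free reads at 20× *read* coverage — the genotyping
use-case corresponds to deep paired-end data, unlike the physical-coverage
regime of the insertion-caller tuning — and the two paths agree on 100% of
cells, each also matching the simulated truth.

The synthetic HERV-K material is deliberately idealised: i.i.d. random
alleles (~9 kbp; 968 bp LTRs flanking a ~7 kbp interior), identical 5′/3′
LTRs, no homology between loci and no repeat context around them.  Real
HERV-K loci share high mutual identity, which shrinks `T` (the uniqueness
filter is what makes the method work there); the brute-force set-difference
tests verify exactly that filter, but the synthetic panels do not probe
mappability of flanking repeats.

## Population statistics

Prevalence counts the provirus state only — solo LTRs and absences are both
non-carriers — reported as percentages (1 d.p. in tables).  Co-occurrence
is the percentage of individuals carrying the provirus at every locus of a
combination.  Burden is the per-individual provirus count over a chosen
polymorphic locus set, with an integer-binned histogram.

The two-sample Kolmogorov–Smirnov test computes D as the sup of the ECDF
difference on an integer lattice (exact with ties).  The p-value is exact —
counting monotone lattice paths that stay inside the band, over
C(m+n, m) — when m·n ≤ 10⁴, and otherwise uses the one-sample KS
distribution at the effective size mn/(m+n).  Both branches agree with an
independent reference implementation to better than 10⁻⁶ on continuous
data; the exact null assumes no ties, so p-values on heavily tied integer
burden data are approximate (the D statistic itself is exact).  The test is
two-sided.

LDA is classical Fisher: eigenvectors of the pooled within-class scatter
inverse times the between-class scatter, via a generalised symmetric
eigenproblem with ridge regularisation ε = 10⁻⁶·trace(Sw)/d so singular
within-class scatter (constant features, one-hot encodings) remains
solvable.  Components are ordered by eigenvalue descending with the sign
convention that each component's first non-zero loading is positive;
projections are therefore deterministic and row-order invariant.  States
encode ordinally (absence 0, solo LTR 1, provirus 2; one-hot behind a
flag); the ratio encoding uses `n/T` directly and — because it captures
allelic variation on top of occupancy — separates cohorts that are
indistinguishable in state space, which the recovery tests demonstrate on
synthetic populations differing only in allele divergence.  No class priors
are used.

The population generator draws states i.i.d. from per-group frequency
triples; provirus ratios are 1 − `allele_noise`·U(0,1) (1 when noise is 0,
i.e. the reference allele), solo-LTR ratios sit near 0.1 of that scale,
absences at 0.  It generates summary-level cohorts only — no linkage
between loci, no within-group population structure.

## Known limitations

- The caller's defaults target the long-insert/low-read-coverage regime;
  deep paired-end data would warrant enabling the depth vote and raising
  `min_tracks_agreeing`.
- Insertions shorter than the read length are outside the design envelope,
  and elements longer than the largest fragment leave no spanning pairs
  (the short-insert track then stays empty; detection rests on orphans and
  clips alone).
- Exact-match k-mer counting has no error correction: at raw-read error
  rate e, the expected observed fraction of a truly present k-mer set is
  bounded below by coverage-dependent terms, and with very low coverage
  n/T underestimates presence.
- The greedy assembler is not a general-purpose assembler; it is sized for
  the few hundred to few thousand reads collected at one call.
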