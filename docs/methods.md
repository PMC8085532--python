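# Methods

This note records the models the package implements, the conventions and
defaults it chose where several were defensible, and what its synthetic
data do and do not establish about real sequencing data.

## Region model

The AZFc is modelled as an ordered list of 19 segments on chrY
(proximal→distal): Gr1, b1, t1, P3_spacer, t2, b2, IR1, g1, r1, r2, b3,
y1, g2, r3, r4, g3, y2, b4, Gr2, plus a 1-Mb single-copy normalization
interval elsewhere on the chromosome.  Family copy counts on the reference
are b=4, t=2, g=3, r=4, y=2, Gr=2, one P3 spacer.  Coordinates are 0-based
half-open internally; the BED-like fixture converts at the I/O boundary
only.

The bundled fixture's coordinates are **synthetic**: GRCh37-plausible
positions constructed to satisfy the region's structural constraints —
segment order, family counts, a b2→b4 start-to-start distance of exactly
3.5 Mb, a b1→b3 distance of exactly 1.6 Mb, and a non-overlapping 1-Mb
normalization interval placed in X-degenerate sequence
(chrY:14.5–15.5 Mb, configurable).  Segment lengths are realistic orders
of magnitude, not measured values; analyses that need true breakpoint
coordinates should load their own map via `load_reference_map`.

Orientations: b1/b3 are direct to each other and b2/b4 to each other, the
two pairs mutually inverted — the arrangement implied by the region's
palindromes, under which a b2/b3 exchange needs an inversion intermediate.
This is load-bearing: it is exactly what makes the duplication-then-
deletion reconstruction unique and a deletion-first ordering structurally
impossible.  The remaining families are stored as direct copies even where
real palindrome arms are inverted (t1/t2, y1/y2); copy-number observables
cannot detect inversions and no direct-repeat event among those families
produces the studied vector (verified by exhaustive search), but users
modelling inversion-dependent events should edit the strand column.

Gr placement: both gray copies sit outside the b1–b4 span.  Any Gr copy
inside b2–b4 would be altered by the inferred scenario, contradicting an
observed unchanged Gr count.

Gene dosage is linear: total copies = copies-per-host-segment × host family
copies + a constant for copies outside the modelled region.  RBMY carries
4 such external copies (reference total 6); PRY, BPY, DAZ and CDY have one
copy per host segment and no external copies.  PRY's reference total is
not stated anywhere authoritative; one-per-blue-segment (4) is used, which
reproduces an unchanged PRY under the inferred scenario.

## Depth model and copy-number calling

Reads from all copies of a family co-align to the reference copies
("multi-mapping collapse"), so normalised depth — mean depth over the
union of a family's reference segments divided by mean depth over the
single-copy interval — estimates k/ref.  The union convention (equivalent
to per-copy averaging when copies have equal lengths) counts each base
once even if interval lists overlap.

Calling uses half-open, lower-inclusive midpoint bins: call k when
nd ∈ [(k−½)/ref, (k+½)/ref).  Boundary ties are measure-zero in practice;
the lower-inclusive choice makes exact expected values round-trip for all
k.  `k_max` defaults to 3×ref; values beyond it clamp with a warning
rather than fail, since a grossly amplified family is still a finding.
Missing rows inside a requested interval are depth 0 by default (the usual
convention for dumps that omit zero rows); `missing_as_zero=False` yields
NaN for pipelines that distinguish "no data" from "no coverage".

## EMA profiling

The confirmatory profile is a recursive exponential moving average,
y[i] = αx[i] + (1−α)y[i−1] with α = 2/(n+1), seeded with the simple mean
of the first n values and reported from position n−1 onward — the standard
convention of time-series EMA routines; the choice matters only in the
first window.  Default window 50 kb at full scale; toy-scale analyses
scale the window with the map (500 bp at 1% scale).  With several controls
the sample EMA is divided by the arithmetic mean of the control EMAs
(per-control normalisation is available by passing single-control lists).
Positions with zero control depth become NaN with a warning.  Segment-mean
summaries should skip the first window of each segment, where the average
still carries the neighbouring segment's level.  The EMA is a
visual/confirmatory instrument; no change-point or breakpoint inference is
built on it.

## NAHR search

Chromosome structures are ordered occurrence lists; each occurrence keeps
its family, orientation, source segment(s) and a reference-projected
anchor coordinate.  Deletion between direct repeats removes the interior
and fuses the endpoints into one hybrid (e.g. "b1/b3") that counts as one
family copy and remains a usable substrate for later events — this is what
makes ordering arguments checkable rather than assumed.  Interchromatidic
exchange has a reciprocal duplication product (… left, span,
hybrid(right/left), span-copy, right, …); intrachromatidic looping-out
deletes only.  Duplications therefore arise only from interchromatidic
events.  Inversions are excluded: the copy-number vector cannot detect
them.

The search is breadth-first over ordered event sequences, stopping at the
first depth with matches (minimal length).  Histories that reach an
identical labelled structure share their expansion work, but **every**
distinct event sequence is retained: sequences differing only in mechanism
(intra- vs interchromatidic deletion) produce identical chromosomes yet
are reported separately, since they are distinct biological histories.
Canonicalization (the family/orientation sequence, hybrids reduced to
their family) is used to compare structures, not to discard histories — a
stricter canonical-pruning search would silently drop mechanism variants.
Families are compared exactly; the spacer as presence/absence.  Cost is
held by a hard cap of three events (the frontier grows factorially; the
analyses this package targets need two).  A two-event scenario is flagged
*concurrent-capable* when both events are definable on the starting
structure — copy-number data cannot distinguish simultaneous sister-
chromatid events from that succession.

Span lengths are start-to-start distances between the exchanged copies'
reference-projected anchors; hybrids resolve to their first-listed
source's coordinate.  These are approximate by construction — the true
exchange points inside the repeats are not identifiable from depth.

## ASD dating

Founder = the cluster's modal haplotype (per-locus mode; ties broken by
minimal total squared distance, then the smaller allele), configurable to
a user-supplied founder, e.g. when dating an upstream node with a clade-
wide modal haplotype.  ASD is founder-based (not pairwise): per-locus mean
squared distance from the founder, averaged over loci.  Age in generations
is ASD divided by the panel-mean mutation rate; years multiply by an
explicit generation interval, default 25 y (a standard Y-chromosome
convention; always reported in the output).  The standard error is the
across-locus standard deviation (ddof = 1) of per-locus age estimates over
√n_loci, scaled to years — an implementation convention describing the
dispersion of the locus clocks, not a coalescent-theory variance, and
documented as such.

The default panel is the 16 moderately mutating single-copy Yfiler Plus
loci (excluding the multi-copy DYS385a/b and DYF387S1, the compound
DYS389II, DYS448 — deleted in the chromosomes this package models — and
the five rapidly mutating loci DYS449/518/570/576/627).  The bundled rate
table compiles typical published father–son germline estimates per locus;
its panel mean is 3.18 × 10⁻³ per locus per generation.  Microvariant
(non-integer) alleles are rejected with a clear error: squared distance in
repeat units is undefined for partial repeats.  Haplotype clusters are
user input (e.g. from a median-joining network built elsewhere); the
package does not construct networks.

## Synthetic data

`simulate_depth` draws per-base depth with expectation
base_coverage × (family copies / reference copies) over each family's
reference segments, base_coverage × presence over the spacer, and
base_coverage over unique and normalization sequence — the multi-mapping
collapse modelled directly at depth level (no read/FASTQ simulation,
because every downstream method consumes only depth).  Noise is Poisson
per base by default (default coverage 38.7×, a typical WGS depth for this
design); `noise="none"` gives exact expectations and serves as the
noiseless oracle in tests; a negative-binomial option
(variance = m(1+δm)) exercises overdispersion.  Real depth additionally
carries GC bias, mappability structure and alignment artifacts the
simulator deliberately omits — passing tests show the estimators invert
the stated depth model, not that real libraries are free of bias.

`make_toy_map(scale)` multiplies all coordinates by `scale` (segments must
stay ≥100 bp), preserving order, counts and span ratios, so per-base
simulation and EMA run in milliseconds at scale 0.01 (≈64 kb simulated per
profile).  Test and acceptance simulations use that scale; interval sizes
remain large enough that Poisson noise at 30× makes miscalls vanishingly
rare.

`simulate_star` / `simulate_nested` evolve lineages from a founder under
the strict single-step symmetric SMM: per generation and locus, mutate
with the locus rate, step ±1 with equal probability; an allele that would
reach zero repeats reflects upward with a logged warning (unreachable from
realistic founders).  Multi-step mutations are excluded, matching the
assumption under which E[ASD] = μG.  Both simulators are bit-reproducible
under a fixed seed.

Dating calibration in the test suite uses star genealogies of 4 tips at
G = 20 generations, 2,000 replicates: the mean estimate must fall within
two Monte-Carlo standard errors of G (and within 5% bias).  The analytic
anchor 1 mutation/16 loci ⇒ ASD = 0.0625 ⇒ 19.65 generations ≈ 491 years
at 25 y/gen pins the unit conventions.

## Known limitations

- Breakpoint positions inside repeats are not identifiable from depth;
  spans are anchor-to-anchor approximations on a synthetic coordinate map.
- Gene conversion, inversions and selection are outside the model.
- The ASD standard error understates uncertainty for non-star genealogies
  (shared branches correlate loci identically, haplotypes are not
  independent).
- The depth caller applies no GC or mappability correction; it assumes the
  control-normalisation absorbs platform effects.
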