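# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `ssrkit`, in the order the pipeline runs.

## Perfect-repeat detection (`ssrkit.detect`)

A microsatellite locus is a *maximal perfect run* of a 2–4 bp motif:
every base equals the base one period earlier, no mismatches, indels or
ambiguity codes, and extending the run by one base on either side breaks
that property.  Detection scans each contig once per period with a
vectorized "equal to the base `p` positions back" comparison and takes
maximal blocks of matches; a block of `m` matching comparisons covers
`m + p` bases and `⌊(m + p)/p⌋` complete motif copies.  Runs containing
N are split at the N (an N breaks perfection like a mismatch; the
flanking fragments remain candidates).  Spans include a trailing partial
motif copy, while `repeat_count` counts complete copies only — so copy
numbers are integers while spans stay maximal for flank extraction.

A run expressible at several periods (e.g. AT vs ATAT) is reported once,
at the smallest qualifying period.  This is enforced through motif
*primitivity*: a run whose leading `p`-mer is itself periodic (ATAT,
AA) is skipped at period `p`, because the same bases form a run at the
smaller period.  Mononucleotide runs are out of scope and fall out of
the same rule.

Canonical motif classes are the lexicographic minimum (A<C<G<T) over all
rotations of the motif and of its reverse complement.  Each class has at
most 2·period members, classification is idempotent, and detecting on
the reverse-complement strand yields the same class multiset — all
property-tested.

**Minimum copy thresholds** default to ≥5 complete copies for
dinucleotides and ≥3 for tri- and tetranucleotides, configurable per
period.  Genome surveys of this kind report mean copy numbers of about
six (di) and three (tri/tetra), which is only consistent with minima of
this order; the exact cutoffs of the original mining tools are usually
unstated, so the choice is explicit configuration rather than a claim.

The detector is verified against an independent brute-force oracle (per
start-position character-by-character extension) on randomly generated
sequences up to 2 kb, including N-containing sequences, and against
planted-truth synthetic genomes at 100% recall and precision.

## Selection tiers and primer candidates (`ssrkit.select`)

Contig selection uses two tiers: tier 1 keeps contigs with length
strictly greater than 200 bp and mean depth ≥ 10×; tier 2 additionally
requires ≥ 100×.  The boundary semantics (strict on length, inclusive
on depth) follow the usual phrasing of such criteria — ">200 bp" vs
"minimum 10×" — and are pinned by tests.  Tier 2 is a subset of tier 1
by construction.  Contigs with *unknown* depth are excluded with a
warning: depth is part of the criterion, and unknown is deliberately
distinct from zero throughout the package.

Primer candidates take up to 150 bp of flank on each side of a locus
(truncated at contig ends) and are rejected — with machine-readable
reason codes — when either flank is shorter than 50 bp, contains N, or
overlaps another detected repeat.  The 150/50 bp defaults suit the
100–350 bp amplicon sizes typical of capillary genotyping; rejection
rather than trimming keeps the operation deterministic and avoids
primers seated in repetitive sequence.  Export is Boulder-IO (the
key=value record format of the Primer3 family); primer design itself is
delegated to those tools.  The two melting-temperature rules (Wallace
`2(A+T)+4(G+C)`; GC-content `64.9 + 41(GC − 16.4)/L`) are advisory
sanity checks for marker tables, not thermodynamic models.

## Multiplex panels (`ssrkit.panels`)

Panel constraints: at most three markers per panel; one motif period per
panel (stutter patterns and binning lattices differ between periods);
and same-dye markers must have allele-size ranges separated by at least
10 bp.  Markers carry one of three dyes (6-FAM, HEX, NED); ROX is
reserved for the internal size standard.  When a marker has no observed
size range, its expected product size ± 15 bp stands in.  The 10 bp gap
and ±15 bp halo are our defaults — commercial multiplex designers
internalize equivalent guards against stutter and bin ambiguity — and
both are exposed as parameters.

Assembly is greedy first-fit over markers sorted by descending PIC (ties
by name): each marker goes into the lowest-numbered panel that stays
violation-free, else opens a new panel.  This is deterministic,
order-independent (the sort removes input-order effects), always yields
a valid partition, and reaches the pigeonhole lower bound ⌈n/3⌉ when
dye/size conflicts allow.  It does not attempt the global optimum a
constraint solver might find; published panel layouts are therefore not
claimed reproducible marker-for-marker, only constraint-equivalent.

## Allelic binning (`ssrkit.binning`)

True alleles of a microsatellite lie on a lattice `offset + k·period`;
electrophoresis reports continuous sizes with sub-bp noise and a
marker-specific offset.  The fitted offset minimizes
`Σᵢ min_k (sizeᵢ − (offset + k·period))²`.  As a function of the offset
this objective is piecewise quadratic: assignments change only at
breakpoints half a period opposite each observed residue (mod period).
The fitter enumerates the breakpoints, solves each quadratic piece in
closed form (mean of the locally adjusted residues, clamped to the
piece) and takes the global minimum, ties toward the smallest offset in
[0, period).  This is exact and deterministic — an exhaustive 0.001-step
grid search is kept in the test suite as an independent oracle, and the
closed-form fit must match it within one grid step on arbitrary inputs.
(A circular-mean estimate is cheaper but minimizes a 1−cos criterion,
not the squared error, and can miss the least-squares optimum on
dispersed residues; it survives only as intuition, not as the
implementation.)

Sizes snap to the nearest lattice point and are reported as the nearest
integer to it.  A size further than 0.35 × period/2 from its lattice
point is flagged `off_ladder` (configurable); a lattice whose fit leaves
any size beyond that threshold is flagged ambiguous — the half-period
two-point case `{150, 151}` at period 2 is the canonical example.  One
lattice is fitted per marker, never per panel, because offsets are
marker-specific.  Binning is translation-equivariant under whole-period
shifts.  Limitations: no stutter-peak modeling, no trace processing; the
input is already-sized fragment tables.  Fragment sizes are required to
lie in (50, 600) bp, the sizing range of common internal standards.

## Genotype statistics (`ssrkit.stats`)

Frequencies are direct counts over non-missing diploid calls (two copies
per individual).  He is Nei's gene diversity `1 − Σ pᵢ²`; PIC is the
Botstein form `1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²`; Ho is the heterozygote
fraction with missing calls excluded from the denominator.  These are
the plain, sample-size-uncorrected estimators, under which
`0 ≤ PIC ≤ He < 1` always holds (property-tested).  Published marker
tables sometimes print PIC > He per marker, which is impossible under
these formulas and indicates a corrected or differently defined He
column in the source software; this package does not imitate that
behavior.  Sample-size-corrected He, F-statistics and Hardy–Weinberg
tests are out of scope.

Allele classes partition pooled alleles by frequency: rare `p < 0.05`,
abundant `p > 0.30`, intermediate in between with both boundaries
assigned to intermediate (strict inequalities on the outer classes leave
the boundaries unassigned; a total partition is required for testable
accounting).

Percentages (transferability, concordance) display at one decimal with
round-half-up; summary statistics display at three decimals.  A
marker whose calls are all missing yields a flagged `no_data` row and is
excluded from aggregates rather than aborting the table.

Attrition chains multiply per-step survival `(1 − rate)` forward, or
divide backward to get required inputs, rounding half-up at each step
(so 729 × 0.5 → 365, and 198 ÷ 0.5 → 396).  Forward and backward chains
are inverse only up to rounding; the drift grows with the rates, which
the property test bounds explicitly.

## Synthetic data (`ssrkit.simulate`)

The genome generator plants repeats with known coordinates into i.i.d.
uniform A/C/G/T background.  The background is first scrubbed of chance
qualifying repeats (detected occurrences are broken by point mutation
and the scan repeated), plants are placed with ≥10 bp clearance, the
bases immediately flanking each plant are forced to break the period,
and the finished contig is re-scanned and regenerated until the detected
loci equal the planted truth exactly.  This guarantees exact
recall/precision accounting.  Defaults: 20 contigs of 500–2000 bp,
Poisson(2) plants per contig, motif mix weighted toward the classes that
dominate grass genomes (AG, CCG, AAAT), copy numbers
`minimum + Poisson` with means ≈6 (di) and ≈3.3 (tri/tetra), and
lognormal coverage (median ≈30×, σ_log = 1.2) so contigs fall on both
sides of the 10× and 100× tiers.

The genotype generator draws two independent allele copies per
individual per marker from configured frequencies on a repeat-unit
lattice (Hardy–Weinberg), applies per-call missingness, and optionally
adds Gaussian sizing noise (default preset σ = 0.15 bp) to produce a
raw-sizes table for the binning step.  The default study design is 11
diploid individuals, the size of a small germplasm validation panel.
One global seed fans out to per-component streams via
`SeedSequence.spawn`; all outputs are byte-identical under a fixed seed.

What the simulations do **not** emulate: read-level sequencing error and
assembly artifacts (coverage is drawn, not computed from reads),
imperfect/compound repeats, null alleles, stutter, and allele-size
homoplasy.  Passing the planted-truth and recovery tests therefore shows
the algorithms are correct on their stated model, not that real
electropherograms or real assemblies are this clean.

## Problem sizes in the test and acceptance runs

The bundled checks use 1,000 random sequences of 100–2,000 bp for the
detector/oracle equivalence, 100 simulated contigs (~300 planted loci)
for recall/precision, 500 individuals for He/Ho recovery, 60 sizes per
lattice at σ = 0.15 bp for binning recovery, and marker sets up to 45
for panel properties; these sizes give stable pass/fail behavior at
3-standard-error tolerances while keeping the whole suite fast.
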