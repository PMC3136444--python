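# Methods

`ril-atlas` analyses recombinant-inbred-line (RIL) genotype matrices from
two-strain *Caenorhabditis* crosses and forward-simulates the cross designs
the analyses assume.  This note records the models, the parameters that
matter, the numerical choices, and the limits of what the synthetic data can
show.

## Genotype model and QC

Genotypes are ABH-coded: `A`/`B` homozygous for parent 1/2, `H`
heterozygous, `?` missing.  Line-level QC removes lines whose H fraction
(over non-missing calls; the denominator is our choice, as finished RIL
should be nearly fully homozygous) exceeds `max_het_frac` (default 0.05).
Marker-level QC removes, in order of precedence: monomorphic markers,
markers at which both parents share a call, markers with call frequency
below `min_call_freq` (default 0.95, computed per marker across lines), and
markers with excess heterozygous calls.  QC is idempotent: a second
application removes nothing.

## Cumulative Haldane maps

Marker order is fixed to physical assembly order per chromosome; de novo
linkage grouping and ordering search are out of scope.  For each adjacent
marker pair the recombination fraction r is the fraction of lines
discordant among lines homozygous at both markers (H calls are too rare in
finished RIL to inform r; they do each contribute one breakpoint per
flanking transition when breakpoints are counted).  Distances are Haldane,
d = −50 ln(1 − 2r) cM, accumulated from 0 at the first marker of each
linkage group.  This treats every breakpoint accumulated over the
multi-generation cross as if it occurred in a single meiosis, which is the
convention that makes the cumulative map proportional to observed
breakpoint counts.  Pairs with r ≥ 0.5 are flagged unlinked and have no
defined distance; map construction fails loudly rather than inflating.

A genetic interval is an adjacent marker pair with positive genetic
distance (runs of completely linked markers collapse to a point); interval
physical size is measured marker-to-marker.  `normalize_map` rescales each
linkage group by one factor to a target (default 50 cM, the expected
per-meiosis length under selfing), optionally normalizing the sum of the
three major recombination domains instead of the whole group.

## Recombination domains

Each chromosome is partitioned into tipA / armA / center / armB / tipB.
Tips are combinatorial: the span from an assembly terminus to the most
internal marker sharing the terminal marker's genetic position; their rate
is zero by definition.  The two arm/center boundaries are estimated by
three-segment continuous piecewise-linear regression of genetic on physical
position over the non-tip markers (tips are excluded from the fit), using
iterative linearization with breakpoints initialized at the 25%/75%
physical quantiles (tolerance 1e−8, ≤100 iterations).  If the iteration
diverges, collapses, or yields a center slope that is not the smallest of
the three (the domain semantics require a low-recombination center), a
deterministic grid search over marker midpoints is used; perfectly linear
input is flagged degenerate rather than fitted.  Boundary genetic positions
are interpolated linearly between flanking markers; the three major
domains are normalized to 50 cM per chromosome, rates are normalized cM per
Mbp, and arm ratios are reported as max/min (≥ 1).

## Transmission ratio distortion

Allele fractions are computed per marker and cross direction as the share
of informative (fixed A or B) lines fixed for B.  Expectations: 0.5 on
autosomes; on the X, 2/3 for the hermaphrodite P0's strain per direction
(males are hemizygous, so two thirds of X copies descend from the
hermaphrodite).  Each marker is tested with a 1-df chi-square goodness of
fit, uncorrected by default — the large-sample form whose hand-computable
values the scan reports.  `chisq_gof(..., continuity=True)` provides the
Yates-corrected variant, which tracks the exact binomial two-sided p within
~0.01 for n ≥ 50 at moderate fractions; the uncorrected form reaches that
agreement only once the deviation is deep in the significance regime, so
the corrected variant is the stated small-sample approximation and the
exact binomial is the test-suite oracle.

Linked markers are not independent tests.  Within each recombination
domain and cross direction the lag-1 autocorrelation ρ of the
allele-fraction series is estimated (mean-centered, N-normalized; a
constant series is assigned ρ = 0, which conservatively keeps N_eff = N),
and the effective test count is the first-order autoregressive value
N_eff = N(1 − ρ)/(1 + ρ), clamped to [1, N].  The genome-wide threshold per
cross direction is 0.05 divided by the summed N_eff; threshold allele
fractions are computed at each marker's own n, toward the B-biased side by
default.  Cross-direction differences are tested per marker with Fisher's
exact test, Bonferroni-corrected by the sum over both directions of the
largest center-domain N_eff.

## Linkage disequilibrium

Finished RIL are effectively haploid gametes, so two-locus haplotypes are
observed directly: no phasing, EM, or Hardy–Weinberg assumption is used
(the original analysis ran a diploid LD tool with its HWE filter disabled;
direct haplotype counting is the cleaner equivalent for fixed lines).
D = p_BB − p_B p_B′, and D′ = |D|/D_max with the standard Lewontin
normalization; pairs involving a marker monomorphic among the scored lines
are undefined (NaN).  Interchromosomal blocks are maximal rectangles of
contiguous markers (map order) with all pairwise D′ ≥ 0.8, grown greedily
with ties resolved toward the larger block.  The gametic association test
compares observed two-locus fixed-class counts against products of marginal
allele frequencies (2×2 chi-square, 1 df), with a warning when any expected
cell is below 1.

## Inversion-like signals from paired maps

Two maps sharing a parental strain are restricted to shared markers and
normalized to 50 cM per chromosome.  Blocks of adjacent markers
nonrecombinant in one map but spanning positive distance in the other are
suppression candidates.  The expected breakpoint count is
λ = (block's cM span in the recombinant map) × (per-domain breakpoint
density, breakpoints/cM, of the nonrecombinant map's RIL set); observing
zero has p = e^(−λ), Bonferroni-corrected over candidates.  The λ
convention is fixed by the worked arithmetic of the source analysis
(5.66 breakpoints/cM × ≈0.89 cM = 5.03); densities are observed transition
counts assigned to the domain of each marker-pair midpoint.  Full-precision
p-values are reported.  Inverted-order blocks — runs whose genetic order
strictly reverses in one map while the other is concordant — are reported
separately and carry no test.

## Map-guided assembly

Supercontigs are assigned to the chromosome of their mapped markers,
ordered by their genetic span, and oriented when two markers disagree in
genetic position (a single marker places but cannot orient; identical
point-spans shared by several contigs are un-orderable and go to the
per-chromosome "random" bin).  Genetic/physical discrepancies (internal
order conflicts; markers of one contig genetically inside another's span)
are resolved by splitting at sequence gaps chosen by a fixed decision tree
(interpolate from local cM/Mbp; nearest gap to a nonrecombinant flank;
smallest-fragment gap for reorder-only cases; move only the discrepant
sequence contig when no unsupported gap exists).  Distance ties break
toward the lower coordinate.  Fragment naming: first splits append
`a`, `b`, …; re-splitting a suffixed contig keeps the letter on the largest
fragment with a digit appended (`c` → `c2`).  Output is an AGP-like layout;
sequence (FASTA) manipulation is out of scope.

## The simulator

The generator reproduces the study conditions: reciprocal crosses between
two inbred strains (the direction label names the male P0 first), six
generations of sib-mating (F1→F7) followed by ten generations of
single-hermaphrodite selfing (F8→F17) for the advanced-intercross design,
or selfing-only for the F2 design; 167 AI-RIL and 89 F2 RIL at the default
preset sizes.  Chromosome lengths, five-domain spans, and per-meiosis Marey
curves (50 cM per chromosome; flat tips, steep arms, shallow center) follow
the published cb4 domain geometry, and default marker counts per chromosome
follow the genotyped SNP counts.  Each meiosis places exactly one crossover
per chromosome (complete interference), uniform on the genetic scale and
mapped to bp through the inverse Marey curve; a Poisson-crossover mode
exists but is off by default.  Males are X0: a male X transmits intact, and
mtDNA follows the oocyte parent strictly (heteroplasmy is not modeled).
Selection is applied as viability at every offspring draw: nuclear
genotype penalties, cytonuclear terms keyed to mtDNA origin, and crossover
suppression inside spans that are heterozygous in the parent.  Lines whose
candidates all die in some generation are recorded extinct, not raised.

Preset selection strengths (fitness 0.2 for the ChrIII center
incompatibility, 0.25 for the ChrIV cytonuclear term, a 0.65-Mbp suppressed
span on ChrIV arm B) are fixed constants chosen once to represent strong
but non-lethal selection of the kind the study reports; they are not fitted
quantities.

What the simulator does not emulate: genotyping error and missing calls
(the study's final matrix is complete), segregating polymorphism within
parental strains, brood-size and mate-competition structure during
sib-mating (three founder hermaphrodites are a bookkeeping simplification),
mutation, and gene conversion.  Tests passing on synthetic data therefore
validate the statistical machinery under the stated design, not robustness
to assay artifacts.

### Design arithmetic vs forward dynamics

Two published expectations deserve care.  First, the expected X map length
of 110.5 cM is 2/3 of the mean autosomal cumulative length — exact
arithmetic on the published table, and the package reproduces it from those
inputs.  In the forward simulation, however, the realized X/autosome ratio
sits above 2/3 (≈0.70 at the study's marker density): the 2/3 factor
reflects X hemizygosity during the outcrossing phase only, while the
selfing phase recombines X and autosomes alike.  Second, the idealized
design captures more breakpoints per line (≈2–3 per autosome at full marker
resolution) than the study observed (1.44–1.66); the study itself lists
reasons its lines fell short of the design maximum (no exchange between
mating pools, pervasive selection, possible self-progeny matings).  The
simulated cumulative map is accordingly longer than the published 928.6 cM.
Neither quantity was tuned toward the published values.

## Problem sizes and runtimes

The calibration and recovery analyses run at sizes chosen to make the
Monte-Carlo error small relative to the assertions while completing in
seconds to minutes on one CPU: the neutral design check uses 2,000 lines
per direction at 12 markers/chromosome (allele fractions do not depend on
marker density); type-I control uses 100 neutral replicates of 80 lines;
the planted viability and cytonuclear presets use 150 lines/direction at 30
markers/chromosome; inversion recovery uses 125 AI-RIL per direction plus
150 F2 lines at the study's full marker density, which is required to
resolve a sub-Mbp suppressed span.

## Known limitations

* The discordant-fraction r estimator approximates the original intercross
  likelihood evaluation; cumulative map lengths are comparable, not
  bit-identical, to that software's output.
* Interval physical size is marker-to-marker; other conventions (bin edge
  to bin edge) would give different means on the same map.
* Block finding in LD uses greedy rectangle growth; pathological mosaics of
  overlapping blocks may be reported as several maximal rectangles.
* The assembly module operates on marker/gap coordinates only and trusts
  the clone-support flags it is given; absent flags make every gap eligible
  for splitting (logged).
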