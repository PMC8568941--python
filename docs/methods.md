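# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `velpipe`, and what the synthetic-cohort tests do and do
not demonstrate about real data.

## Signal model

All coordinates are 0-based half-open (BED convention) internally; 1-based
coordinates appear only in human-facing output.

Region signal is **RPM per bp**: each aligned fragment is replaced by the
200-bp window running 3′-ward from its 5′ end (a strand of "." is treated as
"+"; windows are clipped at position 0), the summed base overlap with the
region is divided by the region length, and the result is normalised per
million mapped reads. Two consequences are intended:

- The extension approximates the unobserved ~200 bp ChIP fragment from a
  short read; the extended fragment spans exactly the extension length, so a
  single fully-contained read contributes `200 / |R|` per-bp coverage.
- Using the *mean* per-bp coverage (not the region sum) makes values
  comparable across loci of different lengths. The single exception is
  super-enhancer **ranking**, which uses the region-summed signal
  (density × length) so that long high-signal clusters rank top, matching
  the ROSE convention. This divergence is deliberate and local to the
  ranking step.

`library_size` defaults to the fragment count of the sample file and can be
overridden in the sample sheet, for cohorts where the fragment file is
already filtered but depth bookkeeping refers to the full library.

## VEL calling

Per-pair fold changes use a pseudocount (default 0.5 RPM) in both numerator
and denominator so that zero-signal loci yield a fold change of 1 rather
than an undefined ratio; the value is small relative to typical peak signal
(tens of RPM) and is configurable. Fold-change thresholds are strict
inequalities, so a locus at exactly 2.0 is not called — the same strictness
applies to all QC minima ("fewer than" excludes, "exactly at" retains).

The paired t-statistic at a merged locus is computed across **all retained
pairs**, not only the pairs that called the locus: recurrence (how many
patients call it) and significance (is the cohort-level shift real) are
separate quantities, and restricting the test to calling pairs would bias it
by selection. Degenerate difference vectors follow fixed conventions:
all-zero differences give p = 1, a constant non-zero shift gives p = 0.

BH correction is applied separately within the gain and the lost record
sets, because the two directions are thresholded and reported separately.
The recurrence threshold r* is selected on the cumulative set — the fraction
of records with recurrence ≥ r that are BH-significant — and the default
target fraction is 0.95 for VELs, 0.9 for VSELs and subgroup analyses.
Significance alpha defaults to 0.05; it is a plain parameter everywhere.

Subgroup-specific gain VELs require the subgroup's mean tumor RPM to exceed
1.5× the mean of **each** other subgroup (strict, all pairwise comparisons),
so a locus can be specific to at most one subgroup.

## Super-enhancers

Stitching removes peaks overlapping ±2.5 kb of any TSS, then merges the
remainder with a 12.5 kb gap. Stitched regions with a single constituent
peak are retained in the ranking for diagnostics but excluded from the
super-enhancer candidate set by default (`min_constituents=2`), following
the "two or more peaks" definition of the ranking.

The tangent cut sorts signals ascending, rescales rank and signal to
[0, 1], and takes the first segment whose discrete slope (first differences
× (N−1)) exceeds 1; the cutoff is the signal at that segment's left end and
`is_super` requires signal strictly above it, which breaks ties toward
fewer super-enhancers. The slope comparison carries a 1e-9 guard so an
exactly linear curve — slope identically 1 — never flags spurious
super-enhancers through float rounding. Because rank and signal are both
rescaled, the cut is invariant to positive affine transforms of the signal
vector. Degenerate inputs: fewer than three regions is an error; all-equal
signals yield zero super-enhancers with a warning.

VSEL patient exclusion (< 10 VSELs) is recomputed at the VSEL stage,
independent of exclusions at the VEL stage, mirroring the staged QC of the
published analysis workflow.

SE→gene assignment takes genes whose TSS lies inside the super-enhancer
plus the nearest TSS within 50 kb of the region midpoint; general
locus→gene assignment uses nearest-TSS within 100 kb. Exact distance ties
report all tied genes sorted by identifier.

## CRC networks

Degrees are computed on one consensus network per tissue group (not
averaged over per-sample networks). Motif hits are consumed as a table;
set semantics make duplicate hits harmless, and hits naming unknown TFs
warn and are ignored. Self-loops count toward both IN and OUT, the
convention of the crc-style software family. The bundled PWM scanner scores
summed log2-odds against a uniform background on both strands, with N
contributing zero, and thresholds at a fraction of the maximum achievable
score; it exists so network tests need no external scanner, not as a motif
discovery tool.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at desk scale:

- **Layout.** TSS, enhancers (1 kb) and super-enhancer clusters (three 1-kb
  peaks inside a 10 kb span) are shuffled and laid left-to-right with
  random 4–12 kb gaps. This guarantees non-overlap, keeps every enhancer
  more than 2.5 kb from every TSS, and separates elements beyond the
  peak-merge gap, while the ordering stays random.
- **Counts.** Per-locus per-sample fragment counts are negative-binomial
  with variance μ + φμ², φ = 0.05 by default and base mean 50 fragments per
  enhancer. φ represents residual sampling/technical variability: the
  biological tumor–normal differences are modelled explicitly as planted
  effects, not folded into the dispersion. At these defaults the per-pair
  background gain-call rate at FC > 2 is ≈ 3–4 %, i.e. recurrence of
  background calls stays low, as in a well-behaved cohort.
- **Planted effects.** Carriers of each planted VEL are chosen
  deterministically (⌈fraction·n⌉ patients after a seeded shuffle) so
  recurrence is exact rather than binomial. Carrier tumors draw gain loci at
  effect_ratio× the base mean (default 3×) and lost loci at 1/effect_ratio.
  SE clusters carry 10× base signal in all samples; a configurable subset
  additionally gains effect_ratio× in carrier tumors.
- **Library composition.** Each sample is padded with uniformly scattered
  background reads up to a fixed nominal depth (250,000 by default). Real
  libraries are dominated by genome-wide background, so planted differences
  barely move the total; without padding, planted gains would inflate tumor
  totals and RPM normalisation would depress every background locus in
  tumors, manufacturing spurious "lost" calls. The padding reproduces the
  compositional regime the RPM model assumes.
- **Peak emission.** A locus enters a sample's peak file when its count
  reaches a detection floor (5 by default), mimicking peak-caller
  sensitivity without implementing one.
- Subgroup structure is planted by a separate operation
  (`plant_subgroup_signal`) that adds extra reads at designated loci in the
  tumor samples of one subgroup (default 3× the other subgroups), on an
  independent seeded stream.

**Problem sizes.** Validation runs use 40 patient pairs, 2,000 enhancers,
200 planted gain + 50 planted lost VELs and 10 SE clusters on a 60 Mb toy
chromosome — large enough for recurrence thresholds and BH behaviour to be
non-trivial while a full pipeline run stays in the tens of seconds. The
published genome-scale QC minima (2,500 peaks, 500 VELs, 10 VSELs per
patient) refer to genome-wide peak universes far larger than this toy
genome, so desk-scale runs pass proportional minima (100 peaks, 50 VELs,
2 VSELs) through the same configuration knobs; the boundary semantics of
the genome-scale defaults are tested separately at their published values.

**What passing tests do not show.** The simulator draws independent counts
per locus — no copy-number confounding, GC or mappability bias, fragment-
length variation, correlated neighbouring loci, or peak-boundary jitter
(emitted peaks coincide with true loci, so merged-locus recurrence counting
is easier than with ragged real peak calls). Recovery rates on synthetic
cohorts are therefore upper bounds on real-data behaviour; the tests
validate the pipeline's logic and calibration, not ChIP-seq preprocessing.

## Known limitations

- RPM has no between-condition compositional correction; cohorts with very
  unequal signal-to-background ratios between tissues would need external
  scaling factors supplied via library-size overrides.
- The per-bp-mean vs region-sum choice for downstream signal is a
  documented convention (per-bp mean everywhere except SE ranking); users
  comparing against sum-based tools should rescale by region length.
- `paired_t_test` assumes approximately normal paired differences; at small
  cohort sizes the recurrence threshold machinery still runs but p-values
  are only as good as the t approximation.
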