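# Methods

This note documents the statistical model behind `sweepscan`, the
parameters that matter, the synthetic-data generator used for
validation, and the numerical and design choices made where conventions
diverge between tools.

## Scope and model

The package detects signatures of recent positive (directional)
selection that differ between two groups of diploid individuals drawn
from one breeding population — the *test* group, in which selection is
hypothesised, and a *control* group. A hard selective sweep drives one
haplotype to high frequency in the affected group, producing three
correlated signals at and around the selected locus: elevated
allele-frequency differentiation, unusually long haplotype
homozygosity, and loss of nucleotide diversity. Each signal is measured
per SNP and combined by empirical-outlier intersection rather than by a
parametric joint model; no demographic null is fitted, so thresholds
are relative (top tail of the observed genome), not absolute
significance levels.

Input is a phased multi-sample VCF of biallelic SNPs, a sample-to-group
table (or a phenotype table plus threshold rules), and gene models in
GFF3. Coordinates are 1-based inclusive everywhere internally; BED's
0-based half-open convention appears only in BED files.

### Variant QC

Retained sites must be biallelic SNPs on whitelisted (autosomal)
chromosomes with missing-genotype fraction ≤ `max_missing_fraction`
(default 0, i.e. complete calls), pooled MAF ≥ 0.05, and a
Hardy–Weinberg exact-test p-value ≥ 10⁻⁶. The HWE test is the
conditional exact test: given n diploids and the observed allele
counts, the probability of h heterozygotes is

P(h) = n! 2ʰ / (n_AA! h! n_aa!) · n_A! n_a! / (2n)!,

and the two-sided p-value sums P over all attainable h with
P(h) ≤ P(h_obs) (no mid-p correction — the convention of standard VCF
tooling). Computation is in log space via log-gamma with a 10⁻¹²
tie-tolerance; the test suite checks it against exact rational
enumeration up to n = 200. Choices fixed here: the test is applied to
the **pooled** sample (QC precedes any grouping); MAF = 0.05 exactly is
**kept** (removal rule is MAF < threshold); each removed variant is
attributed to the first failing filter in the fixed order
multiallelic → non-autosomal → missingness → MAF → HWE, which makes the
QC report a deterministic partition of the input.

### Weir–Cockerham F<sub>ST</sub>

Per site, for r = 2 populations, with n_i diploids with complete calls,
alt-allele frequencies p_i and *observed* heterozygote proportions h_i
(computed from genotype calls, not inferred from p):

- n̄ = (n₁+n₂)/2, n_c = 2n̄ − (n₁²+n₂²)/(2n̄), p̄ and h̄ the
  n-weighted means, s² = Σ nᵢ(pᵢ−p̄)²/n̄,
- a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)],
- b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)],
- c = h̄/2, θ̂ = a/(a+b+c).

Negative θ̂ is clamped to 0 (kept alongside as `fst_raw` for
diagnostics); sites with a+b+c = 0 (monomorphic in both groups) or with
fewer than two complete genotypes in either group are reported missing
and excluded from quantiles. The estimator requires n̄ > 1.

### EHH, iHH and XP-EHH

EHH at site x relative to a core is the fraction of haplotype pairs
identical at every variant between core and x, both ends inclusive;
EHH at the core itself is 1 by convention. Missing alleles count as a
distinct symbol, so an uncalled allele never extends homozygosity. iHH
is the trapezoidal area under EHH over physical distance (no genetic
map is assumed), both arms summed, with two truncation rules:

- an arm stops at the last informative site before a gap larger than
  `max_gap` (default 200,000 bp, the convention of standard haplotype
  scanners);
- integration stops where EHH falls below `cutoff` (default 0.05). The
  curve is treated as piecewise linear, and the final partial trapezoid
  up to the interpolated cutoff crossing is included — a documented
  dialect choice, verified against dense-grid numerical integration.

XP-EHH uses one shared integration extent for both groups, determined
by the **pooled** sample's EHH falling below the cutoff, then
xpehh_raw = ln(iHH_test/iHH_control), z-normalised over all non-missing
values genome-wide using the sample standard deviation (n−1). Sites
with zero area in either group (e.g. isolated SNPs) are missing.
Swapping the groups negates the statistic exactly.

### Diversity ratio

Per-site π = 2j(n−j)/(n(n−1)) over the n non-missing haplotypes of a
group (missing calls reduce n at that site). The contrast statistic is
log₂(π_control/π_test), so diversity loss in the test group is
positive. Sites with π = 0 in either group yield a missing ratio —
pseudocounts would distort the empirical tail — and their count is
logged because silent exclusions shape the quantiles.

### Outliers, regions, annotation

For each statistic the outlier threshold is the value of rank
⌈q·N⌉ from the top (default q = 0.01) among eligible values: all
non-missing values for F<sub>ST</sub> and the diversity ratio, positive
values only for XP-EHH (direction matters there; the other two are
already one-sided). All values tied with the threshold are kept, so the
set can exceed q·N — deterministic and never drops an arbitrary SNP. A
warning fires when fewer than 100/q eligible values are available.

Candidate SNPs are those in the intersection of the F<sub>ST</sub> and
XP-EHH sets ("2way" tier) and additionally of the diversity-ratio set
("3way" tier); both tiers are always produced in 3way mode. Each SNP
becomes a window of ±5,000 bp clipped to [1, chromosome length];
overlapping or book-ended windows merge. Genes overlap a region when
their closed intervals share ≥ 1 bp. All interval logic is checked
against all-pairs brute force in the tests.

## Synthetic data

`simdata.simulate` generates the package's validation data:

- **Background**: per-site alt-allele frequencies Beta(0.8, 0.8)
  rescaled to [0.1, 0.9]; haplotypes drawn independently per site, then
  locally correlated by 180 block-copy events per chromosome (geometric
  block length, mean 15 SNPs; 1–5 recipients per event), giving LD on
  the physical scale of tens of kb at the default SNP density.
- **Sweep**: within a span (default 500 kb) centred on the sweep
  position, a `carrier_frequency` fraction (default 0.9) of test-group
  haplotypes is replaced by one donor haplotype — a hard sweep with
  controllable geometry. Control haplotypes stay polymorphic, so the
  diversity ratio is defined inside the sweep.
- **QC guarantee**: background sites failing the QC predicates with a
  safety margin (MAF ≥ 0.08, HWE p ≥ 10⁻⁴) are redrawn; sweep-span
  sites keep their test-group haplotypes and only the control side is
  redrawn if pooled MAF would fail. Planted violations (low-MAF,
  missing-call, excess-homozygote sites) are inserted outside the sweep
  span at recorded positions, so QC removal counts are checkable
  exactly against the truth object.
- **Gene models** are tiled every 400 kb; one gene spans the swept
  interval so that any candidate region inside it annotates to a known
  ID.

Default dimensions — 15 + 15 diploids, two 10-Mb chromosomes with
2,500 SNPs each — are a desk-scale analogue of a small livestock
resequencing contrast, sized so that a full simulate-and-scan replicate
takes a few seconds and replicate batteries run in minutes on one CPU.

What the generator does **not** emulate: coalescent genealogies and
realistic allele-frequency spectra (rare variants are deliberately
absent so QC removals are exactly the planted ones), recombination-rate
variation, demography (bottlenecks, migration, family structure), soft
or incomplete sweeps beyond the single-donor model, and genotyping
error. Passing recovery tests therefore demonstrates that the
statistics and their integration respond correctly to the hard-sweep
geometry they target — not that power estimates transfer to any real
population.

Validated behaviour under these conditions (recomputed by
`scripts/acceptance.py` and the test suite, never hard-coded): the
three-way intersection localises the planted sweep to within 1 Mb in
≥ 80% of seeds; without a sweep, no region merging more than 3 windows
appears in ≥ 95% of seeds; QC recovers planted violation counts
exactly; two identical pipeline runs are byte-identical.

## Numerical choices and degenerate inputs

- HWE p-values: log-space enumeration, ties included with relative
  tolerance 10⁻¹²; monomorphic sites return 1.
- F<sub>ST</sub>: vectorised components shared between the scalar API
  and the scan; the independent test oracle is a separate straight-line
  transcription.
- EHH identity classes are tracked by iterative label refinement
  (relabelled each step, so no overflow for long haplotypes).
- Zero-variance XP-EHH input, empty eligible outlier sets, fewer than
  two haplotypes for EHH/π, and n̄ ≤ 1 for F<sub>ST</sub> are errors;
  per-site undefined values (0/0 F<sub>ST</sub>, zero iHH, zero π) are
  missing data, excluded from quantiles and counted in logs.
- Pipeline outputs use a fixed float format (`%.10g`), and the manifest
  contains no timestamps, making full runs reproducible bit for bit.

## Known limitations

- Phased input is required and phase is trusted; phasing error rates
  are not modelled. Unphased data must be phased upstream.
- Two populations only; no multi-population estimator, no windowed
  statistics, no iHS/nSL, no genetic-map support.
- Empirical top-1% thresholds are genome-relative: on small SNP sets
  the tails are noisy (the package warns), and the intersection of
  three small tails can be empty even over a true sweep.
- The exact HWE test is O(n) per site in the heterozygote enumeration;
  this is negligible at cohort scale but the QC stage is the slowest
  pure-Python loop at millions of sites.
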