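# Methods

## Scope and data model

All coordinates are 0-based, half-open (BED convention); readers convert
any 1-based dialect at the boundary. Overlap anywhere in the toolkit means
"at least one shared base", so bookended half-open intervals do **not**
overlap. CpG calls are per-dinucleotide (strand-merged); a reader option
collapses per-strand records at positions *p* and *p + 1* by summing
counts. Chromosomes order naturally (chr1 … chr22, then named
chromosomes); sex chromosomes are kept by I/O and excluded only where the
design procedure excludes them.

## Panel design

Candidates are filtered on four criteria: repeat fraction ≤ 0.6
(inclusive — reported descriptions of this cutoff vary between "below
60 %" and "≤ 60 %"; the comparator is exposed in `DesignConfig`), at
least 2 dynamic CpGs (per-CpG level spread across samples ≥ 0.3), length
≥ 100 bp, and autosomal location.

The region score is the sum of three components, each min–max rescaled to
[0, 1] *across the candidate set being scored*: dynamic-CpG density
(count / length), maximum pairwise difference of region-mean methylation,
and a 0/1 enhancer-or-promoter overlap flag. A component that is constant
across the set rescales to all-zero: a non-discriminating component
should contribute no rank information. Dynamic-CpG counting uses per-CpG
levels; the maximum-difference component uses region means.

**Balanced selection.** The published procedure states only its effect
(regions from over-represented origins are skipped despite higher
scores); the mechanism here is a deterministic balanced-greedy rule: each
region's *origin* is the sample with minimal region methylation
(lexicographic tie-break), and at every step the origin with the smallest
cumulative selected bases (ties lexicographic) contributes its
best-scoring remaining region, until the budget is crossed — the crossing
region is kept, since the published budgets ("53 Mb", "30 Mb") are
approximate. This rule is oracle-testable: with a single origin it
degenerates to plain greedy-by-score, and at termination any two origins
with non-empty pools differ in cumulative bases by at most one region
length. eQTL rescue then adds every unselected region overlapping an eQTL
interval, in rank order. Merging across source lists concatenates
provenance labels; a 450K-array-derived source is just another candidate
list, with no array-specific code.

## Tile-based DMR calling

Tiles are anchored to a fixed genome grid (multiples of the 200-bp tile
size) and never clipped, so tiles are comparable across panels; every
grid tile sharing ≥ 1 base with a panel region is kept. Per tile and
sample, methylated and total CpG read counts are summed; the pooled ratio
is algebraically the coverage-weighted mean of per-CpG levels, which the
tests check to machine precision. The retention filter requires total
reads **strictly greater than** 10 (summed CpG coverage stands in for
read count, which the tile abstraction cannot observe) in at least 70 %
of samples (inclusive).

Each sample pair is tested per tile with a two-sided Fisher's exact test
under the probability-mass rule (sum of hypergeometric probabilities of
tables no more probable than the observed one — stated explicitly because
two-sided conventions differ). The implementation works in exact integer
arithmetic on binomial-coefficient weights, so tied tables are resolved
exactly rather than by a floating-point tolerance; it is cross-checked in
tests against both an exact-rational enumeration oracle and
`scipy.stats.fisher_exact`. Benjamini–Hochberg correction (statsmodels'
step-up) is applied per sample pair across that pair's tested tiles;
note that BH is **not** idempotent in general (p = (0, 0.5, 1) ↦
(0, 0.75, 1) ↦ (0, 1, 1)) — re-application can only raise q, which is the
property the tests assert.

A tile is differentially methylated at q ≤ 0.05 and |Δ| ≥ 0.3 (inclusive;
the comparator is exposed since descriptions vary between "≥ 0.3" and
"exceeded 0.3"). Tiles with zero reads in either sample are skipped for
that pair, not imputed. Significant tiles merge into a DMR when the
inter-tile gap is strictly below 400 bp **and** the direction matches; a
DMR carries a single hypo/hyper direction (relative to the first sample),
so opposite-direction runs stay separate. The 400-bp default suits
cohort-wide DMR summaries; two-sample comparisons historically used
200 bp, available via `--merge-dist`. The dynamic fraction is the share
of retained tiles significant in at least one pairwise comparison.
DMR-set matching labels a query DMR *shared* when its distance to the
nearest reference interval is ≤ 300 bp (overlap = 0).

## Coverage model

Per-base depth is Poisson(λ). The cohort requirement — each CpG at depth
≥ k in a fraction *f* of N samples with probability *p* — is read as a
joint requirement over the ⌈fN⌉ samples:
[P(Poisson(λ) ≥ k)]^⌈fN⌉ ≥ p. λ is found by bisection (absolute tolerance
10⁻⁶, bracket verified in tests: the tail-power fails at λ − tol and holds
at λ). An alternative binomial-over-samples reading (≥ ⌈fN⌉ of N succeed)
is available as `mode="binomial"`; it yields systematically lower budgets
and does not reproduce the published 74 M / 1.7 B pair, which is why the
joint reading is the default. Raw reads per sample are
λ·L / ℓ / ((1 − d)(1 − o)): duplicates and off-target reads inflate the
requirement multiplicatively, the natural reading of "adjusted for". At
the published parameterizations the model gives 72.6 M (targeted) and
1.71 B (WGBS) reads per sample. The separately published single-library
figure of 48 M reads at 30× is not reproduced by any parameterization of
this model that we found; it is presumably based on additional empirical
adjustments and is not used as a reference point.

## Synthetic data

The generator emulates the statistical structure the caller assumes, at
desk scale (defaults: 2 chromosomes × 1 Mb, mean CpG spacing 80 bp, 2
cell types, 100 planted DMRs of 400–1000 bp separated by ≥ 600 bp,
baseline methylation Beta(8, 2) (mean 0.8) shared across cell types,
hypomethylation drop Δ = 0.5 floored at 0, Poisson(30) coverage, 0.4 %
conversion failure matching a 99.6 % bisulfite conversion rate). Planted
DMRs are CpG-enriched: every fully contained 200-bp grid tile is
guaranteed ≥ 3 CpGs, mirroring the elevated CpG density of regulatory
DMRs relative to bulk genome. With ≥ 2 cell types the affected subset of
a DMR is a random *proper* subset — a region shifted in every cell type
would not be differential within the set. Only conversion failure
(unmethylated C read as methylated) is modelled; over-conversion of
methylated C is zero by default, matching the single conversion metric
assays typically report. Randomness comes from one seed; per-cell-type
read draws use child seeds spawned deterministically from it, so
generation order never changes results and everything is bit-reproducible
per seed and version.

What the generator does **not** emulate: capture-efficiency and GC bias,
PCR duplicates, read-level structure (no FASTQ), correlated methylation
beyond the planted blocks, SNPs, and hemimethylation. Passing recovery
tests therefore show the caller's statistics behave correctly under the
model's assumptions, not that real capture data meet those assumptions.

**Recovery benchmark.** Truth is defined at tile resolution: a tile is
positive for a sample pair when its noise-free tile-level difference
(unweighted mean of true CpG levels, the expectation of the pooled ratio
under uniform coverage) reaches the caller's own 0.3 threshold. This
classifies DMR-edge tiles honestly — a tile whose true mixture difference
is below threshold is a negative, and calling it counts against
precision. Under the default conditions the caller reaches ≈ 0.97
sensitivity and ≈ 0.98 precision at tile level (the test requires ≥ 0.9
for both), in about three seconds.

## Numerical and interface choices

- Fisher p-values: exact rationals → one final float division.
- Poisson tails via `scipy.stats.poisson.sf`; checked against direct
  factorial summation for k ≤ 100.
- Min–max rescaling, origin assignment, and balanced selection break all
  ties lexicographically, making panel design fully deterministic.
- CLI exit codes: 0 success, 1 data/validation error (including missing
  input files, reported with the path), 2 usage error. Parameter
  precedence: defaults < `--config` YAML < explicit flags; every
  output-producing command writes a `run_manifest.yaml`, and re-running
  with the manifest's parameters reproduces byte-identical outputs.
- Problem sizes in tests (1–2 Mb genomes, ≤ 10⁴ tiles) keep the full
  suite under ten seconds while leaving every statistical check
  well-powered; they are the package's own benchmark conditions.

## Known limitations

- The published capture panel cannot be regenerated: its candidate DMR
  inputs (two WGBS-derived DMR collections, tissue-specific DMRs, a 450K
  array set) and the vendor's probe-level optimization are not public
  inputs to this package. The module reproduces the *procedure*; tests
  validate it on constructed and simulated candidates.
- The balanced-selection mechanism is this package's deterministic
  formalization of a procedure whose published description states only
  its intent.
- The coverage model is an upper-bound approximation: it ignores
  assay-specific coverage heterogeneity.
- Tile-level Fisher testing treats reads as independent Bernoulli calls;
  it does not model biological replicate variance (no beta-binomial
  dispersion), which is precisely the simplicity the tile pipeline
  trades for robustness at high coverage.
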