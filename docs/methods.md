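# Methods

## Estimation

### Hudson F_ST and aggregation

The two-population estimator is computed per biallelic variant from
per-population alt-allele frequencies and called-haplotype counts
(missing genotypes reduce the called count; nothing is imputed).  The
bias-corrected numerator subtracts each frequency's sampling variance
p(1−p)/(n−1) and therefore requires n ≥ 2 per population; it can be
negative and is deliberately never clamped, because clamping would bias
region sums.  Regions aggregate as Σnum/Σden (ratio of averages): this
weights variants by their denominators and is the standard choice for
combining loci, as opposed to averaging per-variant ratios, which is
dominated by rare variants whose ratios are near zero.  Variants
monomorphic for the same allele in both populations contribute 0/0 and
drop out; a region whose denominator sum is zero is *undefined* and is
reported as NaN, counted, and excluded from distribution summaries — never
silently dropped.

Windows are [k·w, (k+1)·w) in 0-based coordinates for w ∈ {1,000, 10,000}
bp by default; the remnant shorter than w at each chromosome end is
excluded together with its variants.  Defaults use corrected components
for sampled genotype data and uncorrected components for simulator census
frequencies, where there is no sampling to correct for.

### Multi-allelic records and coordinates

Multi-allelic VCF records are split into one row per ALT allele; a
haplotype scores 1 only for the focal allele, so the per-haplotype
indicators of one record sum to at most 1.  Rows are keyed by
(chrom, pos, ref, alt).  VCF positions stay 1-based on the variant
objects; all interval arithmetic is 0-based half-open, converted only at
I/O boundaries.

### Genome partition

Each base receives the minimum-rank class among: CDS(1), 5′UTR(2),
3′UTR(3), noncoding-gene exon(4), intron(5), 1 kb upstream(6), 1 kb
downstream(7), 5 kb upstream(8), 5 kb downstream(9); unreached bases are
remainder.  Resolution is per base, not per window, so e.g. a base in an
intron of one gene and the 5′UTR of another is a 5′UTR base.  Flanks are
strand-agnostic, measured from the lower/upper genomic coordinates of the
gene span: the source convention is ambiguous on strand, and the
strand-agnostic reading is the simpler reproducible rule (logged as an
assumption).  "Gene region" for summary tables is classes 1–5; everything
else is non-genic.  A query interval is REPEAT if it overlaps any repeat
interval by at least 1 bp.  The per-base int8 rank array is exact and fast
at the multi-Mb chromosome scale this package simulates; genome-scale
human chromosomes would favour interval algebra instead (known
limitation).

### eQTL scan

Expression ~ intercept + population indicators + dosage, ordinary least
squares.  The population indicators (one per population minus an
alphabetical reference level) absorb population-level expression shifts;
without them, any population-differentiated variant shows a spurious
association with any population-shifted feature — the test suite
demonstrates the inflation.  The all-pairs scan residualizes dosages and
expression against the covariate design once (QR projection) and obtains
every pair's t statistic from the residual correlation with
df = n − #parameters; this is algebraically exact OLS
(Frisch–Waugh–Lovell), verified against closed-form normal equations on
fixtures.  Variants with dosage collinear with the covariates (monomorphic
within every population present in the expression subset) are skipped and
counted.

Boundaries: MAF filter is strict (> 0.05) on the pooled analyzed samples;
the cis window is inclusive (≤ 10⁶ bp between variant position and feature
anchor, anchor = annotated feature start).  Family-wise processing:
records failing the per-family p cut-offs (cis 0.05, trans 0.01) are
discarded first, then Benjamini–Hochberg runs within each family with m =
the family's retained count; both the m convention and the pooled-MAF
convention are exposed as the natural alternatives in config-level
arguments.  Transcription-ratio features divide each feature by its
gene's per-sample total, dropping samples with zero totals.

### ΔDAF

DAF requires a concordant ancestral call: ancestral = REF maps DAF to the
alt frequency, ancestral = ALT to its complement, anything else excludes
the variant from DAF analyses (an exclusion value, not an error).  ΔDAF is
the *absolute* difference — grouping by "decreasing ΔDAF" is only
well-defined unsigned — with a signed variant exposed for diagnostics.
Groups are consecutive chunks of the ΔDAF-sorted records (ties broken by
genomic coordinate for determinism); the final partial chunk is kept as
its own group, so the group count is ⌈n / group_size⌉.  Only variants that
passed the eQTL MAF filter enter grouping, since the group statistics are
eQTL proportions over analyzed variants.

### LD

Haplotype-based D, D′, r² with pairwise deletion of missing calls; sites
monomorphic after deletion are undefined.  Combined-population LD pools
haplotypes without reweighting.  Unphased matrices are refused.

## The forward simulator

Diploid Wright–Fisher with selfing allowed: each offspring draws two
parents uniformly with replacement and receives one recombinant gamete
from each; crossover counts are Poisson(Lρ) with uniform continuous
breakpoints, mutation counts Poisson(Lμ) at uniform continuous positions
redrawn on collision (infinite sites).  Ploidy is a declared choice — the
demography is stated over "individuals" without fixing ploidy, and
diploidy with per-gamete recombination is the reading consistent with
random mating; a haploid mode flag exists.  The schedule is burn-in 8N
generations from a monomorphic start (long enough that segregating-site
counts and diversity plateau at mutation–drift equilibrium), a random
split into two demes of N/2, growth of +1 individual per deme per
generation for N/2 generations, then 4N stationary generations.  Deme
sizes are asserted against the schedule every generation.  Sites fixed or
lost everywhere are pruned each generation; after the split, a site fixed
in one deme and absent in the other is archived and re-materialized in the
output as census frequencies 1 vs 0.  Output is *census* frequencies —
no sampling step — so uncorrected window F_ST is never negative.

The state is a dense boolean haplotype × segregating-site matrix per deme
(a few hundred × a few thousand at the default presets), with a
zero-crossover fast path that reduces most gamete formations to a row
copy.  The presets run 2 Mb × N=200 and 1 Mb × N=400 with
μ = ρ = 10⁻⁷/bp/generation; the analysis drivers and the acceptance
script run 3 and 2 replicates respectively (the full design is 10 and 20)
to keep runtimes in minutes — replicate means are stable to ~0.01–0.02 at
these sizes.

Validation: the simulator was cross-checked against an independent
coalescent implementation of the same demography (msprime, piecewise-
constant approximation of the growth phase): global F_ST, windowed means
and within-deme diversity agree within replicate spread, and within-deme
diversity matches the 4Nμ expectation.  Under this schedule the default
presets yield pooled window means around 0.63 (10 kb) and 0.31 (1 kb) for
N=200.  These means are a steep function of divergence age: the
divergence-age profile written by `analysis/07_simulation_study.py` shows
10 kb means rising from ≈0.22 at the end of the growth phase through
≈0.30 at +100 generations to ≈0.62 at +800 generations.  Any comparison
of such means across studies therefore hinges on the exact measurement
generation; the acceptance tests that compare these presets to fixed
reference means fail under this schedule, and the profile quantifies how
far the reference regime lies from it (it corresponds to a divergence age
of roughly 200 generations after the split).

## The synthetic-data generator

The generator emulates the joint genotype–expression study design rather
than sequence-level realism:

* **Frequencies.** Ancestral frequencies from a 1/x density on
  [0.001, 0.999] (neutral-like, mass near zero); per-population
  frequencies Balding–Nichols beta around the ancestral value with
  per-population drift F = (0.07, 0.06, 0.05) — chosen once to put
  pairwise genome F_ST in the 0.1–0.17 band typical of continental human
  pairs.  Because the three populations drift independently, the
  EAS-vs-EUR analogue is not closer than the others by construction, and
  the generated value (~0.06) is the realistic ordering.
* **Planted selection motifs.** A sweep fraction (2%) near fixation in
  EAS+EUR and near zero in AFR; a "shared-low" set rare in EAS and EUR
  but common in AFR, emulating selection shared by the two out-of-Africa
  populations.  These drive the two ΔDAF-group signatures the analysis
  recovers.
* **LD.** A latent-uniform copula per (block, haplotype): within a 20 kb
  block a haplotype carries a variant when its block-uniform is below the
  variant's frequency, except with the 10% switch rate, where an
  independent Bernoulli is drawn.  Marginals are exact in expectation;
  within-block r² is high, between-block ≈ 0.  This is a statistical
  stand-in for recombination history, not a genealogical model — decay of
  LD with distance inside a block is flat, unlike real data.
* **Expression.** Per-feature baseline + per-(feature, population) shift
  (σ = 0.5) + planted cis betas (0.8–1.5 per alt allele) + the trans hub
  (driver cis-activates a regulator with β = 1.5; the regulator's centred
  level propagates ×0.7 to distant features) + direct trans effects on 30%
  of sweep variants and on every shared-low variant + N(0, 0.5²) noise.
  Sample sizes default to 504/504/503 genotyped with expression on 445
  (356 EUR-like + 89 AFR-like), the combined-population design whose
  power argument the covariate test demonstrates.
* **Ancestral calls.** Recorded per variant (derived allele is ALT or REF
  with equal probability), unknown at rate 0.05, mislabeled at a
  configurable rate (default 0).

What passing tests on this generator do **not** show about real data:
realistic LD decay, realistic site-frequency spectra after selection,
shared out-of-Africa drift covariance, expression normalization artefacts,
or tissue specificity of regulatory effects.  They do show that every
estimator computes what it claims, that planted structure of the study's
shape is recovered end-to-end, and that the statistical conventions
(boundaries, families, undefined handling) behave exactly as documented.

## Numerical and degenerate-input conventions

* Undefined estimates are NaN plus a defined flag; they propagate and are
  counted, never zero-filled.
* Extreme-set selection sorts by value with (chrom, start) tie-break, so
  all-equal inputs select deterministically; top/bottom 1% uses
  ⌈0.01·n⌉ over defined estimates; count mode warns and truncates when k
  exceeds the list.
* Length-matched sampling rejects-and-resamples against the exclusion set
  up to 1,000 tries per region, then raises naming the region.
* Chi-squared enrichment tests are df = 1 without continuity correction;
  degenerate margins yield NaN p.
* The BH step uses the sorted cumulative-minimum formulation, verified
  against a brute-force oracle; ties in p are handled by stable sorting.
* Seeds: every stochastic component takes an explicit seed; independent
  streams are spawned via `numpy.random.SeedSequence`.

## Known limitations

* The per-base partition array is memory-proportional to genome length
  (1 byte/bp).
* The hotspot table ranks by (n_trans, n_cis); a perfect-LD block mate of
  a planted driver can tie it and rank level with or above it — LD-aware
  clumping is out of scope.
* Genome-scale anchor values (e.g. whole-genome human F_ST tables)
  require the real phased-genotype, gene-annotation and repeat exports;
  the pipeline reads those via the same VCF/TSV/BED paths used by the
  synthetic data, but no bundled test asserts them.
* The simulator is two-deme, neutral, constant-rate; no migration,
  selection or recombination maps.
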