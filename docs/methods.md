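# Methods

## Scope and data model

The pipeline consumes phased, complete (no missing calls), biallelic
haplotypes at SNP-chip density.  Haplotypes are a 2N × L 0/1 matrix tied to
a variant map (chromosome, physical bp, genetic cM).  Allele 1 is treated
as "derived" and allele 0 as "ancestral" purely by coding: the scan
statistics are antisymmetric under recoding a core SNP, and both score
signs are interpreted, so an arbitrary but consistent polarization is
sufficient (random assignment of ancestral state is known to leave iHS
rankings essentially unchanged).  Internal interval coordinates are 1-based
inclusive; BED is converted at the boundary.  When no genetic map is
supplied, genetic positions default to 1 cM/Mb (pos_cm = pos_bp × 10⁻⁶),
logged.

## EHH and the three statistics

For a core SNP, allele class c with n_c carriers and an extent covering
sites core..j,

    EHH(j) = Σ_h C(n_h, 2) / C(n_c, 2)

over the distinct haplotype strings h among the carriers.  The computation
refines a haplotype partition site by site outward, so it is O(sites × n_c)
rather than pairwise.  Extension stops when EHH drops below the decay
cutoff (default 0.05), when the next marker lies beyond the maximum
extension from the core (default 1 Mb), when the gap to the next marker
exceeds the maximum gap (default 200 kb), or at the chromosome end.  The
last two leave the curve *truncated*; truncated cores are skipped by
default (`trunc_ok` retains them flagged) because their integrals are not
comparable genome-wide.  Stopping at the maximum extension is normal
termination.  There is no gap-scaling penalty: a gap either terminates the
direction or does not.

iHH is the trapezoidal integral of EHH against genetic distance in cM,
summed over both directions, *including* the final trapezoid that crosses
the cutoff.  Raw statistics:

* **iHS** = ln(iHH₁/iHH₀), each allele class extending until its own
  cutoff.  Cores are skipped, with a recorded reason, when the core MAF is
  below 0.05, an allele class has fewer than two haplotypes, any curve is
  truncated, or an iHH is zero.
* **XP-EHH** = ln(iHH_focal/iHH_reference).  The extent is fixed by the
  EHH decay of the pooled two-population sample; each population's
  all-haplotype EHH is integrated over exactly that extent.  Pooled and
  per-population curves include the core site itself, so their zero-extent
  value is the core-site homozygosity (class-restricted curves start at 1).
  The reported allele frequency is the focal-population frequency.
* **nSL** = ln(SL₁/SL₀), where SL_c is the mean over class pairs of the
  number of consecutive sites (counting the core) over which the pair is
  identical, capped at 100 sites per direction (the conventional default;
  no physical-distance or gap limit, no map).  The chromosome end simply
  ends a tract.

## Standardization and significance

Raw scores are pooled over all chromosomes and z-scored within 100
equal-width allele-frequency bins (SD with n−1 denominator).  Bins holding
fewer than `min_bin_size` (default 2) scores merge into the nearest
populated bin — a deterministic, logged rule chosen because the upstream
convention for sparse bins is undocumented; this is flagged as a divergence
risk when comparing against other implementations.  XP-EHH is standardized
with the same frequency-binned procedure as iHS and nSL (a single-bin mode
is available via `NormParams(n_bins=1)`).  A SNP is significant iff
|z| > 2 strictly; the sign is retained.

## Consensus sweep regions

Window overlap between two SNPs' ±75 kb flanks is equivalent to a centre
distance ≤ 150 kb, so the "sequentially intersecting" accretion closure is
computed exactly as connected components of significant SNPs chained by
gaps ≤ 2 × flank.  A component becomes a region iff it contains a rule-(a)
SNP (≥ 2 statistics) or a rule-(b) pair (window-overlapping, jointly ≥ 2
distinct statistics; the stricter per-SNP reading is available via
`rule_b_strict` but makes rule (b) redundant with rule (a)).  Lone
single-statistic SNPs never seed and remain unassigned.  Region extent is
the union of member windows, clipped at position 1; region length is
end − start, matching the convention of the published span arithmetic
(87,639 = 88,224,250 − 88,136,611).  Components are maximal, so regions on
a chromosome are disjoint by construction and merging is implicit.

## Annotation

Genes are assigned by any-overlap (≥ 1 bp, 1-based inclusive) with the
region extended by 75 kb on each side.  Any-overlap rather than
both-boundary containment was chosen because large genes (e.g. a 154 kb
LDL-receptor-family gene among the bundled candidates) could never be fully
contained in a typical flank.  Interval intersection follows
bedtools-intersect semantics.  Enrichment scores are −log₁₀ of a Fisher
exact P (1.3 ↔ 0.05); a cluster's score is −log₁₀ of the geometric mean of
member P-values.  The enrichment *database* (term membership, kappa
clustering) is out of scope; only the score arithmetic and interval
mechanics are implemented.  Two reference tables are bundled: the 12
candidate genes of the three enriched functional clusters (sheep Oar v3.1
and cattle UMD3.1 coordinates, Ensembl Genes 91) and the per-chromosome
sweep-region summary of the Djallonké scan used for the totals worked
example.

## Quality control

Filter order: non-autosomal markers → samples by call rate (< 99%) →
SNPs by call rate (< 90%) → MAF < 0.05 → Hardy–Weinberg exact P ≤ 0.001.
The order (samples before SNPs, MAF before HWE) follows common PLINK
practice and is recorded in the QC report so discrepancies are diagnosable.
The HWE test is the exact conditional test of the heterozygote count given
allele counts (P = sum of probabilities of all heterozygote counts no more
probable than the observed one), computed on all samples pooled; a
per-population mode exists as a flag.  Any missingness surviving QC is a
hard error — the haplotype statistics are undefined under missing data and
nothing is imputed.

## Population-genetic summaries

F_ST uses the Weir & Cockerham (1984) two-allele variance components a, b,
c per SNP; the genome-wide value is the weighted ratio of sums
Σa / Σ(a+b+c).  Monomorphic SNPs contribute zero components; negative
estimates are reported unclamped.  Inbreeding F per individual is
(O − E)/(L − E) with O the observed homozygous site count and E the
expected count under HWE at pooled frequencies including the 2n/(2n−1)
small-sample factor on expected heterozygosity (the convention of the
common variant-toolkit implementation); L − E = 0 yields a flagged NaN.

## Synthetic data

The generator is a Li–Stephens founder mosaic, not a coalescent
simulation.  Per site, an ancestral frequency is drawn with a folded,
chip-like spectrum (minor allele frequency uniform on [0.05, 0.5], random
orientation) and K founder haplotypes are sampled from it.  Each sample
haplotype copies a founder, switching founder identity between adjacent
sites with probability 1 − exp(−ρ·gap) and flipping each copied allele
with probability ε.  Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_samples / n_samples_ref | 184 / 12 | the study-scale sample sizes |
| marker spacing | 55 kb | medium-density chip (~1 SNP / 55 kb) |
| site placement | jittered regular grid | designed arrays cover the genome evenly; the largest gap stays < 2× spacing, below the 200 kb max-gap |
| K founders | 40 | haplotype diversity high enough that the EHH founder-sharing floor (~1/K) lies below the 0.05 decay cutoff, as in real data |
| ρ switch rate | 10⁻⁶ /bp | mean copying tract 1 Mb, giving LD decay on the 0.1–1 Mb scale typical of livestock chip data |
| ε flip rate | 0.002 /site/copy | within-founder haplotype diversity plus genotyping noise |
| MAF floor | 0.05 | sites below it are dropped (QC attrition), so n_sites is a pre-QC target |

A planted sweep forces ⌈p·2N⌉ carrier haplotypes to allele 1 at the core
and makes each copy one of k sweep founders *exactly* (no flip noise) over
an interval with Exponential(λ) one-sided lengths (k = 1 hard, k > 1
soft).  Population divergence applies the Balding–Nichols construction
symmetrically: each population's founder panel is resampled around the
shared ancestral frequencies with variance d·p(1−p).  Symmetric drift was
chosen over one-sided perturbation of the second population because the
one-sided form cannot exceed weighted F_ST ≈ 0.5 even at d = 1, whereas
full drift should produce fixed differences (F_ST → 1).  The calibration
`calibrate_divergence` maps d to weighted F_ST; d = 0.05 lands at
F_ST ≈ 0.066–0.075 at study-scale sample sizes, i.e. the low-differentiation
regime of the motivating populations is reachable with the documented
mapping.  All randomness flows from one seed through four documented
sub-streams (sites/founders, focal mosaics, sweep, second population), so
enabling one feature never perturbs another's draws.

What the generator does *not* emulate: demographic history (growth,
migration, bottlenecks), recombination-rate variation, chip ascertainment
bias beyond the MAF floor, genotyping error structure, and real inbreeding
(simulated individuals are panmictic, so inbreeding F ≈ 0 even though the
real populations show 0.01–0.06).  Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated model, not
the demographic realism of any particular population.

## Problem sizes used by tests and the acceptance script

Neutral calibration: 50 samples × 2,600 pre-QC sites (~143 Mb), yielding
≥ 2,400 scored cores.  Sweep recovery: 20 replicates of 50 samples × 1,000
sites with a hard sweep at p = 0.7, λ = 2 Mb, judged against the 95th
percentile of |raw iHS| at matched-frequency cores of paired neutral
replicates; full-pipeline recovery: 10 replicates with 12 reference
samples at d = 0.05.  These sizes were chosen as the smallest at which the
quantities of interest are stable; all are re-derived at run time from the
seed.

## Numerical and degenerate-input choices

* The partition refinement relabels groups with `np.unique` each step, so
  group labels never overflow.
* An EHH value of exactly 0 ends extension (all further contributions are
  zero).
* Monomorphic cores and classes with < 2 haplotypes are skip-reasons, not
  errors, in scans; they are hard errors in the standalone `ehh_curve`.
* A frequency bin with zero spread raises rather than emitting infinities.
* Exact HWE P is clamped to 1.0 against floating-point accumulation.
* Sparse-bin merging ties break toward the lower-frequency bin.
* Regions are keyed and ordered by (chromosome, position) throughout, so
  output is independent of input ordering.

## Known limitations

* No phasing and no imputation: input must be phased and complete.
* PLINK `.ped` round trips are not bit-identical in allele coding (the
  first-seen-as-0 recode loses the original symbols); VCF round trips are
  exact.
* The un-binned upstream convention for standardizing XP-EHH is available
  but not the default; comparisons with other tools should pin this choice.
* Sweep-region lengths depend on the window-union convention; tools that
  report SNP-to-SNP spans will give systematically shorter regions.
* The enrichment machinery covers only the score transform; no term
  database ships with the package.
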