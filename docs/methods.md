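# Methods

This note documents the models behind each module, the parameter and
numerical conventions, what the synthetic herd does and does not emulate,
and the design choices made where conventions genuinely diverge.

## Quality control

Two tracks are deliberately kept separate, because the filters that make a
panel safe for LD and prediction work (MAF, Hardy–Weinberg) would erase
exactly the signal the homozygosity analyses need — autozygous regions are
depleted of heterozygotes and enriched for low-MAF homozygotes.

* Standard track, in fixed order: marker call rate < 0.90 removed; exact
  Hardy–Weinberg p < 1e−6 removed; MAF < 0.05 removed; of markers sharing
  a physical position, all but one removed (the highest call rate wins,
  ties keep map order); finally samples with call rate < 0.90 removed.
  Boundary values survive (strict inequalities).
* ROH track: markers with GenCall ≤ 0.7 or GenTrain ≤ 0.4 removed
  (inclusive cuts, taken literally from how array-quality thresholds are
  usually quoted), then samples with > 5% missingness. No MAF, HWE or LD
  filters. GenCall/GenTrain are treated as per-SNP scores supplied in a
  sidecar table; per-call scores are not modelled.

The Hardy–Weinberg test is the exact conditional (Levene–Haldane) test:
given sample size and minor-allele count, the p-value sums the
probabilities of all heterozygote counts no more probable than the
observed one. No mid-p correction. Probabilities are evaluated in log
space (`gammaln`), normalised, and the ≤ comparison allows a 1e−12
relative slack so ties are counted as ties despite floating point.

## LD and the historical effective size

r² is the squared Pearson correlation of genotype dosages (0/1/2), not the
haplotype-phase r²: it needs no phasing, and for the purpose of Ne
estimation its expectation behaves the same to the accuracy the method
supports. Missing data are handled pairwise-complete (individuals missing
at either marker are dropped for that pair). Pairs where either marker is
monomorphic in the pairwise-complete subset are undefined and excluded
from bins — setting them to zero would drag bin means toward zero in
sparse panels.

Pairs are restricted to the same chromosome and distances strictly below
10 Mb, binned in half-open 100 kb intervals [lo, hi). The per-bin mean r²
is converted to Nₑ ≈ (1/4c)(1/r² − α), with c the bin midpoint distance
mapped through a configurable cM/Mb ratio (default 1.25, a common cattle
genome average; 1.0 for the simulator's map), and α = 2 when mutation is
assumed to contribute, 1 otherwise. Each bin speaks about t = 1/(2c)
generations ago; bins whose t rounds to the same integer are aggregated
to a mean ± SD trajectory point. Negative Nₑ values (possible when mean
r² > 1/α) truncate to zero. The t = 1/(2c) mapping is exposed as a
configurable constant because the literature states it in several
typographically mangled forms; 1/(2c) is the only version dimensionally
consistent with trajectories spanning 5–100 generations.

Known bias: estimates for t substantially larger than the number of
simulated (or real) generations of drift reflect a population closer to
linkage equilibrium than the equilibrium model assumes, and come out too
high. This is inherent to the estimator, not a defect of the
implementation, and is why recovery checks average over a window of t
rather than reading single points.

## Runs of homozygosity

Detection: per individual and chromosome, maximal runs of consecutive
homozygous calls, split wherever adjacent SNPs are more than `max_gap_bp`
(1 Mb) apart, then kept when the run has ≥ `min_snps` (15) SNPs and
average density `length/n_snps` ≤ `max_bp_per_snp` (100 kb). Heterozygous
and missing calls both break runs by default — the strictest reading of
"consecutive homozygous SNPs" — with `allow_het_in_run` /
`allow_missing_in_run` available because genotyping error makes small
allowances defensible on real arrays; with allowances the detector returns
maximal windows that start and end homozygous. Density is a whole-run
average, not per-window. Segment length is `end_bp − start_bp`, the
span of the observed SNPs; the underlying IBD segment is always somewhat
longer, so F_ROH is conservative.

F_ROH = Σ length of segments strictly longer than the threshold (4, 8 or
16 Mb) divided by L_AUTOSOME. L_AUTOSOME defaults to 2,499,624,571 bp
(the SNP-covered autosome length of a bovine 50K panel) and, in the
pipeline, to the SNP-covered span of the loaded map. A consequence worth
knowing: nonzero F_ROH>16Mb can never be below 16 Mb / L_AUTOSOME ≈ 0.006,
which puts a visible gap in its distribution.

Ancestor dating: a segment inherited intact from an ancestor g
generations back has expected genetic length 100/(2g) cM; inverting at
1 cM ≈ 1 Mb and flooring gives g = ⌊100/(2·L_cM)⌋, hence the familiar
12/6/3-generation labels for 4/8/16 Mb. Flooring (12.5 → 12) matches the
conventional labels.

Contemporary effective size: ΔF is the unweighted OLS slope of F_ROH on
birth year multiplied by the generation interval (default 5.66 years, an
input constant from pedigree analysis; 1.0 for simulated herds where
cohorts are generations), and Nₑ = 1/(2ΔF). A non-positive ΔF is
reported as undefined rather than clamped — it means no detectable
inbreeding accumulation, not an infinite population. Each length
threshold gets its own regression. Wright's pedigree F (recursive
kinship; unknown parents contribute nothing) provides the pedigree
benchmark, and cohort means carry percentile-bootstrap 95% intervals.

Islands: per-SNP ROH incidence (fraction of individuals whose qualifying
segment covers the position); outliers are incidence > Q3 + 1.5·IQR of
the genome-wide distribution with quartiles by midpoint interpolation
(recorded in output metadata); maximal runs of consecutive outlier SNPs
within a chromosome become islands. With a constant incidence vector the
IQR is zero and nothing exceeds Q3, so no islands are called.

## GBLUP

Model: y = 1μ + Zg + e, g ~ N(0, Gσ²g), e ~ N(0, Rσ²e), solved through
the mixed-model equations at a fixed variance ratio λ = σ²e/σ²g =
(1 − h²)/h², with h² supplied per trait (pseudo-phenotype heritabilities
are rarely published; a REML search was considered out of proportion for
the intended use). G is VanRaden method 1, W W′/(2Σp(1−p)), frequencies
observed over the combined sample, missing dosages imputed to 2p; 0.01·I
is added before inversion (logged in result metadata) because small-herd
G matrices with close relatives are routinely near-singular.

Residual weights: the record weight is w = r²/(1 − r²) from the
reliability r², entering the residual covariance as R_ii = 1/w =
(1 − r²)/r² — reliable records get small residual variance. Because the
weight is sometimes printed as if it sat on R's diagonal directly, a
`weights="as_printed"` option reproduces that literal convention; the
convention used is always recorded in the output. Weights apply to EBV
and dEBV runs alike, with an unweighted option.

Validation is forward prediction: reference = focal-breed animals born up
to the cutoff year (plus donor breeds in the multi-breed scenario; donors
alone in the across-breed scenario, where every focal animal is
validated). dEBV records below reliability 0.30 are discarded; a trait
whose validation set then shrinks below three records is reported
not-evaluable rather than silently skipped. Accuracy is the Pearson
correlation of GEBV with the validation pseudo-phenotypes; bootstrap
resampling of validation animals (default 10,000 reps) gives the SE and
percentile 95% interval, with zero-variance resamples redrawn and
counted. The parent-average correlation, cor(GEBV, 0.5(EBV_sire +
EBV_dam)) over validation animals with both parents phenotyped, is the
diagnostic for the central small-breed failure mode: when validation
animals' proofs carry no own information, GEBV "accuracy" can be high
while the GEBV contains nothing beyond the parent average. GRM PCA
(eigenvectors scaled by √eigenvalue, explained variance over the positive
spectrum) is provided for multi-breed structure checks.

## The synthetic herd

The simulator produces the joint structure the analyses assume, not a
calibrated copy of any real breed: discrete non-overlapping generations;
founders in linkage equilibrium with allele frequencies uniform on
(0.05, 0.95), so all LD is generated by drift (the regime the LD–Nₑ
estimator assumes); recombination as a Poisson process without
interference on chromosomes of fixed genetic length; marker positions
uniform with 1 cM = 1 Mb so the genetic and physical maps coincide; true
breeding values from additive effects at a random subset of markers;
EBV/dEBV built as r·TBV + √(r(1−r))·σ·z so the squared correlation with
the TBV converges to the target reliability r.

Two mating systems. The default `two_sex` mode draws each offspring's
sire from `n_sires` males (default ne/4) and its dam from the remaining
females, reproducing the paternal half-sib families of AI breeding; its
variance effective size is 4·Nm·Nf/(Nm+Nf), below the census size. The
`wright_fisher` mode is the idealized monoecious model with selfing, in
which the textbook laws F_t = 1 − (1 − 1/(2N))^t and per-generation
heterozygosity decay (1 − 1/(2N)) hold exactly; the law-validation tests
run in this mode because the laws simply do not hold for two-sex pair
mating (at ne = 2 the two-sex pedigree is a deterministic full-sib line
with a lower inbreeding trajectory).

The pseudo-phenotype generator additionally offers a `parent_average`
mode, value = rel·own + (1 − rel)·PA applied down the pedigree, because
the defining feature of real low-reliability EBVs — they *are* parent
averages — cannot be produced by independent noise. The confound tests
use it for validation cohorts.

Not emulated: genotyping error beyond a configurable fraction of
low-quality-score markers, selection during the simulation, overlapping
generations, mutation–drift equilibrium (mutation defaults to off), and
ascertainment bias of commercial SNP panels. Passing recovery tests on
this generator therefore demonstrates estimator correctness under the
model's own assumptions, not robustness to real-data pathologies.

## Problem sizes used in the test suite

Recovery checks simulate 29 chromosomes × 1000 markers at census size
100 for 20 generations. Chromosomes are 50 cM (= 50 Mb) there, giving
~50 kb marker spacing: a 30–50K panel's density relative to its genome,
and comfortably inside the ROH density rule. At 100 kb mean spacing the
spacing distribution straddles the 100 kb/SNP density cut and roughly
half of all true ROH are rejected on marker-spacing noise alone — a
panel-design observation worth remembering when applying a 50K-tuned ROH
rule to sparser data. The GBLUP confound experiments use ~450 reference
and 64 validation animals on 3000 markers, five replicates per setting;
the Wright–Fisher law checks use 20 replicates at N = 2 and 10 at N = 30.
All stochastic tests run under fixed seeds.

## Known limitations

* The LD–Nₑ trajectory inherits every caveat of the equilibrium formula:
  constant size, no migration/selection, and a deterministic map from
  distance to time; treat it as a smoothed summary, not a demographic
  reconstruction.
* Nₑ from ΔF regression assumes the cohort trend is linear over the
  window used and that the generation interval is known externally.
* GBLUP variance components are fixed per trait, not estimated; the
  across/multi-breed scenarios share one GRM centred on combined allele
  frequencies (no per-breed centring).
* PED/MAP text files define the counted allele lexicographically, so a
  text round trip preserves dosages only when the counted allele sorts
  first; the binary dialect has no such restriction.
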