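# smallherd

Genomic management analyses for small and endangered livestock breeds.

Small closed populations — a few thousand breeding animals, a few hundred
AI bulls — cannot run genomic selection the way large dairy breeds do, but
SNP-array data still answers the questions their breed managers actually
have: how much linkage disequilibrium is there and what effective
population size does it imply, how fast is inbreeding accumulating, where
in the genome is autozygosity concentrated, and do genomic breeding values
add anything over parent averages? `smallherd` implements that analysis
chain end-to-end, together with a forward-in-time simulator of a small
closed breed so every method can be exercised and validated without access
to proprietary genotypes.

## What it computes

* **Two QC tracks.** A standard track (marker call rate ≥ 0.9, exact
  Hardy–Weinberg p ≥ 1e−6, MAF ≥ 0.05, duplicate-position removal, sample
  call rate ≥ 0.9) feeding LD and prediction, and a stricter ROH track
  (GenCall ≤ 0.7 and GenTrain ≤ 0.4 markers removed, samples > 5% missing
  removed, deliberately **no** MAF/HWE filtering) feeding the
  homozygosity analyses.
* **LD decay and historical Ne.** LD is the squared Pearson correlation of
  0/1/2 dosages, r², over all same-chromosome pairs closer than 10 Mb,
  summarised in 100 kb bins. Under drift–recombination equilibrium
  E(r²) ≈ 1/(α + 4Nₑc), so each bin yields Nₑ ≈ (1/4c)(1/r² − α) for a
  time t = 1/(2c) generations ago; the binned curve becomes an Nₑ
  trajectory.
* **Runs of homozygosity.** ROH are maximal runs of ≥ 15 consecutive
  homozygous SNPs, gaps ≤ 1 Mb, density ≤ 100 kb/SNP. F_ROH =
  L_ROH/L_AUTOSOME at minimum lengths of 4/8/16 Mb, which date the
  common ancestor ≈ 12/6/3 generations back (g = ⌊100/(2·L_cM)⌋ at
  1 cM ≈ 1 Mb). The contemporary effective size is Nₑ = 1/(2ΔF) with ΔF
  the regression slope of F_ROH on birth year times the generation
  interval; Wright's pedigree F is computed for comparison. SNPs whose
  ROH incidence is a Tukey outlier (> Q3 + 1.5·IQR) form autozygosity
  islands.
* **Weighted GBLUP with forward validation.** y = 1μ + Zg + e with
  g ~ N(0, Gσ²g) on a VanRaden genomic relationship matrix and residual
  variances scaled by the pseudo-phenotype reliability (record weight
  r²/(1−r²)). Reference/validation splits follow forward prediction
  (single-, multi- and across-breed), accuracy is cor(GEBV, EBV) with
  10,000-rep bootstrap intervals, and the parent-average correlation
  diagnostic flags accuracies that merely recover 0.5(EBV_sire + EBV_dam).
* **A breed simulator.** Discrete generations, polygynous (AI-style)
  matings or idealized Wright–Fisher, Poisson recombination on a 1 cM =
  1 Mb map, founders in linkage equilibrium, EBV/dEBV pseudo-phenotypes at
  controlled reliability.

## Worked example

Simulate a herd, run the full pipeline, inspect the results:

```
smallherd simulate --out scratch/herd --seed 1 --config examples/sim.yaml
smallherd run --config examples/pipeline.yaml
```

or equivalently in Python:

```python
import smallherd as sh

sim = sh.simulate_breed(sh.SimConfig(ne=100, n_generations=20,
                                     n_chromosomes=29,
                                     markers_per_chromosome=1000,
                                     chrom_length_cm=50.0, seed=1))
g = sim.genotypes

# contemporary Ne from the F_ROH>4Mb trend over the last ten cohorts
segs = sh.detect_roh(g, require_qc=False)
fr = sh.froh(segs, 4.0, g.samples.sample_id,
             l_autosome_bp=1_400_000_000).set_index("sample_id")["f_roh"]
years = g.samples.set_index("sample_id")["birth_year"]
recent = years >= years.max() - 9
d = sh.delta_f_from_regression(fr[recent], years[recent], gi_years=1.0)
print(round(d.delta_f, 5), round(sh.ne_from_delta_f(d.delta_f), 1))
```

prints `0.00454 110.1`: inbreeding rises by ≈ 0.45% per generation, an
inbreeding effective size of ≈ 110 for a herd simulated at census size
100 — the estimator recovers the truth well within its expected factor-of-
1.5 band. The same pipeline on the LD side (`sh.ne_trajectory`) gives a
mean historical Nₑ of ≈ 129 over generations 5–50.

As a desk check of the ancestor-dating rule,
`sh.generations_from_length(4)` returns `12`: a 4 Mb minimum ROH length
corresponds to autozygosity from common ancestors about 12 generations
back.

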