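# A small closed herd: 29 autosomes, ~50 kb marker spacing, 20 generations
# of polygynous matings at census size 100, 2% of markers given failing
# array-quality scores so the ROH QC track has work to do.
n_chromosomes: 29
markers_per_chromosome: 1000
chrom_length_cm: 50.0
ne: 100
n_generations: 20
qtl_count: 300
h2: 0.4
low_score_marker_fraction: 0.02
seed: 1
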