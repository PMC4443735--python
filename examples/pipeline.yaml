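# Full analysis over the file set written by `smallherd simulate`.
input_prefix: scratch/herd
input_format: binary
out_dir: scratch/report
seed: 1
generation_interval_years: 1.0  # simulated cohorts are discrete generations
ne_ld:
  alpha: 1        # the simulated herd has no mutation
  cm_per_mb: 1.0  # and a 1 cM = 1 Mb map
gblup:
  cutoff_year: 2006  # last ~4 cohorts become the validation set
  bootstrap_reps: 10000
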