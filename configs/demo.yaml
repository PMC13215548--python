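# Small demonstration study: the 8-division fixture over 2000-2011 with a
# light survey and short MCMC chains, so the full pipeline finishes in
# under a minute. Full-scale settings are the PipelineConfig defaults.
output_dir: demo_out
seed: 11
truth:
  year_start: 2000
  year_end: 2011
survey:
  clusters_per_stratum: 8
  women_per_cluster: 25
fanova:
  n_perm: 500
model:
  n_iter: 2000
  n_burn: 500
  thin: 3
forecast:
  horizon_to: 2015
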