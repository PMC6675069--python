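# Scaled-down demo pipeline: completes in well under a minute on one CPU
# and reruns byte-identically under a fixed seed.
seed: 7
out_dir: results/demo
counts:
  n_genes: 200
  n_perturbed: 30
biosets:
  n_genes_universe: 200
beams:
  session_length: 600.0
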