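outdir: splitroot_fixture_run
seed: 42
simulation:
  n_genes: 300
  n_planted_pairs: 30
n_perm: 200
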