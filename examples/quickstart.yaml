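# Minimal end-to-end synthetic study: small cohort, reduced draws.
# Run with:  setshift run examples/quickstart.yaml --out-dir results/quickstart
task: prl
seed: 7
cohort:
  preset: paper_like_prl
  n_per_group: 10
fit:
  chains: 4
  warmup: 250
  draws: 250
  seed: 5
compare: true
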