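# End-to-end demo: synthesize asynchronous-RE stripe data, fit (p, d).
# Run with:  stripefit run examples/demo_config.yaml --out demo_out/
seed: 7
synth:
  preset: async_RE        # p = 150 kb, d = 0.06, 500 kb arm
  total_contacts: 1000000 # contacts per profile and replicate
  replicates: 3
fit:
  p_min: 10
  p_max: 500
  p_step: 10
  d_min: 0.01
  d_max: 0.30
  d_step: 0.01
  window: [10, null]      # fit from 10 kb to the arm end
estimate_blocks: true
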