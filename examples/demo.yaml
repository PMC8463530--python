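# End-to-end demo: simulate -> MR -> compound meta-analysis -> concordance.
seed: 11
stages: [simulate, mr, meta, concord]
simulate:
  gwas:
    m: 30
    n_exposure: 10000
    n_outcome: 50000
    n_reference: 5000
    theta: 0.2
  trials:
    arm_size: 1300
options:
  overdispersion: true
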