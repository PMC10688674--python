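# Default simulation grid: Type I error of the treatment test under the
# null, for six RCB layouts and six split-plot layouts, five generating
# block / whole-plot error variances each (error variance 1 throughout;
# split-plot block variance 1).
models:
  - model: rcb
    sigma_e2: 1.0
    reps: 200000
    alpha: 0.05
    layouts:
      - {a: 2, b: 2}
      - {a: 2, b: 4}
      - {a: 3, b: 2}
      - {a: 3, b: 4}
      - {a: 4, b: 4}
      - {a: 10, b: 3}
    variances: [0.1, 0.3, 0.5, 0.7, 0.9]
  - model: splitplot
    sigma_b2: 1.0
    sigma_e2: 1.0
    reps: 200000
    alpha: 0.05
    layouts:
      - {a: 2, b: 4, c: 12}
      - {a: 3, b: 2, c: 12}
      - {a: 3, b: 4, c: 12}
      - {a: 3, b: 4, c: 5}
      - {a: 4, b: 4, c: 12}
      - {a: 10, b: 3, c: 12}
    variances: [0.1, 0.3, 0.5, 0.7, 0.9]
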