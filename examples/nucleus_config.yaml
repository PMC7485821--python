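# Search space and optimiser settings for nucleus segmentation on the
# synthetic scenes.  Setting names match the reference pipeline's knobs.
parameters:
  - {name: Size of adaptive window, kind: integer, min: 11, max: 99, interval: 2}
  - {name: Threshold correction factor I, kind: float, min: 0.6, max: 2.0, interval: 0.05}
  - {name: Typical artifact diameter, kind: float, min: 0, max: 12, interval: 1}
  - {name: Threshold correction factor II, kind: float, min: 0.3, max: 1.5, interval: 0.05}

# Automated evaluation: a well-segmented nucleus is convex (high solidity)
# and of plausible size.
criteria:
  object: nucleus
  measurements:
    - {measurement: solidity, min: 0.92}
    - {measurement: area, min: 80, max: 2000}

optimiser:
  target_qs: 8
  max_iterations: 30
  bootstrap: 2
  xi: 0.3
  candidate_count: 2048
  seed: 0
  gp:
    sigma_n: 0.1
    sigma_f: 1.0
    sigma_l: 1.0
  weights: {automated: 0.5, manual: 0.5}
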