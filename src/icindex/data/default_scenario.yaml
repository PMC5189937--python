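# Pinned default study design: 500 cells x 12 genes sampled at 4 times
# straddling the tipping point of the two-master circuit (the biased
# progenitor attractor folds at mu ~ 0.81 for these kinetic parameters).
# All magic numbers of the scenario live here.
model:
  a: 1.0          # self-activation strength
  b: 1.0          # cross-inhibition strength
  k: 1.0          # first-order decay rate
  S: 0.5          # Hill threshold
  h: 4.0          # Hill exponent
  bias: 0.04      # instructive imperfection on master_x (intended lineage)
  noise_sigma: 0.05
  downstream:     # linear noisy readouts z <- basal + w_x*x + w_y*y
    - {name: ery1, basal: 0.30, w_x: 1.10, w_y: -0.30, decay: 2.0}
    - {name: ery2, basal: 0.80, w_x: 0.90, w_y: -0.10, decay: 2.0}
    - {name: ery3, basal: 1.40, w_x: 0.70, w_y: -0.40, decay: 2.0}
    - {name: ery4, basal: 0.50, w_x: 1.30, w_y: -0.20, decay: 2.0}
    - {name: ery5, basal: 1.10, w_x: 0.60, w_y: -0.15, decay: 2.0}
    - {name: mye1, basal: 0.40, w_x: -0.30, w_y: 1.20, decay: 2.0}
    - {name: mye2, basal: 0.90, w_x: -0.15, w_y: 0.80, decay: 2.0}
    - {name: mye3, basal: 1.50, w_x: -0.40, w_y: 0.70, decay: 2.0}
    - {name: mye4, basal: 0.60, w_x: -0.20, w_y: 1.10, decay: 2.0}
    - {name: mye5, basal: 1.20, w_x: -0.10, w_y: 0.60, decay: 2.0}
simulation:
  n_cells: 500
  dt: 0.01
  t_segment: 15.0
  expression_scale: 20.0
  capture_fraction: 0.25
  schedule:           # monotone decreasing mu; t2 sits just above the fold
    - {time: t0, mu: 1.00}
    - {time: t1, mu: 0.90}
    - {time: t2, mu: 0.82}
    - {time: t3, mu: 0.60}
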