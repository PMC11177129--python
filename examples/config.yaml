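# Example pipeline configuration: simulate a 16-zone survey, run the
# descriptive, spatial and modelling stages, and write reports to out_dir.
seed: 7
out_dir: out/demo_run
simulation:
  n_zones: 16
  lattice_dims: [4, 4]
  clusters_per_zone: 4
  women_per_cluster: 15
  # coefficient order: intercept, xvar[b], res[r]
  beta1: [-0.3, 0.5, 0.4]
  beta2: [0.5, -0.4, 0.3]
  log_psi: 0.336               # outcome odds ratio exp(0.336) ~ 1.4
  re_cov: [[0.3, 0.05], [0.05, 0.4]]
  zone_sd: 0.4
  zone_rho: 0.7
  covariate_spec:
    - {name: xvar, labels: [a, b], probs: [0.5, 0.5]}
    - {name: res, labels: [u, r], probs: [0.4, 0.6], level: cluster}
  seed: 7
predictors_l1: [xvar]
predictors_l2: [res]
quad_points: 5
n_perm: 199
variants: [random_intercept_L1, random_intercept_L1L2]
include_autocovariate: true
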