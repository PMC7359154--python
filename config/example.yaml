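# Example pipeline configuration: a reduced-dimensionality synthetic run
# that finishes in a few minutes on one CPU. Increase n_subpathways /
# n_metabolites (and switch global retention to kaiser) for the full
# study-scale design; the univariate and PCA stages scale easily, the
# classification stage cost grows quadratically with the number of
# retained global components.
schema_version: 1
seed: 1
outdir: results/run
simulate:
  n_per_group: [30, 26, 45, 33, 32]   # bvFTD, nfvPPA, PSP, CBS, Control
  n_subpathways: 24
  n_metabolites: 140
  effects:
    n_affected: 20
    log_fc_magnitude: 0.35
    n_factor_subpathways: 6
    factor_loading: 0.8
    severity_patient_shift: 2.0
    censor_rate: 0.3
    censored_metabolite_fraction: 0.3
analysis:
  fdr_threshold: 0.01
  fdr_method: bh
  n_cv_folds: 10
  n_repetitions: 10
  svm_cost: 1.0
  km_z_cut: 1.0
  global_retention: fixed_k
  global_fixed_k: 8
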