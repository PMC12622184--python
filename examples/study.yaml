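# Full study configuration for `polymix run`.
#
# Four ancestry groups, eight component traits. The trait-score correlation
# matrix and the liability loadings are plausible defaults for a disease
# with correlated cardiometabolic risk-factor scores; they are simulation
# conditions, not estimates of any real cohort.
sim:
  n_per_ancestry: {EUR: 24000, AFR: 10000, AMR: 10000, ASN: 6000}
  prevalence: {EUR: 0.089, AFR: 0.060, AMR: 0.050, ASN: 0.055}
  trait_names: [AF, HF, BMI, height, CAD, SBP, DCM, PR]
  score_corr:
    - [1.00, 0.40, 0.25, 0.15, 0.25, 0.20, 0.15, 0.10]
    - [0.40, 1.00, 0.30, 0.10, 0.35, 0.25, 0.30, 0.05]
    - [0.25, 0.30, 1.00, 0.10, 0.20, 0.25, 0.05, 0.00]
    - [0.15, 0.10, 0.10, 1.00, 0.05, 0.05, 0.05, 0.05]
    - [0.25, 0.35, 0.20, 0.05, 1.00, 0.30, 0.10, 0.00]
    - [0.20, 0.25, 0.25, 0.05, 0.30, 1.00, 0.05, 0.05]
    - [0.15, 0.30, 0.05, 0.05, 0.10, 0.05, 1.00, 0.05]
    - [0.10, 0.05, 0.00, 0.05, 0.00, 0.05, 0.05, 1.00]
  liability_loadings:
    EUR: [0.55, 0.18, 0.12, 0.06, 0.08, 0.05, 0.02, 0.02]
    AFR: [0.28, 0.14, 0.12, 0.03, 0.08, 0.06, 0.02, 0.01]
    AMR: [0.32, 0.16, 0.10, 0.04, 0.07, 0.05, 0.02, 0.01]
    ASN: [0.38, 0.13, 0.09, 0.05, 0.07, 0.05, 0.02, 0.01]
  age_range: [40, 75]
  beta_age: 0.35
  beta_sex: 0.25
  n_pcs: 20
  pc_separation: 3.0
  n_variants: 0          # >0 adds a genotype layer and runs the scoring engine
  seed: 0                # overridden by the master seed's substream

tuning_fraction: 0.30
n_pcs: 20
seed: 1
out_dir: polymix_out
folds: [3, 4, 5]
lower_fold: 0.3333333333
stratify_ancestry: EUR
stratify_step: 0.5
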