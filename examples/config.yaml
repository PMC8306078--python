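# One config drives every CLI stage:
#   fruitspec simulate  --config examples/config.yaml --out scratch/sim
#   fruitspec calibrate --config examples/config.yaml --out scratch/reports.csv
seed: 42
region: NIR            # VIS-NIR (400-1000 nm) or NIR (900-1700 nm), 5 nm step
n_samples: 100
noise_sd: 0.005        # reflectance units, additive sensor noise
baseline_amplitude: 0.02   # absorbance units, smooth per-sample drift
n_stages: 4            # maturity stages
constituents: null     # null -> every constituent with bands in the region

chains:                # pretreatment grid, applied per constituent
  - SM + MC
  - SM + 1st Dev + MC
  - SM + Log + 1st Dev + MC

split:
  calibration_fraction: 0.70
  stratify: true       # per maturity stage

settings:
  max_lv: 20           # candidate latent variables for LOO-CV
  prob_threshold: 0.75 # PRESS-ratio F probability for LV selection
  n_intervals: 20      # interval-PLS blocks per region
  outlier_alpha: 0.01  # F(1, I-1) tail probability to flag a sample
  outlier_max_rounds: 10
  outlier_floor: 0.8   # never drop below this fraction of samples
  refine: best         # refine the best chain per constituent (best|all|none)
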