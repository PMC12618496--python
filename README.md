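# mmsurv

Multimodal survival modelling toolkit: a 3D-volume + text-prompt tabular
transformer with masked cross-attention fusion and a Weibull
accelerated-failure-time (AFT) head for censored survival prediction,
together with individualized survival-curve estimation with Monte-Carlo
uncertainty, a censoring-aware evaluation battery, baseline architectures,
imputation comparators, and interpretability operators. Everything is
testable on synthetic multimodal cohorts with known ground truth — no
downloads, no GPU.

## Layout

| module | role |
|---|---|
| `mmsurv.synthetic` | toy multimodal survival cohorts (covariate-dependent Weibull AFT event times, calibrated exponential censoring, ellipsoidal lesions, MAR missingness) with an oracle concordance ceiling |
| `mmsurv.tabular` | cohort TSV/CSV IO with explicit `NA` missingness, age/KPS discretization, natural-language prompt serialization from a versioned template table |
| `mmsurv.volumes` | resampling to a target grid, centered shape standardization, per-scan z-scoring; NIfTI IO (RAS-reoriented) |
| `mmsurv.weibull` | Weibull AFT math: survival/density, censored NLL with analytic gradients, per-patient curves with Monte-Carlo CIs + KDE densities, five-family parametric goodness-of-fit vs Kaplan–Meier |
| `mmsurv.nn` | a small numpy reverse-mode autodiff engine, transformer layers with exact masked attention, the fusion architecture (two survival-query tokens, modality adaptors), and the CNN / image-only ViT / non-imaging (NIMT) baselines |
| `mmsurv.training` | two-stage protocol: imaging-encoder pretraining, then frozen-encoder fusion training with augmentation, leakage audits, and validation C-index early stopping |
| `mmsurv.metrics` | Harrell C-index, IPCW time-dependent AUC/IAUC and Brier/IBS, calibration slope/intercept/ECE, decision curves, KM/log-rank, risk stratification (median and log-rank-optimal cutoffs), percentile bootstrap CIs and paired/two-sample bootstrap tests, cohort comparison (χ²/ANOVA) |
| `mmsurv.impute` | mode and MICE imputation comparators for the masked-attention mechanism |
| `mmsurv.interpret` | Eigen-CAM volumes, gradient×input tabular relevance, exact coalition-enumeration Shapley values, CAM-vs-mask localization metrics |
| `mmsurv.cli` / `mmsurv.compare` | subcommand CLI and the model/imputation comparison matrix |

The network runs on a self-contained numpy autodiff engine (`mmsurv.nn.autodiff`),
so no deep-learning framework is required. The text encoder defaults to a
deterministic hashed-stub backend (one pseudo-random unit vector per distinct
prompt); a pretrained language-model backend is accepted as configuration but
requires an optional dependency.

## CLI

All commands write their fully-resolved configuration next to their outputs
and derive all randomness from `--seed`.

```bash
mmsurv simulate --out runs/data --n 400 --seed 0          # synthetic cohort + volumes + ground truth
mmsurv prep     --data runs/data --out runs/prepped       # resample / z-score / standardize
mmsurv pretrain --data runs/data --out runs/enc --epochs 25 --seed 0
mmsurv train    --data runs/data --encoder runs/enc/encoder.npz \
                --out runs/model --epochs 120 --seed 0
mmsurv predict  --model runs/model/model.npz --data runs/data --out runs/preds.csv
mmsurv evaluate --predictions runs/preds.csv --data runs/data \
                --out runs/metrics.json --n-boot 999 --seed 0
mmsurv stratify --predictions runs/preds.csv --data runs/data \
                --method logrank_optimal --out runs/strat.json
mmsurv explain  --model runs/model/model.npz --data runs/data \
                --subject S0001 --out runs/explain
mmsurv compare  --data runs/data --out runs/compare.json --epochs 40
```

`compare` trains the fusion model against the CNN / image-only ViT / NIMT
baselines and against mode/MICE imputation on one cohort, and emits a metric
matrix (C-index, IAUC, IBS) with percentile-bootstrap CIs and
paired-bootstrap p-values.

## Conventions

- Time is months end-to-end; `event` is 1 = death, 0 = censored.
- Survival function `S(t) = exp(-(t/lambda)^rho)`; networks emit
  `(log lambda, log rho)` clamped to `lambda in [0.1, 600]` months,
  `rho in [0.2, 10]`.
- The scalar risk score is the negative predicted median survival time
  (configurable to `-log lambda`).
- Missing tabular variables are first-class: absent tokens get
  presence-mask `False` and `-inf` attention logits, so model outputs are
  bitwise independent of their placeholder values.
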