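# gaitpd

Explainable, subject-wise validated analysis of vertical ground reaction
force (VGRF) gait signals for Parkinson's disease (PD): window-level
classification with small sequence models, stability-consensus selection of
Integrated-Gradients gait biomarkers with nonparametric validation, and
continuous Hoehn & Yahr (H&Y) severity regression. A synthetic gait-cohort
generator with known ground truth makes every stage testable offline.

## Who this is for

Researchers working with plantar-pressure walking records (the PhysioNet
gait-in-PD text dialect: whitespace-delimited, time + 8 left + 8 right
sensors + left/right total force, 100 Hz) who need an analysis pipeline in
which *no subject's data ever crosses a train/validation/test boundary* —
the leakage that inflates most record-wise gait classification results —
and in which feature-importance claims survive repetition across both
random splits and model architectures.

## The method

**Windowed token representation.** Each record is cut into L = 100-sample
windows with 50% overlap. For every window, each of the 18 channels c
contributes a token with two features, the within-window mean and standard
deviation, z-scored per channel with statistics (μ_c, σ_c) fitted on
training subjects only. Window std is the variability summary: rigid,
low-variability PD gait lowers it.

**Stage 1 — classification.** Three differentiable backbones over the
18 × 2 token sequence (TCN with dilated causal convolutions; BiGRU with
additive attention pooling; per-token embedding + transformer encoder) are
trained with AdamW and weighted binary cross-entropy (positive-class weight
n_neg/n_pos), early-stopped on validation AUC. Evaluation repeats over
subject-wise stratified 70/15/15 splits (seeds base, base+1, …), reporting
AUC/accuracy/sensitivity/specificity as mean ± SD with empirical bootstrap
95% CIs, and comparing architectures with an exact paired Wilcoxon
signed-rank test (at n = 5 repeats the smallest attainable two-sided p is
0.0625; both sidednesses are reported).

**Stability-consensus XAI.** Integrated Gradients attributes each window
probability to the 36 token features,

&nbsp;&nbsp;IG_i = (x_i − x′_i) · (1/m) Σ_{k=1..m} ∂F(x′ + (k/m)(x − x′))/∂x_i,

aggregated as mean |IG| over test windows per (architecture × split)
experiment. Features in the top 20% of an experiment count as selected; the
stability score is the fraction of experiments selecting a feature, and
features scoring ≥ 20% (inclusive) form the consensus set. Consensus
features are then validated at the data level: Mann–Whitney U,
Cliff's δ = (#{x>y} − #{x<y})/(n_x·n_y) oriented PD − control, and
Benjamini–Hochberg FDR within the consensus family.

**Stage 2 — severity.** Each subject is summarized by the across-window
mean and std of the 36 raw-unit features (72 predictors); an XGBoost
regressor predicts continuous H&Y under the same subject-wise segregation,
scored by MAE, RMSE, R², Spearman ρ, Cohen's f² = R²/(1 − R²), and
noncentral-F post hoc power with noncentrality λ = f²·n.

## Worked example

```python
from gaitpd import RunConfig, run_all
from gaitpd.synth import CohortConfig
from gaitpd.backbones import TrainingConfig

config = RunConfig(
    cohort=CohortConfig(n_control=20, n_pd=20, record_seconds=30.0, seed=11),
    n_repeats=3, base_seed=11, archs=("tcn", "fcnn_transformer"),
    hidden=16, depth=2,
    training=TrainingConfig(learning_rate=3e-3, max_epochs=40, patience=8),
)
result = run_all(config)
```

Printed output (`result.stage1.summary`, consensus, and `result.severity`):

```
            arch  auc_mean  auc_sd  auc_ci_lower  auc_ci_upper  accuracy_mean
             tcn       1.0     0.0           1.0           1.0          0.666
fcnn_transformer       1.0     0.0           1.0           1.0          0.988
consensus features: ['sensor_12_std', 'sensor_11_std', 'sensor_13_std', 'sensor_1_std', 'sensor_8_std'] ...
top biomarker: sensor_12_std  delta=-0.997  p_adj=0.00e+00
stage 2 (n=18): MAE=0.110 RMSE=0.241 R2=0.948 rho=0.921 power=0.231
```

Reading it: both backbones separate the synthetic groups perfectly at
window level (the planted effect suppresses PD variability strongly); the
TCN's 0.666 accuracy at AUC 1.0 shows a miscalibrated 0.5 threshold, not
poor discrimination. Every consensus feature is a std (variability)
feature, and the top one is strongly *lower* in PD (δ = −0.997). Held-out
severity predictions preserve stage order (ρ = 0.921) with errors around a
tenth of an H&Y step; the low post hoc power reflects the small test-subject
count (n = 18) against 72 predictors, exactly what the power analysis is
there to flag.

The same pipeline is scriptable from the shell:

```bash
gaitpd simulate --seed 1 --out data/        # write a synthetic cohort
gaitpd all --config run.yaml --out results/ # full pipeline + artifacts
```

## Layout

| Module | Role |
| --- | --- |
| `gaitpd.io` | VGRF text dialect + demographics CSV, validation |
| `gaitpd.synth` | synthetic cohort generator with ground truth |
| `gaitpd.windowing` | windows, z-scoring, 18 × 2 tokens, leakage-tagged stats |
| `gaitpd.splits` | stratified subject-wise 70/15/15 repeats, leakage guards |
| `gaitpd.autodiff` / `gaitpd.backbones` | numpy autodiff; TCN, BiGRU-Attn, FCNN-Transformer, AdamW training |
| `gaitpd.evaluate` | metrics, bootstrap CIs, exact paired Wilcoxon |
| `gaitpd.attribution` / `gaitpd.stability` | Integrated Gradients; stability-consensus selection |
| `gaitpd.stats` | Mann–Whitney, Cliff's delta, BH-FDR, biomarker tables |
| `gaitpd.severity` | subject vectors, XGBoost H&Y regression, f², power |
| `gaitpd.pipeline` / `gaitpd.cli` | orchestration, artifacts, `gaitpd` CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices, and
what the synthetic cohort does and does not establish about real data.
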