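# Methods

## Problem and pipeline

Parkinsonian gait is rigid and temporally uniform compared with healthy
walking: the cycle-to-cycle and within-cycle variability of the vertical
ground reaction force (VGRF) drops as the disease progresses, while the
average load (body weight support) barely changes. The package turns this
into a two-stage analysis over multichannel VGRF records (16 plantar
sensors + 2 total-force channels, 100 Hz):

1. **Detection.** Windowed 18-token (mean, std) features → three small
   sequence classifiers → repeated subject-wise evaluation.
2. **Interpretation and severity.** Integrated-Gradients attributions,
   made robust by requiring agreement across splits *and* architectures,
   validated nonparametrically at the data level; then continuous
   Hoehn & Yahr (H&Y) regression on subject-level feature summaries.

The binding methodological constraint throughout is subject-wise
segregation: normalization statistics, model selection, attribution
aggregation and severity regression all see a subject's data on only one
side of the train/evaluation boundary, and runtime guards
(`assert_stats_clean`, `assert_no_leakage`, the stage-2 overlap check)
raise rather than warn when that is violated.

## Synthetic cohort: what it emulates

`gaitpd.synth` generates cohorts in the same file dialect and statistical
shape the analysis assumes. Each sensor channel carries one or two
raised-Gaussian pressure bumps per gait cycle (heel bumps early in stance,
toe bumps late), feet anti-phased by half a stride, totals equal to the sum
of their eight sensors before additive sensor noise. Defaults describe the
reference cohort: 73 controls + 93 PD subjects, PD stages drawn from
{1, 1.5, 2, 2.5, 3} with mean ≈ 2.3 and SD ≈ 0.6, 100 Hz, 120 s records,
1.1 s stride period.

Severity h acts on *variability*, not mean load:

* the oscillatory component of every channel and the cycle-to-cycle
  amplitude noise are scaled by `v = 1 − β·h` (`variability_suppression`,
  default β = 0.3), with the static baseline raised so the cycle-mean force
  is unchanged;
* the stride period lengthens by `1 + γ·h` (`speed_slowing`, default
  γ = 0.1).

A design note on the first point: if severity only narrowed the
*distribution* of cycle amplitudes (a pure coefficient-of-variation
effect), the median of the window-std feature would not move and no
location test could detect the group difference. Scaling the dynamic range
itself — while compensating the baseline — is what makes "variability down,
mean unchanged" literally true in the features the pipeline measures, and
it keeps the realized amplitude CV equal to `amp_cv_control·(1 − β·h)`,
which the generator records per subject as recoverable ground truth.

Key generator parameters (units, defaults):

| parameter | default | meaning |
| --- | --- | --- |
| `record_seconds` | 120 s | record length (30 s in the scaled test runs) |
| `stride_period_s` | 1.1 s | base stride period μ_T |
| `amp_cv_control` | 0.08 | control cycle-to-cycle amplitude CV |
| `variability_suppression` β | 0.3 | per-unit-H&Y variability reduction |
| `speed_slowing` γ | 0.1 | per-unit-H&Y period lengthening |
| `noise_sd` | 3 N | additive sensor noise |
| `subject_scale_sd`, `subject_period_sd` | 0 | between-subject nuisance spread (see below) |

Sensor template amplitudes (220–380 N) were chosen so control window-std
values land in the ~70–120 N range typical of plantar-sensor summaries;
they are shape parameters, not claims about any particular hardware.

All randomness descends from one seed; each subject draws from a substream
keyed by a SHA-256 hash of its id, so cohorts are reproducible regardless
of generation order, and the demographics table carries optional noisy
clinical correlates (UPDRS, TUG, speed) of the true stage.

**What it does not emulate — and why the nuisance knobs default to 0.**
Real cohorts have between-subject differences in body weight and cadence.
The two knobs exist (`subject_scale_sd`, `subject_period_sd`) but default
to zero because the package's data-level biomarker tests use the *window*
as the sampling unit: with subject-level nuisance variation, windows are
clustered and window-level Mann–Whitney p-values become anticonservative
(in a calibration run with scale SD 0.08, ≈ a third of features were
falsely FDR-significant under a no-effect cohort). With the defaults,
windows are exchangeable across subjects under the null and the FDR
behaves nominally. The corollary for real data: window-level p-values
should be read as descriptive; `validate_features(..., by_subject=True)`
aggregates to per-subject means first and is the defensible inferential
unit for clustered cohorts. Passing synthetic tests therefore demonstrates
correctness of the machinery and recoverability of a planted effect — not
that window-level significance on a real cohort is calibrated. The
generator also makes no attempt at joint kinematics, freezing episodes, or
force plateaus (swing-phase force is not clamped at zero when the baseline
compensation lifts it).

## Windowing and normalization

Window length 100 samples (1 s), overlap 50%, step = round(L·(1−overlap))
with a floor of 1; trailing partial windows are discarded; records shorter
than one window raise a distinct `RecordTooShort`. Z-score statistics are
fitted per split on training subjects only (the fitted object remembers its
contributors so contamination is detectable); channels with std below
`epsilon` (1e−8) are treated as constant (σ set to 1). Biomarker
statistics always use the raw, unnormalized features so medians and IQRs
stay in Newtons; model inputs always use the normalized ones. Windows
never span separate records.

## Splits

Stratified by group so both classes appear in every partition (AUC needs
both); per-class counts follow largest-remainder rounding of the 70/15/15
ratios, ties broken in partition order (train, val, test); repeat k uses
seed base+k. Infeasible requests (a partition that would lose a class,
fewer than 3 subjects per class) raise rather than degrade.

## Backbones and training

No deep-learning framework is required: `gaitpd.autodiff` is a ~300-line
reverse-mode autodiff over numpy arrays (broadcasted arithmetic, batched
matmul, reductions, softmax/sigmoid/softplus, slicing/concat), verified
against finite differences in the test suite. On it sit three
architectures with one I/O contract (batch of 18 × 2 windows → PD logits),
so evaluation and attribution are architecture-agnostic:

* **TCN** — `depth` blocks of kernel-3 causal convolutions with dilations
  1, 2, 4, …, residual connections, mean-pooled;
* **BiGRU-Attn** — one bidirectional GRU layer, additive attention pooling;
* **FCNN-Transformer** — per-token linear embedding + learned positions,
  `depth` encoder layers (multi-head attention + FFN + layer norm), mean
  pooling, MLP head.

Defaults: width 32, depth 3 (transformer: 2 would also be reasonable;
depth is shared for uniformity), 4 heads, dropout 0. Training: AdamW
(lr 1e−3, weight decay 1e−4), batch 64, ≤ 100 epochs, patience 10 on
validation AUC, parameters restored to the best-validation epoch; the
weighted BCE uses positive-class weight n_neg/n_pos computed on training
windows. The scaled test runs use width 16, depth 2, lr 3e−3 and ≤ 40
epochs — small enough for a single CPU, demonstrably sufficient to reach
validation AUC ≥ 0.99 on a separable fixture. These are engineering
defaults, exposed in `ModelSpec`/`TrainingConfig`, not tuned claims.

## Attribution and consensus

Integrated Gradients uses the right-Riemann approximation with m = 50
steps by default (16 in scaled runs, 256 in the completeness check, where
the gap |ΣIG − ΔF| must fall below 1e−2). The baseline is the all-zero
feature vector — the training-cohort channel mean in z-scored space —
chosen as the conventional "absence of signal" reference and exposed as a
parameter. Aggregation is mean |IG| over test windows; signed means are
exported alongside for inspection.

Consensus selection: top-20% cut per experiment (k = ceil(0.2·36) = 8,
ties broken by canonical feature order), stability score = selection count
over n_experiments, consensus at score ≥ 0.2 inclusive. n_experiments
defaults to n_splits × n_architectures (15 under the reference protocol);
an override exists because the experiment count is a protocol choice, not
a law.

## Statistics

* Mann–Whitney U: U = #{x>y} + ½#{ties}; exact permutation p when
  min(n, m) ≤ 8 (full enumeration), tie-corrected normal approximation
  otherwise (via scipy).
* Cliff's δ oriented PD − CO; negative means PD below control.
* BH-FDR (statsmodels step-up) applied within the consensus family only.
* Paired Wilcoxon across splits: exact distribution via the
  generating-function of the signed-rank sum with average ranks doubled to
  integers — exact for n ≤ 25 even with ties, where scipy's exact method
  is unavailable; zeros dropped; both one- and two-sided p reported
  because at n = 5 the two-sided floor is 0.0625.
* Repeat summaries: mean, sample SD (ddof 1), and a seeded 10⁴-resample
  percentile bootstrap of the mean as the empirical 95% CI.

## Severity regression

Subject vectors are the across-window mean and std of the 36 raw features
(72 predictors). The regressor is XGBoost (300 trees, depth 3, lr 0.05,
subsample 0.9, squared error, fixed seed) — conservative defaults, exposed
in `SeverityModelConfig`. Stage-2 evaluation pools held-out predictions
over the repeated splits: per split the model trains on train+val subjects
(controls at stage 0) and predicts test subjects; a subject tested in
several splits gets its mean held-out prediction. The default "inclusive"
population keeps all test subjects (so stage-0 rows appear in the report);
"paper_literal" mode restricts evaluation to subjects the best stage-1
model flags as PD. Power analysis uses Cohen's λ = f²·n with a noncentral
F on (k, n−k−1) df; when n is small the predictor count is capped at n−2
so the df stay feasible — the resulting low power on small test sets is
the honest reading, not an artifact.

## Degenerate inputs and numerical choices

Quantiles use linear interpolation (IQR values depend on this and it is
the numpy default). AUC uses midranks, so ties count ½. A constant actual
vector makes R² and ρ undefined and raises. f² is undefined at R² = 1 and
raises. All-zero Wilcoxon differences give p = 1. Empty consensus is a
valid, warned outcome, not an error. IG on x = baseline is exactly zero;
features identical to the baseline in all windows receive exactly zero
aggregate attribution.

## Known limitations

* The backbones are deliberately small and CPU-bound; they characterize
  the pipeline, not the ceiling of achievable discrimination.
* The synthetic effect at default β = 0.3 is strong (near-perfect AUC,
  |δ| ≈ 1); it exercises recoverability, not difficulty. Harder regimes
  are reachable by lowering β or adding the nuisance spreads — at the cost
  of the window-level inference caveat above.
* Stage-2 post hoc power is computed on the pooled held-out subject count,
  which is small in scaled runs; its values are reported as computed.
* The H&Y scale is treated as a continuous target; ordinal losses are out
  of scope.
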