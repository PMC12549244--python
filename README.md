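# physiotrust

Inferring an operator's trust in an autonomous system from multimodal
physiological signals, task-interaction behavior and operator background —
as a tested, reusable Python pipeline.

Supervisory ("human-on-the-loop") operators calibrate how much they rely on
an autonomous teammate, and that trust changes on the scale of seconds.
Surveys capture it only coarsely and disruptively. This package implements
the alternative: treat the continuous trust slider report `y ∈ [0, 1]`
collected every 45-s epoch as a regression target and model it from
electrocardiography, electrodermal activity, respiration, 19-channel EEG,
20-channel fNIRS, eye tracking, button-click ("embedded") measures and
pre-experiment background surveys.

The model is ordinary least squares on an algorithmically down-selected
predictor set,

    y = β₀ + β₁X₁ + … + β_pX_p,

where the candidate pool is a 1,774-column design matrix (682 base features
expanded by eight baseline-normalization "versions"), down-selected by
two-round relaxed-LASSO stability selection: 50 repetitions of 10-fold
cross-validated LASSO recording the support at the min-MSE and 1-SE
penalties (100 sets), then 50 further repetitions at the 1-SE rule on the
union of retained features. Each candidate set is refit by OLS, scored by
adjusted R² and exhaustive leave-one-trial-out Q² = 1 − PRESS/TSS, and
screened by two anti-overfitting constraints (p ≤ n/5 and
|adj R² − Q²| ≤ 0.2). External validation is leave-one-trial-out-per-session
Monte-Carlo cross-validation: one random trial withheld per
participant-session (1/6 of the epochs), repeated 10 times, reporting test
Q², RMSE and median absolute error with predictions capped to [0, 1].

Because the kind of human-subject dataset this targets is rarely deposited,
the package includes a first-class synthetic study generator: the full
protocol hierarchy (12 participants × 4 sessions × 6 trials × 8 epochs of
45 s, with pre-experimental and pre-trial baselines), stream-appropriate
signal physics, and a planted sparse linear trust structure whose ground
truth is returned for recovery testing. See `docs/methods.md` for the
science and every numerical choice.

## Worked example

```python
from physiotrust import (StudyDesign, SelectionConfig, generate_study,
                         assemble_design_matrix, run_mccv)

design = StudyDesign(n_participants=3, n_sessions=2, n_trials=6, n_epochs=8)
dataset = generate_study(design, seed=1)          # 288 epochs + baselines
matrix = assemble_design_matrix(dataset)          # 682 base -> 1,774 columns
config = SelectionConfig(n_reps_round1=5, n_reps_round2=5, cv_folds=5,
                         n_lambdas=30, lambda_min_ratio=0.1, seed=1)
report = run_mccv(matrix, config, n_splits=2, seed=1)
print(report.table.round(3))
```

Running `python examples/05_full_pipeline.py` (the same computation)
prints, per split, the training fit, the selection-stage cross-validation
fit, and the performance on the withheld trials:

```
       adj_r2  model_q2  test_q2   rmse    mae  predictors  capped
split
1       0.856     0.824    0.776  0.103  0.059          44       0
2       0.862     0.833    0.750  0.092  0.067          37       0
```

`test_q2 > 0` means the model beats the training-mean predictor on trials
it never saw; `rmse ≈ 0.1` says predictions sit within ~10% of the trust
scale; `mae` is the median absolute error; `capped` counts predictions
clipped to the [0, 1] bounds. Numbers are from this synthetic
configuration and vary with seed and scale.

The other `examples/` scripts are one-capability narratives: study
simulation, signal cleaning against generator truth, feature-dictionary
assembly, and stability selection on a planted instance. A thin CLI mirrors
the stages: `physiotrust simulate | extract | fit | evaluate | report`.

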