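"""End-to-end run: simulate, extract, cross-validate, report.

A reduced study (3 participants x 2 sessions) keeps this example quick;
the same call chain scales to the full 12x4x6x8 protocol.  Expect a couple
of minutes of feature extraction.
"""

import warnings

warnings.filterwarnings("ignore")

from physiotrust import (
    SelectionConfig,
    StudyDesign,
    assemble_design_matrix,
    generate_study,
    run_mccv,
)

design = StudyDesign(n_participants=3, n_sessions=2, n_trials=6, n_epochs=8)
dataset = generate_study(design, seed=1)
print(f"simulated {len(dataset)} epochs; extracting features ...")

matrix = assemble_design_matrix(dataset)
config = SelectionConfig(n_reps_round1=5, n_reps_round2=5, cv_folds=5,
                         n_lambdas=30, lambda_min_ratio=0.1, seed=1)
report = run_mccv(matrix, config, n_splits=2, seed=1)

print("\nper-split report (adjusted R², LOTO Q², test Q², RMSE, median AE,")
print("predictor count, capped predictions):")
print(report.table.round(3).to_string())
print("\nmean ± sd:")
print(report.summary.round(3).to_string())
print("\nper-participant RMSE on the detail split:")
print(report.per_participant_rmse.round(3).to_string())
print("\nEach row is one random leave-one-trial-out-per-session split; test")
print("Q² > 0 means the model beats the training-mean predictor on trials")
print("it never saw.")
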