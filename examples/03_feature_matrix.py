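"""Extract the per-epoch feature dictionary and expand the eight baseline
versions into the full design matrix.

Base features per category: ECG 28, EDA 63, respiration 28, EEG 125,
fNIRS 360, eye 37, embedded 16, background 25 (682 total).  Psychophysio-
logical features carry all eight baseline versions; EEG only the pre-trial
ratio (v4); fNIRS only the pre-trial difference (v1) — 1,774 columns.
"""

from physiotrust import StudyDesign, generate_study, assemble_design_matrix
from physiotrust.features.dictionary import CATEGORY_COUNTS

design = StudyDesign(n_participants=1, n_sessions=2, n_trials=2, n_epochs=4)
dataset = generate_study(design, seed=4)
fm = assemble_design_matrix(dataset)

print("base feature counts:", CATEGORY_COUNTS)
print(f"base matrix: {fm.base.shape[0]} epochs x {fm.base.shape[1] - 5} features")

X, y = fm.versioned()
print(f"versioned design matrix: {X.shape[0]} x {X.shape[1]} (expect 1,774 columns)")
print("example columns:", list(X.columns[:3]), "...", list(X.columns[-3:]))

row = fm.base.iloc[0]
print(f"\nepoch (p{int(row.participant)}, s{int(row.session)}, t{int(row.trial)}, "
      f"e{int(row.epoch)}): mean HR {row.ecg_hr_mean:.1f} bpm, "
      f"SCL {row.eda_scl_mean:.2f} µS, trust y={row.y:.3f}")
print("pre-trial-baselined HR (v1):", round(X.iloc[0]["ecg_hr_mean__v1"], 3),
      "= active minus that trial's baseline HR")
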