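"""Generate a synthetic trust study and inspect its structure.

The generator reproduces the protocol of a multi-session human-autonomy
teaming experiment: participants x sessions x trials x 45-s epochs, one
trust report per epoch, and a planted sparse linear mapping from latent
physiological states to trust.
"""

import numpy as np

from physiotrust import StudyDesign, generate_study, inject_missingness

design = StudyDesign(n_participants=2, n_sessions=2, n_trials=3, n_epochs=8)
dataset = generate_study(design, seed=1)
inject_missingness(dataset, epoch_drop_p=0.01, seed=2)

print(f"epoch records: {len(dataset)} "
      f"({design.n_participants}x{design.n_sessions}x{design.n_trials}x{design.n_epochs})")
print(f"pre-experimental baselines: {len(dataset.preexp_baselines)} (one per session)")
print(f"pre-trial baselines: {len(dataset.pretrial_baselines)} (trials 2+)")
print(f"missing fraction (epoch x stream slots): {dataset.missing_fraction():.4f}")

truth = dataset.truth
print(f"\nplanted predictors ({len(truth.planted)}), beta in trust units per SD:")
for p, b in zip(truth.planted, truth.betas):
    print(f"  {p.name:24s} beta={b:+.4f}  stream={p.stream}")

rec = dataset.records[0]
ecg, ecg_truth = rec.signals("ecg")
print(f"\nfirst epoch {rec.key}: trust report y={rec.y:.3f}")
print(f"  ECG: {ecg.size} samples at 500 Hz, {len(ecg_truth['r_peaks'])} true R-peaks")
print(f"  embedded record: {rec.embedded['n_reviewed']}/{rec.embedded['n_satellites']} "
      "satellites reviewed")

# The trust report is the planted linear form plus noise, clipped to [0, 1]:
recon = truth.intercept + truth.participant_offsets[rec.participant] \
    + truth.session_effects[(rec.participant, rec.session)] + float(truth.betas @ rec.z)
print(f"  systematic trust {recon:.3f} (+ reporting noise sd {truth.noise_sd}) -> y")
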