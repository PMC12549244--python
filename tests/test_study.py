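"""Study-level generator: protocol structure, planted trust mapping,
determinism, missingness rules."""

import numpy as np
import pytest

from physiotrust import StudyDesign, TrustSpec, generate_study, inject_missingness
from physiotrust.synth.study import DEFAULT_PLANTED, PlantedFeature


def test_default_design_yields_2304_epoch_records():
    ds = generate_study(StudyDesign(), seed=0)
    assert len(ds) == 2304  # 12 x 4 x 6 x 8


def test_tiny_design_record_count_and_baselines():
    d = StudyDesign(n_participants=1, n_sessions=1, n_trials=1, n_epochs=8)
    ds = generate_study(d, seed=0)
    assert len(ds) == 8
    assert len(ds.preexp_baselines) == 1
    assert len(ds.pretrial_baselines) == 0  # trial 1 uses the pre-exp tail


def test_same_seed_identical_dataset_field_by_field():
    d = StudyDesign(n_participants=1, n_sessions=1, n_trials=2, n_epochs=3)
    a = generate_study(d, seed=5)
    b = generate_study(d, seed=5)
    for ra, rb in zip(a.records, b.records):
        assert ra.key == rb.key
        assert ra.y == rb.y
        assert np.array_equal(ra.z, rb.z)
        assert ra.embedded == rb.embedded
        xa, _ = ra.signals("ecg")
        xb, _ = rb.signals("ecg")
        assert np.array_equal(xa, xb)
    c = generate_study(d, seed=6)
    assert any(ra.y != rc.y for ra, rc in zip(a.records, c.records))


def test_trust_in_unit_interval_and_linear_structure():
    d = StudyDesign(n_participants=2, n_sessions=2, n_trials=2, n_epochs=8)
    spec = TrustSpec(noise_sd=0.0, participant_sd=0.0,
                     reliability_effect=0.0, explainability_effect=0.0)
    ds = generate_study(d, spec, seed=1)
    for rec in ds.records:
        assert 0.0 <= rec.y <= 1.0
        # noiseless: trust is exactly the planted linear form (pre-clip)
        expect = spec.intercept + float(ds.truth.betas @ rec.z)
        assert rec.y == pytest.approx(np.clip(expect, 0, 1), abs=1e-12)


def test_planted_effect_size_convention():
    spec = TrustSpec()
    # equal |beta| with signal R2 = 0.85 at the configured noise SD
    sig_var = float(np.sum(spec.betas**2))
    r2 = sig_var / (sig_var + spec.noise_sd**2)
    assert r2 == pytest.approx(0.85, abs=1e-9)
    assert np.all(np.abs(spec.betas) / spec.noise_sd >= 0.3)


def test_planted_features_span_at_least_four_streams():
    streams = {p.stream for p in DEFAULT_PLANTED}
    assert len(DEFAULT_PLANTED) == 15
    assert len(streams) >= 4


def test_unknown_planted_feature_rejected():
    bad = TrustSpec(planted=(PlantedFeature("not_a_feature", "ecg", 1),))
    with pytest.raises(ValueError, match="not in the feature dictionary"):
        generate_study(StudyDesign(1, 1, 1, 1), bad, seed=0)


def test_session_conditions_modulate_trust_mean():
    d = StudyDesign(n_participants=3, n_sessions=4, n_trials=2, n_epochs=8)
    spec = TrustSpec(participant_sd=0.0)
    ds = generate_study(d, spec, seed=2)
    by_rel = {0.67: [], 0.84: []}
    for rec in ds.records:
        by_rel[rec.condition["reliability"]].append(rec.trust_sys)
    assert np.mean(by_rel[0.84]) > np.mean(by_rel[0.67])


class TestMissingness:
    def _ds(self, seed=0):
        d = StudyDesign(n_participants=2, n_sessions=2, n_trials=3, n_epochs=8)
        return generate_study(d, seed=seed)

    def test_zero_probabilities_leave_dataset_unchanged(self):
        ds = inject_missingness(self._ds(), 0.0, 0.0, 0, seed=0)
        assert ds.missing_fraction() == 0.0

    def test_epoch_drop_rate_matches_target(self):
        # default target reproduces the reference imputed fraction (0.24%)
        ds = generate_study(StudyDesign(), seed=1)
        inject_missingness(ds, epoch_drop_p=0.0024, seed=1)
        frac = ds.missing_fraction()
        n_slots = len(ds) * 6
        se = np.sqrt(0.0024 * (1 - 0.0024) / n_slots)
        assert abs(frac - 0.0024) < 4 * se

    def test_whole_session_stream_drop_flags_every_epoch(self):
        ds = inject_missingness(self._ds(), 0.0, 0.0, 1, seed=3)
        flagged = [
            (r.participant, r.session, s)
            for r in ds.records
            for s in r.missing
            if r.missing[s]
        ]
        assert len(set(flagged)) == 1
        p, sess, stream = flagged[0]
        n_epochs_in_session = sum(
            1 for r in ds.records if (r.participant, r.session) == (p, sess)
        )
        assert len(flagged) == n_epochs_in_session

    def test_trust_reports_never_dropped(self):
        ds = inject_missingness(self._ds(), 0.3, 0.0, 0, seed=4)
        assert all(np.isfinite(r.y) for r in ds.records)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            inject_missingness(self._ds(), epoch_drop_p=1.5)

    def test_total_wipeout_rejected(self):
        d = StudyDesign(n_participants=1, n_sessions=1, n_trials=2, n_epochs=4)
        ds = generate_study(d, seed=0)
        with pytest.raises(ValueError, match="imputation undefined"):
            inject_missingness(ds, epoch_drop_p=1.0, seed=0)
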