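"""Full synthetic study generation with a planted sparse trust structure.

The generator reproduces the protocol hierarchy (participants x sessions x
trials x 45-s epochs, with per-session 2-min pre-experimental and per-trial
45-s pre-trial baselines) and plants a known linear mapping from a sparse
set of latent physiological features to the trust report:

    y = clip(b0 + delta_p + session_effect + sum_i beta_i * z_i + eps, 0, 1)

where each ``z_i ~ N(0,1)`` is an epoch-level latent state realized
physically in the raw signals (e.g. ``z`` for mean heart rate shifts the
ECG generator's HR parameter), ``delta_p`` is a participant's dispositional
offset (echoed noisily by the background surveys), and the session's
reliability/explainability condition shifts the trust mean.  The ground
truth (coefficients, latent draws, per-epoch systematic trust) is stored so
support-recovery and calibration tests can compare fitted models against
what was planted.

Effect-size convention: planted coefficients share one magnitude chosen so
that the latent signal explains ``signal_r2`` of the (unclipped) trust
variance given ``noise_sd``; each |beta|/noise_sd is then well above 0.3.

Because a full-protocol dataset holds ~600 M raw samples, epoch records
store generator parameters and seeds instead of waveforms; signals are
materialized lazily (and deterministically) on access.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from physiotrust.design import StudyDesign
from physiotrust.synth import signals as sig
from physiotrust.synth.embedded import (
    embedded_link,
    generate_background,
    generate_embedded,
)

__all__ = [
    "PlantedFeature",
    "TrustSpec",
    "TrustGroundTruth",
    "EpochRecord",
    "BaselineRecord",
    "StudyDataset",
    "generate_study",
    "inject_missingness",
    "STREAMS",
    "DEFAULT_PLANTED",
]

STREAMS: tuple[str, ...] = ("ecg", "eda", "rsp", "eeg", "fnirs", "eye")


@dataclass(frozen=True)
class PlantedFeature:
    """One planted predictor: the base-feature name it is read out as, the
    documented near-duplicate readouts (aliases), and the coefficient sign."""

    name: str
    stream: str
    sign: int
    aliases: tuple[str, ...] = ()


# The 15 default planted features span all six streams.  Aliases list the
# extracted features that are deterministic near-duplicates of the same
# generator parameter (e.g. RMSSD = sqrt(2)*SDNN for i.i.d. RR intervals),
# among which LASSO keeps an arbitrary representative.
DEFAULT_PLANTED: tuple[PlantedFeature, ...] = (
    PlantedFeature("ecg_hr_mean", "ecg", +1,
                   ("ecg_rr_mean", "ecg_rr_median", "ecg_hr_min", "ecg_hr_max")),
    PlantedFeature("ecg_sdnn", "ecg", -1,
                   ("ecg_rmssd", "ecg_sdsd", "ecg_rr_cv", "ecg_rr_range",
                    "ecg_rr_min", "ecg_rr_max", "ecg_sd1", "ecg_sd2",
                    "ecg_pnn50", "ecg_pnn20", "ecg_total_power",
                    "ecg_vlf_power", "ecg_lf_power", "ecg_hf_power")),
    PlantedFeature("eda_scl_mean", "eda", +1,
                   ("eda_tonic_mean", "eda_scl_min", "eda_scl_max",
                    "eda_tonic_min", "eda_tonic_max", "eda_scl_auc",
                    "eda_tonic_auc")),
    PlantedFeature("eda_scr_amp_mean", "eda", +1,
                   ("eda_scr_amp_max", "eda_scr_amp_min", "eda_scr_amp_sum",
                    "eda_iscr", "eda_phasic_mean", "eda_phasic_sd",
                    "eda_phasic_max", "eda_phasic_auc", "eda_driver_mean",
                    "eda_driver_sd", "eda_driver_max", "eda_deriv_sd",
                    "eda_deriv_max", "eda_deriv_range", "eda_phasic_range")),
    PlantedFeature("rsp_rate", "rsp", -1,
                   ("rsp_bi_mean", "rsp_dom_freq", "rsp_bi_min", "rsp_bi_max")),
    PlantedFeature("rsp_amp_mean", "rsp", +1,
                   ("rsp_amp_max", "rsp_amp_min", "rsp_sig_sd", "rsp_sig_rms",
                    "rsp_sig_auc")),
    PlantedFeature("eeg_Pz_alpha", "eeg", +1,
                   ("eeg_parietal_alpha", "eeg_whole_alpha")),
    PlantedFeature("eeg_Fz_theta", "eeg", -1,
                   ("eeg_prefrontal_theta", "eeg_whole_theta")),
    PlantedFeature("eeg_occipital_beta", "eeg", +1,
                   ("eeg_O1_beta", "eeg_O2_beta", "eeg_whole_beta")),
    PlantedFeature("fnirs_ch03_hbo_max", "fnirs", +1,
                   ("fnirs_ch03_hbo_rms", "fnirs_ch03_hbo_var",
                    "fnirs_ch03_hbo_auc", "fnirs_ch03_hbr_min",
                    "fnirs_ch03_hbr_rms", "fnirs_ch03_hbr_var")),
    PlantedFeature("fnirs_ch07_hbo_max", "fnirs", -1,
                   ("fnirs_ch07_hbo_rms", "fnirs_ch07_hbo_var",
                    "fnirs_ch07_hbo_auc", "fnirs_ch07_hbr_min",
                    "fnirs_ch07_hbr_rms", "fnirs_ch07_hbr_var")),
    PlantedFeature("eye_pupil_mean", "eye", +1,
                   ("eye_pupil_min", "eye_pupil_max", "eye_pupil_rms")),
    PlantedFeature("eye_fix_dur_mean", "eye", +1,
                   ("eye_fix_dur_sd", "eye_fix_total", "eye_sacc_count",
                    "eye_sacc_rate")),
    PlantedFeature("eye_sacc_amp_mean", "eye", -1, ()),
    PlantedFeature("eye_blink_dur_mean", "eye", -1,
                   ("eye_blink_dur_max", "eye_blink_dur_min",
                    "eye_blink_dur_sd", "eye_closure_frac")),
)

_PZ = sig.EEG_CHANNELS.index("Pz")
_FZ = sig.EEG_CHANNELS.index("Fz")
_O1 = sig.EEG_CHANNELS.index("O1")
_O2 = sig.EEG_CHANNELS.index("O2")


@dataclass(frozen=True)
class TrustSpec:
    """Configuration of the planted trust structure."""

    planted: tuple[PlantedFeature, ...] = DEFAULT_PLANTED
    intercept: float = 0.55
    noise_sd: float = 0.06
    signal_r2: float = 0.85
    participant_sd: float = 0.05
    reliability_effect: float = 0.05
    explainability_effect: float = 0.02
    embedded_noise_sd: float = 0.22

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.signal_r2 < 1):
            raise ValueError("signal_r2 must be in (0, 1)")

    @property
    def beta_magnitude(self) -> float:
        """Shared |beta| so the latent signal explains signal_r2 of the
        unclipped trust variance."""
        if self.noise_sd == 0:
            return 0.037  # noiseless runs keep the default effect scale
        sig_var = self.noise_sd**2 * self.signal_r2 / (1.0 - self.signal_r2)
        return float(np.sqrt(sig_var / len(self.planted)))

    @property
    def betas(self) -> np.ndarray:
        return np.array([p.sign * self.beta_magnitude for p in self.planted])


@dataclass
class TrustGroundTruth:
    """What was planted, for recovery tests."""

    planted: tuple[PlantedFeature, ...]
    betas: np.ndarray
    intercept: float
    noise_sd: float
    participant_offsets: dict[int, float]
    session_effects: dict[tuple[int, int], float]
    z: dict[tuple, np.ndarray] = field(default_factory=dict)
    trust_sys: dict[tuple, float] = field(default_factory=dict)

    @property
    def active_feature_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.planted)

    def alias_groups(self) -> dict[str, tuple[str, ...]]:
        """Planted name -> (name, *aliases)."""
        return {p.name: (p.name,) + p.aliases for p in self.planted}


def _epoch_seed(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master) & 0x7FFFFFFF, *key]))


def _stream_params(design: StudyDesign, duration_s: float, z_by_name: dict[str, float]) -> dict:
    """Map latent feature values to per-stream generator kwargs."""
    fs = design.sampling_rates

    def zv(name):
        return z_by_name.get(name, 0.0)

    alpha = np.full(19, 20.0)
    alpha[_PZ] *= max(0.1, 1.0 + 0.35 * zv("eeg_Pz_alpha"))
    theta = np.full(19, 15.0)
    theta[_FZ] *= max(0.1, 1.0 + 0.35 * zv("eeg_Fz_theta"))
    beta_band = np.full(19, 8.0)
    occ = max(0.1, 1.0 + 0.35 * zv("eeg_occipital_beta"))
    beta_band[_O1] *= occ
    beta_band[_O2] *= occ

    act = np.ones(20)
    act[2] = max(0.1, 1.0 + 0.30 * zv("fnirs_ch03_hbo_max"))
    act[6] = max(0.1, 1.0 + 0.30 * zv("fnirs_ch07_hbo_max"))

    return {
        "ecg": dict(
            duration_s=duration_s,
            mean_hr_bpm=float(np.clip(72.0 + 6.0 * zv("ecg_hr_mean"), 45.0, 150.0)),
            hrv_sd_ms=float(np.clip(40.0 + 12.0 * zv("ecg_sdnn"), 8.0, 120.0)),
            fs=fs["ecg"],
            mains_amp=0.02,
        ),
        "eda": dict(
            duration_s=duration_s,
            tonic_level_uS=float(np.clip(8.0 + 1.5 * zv("eda_scl_mean"), 1.5, 38.0)),
            scr_rate_per_min=6.0,
            scr_amp_uS=float(np.clip(0.4 + 0.12 * zv("eda_scr_amp_mean"), 0.05, 2.0)),
            fs=fs["eda"],
        ),
        "rsp": dict(
            duration_s=duration_s,
            rate_bpm=float(np.clip(15.0 + 2.5 * zv("rsp_rate"), 6.0, 30.0)),
            amplitude=float(np.clip(1.0 + 0.25 * zv("rsp_amp_mean"), 0.2, 3.0)),
            fs=fs["rsp"],
        ),
        "eeg": dict(
            duration_s=duration_s,
            band_power_targets={"alpha": alpha, "theta": theta, "beta": beta_band},
            blink_rate_per_min=12.0,
            fs=fs["eeg"],
        ),
        "fnirs": dict(
            duration_s=duration_s,
            activation_amp=act,
            time_to_peak_s=6.0,
            fs=fs["fnirs"],
        ),
        "eye": dict(
            duration_s=duration_s,
            pupil_mean_mm=float(np.clip(3.5 + 0.4 * zv("eye_pupil_mean"), 2.0, 6.0)),
            blink_rate_per_min=12.0,
            blink_dur_s=float(np.clip(0.18 + 0.045 * zv("eye_blink_dur_mean"), 0.05, 0.5)),
            fix_dur_s=float(np.clip(0.45 + 0.10 * zv("eye_fix_dur_mean"), 0.15, 1.2)),
            saccade_amp_deg=float(np.clip(6.0 + 1.2 * zv("eye_sacc_amp_mean"), 1.0, 15.0)),
            fs=fs["eye"],
        ),
    }


_GENERATORS = {
    "ecg": sig.generate_ecg,
    "eda": sig.generate_eda,
    "rsp": sig.generate_resp,
    "eeg": sig.generate_eeg,
    "fnirs": sig.generate_fnirs,
    "eye": sig.generate_eye,
}


class _SignalCarrier:
    """Lazy, deterministic signal materialization shared by epoch and
    baseline records."""

    gen_params: dict
    seeds: dict

    def signals(self, stream: str | None = None):
        """Materialize raw signals: dict stream -> (data, truth), or one
        stream's (data, truth) when ``stream`` is given."""
        if stream is not None:
            fn = _GENERATORS[stream]
            rng = np.random.default_rng(self.seeds[stream])
            return fn(seed=rng, **self.gen_params[stream])
        return {s: self.signals(s) for s in self.gen_params}


@dataclass
class EpochRecord(_SignalCarrier):
    """One 45-s observation: indices, trust report, lazy signal bundle,
    embedded-measure record and missingness flags."""

    participant: int
    session: int
    trial: int
    epoch: int
    y: float
    condition: dict
    trust_sys: float
    z: np.ndarray
    gen_params: dict
    seeds: dict
    embedded: dict
    missing: dict = field(default_factory=lambda: {s: False for s in STREAMS})

    @property
    def key(self) -> tuple[int, int, int, int]:
        return (self.participant, self.session, self.trial, self.epoch)


@dataclass
class BaselineRecord(_SignalCarrier):
    """Resting baseline period: 'preexp' (2 min, per session) or 'pretrial'
    (45 s, before trials 2+)."""

    kind: str
    participant: int
    session: int
    trial: int | None
    gen_params: dict
    seeds: dict
    missing: dict = field(default_factory=lambda: {s: False for s in STREAMS})


@dataclass
class StudyDataset:
    design: StudyDesign
    records: list
    preexp_baselines: dict
    pretrial_baselines: dict
    truth: TrustGroundTruth
    background: dict
    seed: int
    trust_spec: "TrustSpec | None" = None

    def record(self, key) -> EpochRecord:
        return self._index[tuple(key)]

    def __post_init__(self):
        self._index = {r.key: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def missing_fraction(self) -> float:
        """Fraction of epoch x stream observation slots flagged missing."""
        flags = [r.missing[s] for r in self.records for s in STREAMS]
        return float(np.mean(flags))


def generate_study(
    design: StudyDesign | None = None,
    trust_spec: TrustSpec | None = None,
    seed: int = 0,
) -> StudyDataset:
    """Generate a complete synthetic study.

    One :class:`EpochRecord` per (participant, session, trial, epoch), plus
    per-session pre-experimental and per-trial pre-trial baseline records
    (trial 1's baseline is the tail of the pre-experimental period and is
    not stored separately).  Identical (design, spec, seed) yields an
    identical dataset.
    """
    design = design or StudyDesign()
    spec = trust_spec or TrustSpec()

    from physiotrust.features.dictionary import BASE_FEATURE_NAMES

    unknown = [p.name for p in spec.planted if p.name not in BASE_FEATURE_NAMES]
    if unknown:
        raise ValueError(f"planted feature names not in the feature dictionary: {unknown}")

    betas = spec.betas
    names = [p.name for p in spec.planted]

    participant_offsets = {
        p: float(_epoch_seed(seed, p, 0, 0, 0, 99).normal(0.0, spec.participant_sd))
        for p in range(1, design.n_participants + 1)
    }
    session_effects = {}
    for p in range(1, design.n_participants + 1):
        for s in range(1, design.n_sessions + 1):
            cond = design.condition(s)
            eff = spec.reliability_effect * (1.0 if cond["reliability"] >= 0.8 else -1.0)
            eff += spec.explainability_effect * (
                1.0 if cond["explainability"] == "high" else -1.0
            )
            session_effects[(p, s)] = eff

    truth = TrustGroundTruth(
        planted=spec.planted,
        betas=betas,
        intercept=spec.intercept,
        noise_sd=spec.noise_sd,
        participant_offsets=participant_offsets,
        session_effects=session_effects,
    )

    records: list[EpochRecord] = []
    preexp: dict = {}
    pretrial: dict = {}
    background: dict = {}

    for p in range(1, design.n_participants + 1):
        bg_rng = _epoch_seed(seed, p, 0, 0, 0, 7)
        background[p] = generate_background(p, participant_offsets[p], seed=bg_rng)
        for s in range(1, design.n_sessions + 1):
            cond = dict(design.condition(s))
            base_params = _stream_params(design, design.preexp_baseline_s, {})
            preexp[(p, s)] = BaselineRecord(
                kind="preexp",
                participant=p,
                session=s,
                trial=None,
                gen_params=base_params,
                seeds={st: [seed, p, s, 0, 0, k] for k, st in enumerate(STREAMS)},
            )
            for t in range(1, design.n_trials + 1):
                if t > 1:
                    bparams = _stream_params(design, design.pretrial_baseline_s, {})
                    pretrial[(p, s, t)] = BaselineRecord(
                        kind="pretrial",
                        participant=p,
                        session=s,
                        trial=t,
                        gen_params=bparams,
                        seeds={st: [seed, p, s, t, 100, k] for k, st in enumerate(STREAMS)},
                    )
                trial_sys = []
                trial_records = []
                for e in range(1, design.n_epochs + 1):
                    rng = _epoch_seed(seed, p, s, t, e, 1)
                    z = rng.standard_normal(len(names))
                    t_sys = (
                        spec.intercept
                        + participant_offsets[p]
                        + session_effects[(p, s)]
                        + float(betas @ z)
                    )
                    eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                    y = float(np.clip(t_sys + eps, 0.0, 1.0))
                    gen_params = _stream_params(
                        design, design.epoch_s, dict(zip(names, z))
                    )
                    rec = EpochRecord(
                        participant=p,
                        session=s,
                        trial=t,
                        epoch=e,
                        y=y,
                        condition=cond,
                        trust_sys=t_sys,
                        z=z,
                        gen_params=gen_params,
                        seeds={st: [seed, p, s, t, e, 10 + k] for k, st in enumerate(STREAMS)},
                        embedded={},  # filled after the trial's reliance slider
                    )
                    truth.z[rec.key] = z
                    truth.trust_sys[rec.key] = t_sys
                    trial_sys.append(float(np.clip(t_sys, 0.0, 1.0)))
                    trial_records.append(rec)
                # post-trial reliance slider from the trial's mean systematic
                # trust, then broadcast to the trial's epochs
                slider_rng = _epoch_seed(seed, p, s, t, 0, 5)
                reliance = float(
                    np.clip(
                        embedded_link("reliance", float(np.mean(trial_sys)))
                        + 0.05 * slider_rng.standard_normal(),
                        0.0,
                        1.0,
                    )
                )
                for rec in trial_records:
                    emb_rng = _epoch_seed(seed, p, s, t, rec.epoch, 6)
                    rec.embedded = generate_embedded(
                        session=s,
                        trial=t,
                        epoch=rec.epoch,
                        explainability=cond["explainability"],
                        trust=float(np.clip(rec.trust_sys, 0.0, 1.0)),
                        reliance_slider=reliance,
                        seed=emb_rng,
                        trust_noise_sd=spec.embedded_noise_sd,
                    )
                records.extend(trial_records)

    return StudyDataset(
        design=design,
        records=records,
        preexp_baselines=preexp,
        pretrial_baselines=pretrial,
        truth=truth,
        background=background,
        seed=seed,
        trust_spec=spec,
    )


def inject_missingness(
    dataset: StudyDataset,
    epoch_drop_p: float = 0.0024,
    trial_drop_p: float = 0.0,
    session_stream_drop_count: int = 0,
    seed: int = 0,
) -> StudyDataset:
    """Flag epoch x stream slots as missing (trust reports are never dropped).

    ``epoch_drop_p`` is the per-(epoch, stream) Bernoulli probability, so it
    equals the expected missing fraction; ``trial_drop_p`` drops whole
    (trial, stream) blocks; ``session_stream_drop_count`` whole-session
    single-stream outages (the reference study observed two).  Raises if the
    draw would leave some participant-stream with no donor session.
    """
    for p_ in (epoch_drop_p, trial_drop_p):
        if not (0.0 <= p_ <= 1.0):
            raise ValueError("drop probabilities must be in [0, 1]")
    if session_stream_drop_count < 0:
        raise ValueError("session_stream_drop_count must be >= 0")

    rng = np.random.default_rng(seed)
    d = dataset.design

    for rec in dataset.records:
        for s in STREAMS:
            if rng.random() < epoch_drop_p:
                rec.missing[s] = True

    if trial_drop_p > 0:
        for p in range(1, d.n_participants + 1):
            for se in range(1, d.n_sessions + 1):
                for t in range(1, d.n_trials + 1):
                    for s in STREAMS:
                        if rng.random() < trial_drop_p:
                            for e in range(1, d.n_epochs + 1):
                                dataset.record((p, se, t, e)).missing[s] = True

    if session_stream_drop_count > 0:
        triples = [
            (p, se, s)
            for p in range(1, d.n_participants + 1)
            for se in range(1, d.n_sessions + 1)
            for s in STREAMS
        ]
        picks = rng.choice(len(triples), size=session_stream_drop_count, replace=False)
        for i in picks:
            p, se, s = triples[i]
            for t in range(1, d.n_trials + 1):
                for e in range(1, d.n_epochs + 1):
                    dataset.record((p, se, t, e)).missing[s] = True
            dataset.preexp_baselines[(p, se)].missing[s] = True
            for t in range(2, d.n_trials + 1):
                dataset.pretrial_baselines[(p, se, t)].missing[s] = True

    # donor check: every (participant, stream) needs at least one session
    # with observed data, and no participant-session may lose every epoch of
    # every stream
    for p in range(1, d.n_participants + 1):
        for s in STREAMS:
            per_session_all_missing = []
            for se in range(1, d.n_sessions + 1):
                flags = [
                    dataset.record((p, se, t, e)).missing[s]
                    for t in range(1, d.n_trials + 1)
                    for e in range(1, d.n_epochs + 1)
                ]
                per_session_all_missing.append(all(flags))
            if all(per_session_all_missing):
                raise ValueError(
                    f"participant {p} stream {s}: all sessions fully missing, "
                    "imputation undefined"
                )
        for se in range(1, d.n_sessions + 1):
            if all(
                dataset.record((p, se, t, e)).missing[s]
                for t in range(1, d.n_trials + 1)
                for e in range(1, d.n_epochs + 1)
                for s in STREAMS
            ):
                raise ValueError(
                    f"participant {p} session {se}: every stream of every epoch "
                    "dropped, imputation undefined"
                )
    return dataset
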