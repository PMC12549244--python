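"""Study protocol description.

The experimental protocol this package emulates is a multi-session
human-on-the-loop supervision task: participants monitor a simulated
autonomous system across several sessions, each session consisting of
6-minute trials subdivided into 45-s epochs.  At the end of every epoch the
participant reports trust on a continuous [0, 1] slider, so the epoch is the
unit of observation.  Each session carries one cell of a 2x2
reliability x explainability manipulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StudyDesign", "SESSION_CONDITIONS", "DEFAULT_SAMPLING_RATES"]

#: Sampling rate per stream in Hz.  The hardware class implied by a 3-lead
#: ECG, finger EDA, chest-band respiration, 19-channel EEG, 20-channel fNIRS
#: and head-mounted eye tracking typically runs at these rates.
DEFAULT_SAMPLING_RATES: dict[str, float] = {
    "ecg": 500.0,
    "eda": 32.0,
    "rsp": 32.0,
    "eeg": 250.0,
    "fnirs": 10.0,
    "eye": 120.0,
}

#: The four autonomous-system conditions, one per session: system reliability
#: (fraction of correct classifications) crossed with explainability
#: (terse vs naturalistic communication).
SESSION_CONDITIONS: tuple[dict, ...] = (
    {"reliability": 0.67, "explainability": "low"},
    {"reliability": 0.67, "explainability": "high"},
    {"reliability": 0.84, "explainability": "low"},
    {"reliability": 0.84, "explainability": "high"},
)


@dataclass(frozen=True)
class StudyDesign:
    """Protocol dimensions and timing constants.

    Defaults reproduce the reference protocol: 12 participants x 4 sessions
    x 6 trials x 8 epochs of 45 s (2,304 epochs), a 2-min pre-experimental
    baseline per session and a 45-s pre-trial baseline before trials 2-6.
    Trial 1 begins immediately after the pre-experimental baseline, so its
    per-trial baseline is taken as the last 45 s of the pre-experimental
    baseline.
    """

    n_participants: int = 12
    n_sessions: int = 4
    n_trials: int = 6
    n_epochs: int = 8
    epoch_s: float = 45.0
    pretrial_baseline_s: float = 45.0
    preexp_baseline_s: float = 120.0
    sampling_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_RATES)
    )

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_sessions", "n_trials", "n_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("epoch_s", "pretrial_baseline_s", "preexp_baseline_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for stream, fs in self.sampling_rates.items():
            if fs <= 0:
                raise ValueError(f"sampling rate for {stream!r} must be positive")

    @property
    def n_epochs_total(self) -> int:
        return self.n_participants * self.n_sessions * self.n_trials * self.n_epochs

    @property
    def trial_s(self) -> float:
        """Active trial length in seconds (epochs are contiguous)."""
        return self.n_epochs * self.epoch_s

    def condition(self, session: int) -> dict:
        """Reliability/explainability cell for a 1-based session index."""
        return SESSION_CONDITIONS[(session - 1) % len(SESSION_CONDITIONS)]

    def epoch_keys(self):
        """Yield (participant, session, trial, epoch) 1-based index tuples."""
        for p in range(1, self.n_participants + 1):
            for s in range(1, self.n_sessions + 1):
                for t in range(1, self.n_trials + 1):
                    for e in range(1, self.n_epochs + 1):
                        yield (p, s, t, e)
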