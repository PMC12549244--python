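"""Leave-one-trial-out-per-session (LOTOPS) train/test splitting.

For every (participant, session) pair exactly one of the session's trials
is withheld, so the test partition is 1/Tth of the epochs (1/6 with the
default six trials) and every participant and session contributes unseen
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from physiotrust.design import StudyDesign

__all__ = ["SplitScheme", "lotops_split"]


@dataclass(frozen=True)
class SplitScheme:
    """Mapping (participant, session) -> withheld trial, with derived
    epoch-level train/test membership."""

    withheld: dict[tuple[int, int], int]
    seed: int

    def is_test(self, keys: pd.DataFrame) -> np.ndarray:
        """Boolean test-membership for rows with participant/session/trial
        columns."""
        wt = keys.apply(
            lambda r: self.withheld[(int(r["participant"]), int(r["session"]))],
            axis=1,
        )
        return (keys["trial"].to_numpy() == wt.to_numpy())

    def n_withheld_trials(self) -> int:
        return len(self.withheld)


def lotops_split(design: StudyDesign, seed: int = 0) -> SplitScheme:
    """Draw one uniformly random withheld trial per participant-session."""
    if design.n_trials < 2:
        raise ValueError("LOTOPS needs at least 2 trials per session")
    rng = np.random.default_rng(seed)
    withheld = {
        (p, s): int(rng.integers(1, design.n_trials + 1))
        for p in range(1, design.n_participants + 1)
        for s in range(1, design.n_sessions + 1)
    }
    return SplitScheme(withheld=withheld, seed=seed)
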