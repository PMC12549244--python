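"""Shared fixtures: small end-to-end datasets (signal-level) and a fast
feature-level matrix builder that bypasses waveform synthesis for tests of
the modeling/validation harness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from physiotrust import StudyDesign, generate_study
from physiotrust.features import assemble_design_matrix
from physiotrust.features.dictionary import BASE_FEATURE_NAMES
from physiotrust.features.matrix import KEY_COLUMNS, PHYSIO_FEATURES, FeatureMatrix


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_participants=2, n_sessions=2, n_trials=3, n_epochs=4)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_study(small_design, seed=42)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return assemble_design_matrix(small_dataset)


def make_feature_level_matrix(
    n_participants=4,
    n_sessions=2,
    n_trials=6,
    n_epochs=8,
    n_signal=6,
    signal_strength=0.06,
    noise_sd=0.05,
    seed=0,
    signal_from: str | None = None,
) -> tuple[FeatureMatrix, list]:
    """Build a FeatureMatrix directly at the feature level (no waveforms).

    Base features are standard normal draws; the trust report is a linear
    function of ``n_signal`` of them plus noise.  ``signal_from="emb"``
    restricts signal carriers to embedded measures, which enter the design
    matrix unversioned (useful for exact-fit checks).  Returns the matrix
    and the names of the signal-carrying base features.
    """
    rng = np.random.default_rng(seed)
    keys = [
        (p, s, t, e)
        for p in range(1, n_participants + 1)
        for s in range(1, n_sessions + 1)
        for t in range(1, n_trials + 1)
        for e in range(1, n_epochs + 1)
    ]
    n = len(keys)
    base = pd.DataFrame(keys, columns=KEY_COLUMNS)
    vals = rng.standard_normal((n, len(BASE_FEATURE_NAMES)))
    base = pd.concat(
        [base, pd.DataFrame(vals, columns=list(BASE_FEATURE_NAMES))], axis=1
    )
    # participant-constant background columns
    for c in [c for c in BASE_FEATURE_NAMES if c.startswith("bg_")]:
        per_p = dict(zip(range(1, n_participants + 1), rng.standard_normal(n_participants)))
        base[c] = base["participant"].map(per_p)

    if signal_from == "emb":
        pool = [c for c in BASE_FEATURE_NAMES if c.startswith("emb_")]
    else:
        pool = [c for c in BASE_FEATURE_NAMES if not c.startswith("bg_")]
    signal_cols = list(rng.choice(pool, size=n_signal, replace=False))
    betas = signal_strength * np.where(rng.random(n_signal) < 0.5, -1.0, 1.0)
    y = 0.55 + base[signal_cols].to_numpy() @ betas + noise_sd * rng.standard_normal(n)
    base["y"] = np.clip(y, 0.0, 1.0)

    trial_index = pd.MultiIndex.from_tuples(
        [
            (p, s, t)
            for p in range(1, n_participants + 1)
            for s in range(1, n_sessions + 1)
            for t in range(1, n_trials + 1)
        ]
    )
    pretrial = pd.DataFrame(
        rng.standard_normal((len(trial_index), len(PHYSIO_FEATURES))) * 0.1 + 1.0,
        index=trial_index,
        columns=list(PHYSIO_FEATURES),
    )
    sess_index = pd.MultiIndex.from_tuples(
        [(p, s) for p in range(1, n_participants + 1) for s in range(1, n_sessions + 1)]
    )
    preexp = pd.DataFrame(
        rng.standard_normal((len(sess_index), len(PHYSIO_FEATURES))) * 0.1 + 1.0,
        index=sess_index,
        columns=list(PHYSIO_FEATURES),
    )
    fm = FeatureMatrix(
        base=base,
        mask=pd.DataFrame(0, index=base.index, columns=list(PHYSIO_FEATURES), dtype=np.int8),
        pretrial=pretrial,
        preexp=preexp,
    )
    return fm, signal_cols


@pytest.fixture(scope="session")
def feature_level_matrix():
    return make_feature_level_matrix(seed=7)
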