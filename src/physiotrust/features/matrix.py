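"""Design-matrix assembly: extraction over the whole study, baselining,
hierarchical imputation.

The assembled :class:`FeatureMatrix` keeps the *base* (unversioned) features
together with the per-trial and per-session baseline feature tables, and
expands to the 1,774-column versioned matrix on demand.  The expansion is
split-aware: participant mean/SD for versions 7-8 are computed from a given
set of training epochs so that test epochs never leak into the statistics.

Missing data is imputed hierarchically, in the order (1) mean of the rest of
the trial, (2) mean of the rest of the session, (3) mean of the
participant's other sessions; a cell with no donor at any level is a hard
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from physiotrust.features.dictionary import (
    CATEGORY_FEATURES,
    FEATURE_DICTIONARY,
    PSYCHOPHYS_CATEGORIES,
)
from physiotrust.features.extract import (
    extract_background,
    extract_embedded,
    extract_epoch_features,
    extract_signal_features,
)

__all__ = [
    "FeatureMatrix",
    "assemble_design_matrix",
    "impute_missing",
    "hierarchical_impute",
    "KEY_COLUMNS",
]

KEY_COLUMNS = ["participant", "session", "trial", "epoch"]

_EPS = 1e-12


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Baseline-ratio with defined degenerate cases: 0/0 -> 1 (value equals
    its zero baseline: no change), x/0 -> NaN (imputed later)."""
    out = np.where(np.abs(den) > _EPS, num / np.where(den == 0, 1.0, den), np.nan)
    both_zero = (np.abs(den) <= _EPS) & (np.abs(num) <= _EPS)
    return np.where(both_zero, 1.0, out)

_PHYSIO_CATS = ("ecg", "eda", "rsp", "eeg", "fnirs", "eye")
PHYSIO_FEATURES = tuple(n for c in _PHYSIO_CATS for n in CATEGORY_FEATURES[c])
_PP_FEATURES = tuple(n for c in PSYCHOPHYS_CATEGORIES for n in CATEGORY_FEATURES[c])
_EEG_FEATURES = CATEGORY_FEATURES["eeg"]
_FNIRS_FEATURES = CATEGORY_FEATURES["fnirs"]


def hierarchical_impute(
    values: pd.DataFrame, keys: pd.DataFrame, allow_global: bool = False
):
    """Fill NaNs by trial-mates, then session-mates, then the participant's
    other sessions.  Returns ``(filled, levels)`` where ``levels`` records
    0 = observed, 1/2/3 = imputation level used (4 = global fallback when
    ``allow_global``).  Raises when a cell has no donor.
    """
    df = values.copy()
    levels = pd.DataFrame(0, index=df.index, columns=df.columns, dtype=np.int8)
    missing = df.isna()
    if not missing.any().any():
        return df, levels

    groupers = [
        (1, [keys["participant"], keys["session"], keys["trial"]]),
        (2, [keys["participant"], keys["session"]]),
        (3, [keys["participant"]]),
    ]
    for level, by in groupers:
        still = df.isna()
        if not still.any().any():
            break
        donor = df.groupby(by, sort=False).transform("mean")
        fill = still & donor.notna()
        df = df.where(~fill, donor)
        levels = levels.where(~fill, np.int8(level))
    still = df.isna()
    if still.any().any():
        if allow_global:
            donor = pd.DataFrame(
                np.broadcast_to(df.mean(axis=0).to_numpy(), df.shape),
                index=df.index,
                columns=df.columns,
            )
            fill = still & donor.notna()
            df = df.where(~fill, donor)
            levels = levels.where(~fill, np.int8(4))
            still = df.isna()
        if still.any().any():
            rows, cols = np.nonzero(still.to_numpy())
            cell = (df.index[rows[0]], df.columns[cols[0]])
            raise ValueError(f"no imputation donor at any level for cell {cell}")
    return df, levels


@dataclass
class FeatureMatrix:
    """Epochs x base features, with baseline tables retained for versioning."""

    base: pd.DataFrame          # KEY_COLUMNS + 682 base features + 'y'
    mask: pd.DataFrame          # imputation provenance for physio columns
    pretrial: pd.DataFrame      # (participant, session, trial) x 641 physio
    preexp: pd.DataFrame        # (participant, session) x 641 physio

    @property
    def keys(self) -> pd.DataFrame:
        return self.base[KEY_COLUMNS]

    @property
    def y(self) -> pd.Series:
        return self.base["y"]

    def __len__(self) -> int:
        return len(self.base)

    # -- versioned expansion ------------------------------------------------

    def versioned(self, train_index=None, impute: bool = True):
        """Expand to the full versioned design matrix.

        ``train_index`` (row labels of ``base``) restricts the participant
        mean/SD used by versions 7-8 to training epochs; default uses all
        epochs (descriptive-model setting).  Returns ``(X, y)`` with X in
        canonical column order.
        """
        base = self.base
        keys = self.keys
        pst = pd.MultiIndex.from_frame(keys[["participant", "session", "trial"]])
        ps = pd.MultiIndex.from_frame(keys[["participant", "session"]])

        # baseline tables may themselves carry NaN (undefined statistics in
        # a 45-s resting window); fill them hierarchically first
        bt_keys = self.pretrial.index.to_frame(index=False)
        bt_keys.columns = ["participant", "session", "trial"]
        bt, _ = hierarchical_impute(
            self.pretrial.reset_index(drop=True), bt_keys, allow_global=True
        )
        bt.index = self.pretrial.index
        be_keys = self.preexp.index.to_frame(index=False)
        be_keys.columns = ["participant", "session"]
        be_keys["trial"] = 0
        be, _ = hierarchical_impute(
            self.preexp.reset_index(drop=True), be_keys, allow_global=True
        )
        be.index = self.preexp.index
        bmean = bt.groupby(level=[0, 1]).mean()

        def aligned(table, index, cols):
            out = table.loc[index, list(cols)].to_numpy()
            return pd.DataFrame(out, index=base.index, columns=list(cols))

        blocks: dict[str, pd.DataFrame] = {}

        def add_block(cols, version, values):
            df = pd.DataFrame(values, index=base.index)
            df.columns = [f"{c}__v{version}" for c in cols]
            for c in df.columns:
                blocks[c] = df[c]

        # psychophysiological categories: all eight versions
        a_pp = base[list(_PP_FEATURES)]
        btr = aligned(bt, pst, _PP_FEATURES)
        bme = aligned(bmean, ps, _PP_FEATURES)
        bpe = aligned(be, ps, _PP_FEATURES)
        add_block(_PP_FEATURES, 1, a_pp.to_numpy() - btr.to_numpy())
        add_block(_PP_FEATURES, 2, a_pp.to_numpy() - bme.to_numpy())
        add_block(_PP_FEATURES, 3, a_pp.to_numpy() - bpe.to_numpy())
        for v, den in ((4, btr), (5, bme), (6, bpe)):
            add_block(_PP_FEATURES, v, _safe_ratio(a_pp.to_numpy(), den.to_numpy()))

        if train_index is None:
            train_rows = base
        else:
            train_rows = base.loc[train_index]
        stats = train_rows.groupby("participant")[list(_PP_FEATURES)].agg(["mean", "std"])
        mu = stats.xs("mean", axis=1, level=1)
        sd = stats.xs("std", axis=1, level=1)
        mu_al = aligned(mu, pd.Index(keys["participant"]), _PP_FEATURES).to_numpy()
        sd_al = aligned(sd, pd.Index(keys["participant"]), _PP_FEATURES).to_numpy()
        diff = a_pp.to_numpy() - mu_al
        z = np.where(
            sd_al > 1e-12,
            diff / np.where(sd_al == 0, 1, sd_al),
            # zero-variance feature: a value equal to the mean is "no
            # deviation" (0); a different value has no defined scale (NaN)
            np.where(np.abs(diff) < 1e-12, 0.0, np.nan),
        )
        add_block(_PP_FEATURES, 7, z)
        add_block(_PP_FEATURES, 8, a_pp.to_numpy() - mu_al)

        # EEG: version 4 only (pre-trial ratio)
        a_eeg = base[list(_EEG_FEATURES)].to_numpy()
        add_block(_EEG_FEATURES, 4, _safe_ratio(a_eeg, aligned(bt, pst, _EEG_FEATURES).to_numpy()))

        # fNIRS: version 1 only (pre-trial difference)
        a_fn = base[list(_FNIRS_FEATURES)].to_numpy()
        add_block(_FNIRS_FEATURES, 1, a_fn - aligned(bt, pst, _FNIRS_FEATURES).to_numpy())

        # embedded and background enter unversioned
        for c in CATEGORY_FEATURES["embedded"] + CATEGORY_FEATURES["background"]:
            blocks[c] = base[c]

        X = pd.concat(blocks, axis=1)
        X = X[list(FEATURE_DICTIONARY.versioned_names())]
        if impute:
            X, _ = hierarchical_impute(X, keys)
        return X, self.y.copy()


def impute_missing(matrix: FeatureMatrix) -> FeatureMatrix:
    """Hierarchically impute the base physiological features.

    Observed cells are preserved exactly; the returned matrix's ``mask``
    records the imputation level per cell (0 = observed).  Idempotent.
    """
    filled, levels = hierarchical_impute(
        matrix.base[list(PHYSIO_FEATURES)], matrix.keys
    )
    base = matrix.base.copy()
    base[list(PHYSIO_FEATURES)] = filled
    return FeatureMatrix(
        base=base, mask=levels, pretrial=matrix.pretrial, preexp=matrix.preexp
    )


def _slice_signals(signals: dict, t0: float, duration: float, rates: dict) -> dict:
    """Cut a time window out of a materialized signal bundle (used to derive
    trial 1's pre-trial baseline from the pre-experimental period's tail)."""
    out = {}
    for stream, data in signals.items():
        fs = rates[stream]
        lo = int(round(t0 * fs))
        hi = lo + int(round(duration * fs))
        if stream == "fnirs":
            hbo, hbr = data
            out[stream] = (hbo[:, lo:hi], hbr[:, lo:hi])
        elif stream == "eye":
            b = data
            sl = {"pupil": b["pupil"][lo:hi]}
            for group, tkey in (("blinks", "onset"), ("fixations", "onset"), ("saccades", "onset")):
                g = b[group]
                sel = (np.asarray(g[tkey]) >= t0) & (np.asarray(g[tkey]) < t0 + duration)
                sl[group] = {
                    k: (np.asarray(v)[sel] - (t0 if k == "onset" else 0))
                    for k, v in g.items()
                }
            out[stream] = sl
        elif stream == "eeg":
            out[stream] = data[:, lo:hi]
        else:
            out[stream] = data[lo:hi]
    return out


def assemble_design_matrix(
    dataset,
    run_ica: bool = True,
    impute: bool = True,
    progress: bool = False,
) -> FeatureMatrix:
    """Extract features for every epoch and baseline period of a study.

    Streams flagged missing extract as NaN and, when ``impute`` is set
    (default), are filled by the trial/session/other-sessions hierarchy.
    """
    design = dataset.design
    rates = design.sampling_rates
    rows = []
    for i, rec in enumerate(dataset.records):
        if progress and i % 50 == 0:
            print(f"extracting epoch {i + 1}/{len(dataset.records)}", flush=True)
        vals = extract_epoch_features(rec, rates, design.epoch_s, run_ica=run_ica)
        vals.update(extract_embedded(rec.embedded))
        vals.update(extract_background(dataset.background[rec.participant]))
        row = dict(zip(KEY_COLUMNS, rec.key))
        row.update(vals)
        row["y"] = rec.y
        rows.append(row)
    base = pd.DataFrame(rows)

    pre_rows, pre_index = {}, []
    pretrial_rows, pretrial_index = {}, []
    for (p, s), brec in dataset.preexp_baselines.items():
        signals = {
            st: brec.signals(st)[0]
            for st in brec.gen_params
            if not brec.missing.get(st, False)
        }
        seed = abs(hash(tuple(brec.seeds.get("eeg", [0])))) % (2**31)
        vals = extract_signal_features(
            signals, rates, design.preexp_baseline_s, ica_seed=seed, run_ica=run_ica
        )
        pre_index.append((p, s))
        pre_rows[(p, s)] = [vals[n] for n in PHYSIO_FEATURES]
        # trial 1's pre-trial baseline = last 45 s of the pre-experimental period
        tail = _slice_signals(
            signals,
            design.preexp_baseline_s - design.pretrial_baseline_s,
            design.pretrial_baseline_s,
            rates,
        )
        tvals = extract_signal_features(
            tail, rates, design.pretrial_baseline_s, ica_seed=seed + 1, run_ica=run_ica
        )
        pretrial_index.append((p, s, 1))
        pretrial_rows[(p, s, 1)] = [tvals[n] for n in PHYSIO_FEATURES]

    for (p, s, t), brec in dataset.pretrial_baselines.items():
        signals = {
            st: brec.signals(st)[0]
            for st in brec.gen_params
            if not brec.missing.get(st, False)
        }
        seed = abs(hash(tuple(brec.seeds.get("eeg", [0])))) % (2**31)
        vals = extract_signal_features(
            signals, rates, design.pretrial_baseline_s, ica_seed=seed, run_ica=run_ica
        )
        pretrial_index.append((p, s, t))
        pretrial_rows[(p, s, t)] = [vals[n] for n in PHYSIO_FEATURES]

    preexp = pd.DataFrame.from_dict(pre_rows, orient="index", columns=list(PHYSIO_FEATURES))
    preexp.index = pd.MultiIndex.from_tuples(list(pre_rows))
    preexp = preexp.sort_index()
    pretrial = pd.DataFrame.from_dict(
        pretrial_rows, orient="index", columns=list(PHYSIO_FEATURES)
    )
    pretrial.index = pd.MultiIndex.from_tuples(list(pretrial_rows))
    pretrial = pretrial.sort_index()

    fm = FeatureMatrix(
        base=base,
        mask=pd.DataFrame(
            0, index=base.index, columns=list(PHYSIO_FEATURES), dtype=np.int8
        ),
        pretrial=pretrial,
        preexp=preexp,
    )
    if impute:
        fm = impute_missing(fm)
    return fm
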