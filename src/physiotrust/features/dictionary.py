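"""The frozen feature dictionary.

Base (unversioned) features per category: ECG 28, EDA 63, respiration 28,
EEG 125, fNIRS 360, eye 37, embedded 16, background 25 — 682 in all.  Eight
baseline versions apply to the psychophysiological categories (ECG, EDA,
respiration, eye; 156 features), EEG carries version 4 only (pre-trial
baseline ratio) and fNIRS version 1 only (pre-trial baseline difference);
embedded and background features are unversioned.  The versioned design
matrix therefore has 156*8 + 125 + 360 + 16 + 25 = 1,774 columns.

Category counts are asserted at import time; the name lists are the single
source of truth for every extractor and for the matrix assembler.
"""

from __future__ import annotations

from dataclasses import dataclass

from physiotrust.synth.embedded import BACKGROUND_MEASURES, EMBEDDED_MEASURES
from physiotrust.synth.signals import EEG_BANDS, EEG_CHANNELS

__all__ = [
    "FeatureDictionary",
    "FEATURE_DICTIONARY",
    "BASE_FEATURE_NAMES",
    "CATEGORY_COUNTS",
    "N_VERSIONED_FEATURES",
    "EEG_REGIONS",
    "PSYCHOPHYS_CATEGORIES",
    "ALL_VERSIONS",
]

ALL_VERSIONS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)

# ---------------------------------------------------------------------------
# per-category name lists
# ---------------------------------------------------------------------------

ECG_FEATURES: tuple[str, ...] = (
    # RR time domain (16)
    "ecg_rr_mean", "ecg_rr_median", "ecg_sdnn", "ecg_rmssd", "ecg_sdsd",
    "ecg_pnn50", "ecg_pnn20", "ecg_rr_min", "ecg_rr_max", "ecg_rr_range",
    "ecg_rr_cv", "ecg_hr_mean", "ecg_hr_min", "ecg_hr_max",
    "ecg_rr_skew", "ecg_rr_kurt",
    # frequency domain (9)
    "ecg_vlf_power", "ecg_lf_power", "ecg_hf_power", "ecg_total_power",
    "ecg_lf_hf", "ecg_lf_nu", "ecg_hf_nu", "ecg_lf_peak", "ecg_hf_peak",
    # Poincare (3)
    "ecg_sd1", "ecg_sd2", "ecg_sd1_sd2",
)

_EDA_STATS = ("mean", "sd", "min", "max", "range", "slope", "auc", "skew", "kurt")
EDA_FEATURES: tuple[str, ...] = tuple(
    f"eda_{src}_{st}" for src in ("scl", "tonic", "phasic", "driver") for st in _EDA_STATS
) + tuple(f"eda_deriv_{st}" for st in _EDA_STATS) + (
    "eda_scr_count", "eda_scr_rate",
    "eda_scr_amp_mean", "eda_scr_amp_sd", "eda_scr_amp_max", "eda_scr_amp_min",
    "eda_scr_amp_sum",
    "eda_scr_rise_mean", "eda_scr_rise_sd", "eda_scr_rise_max",
    "eda_scr_rec_mean", "eda_scr_rec_sd", "eda_scr_rec_max",
    "eda_scr_first_latency", "eda_iscr",
    "eda_scr_isi_mean", "eda_scr_isi_sd", "eda_scr_time_frac",
)

RSP_FEATURES: tuple[str, ...] = (
    # breath-interval statistics (9)
    "rsp_bi_mean", "rsp_bi_sd", "rsp_bi_min", "rsp_bi_max", "rsp_bi_range",
    "rsp_bi_cv", "rsp_bi_skew", "rsp_bi_kurt", "rsp_rate",
    # amplitude statistics (6)
    "rsp_amp_mean", "rsp_amp_sd", "rsp_amp_min", "rsp_amp_max",
    "rsp_amp_range", "rsp_amp_cv",
    # inhale/exhale (5)
    "rsp_inhale_mean", "rsp_exhale_mean", "rsp_inhale_sd", "rsp_exhale_sd",
    "rsp_ie_ratio",
    # signal statistics (7)
    "rsp_sig_mean", "rsp_sig_sd", "rsp_sig_skew", "rsp_sig_kurt",
    "rsp_sig_rms", "rsp_sig_slope", "rsp_sig_auc",
    # spectral (1)
    "rsp_dom_freq",
)

#: 10-20 channel groupings for region-average band powers.
EEG_REGIONS: dict[str, tuple[str, ...]] = {
    "prefrontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("C3", "Cz", "C4"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("O1", "O2"),
    "temporal": ("T7", "T8", "P7", "P8"),
    "whole": EEG_CHANNELS,
}

EEG_FEATURES: tuple[str, ...] = tuple(
    f"eeg_{ch}_{band}" for ch in EEG_CHANNELS for band in EEG_BANDS
) + tuple(f"eeg_{region}_{band}" for region in EEG_REGIONS for band in EEG_BANDS)

_FNIRS_HBO_STATS = ("max", "ttmax", "mean", "var", "skew", "kurt", "rms", "slope", "auc")
_FNIRS_HBR_STATS = ("min", "ttmin", "mean", "var", "skew", "kurt", "rms", "slope", "auc")
FNIRS_FEATURES: tuple[str, ...] = tuple(
    f"fnirs_ch{c:02d}_{sp}_{st}"
    for c in range(1, 21)
    for sp, stats in (("hbo", _FNIRS_HBO_STATS), ("hbr", _FNIRS_HBR_STATS))
    for st in stats
)

EYE_FEATURES: tuple[str, ...] = (
    # pupil statistics (9)
    "eye_pupil_mean", "eye_pupil_sd", "eye_pupil_min", "eye_pupil_max",
    "eye_pupil_range", "eye_pupil_slope", "eye_pupil_skew", "eye_pupil_kurt",
    "eye_pupil_rms",
    # pupil dynamics (3)
    "eye_pcv", "eye_pdv", "eye_mav",
    # blinks (6 + 2 + 1)
    "eye_blink_count", "eye_blink_rate", "eye_blink_dur_mean",
    "eye_blink_dur_sd", "eye_blink_dur_min", "eye_blink_dur_max",
    "eye_ibi_mean", "eye_ibi_sd", "eye_closure_frac",
    # fixations / saccades (16)
    "eye_dwell_aoi1", "eye_dwell_aoi2", "eye_dwell_aoi3", "eye_dwell_aoi4",
    "eye_fixcount_aoi1", "eye_fixcount_aoi2", "eye_fixcount_aoi3",
    "eye_fixcount_aoi4",
    "eye_fix_dur_mean", "eye_fix_dur_sd", "eye_fix_total",
    "eye_sacc_count", "eye_sacc_rate", "eye_sacc_amp_mean",
    "eye_aoi_trans_count", "eye_aoi_trans_entropy",
)

CATEGORY_FEATURES: dict[str, tuple[str, ...]] = {
    "ecg": ECG_FEATURES,
    "eda": EDA_FEATURES,
    "rsp": RSP_FEATURES,
    "eeg": EEG_FEATURES,
    "fnirs": FNIRS_FEATURES,
    "eye": EYE_FEATURES,
    "embedded": EMBEDDED_MEASURES,
    "background": BACKGROUND_MEASURES,
}

CATEGORY_COUNTS: dict[str, int] = {
    "ecg": 28, "eda": 63, "rsp": 28, "eeg": 125, "fnirs": 360,
    "eye": 37, "embedded": 16, "background": 25,
}

PSYCHOPHYS_CATEGORIES: tuple[str, ...] = ("ecg", "eda", "rsp", "eye")

#: Versions applicable per category.
VERSION_APPLICABILITY: dict[str, tuple[int, ...]] = {
    "ecg": ALL_VERSIONS, "eda": ALL_VERSIONS, "rsp": ALL_VERSIONS,
    "eye": ALL_VERSIONS, "eeg": (4,), "fnirs": (1,),
    "embedded": (), "background": (),
}


@dataclass(frozen=True)
class FeatureDictionary:
    """Ordered base feature names with category and version metadata."""

    categories: dict[str, tuple[str, ...]]
    applicability: dict[str, tuple[int, ...]]

    @property
    def base_names(self) -> tuple[str, ...]:
        return tuple(n for cat in self.categories.values() for n in cat)

    def category_of(self, base_name: str) -> str:
        for cat, names in self.categories.items():
            if base_name in names:
                return cat
        raise KeyError(base_name)

    def versions_of(self, base_name: str) -> tuple[int, ...]:
        return self.applicability[self.category_of(base_name)]

    def versioned_names(self) -> tuple[str, ...]:
        """All design-matrix column names, category order then version."""
        out = []
        for cat, names in self.categories.items():
            versions = self.applicability[cat]
            if not versions:
                out.extend(names)
            else:
                for name in names:
                    out.extend(f"{name}__v{v}" for v in versions)
        return tuple(out)

    @staticmethod
    def base_of(column: str) -> str:
        """Base feature name of a (possibly versioned) column name."""
        return column.split("__v")[0]


FEATURE_DICTIONARY = FeatureDictionary(
    categories=CATEGORY_FEATURES, applicability=VERSION_APPLICABILITY
)
BASE_FEATURE_NAMES: tuple[str, ...] = FEATURE_DICTIONARY.base_names
N_VERSIONED_FEATURES: int = len(FEATURE_DICTIONARY.versioned_names())

# import-time structural assertions: the dictionary is the contract
for _cat, _names in CATEGORY_FEATURES.items():
    assert len(_names) == CATEGORY_COUNTS[_cat], (
        _cat, len(_names), CATEGORY_COUNTS[_cat]
    )
assert len(set(BASE_FEATURE_NAMES)) == sum(CATEGORY_COUNTS.values()) == 682
assert N_VERSIONED_FEATURES == 156 * 8 + 125 + 360 + 16 + 25 == 1774
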