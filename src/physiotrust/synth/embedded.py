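"""Task-interaction (embedded) measures and operator background measures.

Embedded measures are the button-click behaviors logged during each 45-s
epoch: review activity, agreement with the autonomous system, map-task
interactions, screen switches, and the post-trial reliance slider.  The
generator drives them from the epoch's systematic trust level through
monotone saturating links (an operator who trusts the system reviews less,
agrees more, spends more time in the passive map task), each perturbed by
measure-specific noise so they are informative but imperfect proxies.

The links are saturating ramps: ``link(t) = lo + (hi - lo) * clip((t - 0.05)
/ 0.90, 0, 1)``, so a latent trust of 1 lands exactly on the measure's
configured ceiling (or floor for decreasing measures) — a property the tests
rely on.

Background measures are 25 per-participant values: eight survey subscale
scores, ten demographic / experience items, self-reported sleep, and six
psychomotor-vigilance summary statistics.  Survey scores correlate with the
participant's dispositional trust offset so that models can exploit them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "generate_embedded",
    "generate_background",
    "embedded_link",
    "EMBEDDED_MEASURES",
    "BACKGROUND_MEASURES",
    "N_SATELLITES_PER_EPOCH",
    "N_MAP_ALLOWED_PER_EPOCH",
]

#: Two satellite classifications arrive every 30 s -> 3 per 45-s epoch.
N_SATELLITES_PER_EPOCH = 3
#: Two map selections allowed every 30 s -> 3 per 45-s epoch.
N_MAP_ALLOWED_PER_EPOCH = 3

#: The 16 embedded measures, in canonical order.
EMBEDDED_MEASURES: tuple[str, ...] = (
    "emb_session",
    "emb_trial",
    "emb_epoch",
    "emb_review_time_total",
    "emb_review_time_mean",
    "emb_pct_reviewed",
    "emb_pct_ignored",
    "emb_pct_agree",
    "emb_pct_passive_agree",
    "emb_classify_delay_mean",
    "emb_pct_rereviewed",
    "emb_map_selections",
    "emb_pct_map_interactions",
    "emb_reliance_slider",
    "emb_screen_switches",
    "emb_explainability",
)

#: (lo, hi, increasing-with-trust) per behavioral link.
_LINKS: dict[str, tuple[float, float, bool]] = {
    "p_review": (0.0, 0.95, False),       # trusting operators review less
    "p_agree": (0.30, 1.0, True),         # ... agree more
    "p_passive_agree": (0.0, 1.0, True),  # ... accept without review
    "review_dwell_s": (2.0, 9.0, False),  # ... dwell less per review
    "classify_delay_s": (1.0, 6.0, False),
    "p_rereview": (0.0, 0.5, False),
    "p_map": (0.2, 1.0, True),            # ... spend effort on the map task
    "reliance": (0.05, 1.0, True),
    "screen_switch_rate": (1.0, 8.0, False),
}


def embedded_link(name: str, trust: float) -> float:
    """Deterministic monotone link value for a behavioral quantity.

    ``trust`` of 1.0 returns the configured ceiling for increasing measures
    and the floor for decreasing ones.
    """
    lo, hi, increasing = _LINKS[name]
    x = trust if increasing else 1.0 - trust
    return lo + (hi - lo) * float(np.clip((x - 0.05) / 0.90, 0.0, 1.0))


def generate_embedded(
    session: int,
    trial: int,
    epoch: int,
    explainability: str,
    trust: float,
    reliance_slider: float,
    seed=0,
    trust_noise_sd: float = 0.22,
) -> dict:
    """Generate one epoch's raw interaction record.

    ``trust`` is the epoch's systematic trust level in [0, 1];
    ``reliance_slider`` is the trial-level post-trial slider value broadcast
    to the trial's epochs.  ``trust_noise_sd`` perturbs the latent level
    independently per behavioral quantity, keeping the measures noisy
    proxies rather than perfect readouts.  Returns a raw count/time record
    consumed by the feature extractor.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def t_m():
        return float(np.clip(trust + trust_noise_sd * rng.standard_normal(), 0.0, 1.0))

    noiseless = trust_noise_sd == 0.0
    n_sat = N_SATELLITES_PER_EPOCH

    p_review = embedded_link("p_review", trust if noiseless else t_m())
    n_reviewed = int(rng.binomial(n_sat, p_review)) if not noiseless else int(
        round(n_sat * p_review)
    )
    n_ignored = n_sat - n_reviewed

    p_agree = embedded_link("p_agree", trust if noiseless else t_m())
    n_agree_reviewed = (
        int(rng.binomial(n_reviewed, p_agree)) if not noiseless else int(round(n_reviewed * p_agree))
    )
    p_passive = embedded_link("p_passive_agree", trust if noiseless else t_m())
    n_passive = (
        int(rng.binomial(n_ignored, p_passive)) if not noiseless else int(round(n_ignored * p_passive))
    )

    dwell = embedded_link("review_dwell_s", trust if noiseless else t_m())
    review_times = (
        np.abs(rng.normal(dwell, 0.15 * dwell, size=n_reviewed)) if n_reviewed else np.array([])
    )
    delay = embedded_link("classify_delay_s", trust if noiseless else t_m())

    p_rereview = embedded_link("p_rereview", trust if noiseless else t_m())
    n_rereviewed = (
        int(rng.binomial(n_reviewed, p_rereview)) if not noiseless else int(
            round(n_reviewed * p_rereview)
        )
    )

    p_map = embedded_link("p_map", trust if noiseless else t_m())
    n_map = (
        int(rng.binomial(N_MAP_ALLOWED_PER_EPOCH, p_map))
        if not noiseless
        else int(round(N_MAP_ALLOWED_PER_EPOCH * p_map))
    )

    sw_rate = embedded_link("screen_switch_rate", trust if noiseless else t_m())
    n_switches = int(rng.poisson(sw_rate)) if not noiseless else int(round(sw_rate))

    return {
        "session": session,
        "trial": trial,
        "epoch": epoch,
        "explainability": explainability,
        "n_satellites": n_sat,
        "n_reviewed": n_reviewed,
        "n_rereviewed": n_rereviewed,
        "n_agree_reviewed": n_agree_reviewed,
        "n_passive_agree": n_passive,
        "review_time_total_s": float(review_times.sum()),
        "classify_delay_mean_s": float(delay) if n_reviewed else 0.0,
        "n_map_selections": n_map,
        "n_map_allowed": N_MAP_ALLOWED_PER_EPOCH,
        "reliance_slider": float(reliance_slider),
        "n_screen_switches": n_switches,
    }


#: The 25 operator-background measures, in canonical order.
BACKGROUND_MEASURES: tuple[str, ...] = (
    "bg_bigfive_extraversion",
    "bg_bigfive_agreeableness",
    "bg_pas_high_expectations",
    "bg_cvs_masculinity",
    "bg_propensity_to_trust",
    "bg_aicp",
    "bg_utaut_performance",
    "bg_utaut_effort",
    "bg_age",
    "bg_sex",
    "bg_race",
    "bg_ethnicity",
    "bg_dominant_hand",
    "bg_videogame_exp",
    "bg_robotics_exp",
    "bg_navaid_use",
    "bg_aerospace_display_exp",
    "bg_military_monitor_exp",
    "bg_sleep_hours",
    "bg_pvt_mean_rt",
    "bg_pvt_median_rt",
    "bg_pvt_sd_rt",
    "bg_pvt_lapses",
    "bg_pvt_fastest10",
    "bg_pvt_slowest10",
)

# survey subscales scored 1-5; dispositional-trust-linked ones load on the
# participant's trust offset (delta, in trust units) with noise
_TRUST_LINKED = {
    "bg_pas_high_expectations": 4.0,
    "bg_propensity_to_trust": 6.0,
    "bg_aicp": 5.0,
    "bg_utaut_performance": 4.0,
    "bg_utaut_effort": 3.0,
}


def generate_background(participant: int, trust_offset: float, seed=0) -> dict:
    """25 per-participant background values.

    Trust-related survey subscales are linear in the participant's
    dispositional trust offset (plus noise); demographics and
    psychomotor-vigilance metrics are trust-independent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for name in (
        "bg_bigfive_extraversion",
        "bg_bigfive_agreeableness",
        "bg_cvs_masculinity",
    ):
        out[name] = float(np.clip(rng.normal(3.0, 0.8), 1.0, 5.0))
    for name, gain in _TRUST_LINKED.items():
        out[name] = float(np.clip(3.0 + gain * trust_offset + rng.normal(0, 0.35), 1.0, 5.0))
    out["bg_age"] = float(np.clip(rng.normal(26.0, 8.0), 18, 65))
    out["bg_sex"] = float(rng.integers(0, 2))
    out["bg_race"] = float(rng.integers(0, 5))
    out["bg_ethnicity"] = float(rng.integers(0, 2))
    out["bg_dominant_hand"] = float(rng.random() < 0.9)
    for name in (
        "bg_videogame_exp",
        "bg_robotics_exp",
        "bg_navaid_use",
        "bg_aerospace_display_exp",
        "bg_military_monitor_exp",
    ):
        out[name] = float(rng.integers(1, 6))
    out["bg_sleep_hours"] = float(np.clip(rng.normal(7.2, 1.0), 4.0, 10.0))
    mean_rt = float(rng.normal(285.0, 25.0))
    sd_rt = float(abs(rng.normal(45.0, 10.0)))
    out["bg_pvt_mean_rt"] = mean_rt
    out["bg_pvt_median_rt"] = mean_rt - 0.3 * sd_rt
    out["bg_pvt_sd_rt"] = sd_rt
    out["bg_pvt_lapses"] = float(rng.poisson(1.5))
    out["bg_pvt_fastest10"] = mean_rt - 1.3 * sd_rt
    out["bg_pvt_slowest10"] = mean_rt + 1.8 * sd_rt
    assert set(out) == set(BACKGROUND_MEASURES)
    return out
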