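"""Synthetic cohort generator with known, person-specific ground truth.

Emulates the study design end to end: each person receives five
pseudorandom survey prompts per day between 08:30 and 22:30 (answered with
a configurable compliance probability), while a continuous app-session log
is generated with circadian session rates, sessions drawn over the 18 core
app categories plus an "other" remainder, and one nightly no-use gap whose
bounds equal a drawn sleep onset and offset. Momentary stress is produced
from a person-specific linear model over the very features the downstream
pipeline extracts (temporal features, category durations, sleep proxies),
plus Gaussian noise, and is then expressed as two 7-point Likert items
(the relaxation item reverse-keyed).

Because the per-person coefficients are recorded as ground truth, every
downstream stage — feature extraction, idiographic model fit, Shapley-based
heterogeneity — has a recoverable target: a feature given a positive
coefficient for a person should surface as a positive feature-attribution
relation for that same person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .app_log import CORE_CATEGORIES, OTHER_CATEGORY
from .features import DURATION_COLUMNS, FEATURE_COLUMNS, SLEEP_COLUMNS, TIME_COLUMNS

#: Features that carry ground-truth coefficients: the temporal features,
#: per-category use duration, and the sleep proxies. Frequency features are
#: deliberately outside the generating model (they are near-duplicates of
#: the durations and would make "which feature caused it" ill-posed).
TRUTH_FEATURES: tuple[str, ...] = tuple(TIME_COLUMNS + DURATION_COLUMNS + SLEEP_COLUMNS)

# One representative (mappable) app name per category, used as the
# generated sessions' app_name so that the shipped coding scheme recovers
# the generating category exactly.
_CATEGORY_APP = {
    "browser": "Chrome",
    "calling": "Phone",
    "camera": "Camera",
    "dating": "Tinder",
    "email": "Gmail",
    "exercise": "RunKeeper",
    "food_drink": "UberEATS",
    "gallery": "Gallery",
    "game": "CandyCrush",
    "messenger": "WhatsApp",
    "music_audio": "Spotify",
    "productivity": "Microsoft Word",
    "shared_transportation": "9292OV",
    "social_network": "Instagram",
    "tracker": "Pedometer",
    "video": "YouTube",
    "weather": "Weather",
    "work": "StudentJob",
}


@dataclass(frozen=True)
class Effect:
    """How one feature's ground-truth coefficient is drawn per person.

    ``fixed`` gives every person the same coefficient (a homogeneous
    cohort); ``mixture`` draws the sign from a (negative, zero, positive)
    mixture with the given magnitude, producing the across-person
    heterogeneity the explanation stage is meant to recover.
    """

    kind: str  # "fixed" | "mixture"
    value: float = 0.0
    mixture: tuple[float, float, float] = (0.3, 0.4, 0.3)
    magnitude: float = 1.0

    @classmethod
    def fixed(cls, value: float) -> "Effect":
        return cls(kind="fixed", value=value)

    @classmethod
    def heterogeneous(
        cls, magnitude: float = 1.0, mixture: tuple[float, float, float] = (0.3, 0.4, 0.3)
    ) -> "Effect":
        if abs(sum(mixture) - 1.0) > 1e-9 or min(mixture) < 0:
            raise ValueError("mixture proportions must be nonnegative and sum to 1")
        return cls(kind="mixture", mixture=mixture, magnitude=magnitude)

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.value
        sign = rng.choice([-1.0, 0.0, 1.0], p=self.mixture)
        return sign * self.magnitude


def _default_effects() -> dict[str, Effect]:
    # Temporal effects are homogeneous (same direction for everyone:
    # more stress earlier in the day, on weekdays, later in the month and
    # under lockdown); app-use and sleep effects are heterogeneous
    # sign mixtures. Coefficients are in stress-scale units per unit of the
    # generator's internal standardized feature (see _GENERATOR_SCALES).
    return {
        "hour_of_day": Effect.fixed(-0.5),
        "weekend": Effect.fixed(-0.3),
        "day_of_month": Effect.fixed(0.3),
        "covid": Effect.fixed(0.5),
        "duration_messenger": Effect.heterogeneous(1.0),
        "duration_social_network": Effect.heterogeneous(1.0),
        "sleep_duration": Effect.heterogeneous(1.0),
        "sleep_onset": Effect.heterogeneous(1.0),
    }


def _default_prevalence() -> dict[str, float]:
    # Core-category mass ~0.77 (messenger and social apps dominate, as in
    # student phone use); the remainder is uncategorized "other" traffic.
    p = {
        "messenger": 0.20,
        "social_network": 0.14,
        "browser": 0.07,
        "video": 0.08,
        "music_audio": 0.05,
        "game": 0.04,
        "email": 0.04,
        "gallery": 0.03,
        "camera": 0.02,
        "calling": 0.02,
        "productivity": 0.02,
        "weather": 0.01,
        "food_drink": 0.01,
        "exercise": 0.01,
        "dating": 0.01,
        "shared_transportation": 0.005,
        "tracker": 0.005,
        "work": 0.01,
        OTHER_CATEGORY: 0.23,
    }
    assert abs(sum(p.values()) - 1.0) < 1e-9
    return p


@dataclass
class SyntheticConfig:
    """Study-design parameters of the simulated cohort.

    Defaults mirror the emulated design: 5 prompts/day in 08:30-22:30,
    nightly sleep around midnight lasting ~8 h, ~80% compliance, a lockdown
    switch halfway through the study, and person-specific linear
    feature-stress effects with heterogeneous signs.
    """

    n_persons: int = 30
    n_days: int = 30
    prompts_per_day: int = 5
    prompt_window: tuple[float, float] = (8.5, 22.5)  # clock hours
    session_rate: dict[str, float] = field(
        default_factory=lambda: {"morning": 6.0, "afternoon": 8.0, "evening": 10.0}
    )  # mean app sessions per hour by day segment (<12h, 12-18h, >=18h)
    mean_session_s: float = 90.0  # lognormal median session length, seconds
    category_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    sleep_onset_mean_sd: tuple[float, float] = (24.0, 0.75)  # hours, >24 = post-midnight
    sleep_duration_mean_sd: tuple[float, float] = (8.0, 0.75)  # hours
    noise_sd: float = 0.5  # latent stress noise, stress-scale units
    compliance_prob: float = 0.8
    lockdown_day: int | None = None  # default: halfway through the study
    start_date: str = "2020-02-03"  # a Monday
    intercept: float = 4.0
    effects: dict[str, Effect] = field(default_factory=_default_effects)
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 (sleep proxies need a prior night)")
        if self.prompts_per_day < 1:
            raise ValueError("prompts_per_day must be >= 1")
        if not self.category_prevalence:
            raise ValueError("category_prevalence must not be empty")
        total = sum(self.category_prevalence.values())
        if abs(total - 1.0) > 1e-8 or min(self.category_prevalence.values()) < 0:
            raise ValueError("category_prevalence must be a probability vector summing to 1")
        if not 0.0 <= self.compliance_prob <= 1.0:
            raise ValueError("compliance_prob must lie in [0, 1]")
        for sd in (self.sleep_onset_mean_sd[1], self.sleep_duration_mean_sd[1], self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        unknown = set(self.effects) - set(TRUTH_FEATURES)
        if unknown:
            raise ValueError(f"effects refer to non-truth features: {sorted(unknown)}")

    @property
    def resolved_lockdown_day(self) -> int:
        return self.n_days // 2 if self.lockdown_day is None else self.lockdown_day

    @property
    def lockdown_date(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date) + pd.Timedelta(days=self.resolved_lockdown_day)


# Internal standardized scales on which ground-truth coefficients act:
# x_std = (x_raw - center) / span. Chosen so each active feature moves
# roughly one unit over its realistic range, making coefficient magnitudes
# directly comparable to noise_sd.
def _standardize(feature: str, raw: float) -> float:
    if feature == "hour_of_day":
        return (raw - 15.5) / 14.0
    if feature == "day_of_month":
        return (raw - 15.5) / 30.0
    if feature.startswith("duration_"):
        return raw / 3600.0
    if feature.startswith("frequency_"):
        return raw / 10.0
    if feature == "sleep_duration":
        return (raw - 8.0) / 2.0
    if feature == "sleep_onset":
        return (raw - 24.0) / 2.0
    return raw  # weekend, covid: already 0/1


@dataclass
class GroundTruth:
    """The generating model: one coefficient vector per person (on the
    generator's standardized feature scales), plus the drawn nightly sleep."""

    coefficients: pd.DataFrame  # persons x TRUTH_FEATURES
    intercept: pd.Series  # per person
    noise_sd: float
    sleep: pd.DataFrame  # person_id, night_date, onset, duration

    def to_json_dict(self) -> dict:
        return {
            "noise_sd": self.noise_sd,
            "intercept": self.intercept.to_dict(),
            "coefficients": {
                str(p): row.to_dict() for p, row in self.coefficients.iterrows()
            },
        }


def truth_sign_table(truth: GroundTruth, threshold: float = 0.0) -> pd.DataFrame:
    """Per-person, per-feature coefficient sign in {-1, 0, +1}.

    Coefficients with absolute value <= ``threshold`` count as 0. This table
    is the oracle against which recovered feature-attribution signs are
    scored.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    c = truth.coefficients
    return pd.DataFrame(
        np.where(np.abs(c) <= threshold, 0, np.sign(c)).astype(int),
        index=c.index,
        columns=c.columns,
    )


_ANCHOR_S = 60.0  # anchor sessions flanking each sleep gap, seconds


def _person_rng(seed: int, person: int) -> np.random.Generator:
    # Global seed streams to per-person sub-seeds so cohorts of different
    # sizes share person-level draws.
    return np.random.default_rng([seed, person])


def _segment_rate(rates: dict[str, float], hour: float) -> float:
    if hour < 12:
        return rates["morning"]
    if hour < 18:
        return rates["afternoon"]
    return rates["evening"]


def _generate_sessions(rng, cfg: SyntheticConfig, wake_intervals, day0: pd.Timestamp):
    """App sessions (start_s, end_s, category) within the wake intervals,
    with anchor sessions pinning each interval's bounds so the nightly gap
    equals the drawn sleep exactly. Times in seconds since day0."""
    cats = list(cfg.category_prevalence.keys())
    probs = np.array([cfg.category_prevalence[c] for c in cats])
    sessions = []

    def draw_cat():
        return cats[int(rng.choice(len(cats), p=probs))]

    for a, b in wake_intervals:
        if b - a < 4 * _ANCHOR_S:
            continue
        sessions.append((a, a + _ANCHOR_S, draw_cat()))
        t = a + _ANCHOR_S
        while True:
            hour = (t % 86400.0) / 3600.0
            rate = _segment_rate(cfg.session_rate, hour)
            gap = rng.exponential(3600.0 / max(rate, 1e-9))
            dur = min(rng.lognormal(np.log(cfg.mean_session_s), 0.8), 1800.0)
            start = t + max(gap, 1.0)
            end = start + dur
            if end >= b - 2 * _ANCHOR_S:
                break
            sessions.append((start, end, draw_cat()))
            t = end
        sessions.append((b - _ANCHOR_S, b, draw_cat()))
    return sessions


def _window_sums(starts, ends, cat_codes, t_s, window_s, n_cat):
    """Per-category (duration, frequency) for the window (t-window, t], on
    sorted non-overlapping sessions given in seconds."""
    dur = np.zeros(n_cat)
    freq = np.zeros(n_cat)
    lo = int(np.searchsorted(ends, t_s - window_s, side="right"))
    hi = int(np.searchsorted(starts, t_s, side="left"))
    for j in range(lo, hi):
        c = cat_codes[j]
        if c < 0:
            continue
        overlap = min(ends[j], t_s) - max(starts[j], t_s - window_s)
        if overlap > 0:
            dur[c] += overlap
            freq[c] += 1
    return dur, freq


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (app_events, ema, truth) for one synthetic cohort.

    ``app_events`` has columns person_id, app_name, category, start, end
    (sessions non-overlapping within person; one nightly gap whose bounds
    equal the drawn sleep onset/offset). ``ema`` has one row per *answered*
    prompt: person_id, day, prompt_time, completion_time, item_relaxed,
    item_stressed. Fully reproducible from ``config.seed``.
    """
    config.validate()
    day0 = pd.Timestamp(config.start_date).normalize()
    cat_index = {c: i for i, c in enumerate(CORE_CATEGORIES)}
    n_cat = len(CORE_CATEGORIES)
    active = [f for f, e in config.effects.items() if e.kind == "fixed" or e.magnitude != 0]

    all_events = []
    all_ema = []
    coef_rows = {}
    sleep_rows = []

    for p in range(config.n_persons):
        pid = f"p{p:03d}"
        rng = _person_rng(config.seed, p)

        coefs = pd.Series(0.0, index=list(TRUTH_FEATURES))
        for feat in TRUTH_FEATURES:  # fixed iteration order for determinism
            if feat in config.effects:
                coefs[feat] = config.effects[feat].draw(rng)
        coef_rows[pid] = coefs

        # --- nightly sleep (night i spans day i -> day i+1) ---
        om, osd = config.sleep_onset_mean_sd
        dm, dsd = config.sleep_duration_mean_sd
        onsets = np.clip(rng.normal(om, osd, config.n_days - 1), 21.0, 27.5)
        durations = np.clip(rng.normal(dm, dsd, config.n_days - 1), 4.0, 12.0)
        sleep_start_s = np.arange(config.n_days - 1) * 86400.0 + onsets * 3600.0
        sleep_end_s = sleep_start_s + durations * 3600.0
        for i in range(config.n_days - 1):
            sleep_rows.append(
                (pid, day0 + pd.Timedelta(days=i), float(onsets[i]), float(durations[i]))
            )

        # --- wake intervals between sleeps ---
        wake = []
        start_s = 8.0 * 3600.0  # first morning: no prior night
        for i in range(config.n_days - 1):
            wake.append((start_s, sleep_start_s[i]))
            start_s = sleep_end_s[i]
        wake.append((start_s, (config.n_days - 1) * 86400.0 + 23.5 * 3600.0))

        sessions = _generate_sessions(rng, config, wake, day0)
        sessions.sort()
        starts = np.array([s[0] for s in sessions])
        ends = np.array([s[1] for s in sessions])
        codes = np.array([cat_index.get(s[2], -1) for s in sessions])
        for s0, s1, cat in sessions:
            name = (
                _CATEGORY_APP[cat]
                if cat in _CATEGORY_APP
                else f"unknownapp{int(rng.integers(50))}"
            )
            all_events.append(
                (
                    pid,
                    name,
                    cat,
                    day0 + pd.Timedelta(seconds=round(s0)),
                    day0 + pd.Timedelta(seconds=round(s1)),
                )
            )

        # --- prompts and stress ---
        mean_onset = float(np.mean(onsets))
        mean_duration = float(np.mean(durations))
        w_lo, w_hi = config.prompt_window
        for day in range(config.n_days):
            hours = np.sort(rng.uniform(w_lo, w_hi, config.prompts_per_day))
            answered = rng.random(config.prompts_per_day) < config.compliance_prob
            delays = rng.uniform(60.0, 600.0, config.prompts_per_day)
            for k in range(config.prompts_per_day):
                t_s = day * 86400.0 + hours[k] * 3600.0
                if not answered[k]:
                    continue
                prompt = day0 + pd.Timedelta(seconds=round(t_s))

                dur, freq = _window_sums(starts, ends, codes, t_s, 3600.0, n_cat)
                if day == 0:
                    onset_h, dur_h = mean_onset, mean_duration
                else:
                    onset_h, dur_h = float(onsets[day - 1]), float(durations[day - 1])

                x = {}
                for feat in active:
                    if feat.startswith("duration_"):
                        raw = dur[cat_index[feat[len("duration_"):]]]
                    elif feat.startswith("frequency_"):
                        raw = freq[cat_index[feat[len("frequency_"):]]]
                    elif feat == "sleep_onset":
                        raw = onset_h
                    elif feat == "sleep_duration":
                        raw = dur_h
                    elif feat == "hour_of_day":
                        raw = prompt.hour
                    elif feat == "weekend":
                        raw = float(prompt.dayofweek >= 5)
                    elif feat == "day_of_month":
                        raw = prompt.day
                    elif feat == "covid":
                        raw = float(day >= config.resolved_lockdown_day)
                    else:
                        raw = 0.0
                    x[feat] = _standardize(feat, raw)

                latent = config.intercept + sum(
                    coefs[f] * v for f, v in x.items()
                )
                latent += rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                item_sd = config.noise_sd / 2.0
                eps_s = rng.normal(0.0, item_sd) if item_sd > 0 else 0.0
                eps_r = rng.normal(0.0, item_sd) if item_sd > 0 else 0.0
                stressed = int(np.clip(np.round(latent + eps_s), 1, 7))
                relaxed = int(np.clip(np.round(8.0 - latent + eps_r), 1, 7))
                all_ema.append(
                    (
                        pid,
                        day,
                        prompt,
                        prompt + pd.Timedelta(seconds=round(delays[k])),
                        relaxed,
                        stressed,
                    )
                )

    events = pd.DataFrame(
        all_events, columns=["person_id", "app_name", "category", "start", "end"]
    ).sort_values(["person_id", "start"], kind="mergesort").reset_index(drop=True)
    ema = pd.DataFrame(
        all_ema,
        columns=[
            "person_id",
            "day",
            "prompt_time",
            "completion_time",
            "item_relaxed",
            "item_stressed",
        ],
    )
    truth = GroundTruth(
        coefficients=pd.DataFrame(coef_rows).T[list(TRUTH_FEATURES)],
        intercept=pd.Series(config.intercept, index=list(coef_rows)),
        noise_sd=config.noise_sd,
        sleep=pd.DataFrame(
            sleep_rows, columns=["person_id", "night_date", "onset", "duration"]
        ),
    )
    return events, ema, truth


def write_cohort(events, ema, truth, outdir) -> None:
    """Write the generator's outputs in the pipeline's input formats:
    app_events.csv, ema.csv and truth.json."""
    import json
    from pathlib import Path

    from .app_log import write_events

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_events(events, outdir / "app_events.csv")
    out = ema[
        ["person_id", "prompt_time", "completion_time", "item_relaxed", "item_stressed"]
    ].copy()
    out["prompt_time"] = out["prompt_time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["completion_time"] = out["completion_time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(outdir / "ema.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))
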