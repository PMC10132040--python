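"""Feature extraction for momentary-stress modeling.

Each answered experience-sampling prompt becomes one row: the outcome is the
two-item momentary stress score (unweighted average after reverse-keying the
relaxation item), within-person centered; the predictors are

* per app category, the seconds of use (*duration*) and the number of
  sessions (*frequency*) in the 60 minutes before the prompt (36 features),
* smartphone-derived sleep proxies for the previous night: sleep onset
  (clock hours, post-midnight hours coded >24) and sleep duration (hours),
* temporal features: hour of day (0-23), weekend indicator, day of month,
  and a lockdown indicator (0 before the lockdown date, 1 from it onward).

Features are min-max scaled to [0, 1] with bounds estimated on training
rows only; test values may leave [0, 1] and are deliberately not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .app_log import CORE_CATEGORIES

# Canonical feature-column order: 18 durations, 18 frequencies
# (category-alphabetical), sleep, time.
DURATION_COLUMNS = [f"duration_{c}" for c in CORE_CATEGORIES]
FREQUENCY_COLUMNS = [f"frequency_{c}" for c in CORE_CATEGORIES]
SLEEP_COLUMNS = ["sleep_onset", "sleep_duration"]
TIME_COLUMNS = ["hour_of_day", "weekend", "day_of_month", "covid"]
FEATURE_COLUMNS = DURATION_COLUMNS + FREQUENCY_COLUMNS + SLEEP_COLUMNS + TIME_COLUMNS

LIKERT_MIN, LIKERT_MAX = 1, 7


# ---------------------------------------------------------------- outcome --


def score_stress(item_relaxed, item_stressed):
    """Two-item momentary stress score on the 1-7 scale.

    The relaxation item is reverse-keyed (8 - x) before the unweighted
    average, so (relaxed=1, stressed=7) scores 7.0 and (relaxed=7,
    stressed=1) scores 1.0. Accepts scalars or arrays; raises ``ValueError``
    if any item lies outside 1..7.
    """
    relaxed = np.asarray(item_relaxed, dtype=float)
    stressed = np.asarray(item_stressed, dtype=float)
    for item in (relaxed, stressed):
        if np.any((item < LIKERT_MIN) | (item > LIKERT_MAX)):
            raise ValueError("Likert items must lie in 1..7")
    out = ((8.0 - relaxed) + stressed) / 2.0
    return float(out) if out.ndim == 0 else out


def center_within_person(
    values, person_ids, train_mask=None
) -> np.ndarray:
    """Subtract each person's own mean, so models predict deviations from a
    personal norm.

    By default the mean is taken over all of a person's observations. With
    ``train_mask`` the mean is estimated on that person's training rows only
    (a leakage-free variant); persons with no training row fall back to
    their full-series mean.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    pid = pd.Series(np.asarray(person_ids))
    if train_mask is None:
        means = s.groupby(pid).transform("mean")
    else:
        mask = np.asarray(train_mask, dtype=bool)
        train_means = s[mask].groupby(pid[mask]).mean()
        full_means = s.groupby(pid).mean()
        per_person = train_means.reindex(full_means.index).fillna(full_means)
        means = pid.map(per_person)
    return (s - means).to_numpy()


def load_ema(path) -> pd.DataFrame:
    """Read an EMA CSV (person_id, prompt_time, completion_time, item_relaxed,
    item_stressed), score stress and center it within person.

    Rows with out-of-range items are flagged invalid and excluded from
    scoring and centering.
    """
    df = pd.read_csv(path)
    required = {"person_id", "prompt_time", "item_relaxed", "item_stressed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EMA table is missing columns: {sorted(missing)}")
    df["prompt_time"] = pd.to_datetime(df["prompt_time"], format="ISO8601")
    if "completion_time" in df.columns:
        df["completion_time"] = pd.to_datetime(df["completion_time"], format="ISO8601")
    valid = (
        df["item_relaxed"].between(LIKERT_MIN, LIKERT_MAX)
        & df["item_stressed"].between(LIKERT_MIN, LIKERT_MAX)
    )
    df = df[valid].reset_index(drop=True)
    df["stress_raw"] = score_stress(df["item_relaxed"], df["item_stressed"])
    df["stress_centered"] = center_within_person(df["stress_raw"], df["person_id"])
    return df.sort_values(["person_id", "prompt_time"], kind="mergesort").reset_index(
        drop=True
    )


# ------------------------------------------------------ app-usage windows --


def window_features(
    events: pd.DataFrame, t: pd.Timestamp, window_minutes: int = 60
) -> dict[str, float]:
    """Per-category (duration, frequency) for the window ``(t - window, t]``.

    Duration is the summed overlap (seconds) of a category's sessions with
    the window; frequency counts sessions intersecting the window, including
    sessions that merely span its boundary. Categories without events map to
    (0, 0); ``"other"`` events are ignored.
    """
    t = pd.Timestamp(t)
    t0 = t - pd.Timedelta(minutes=window_minutes)
    out = {c: 0.0 for c in DURATION_COLUMNS}
    out.update({c: 0.0 for c in FREQUENCY_COLUMNS})
    if len(events) == 0:
        return out
    hit = events[(events["start"] < t) & (events["end"] > t0)]
    for cat, grp in hit.groupby("category", sort=False):
        if cat not in CORE_CATEGORIES:
            continue
        clipped = (
            grp["end"].clip(upper=t) - grp["start"].clip(lower=t0)
        ).dt.total_seconds()
        out[f"duration_{cat}"] = float(clipped.sum())
        out[f"frequency_{cat}"] = float(len(grp))
    return out


def _window_matrix(events: pd.DataFrame, ema: pd.DataFrame, window_minutes: int):
    """Vectorized per-prompt window features for a whole cohort."""
    cat_index = {c: i for i, c in enumerate(CORE_CATEGORIES)}
    n_cat = len(CORE_CATEGORIES)
    dur = np.zeros((len(ema), n_cat))
    freq = np.zeros((len(ema), n_cat))
    win = pd.Timedelta(minutes=window_minutes)

    ev_by_person = dict(tuple(events.groupby("person_id", sort=False)))
    for rows, (pid, grp) in _iter_person_rows(ema, ev_by_person):
        starts = grp["start"].to_numpy(dtype="datetime64[ns]").astype("int64")
        ends = grp["end"].to_numpy(dtype="datetime64[ns]").astype("int64")
        cats = grp["category"].map(cat_index).to_numpy(na_value=-1, dtype=float).astype(int)
        prompts = ema.loc[rows, "prompt_time"].to_numpy(dtype="datetime64[ns]").astype("int64")
        w = int(win.value)
        for r, t in zip(rows, prompts):
            # non-overlapping sessions => starts and ends are both sorted
            lo = int(np.searchsorted(ends, t - w, side="right"))
            hi = int(np.searchsorted(starts, t, side="left"))
            for j in range(lo, hi):
                c = cats[j]
                if c < 0:
                    continue
                overlap = min(ends[j], t) - max(starts[j], t - w)
                if overlap > 0:
                    dur[r, c] += overlap / 1e9
                    freq[r, c] += 1
    return dur, freq


def _iter_person_rows(ema: pd.DataFrame, ev_by_person: dict):
    for pid, idx in ema.groupby("person_id", sort=False).groups.items():
        grp = ev_by_person.get(pid)
        if grp is None or len(grp) == 0:
            continue
        yield np.asarray(idx), (pid, grp)


# ------------------------------------------------------------ sleep proxy --

#: Default rule parameters for the gap-based sleep proxy: the candidate
#: window in which a sleep gap may start, the events considered (scan
#: interval around the night), and the minimum qualifying gap length.
SLEEP_SCAN_START_HOUR = 18  # day d
SLEEP_SCAN_END_HOUR = 14  # day d+1
SLEEP_ONSET_WINDOW = (20.0, 36.0)  # gap must start between d 20:00 and d+1 12:00
SLEEP_MIN_GAP_HOURS = 3.0


@dataclass
class SleepProxy:
    """Estimated sleep for one person-night, derived from the longest
    qualifying no-use gap. Onset uses the post-midnight >24 convention."""

    person_id: object
    night_date: pd.Timestamp
    onset: float  # hours, in [18, 36)
    duration: float  # hours


def detect_sleep(
    events: pd.DataFrame,
    night_date,
    min_gap_hours: float = SLEEP_MIN_GAP_HOURS,
) -> SleepProxy | None:
    """Sleep proxy for the night anchored at ``night_date`` (one person's events).

    Considers sessions intersecting [d 18:00, d+1 14:00] and takes the
    longest inter-session gap that starts between d 20:00 and d+1 12:00 and
    lasts at least ``min_gap_hours``. Sleep onset is the clock hour at which
    the last pre-gap session ended (post-midnight hours reported as
    hour + 24); duration is the gap length in hours. Returns ``None`` when
    no gap qualifies or the night interval holds no events.
    """
    d = pd.Timestamp(night_date).normalize()
    scan_lo = d + pd.Timedelta(hours=SLEEP_SCAN_START_HOUR)
    scan_hi = d + pd.Timedelta(days=1, hours=SLEEP_SCAN_END_HOUR)
    night = events[(events["end"] > scan_lo) & (events["start"] < scan_hi)]
    if len(night) < 2:
        return None
    night = night.sort_values("start", kind="mergesort")
    ends = night["end"].to_numpy()
    starts = night["start"].to_numpy()
    gap_start = ends[:-1]
    gap_len = (starts[1:] - gap_start) / np.timedelta64(1, "h")
    onset_hours = (gap_start - d.to_numpy()) / np.timedelta64(1, "h")
    ok = (
        (onset_hours >= SLEEP_ONSET_WINDOW[0])
        & (onset_hours < SLEEP_ONSET_WINDOW[1])
        & (gap_len >= min_gap_hours)
    )
    if not ok.any():
        return None
    best = int(np.flatnonzero(ok)[np.argmax(gap_len[ok])])
    return SleepProxy(
        person_id=night["person_id"].iloc[0] if "person_id" in night else None,
        night_date=d,
        onset=float(onset_hours[best]),
        duration=float(gap_len[best]),
    )


def sleep_table(events: pd.DataFrame, min_gap_hours: float = SLEEP_MIN_GAP_HOURS) -> pd.DataFrame:
    """Sleep proxies for every person-night spanned by the event log.

    Returns columns person_id, night_date, onset, duration; nights without a
    qualifying gap are absent.
    """
    rows = []
    for pid, grp in events.groupby("person_id", sort=False):
        d0 = grp["start"].min().normalize()
        d1 = grp["end"].max().normalize()
        for d in pd.date_range(d0, d1 - pd.Timedelta(days=1), freq="D"):
            proxy = detect_sleep(grp, d, min_gap_hours=min_gap_hours)
            if proxy is not None:
                rows.append((pid, d, proxy.onset, proxy.duration))
    return pd.DataFrame(rows, columns=["person_id", "night_date", "onset", "duration"])


@dataclass
class AttachSleepReport:
    n_imputed: int = 0
    dropped_persons: list = None

    def __post_init__(self):
        if self.dropped_persons is None:
            self.dropped_persons = []


def attach_sleep(
    ema: pd.DataFrame, sleep: pd.DataFrame
) -> tuple[pd.DataFrame, AttachSleepReport]:
    """Attach the most recent completed night's proxies to each observation.

    A prompt on day d receives the proxies of the night d-1 -> d. Nights
    without a detected proxy are person-median imputed with the
    ``sleep_missing`` flag set; persons with zero detected nights are
    dropped and reported.
    """
    report = AttachSleepReport()
    ema = ema.copy()
    key = pd.MultiIndex.from_frame(sleep[["person_id", "night_date"]])
    onset = pd.Series(sleep["onset"].to_numpy(), index=key)
    duration = pd.Series(sleep["duration"].to_numpy(), index=key)

    night_key = pd.MultiIndex.from_arrays(
        [ema["person_id"], ema["prompt_time"].dt.normalize() - pd.Timedelta(days=1)]
    )
    ema["sleep_onset"] = onset.reindex(night_key).to_numpy()
    ema["sleep_duration"] = duration.reindex(night_key).to_numpy()
    ema["sleep_missing"] = ema["sleep_onset"].isna()

    med = sleep.groupby("person_id")[["onset", "duration"]].median()
    have_any = ema["person_id"].isin(med.index)
    report.dropped_persons = sorted(ema.loc[~have_any, "person_id"].unique().tolist())
    ema = ema[have_any].reset_index(drop=True)

    miss = ema["sleep_missing"]
    report.n_imputed = int(miss.sum())
    ema.loc[miss, "sleep_onset"] = ema.loc[miss, "person_id"].map(med["onset"]).to_numpy()
    ema.loc[miss, "sleep_duration"] = (
        ema.loc[miss, "person_id"].map(med["duration"]).to_numpy()
    )
    return ema, report


# ---------------------------------------------------------- time features --


def time_features(prompt_time, lockdown_date=None):
    """(hour_of_day, weekend, day_of_month, covid) for one timestamp.

    ``covid`` is 1 from the lockdown instant onward (closed left boundary);
    with no lockdown date it is 0 everywhere.
    """
    t = pd.Timestamp(prompt_time)
    covid = 0 if lockdown_date is None else int(t >= pd.Timestamp(lockdown_date))
    return t.hour, int(t.dayofweek >= 5), t.day, covid


# -------------------------------------------------------- feature matrix --


def build_feature_matrix(
    events: pd.DataFrame,
    ema: pd.DataFrame,
    lockdown_date=None,
    window_minutes: int = 60,
    min_gap_hours: float = SLEEP_MIN_GAP_HOURS,
) -> tuple[pd.DataFrame, AttachSleepReport]:
    """Assemble the full per-observation feature matrix.

    Returns a frame with the 42 feature columns in canonical order followed
    by ``person_id, prompt_time, stress_raw, stress_centered, sleep_missing``.
    """
    ema = ema.sort_values(["person_id", "prompt_time"], kind="mergesort").reset_index(
        drop=True
    )
    if "stress_raw" not in ema.columns:
        ema = ema.copy()
        ema["stress_raw"] = score_stress(ema["item_relaxed"], ema["item_stressed"])
    if "stress_centered" not in ema.columns:
        ema = ema.copy()
        ema["stress_centered"] = center_within_person(ema["stress_raw"], ema["person_id"])
    sleep = sleep_table(events, min_gap_hours=min_gap_hours)
    ema, report = attach_sleep(ema, sleep)

    dur, freq = _window_matrix(events, ema, window_minutes)
    for i, c in enumerate(DURATION_COLUMNS):
        ema[c] = dur[:, i]
    for i, c in enumerate(FREQUENCY_COLUMNS):
        ema[c] = freq[:, i]

    t = ema["prompt_time"]
    ema["hour_of_day"] = t.dt.hour
    ema["weekend"] = (t.dt.dayofweek >= 5).astype(int)
    ema["day_of_month"] = t.dt.day
    if lockdown_date is None:
        ema["covid"] = 0
    else:
        ema["covid"] = (t >= pd.Timestamp(lockdown_date)).astype(int)

    cols = FEATURE_COLUMNS + [
        "person_id",
        "prompt_time",
        "stress_raw",
        "stress_centered",
        "sleep_missing",
    ]
    return ema[cols], report


# ----------------------------------------------------------------- scaling --


@dataclass
class ScalerRecord:
    """Frozen min-max bounds estimated on training rows."""

    columns: list[str]
    data_min: np.ndarray
    data_max: np.ndarray

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[self.columns].to_numpy(dtype=float)
        span = self.data_max - self.data_min
        constant = span == 0
        out = (x - self.data_min) / np.where(constant, 1.0, span)
        out[:, constant] = 0.0  # constant train column: everything maps to 0
        return pd.DataFrame(out, columns=self.columns, index=df.index)


def minmax_fit_apply(
    train: pd.DataFrame, *others: pd.DataFrame, columns: list[str] | None = None
) -> tuple[list[pd.DataFrame], ScalerRecord]:
    """Min-max scale features to [0, 1] using training-set bounds.

    The training frame maps into [0, 1]; the other frames are transformed
    with the same bounds and may exit [0, 1] (no clipping). A column that is
    constant in training maps to 0 everywhere.
    """
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    columns = list(columns) if columns is not None else list(train.columns)
    scaler = MinMaxScaler(clip=False)
    scaler.fit(train[columns].to_numpy(dtype=float))
    record = ScalerRecord(
        columns=columns, data_min=scaler.data_min_.copy(), data_max=scaler.data_max_.copy()
    )
    return [record.transform(df) for df in (train, *others)], record


# ------------------------------------------------------ variance structure --


def variance_decomposition(values, person_ids) -> float:
    """Share of total outcome variance attributable to within-person
    fluctuation (pooled within-person sum of squares over total sum of
    squares). Raises on zero total variance."""
    s = pd.Series(np.asarray(values, dtype=float))
    pid = pd.Series(np.asarray(person_ids))
    counts = pid.value_counts()
    if len(counts) < 2 or (counts < 2).all():
        raise ValueError("need >=2 persons with >=2 observations")
    sst = float(((s - s.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("total variance is zero; within-person share undefined")
    ssw = float(((s - s.groupby(pid).transform("mean")) ** 2).sum())
    return ssw / sst
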