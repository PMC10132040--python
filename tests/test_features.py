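"""Feature extraction: stress scoring, windows, sleep proxy, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emastress.features import (
    DURATION_COLUMNS,
    FEATURE_COLUMNS,
    attach_sleep,
    build_feature_matrix,
    center_within_person,
    detect_sleep,
    minmax_fit_apply,
    score_stress,
    sleep_table,
    time_features,
    variance_decomposition,
    window_features,
)

T = pd.Timestamp


# ---------------------------------------------------------------- outcome --


@pytest.mark.parametrize(
    "relaxed,stressed,expected",
    [(1, 7, 7.0), (7, 1, 1.0), (4, 4, 4.0), (2, 6, 6.0)],
)
def test_score_stress_reverse_keys_relaxation(relaxed, stressed, expected):
    assert score_stress(relaxed, stressed) == expected


def test_score_stress_rejects_out_of_range():
    with pytest.raises(ValueError):
        score_stress(0, 4)
    with pytest.raises(ValueError):
        score_stress(4, 8)


def test_centering_examples():
    out = center_within_person([3.0, 5.0], ["a", "a"])
    assert np.allclose(out, [-1.0, 1.0])
    assert np.allclose(center_within_person([4, 4, 4], ["a"] * 3), 0.0)


@settings(max_examples=40, derandomize=True)
@given(
    st.lists(st.floats(1, 7), min_size=1, max_size=20),
    st.lists(st.floats(1, 7), min_size=1, max_size=20),
)
def test_centering_zero_mean_and_idempotent(xs, ys):
    values = np.array(xs + ys)
    pids = ["a"] * len(xs) + ["b"] * len(ys)
    c1 = center_within_person(values, pids)
    for pid in ("a", "b"):
        assert abs(c1[np.array(pids) == pid].mean()) < 1e-9
    c2 = center_within_person(c1, pids)
    assert np.allclose(c1, c2, atol=1e-9)


def test_train_only_centering_uses_train_means():
    values = [1.0, 2.0, 9.0, 9.0]
    pids = ["a"] * 4
    mask = [True, True, False, False]
    out = center_within_person(values, pids, train_mask=mask)
    assert np.allclose(out, [-0.5, 0.5, 7.5, 7.5])


# ------------------------------------------------------------------ window --


def _events(rows):
    df = pd.DataFrame(rows, columns=["person_id", "category", "start", "end"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def test_window_features_empty():
    out = window_features(_events([]), T("2020-02-03T12:00:00"))
    assert all(v == 0.0 for v in out.values())
    assert len(out) == 36


def test_window_features_inside_and_boundary():
    t = T("2020-02-03T12:00:00")
    ev = _events(
        [
            # fully inside, 300 s
            ("a", "messenger", "2020-02-03T11:30:00", "2020-02-03T11:35:00"),
            # spans the left boundary: 20 min total, 10 min inside
            ("a", "browser", "2020-02-03T10:50:00", "2020-02-03T11:10:00"),
            # entirely before the window
            ("a", "game", "2020-02-03T09:00:00", "2020-02-03T09:30:00"),
        ]
    )
    out = window_features(ev, t)
    assert out["duration_messenger"] == 300.0
    assert out["frequency_messenger"] == 1.0
    assert out["duration_browser"] == 600.0  # clipped overlap
    assert out["frequency_browser"] == 1.0  # intersecting counts
    assert out["duration_game"] == 0.0 and out["frequency_game"] == 0.0


def test_window_duration_conservation(demo_matrix):
    """Non-overlapping sessions: per-category durations sum to at most the
    window length for every observation."""
    total = demo_matrix[DURATION_COLUMNS].sum(axis=1)
    assert (total <= 3600.0 + 1e-9).all()


# ------------------------------------------------------------------- sleep --


def _night_events(pairs, pid="a"):
    return _events([(pid, "messenger", s, e) for s, e in pairs])


def test_detect_sleep_basic_gap():
    ev = _night_events(
        [
            ("2020-02-03T22:00:00", "2020-02-03T23:30:00"),
            ("2020-02-04T07:30:00", "2020-02-04T08:00:00"),
        ]
    )
    proxy = detect_sleep(ev, "2020-02-03")
    assert proxy.onset == pytest.approx(23.5)
    assert proxy.duration == pytest.approx(8.0)


def test_detect_sleep_post_midnight_convention():
    ev = _night_events(
        [
            ("2020-02-04T01:00:00", "2020-02-04T01:30:00"),
            ("2020-02-04T09:30:00", "2020-02-04T10:00:00"),
        ]
    )
    proxy = detect_sleep(ev, "2020-02-03")
    assert proxy.onset == pytest.approx(25.5)
    assert proxy.duration == pytest.approx(8.0)


def test_detect_sleep_no_qualifying_gap():
    # continuous use every 30 minutes all night: no gap reaches 3 h
    pairs = []
    t = pd.Timestamp("2020-02-03T19:00:00")
    while t < pd.Timestamp("2020-02-04T13:00:00"):
        pairs.append((str(t), str(t + pd.Timedelta(minutes=5))))
        t += pd.Timedelta(minutes=30)
    assert detect_sleep(_night_events(pairs), "2020-02-03") is None


def test_detect_sleep_ignores_daytime_events():
    core = [
        ("2020-02-03T22:00:00", "2020-02-03T23:30:00"),
        ("2020-02-04T07:30:00", "2020-02-04T08:00:00"),
    ]
    daytime = [
        ("2020-02-03T10:00:00", "2020-02-03T10:30:00"),
        ("2020-02-04T15:00:00", "2020-02-04T15:30:00"),
    ]
    a = detect_sleep(_night_events(core), "2020-02-03")
    b = detect_sleep(_night_events(core + daytime), "2020-02-03")
    assert (a.onset, a.duration) == (b.onset, b.duration)


def test_sleep_recovery_on_synthetic_cohort(demo_cohort):
    """Detected sleep matches the generator's drawn sleep to within the
    session-placement resolution (<= 10 minutes mean absolute error)."""
    events, _, truth = demo_cohort
    det = sleep_table(events)
    merged = det.merge(
        truth.sleep, on=["person_id", "night_date"], suffixes=("_det", "_true")
    )
    assert len(merged) >= 0.95 * len(truth.sleep)
    dur_mae = (merged["duration_det"] - merged["duration_true"]).abs().mean()
    onset_mae = (merged["onset_det"] - merged["onset_true"]).abs().mean()
    assert dur_mae <= 10 / 60
    assert onset_mae <= 10 / 60


def test_attach_sleep_rules():
    sleep = pd.DataFrame(
        {
            "person_id": ["a", "a"],
            "night_date": [T("2020-02-03"), T("2020-02-04")],
            "onset": [23.5, 25.0],
            "duration": [8.0, 7.0],
        }
    )
    ema = pd.DataFrame(
        {
            "person_id": ["a"] * 4 + ["b"],
            "prompt_time": [
                T("2020-02-04T14:00:00"),  # night 02-03
                T("2020-02-04T20:00:00"),  # same day -> identical proxies
                T("2020-02-05T09:00:00"),  # night 02-04
                T("2020-02-03T12:00:00"),  # first day, no prior night -> median
                T("2020-02-04T10:00:00"),  # person with zero nights -> dropped
            ],
        }
    )
    out, report = attach_sleep(ema, sleep)
    assert report.dropped_persons == ["b"]
    assert len(out) == 4
    assert out.iloc[0]["sleep_onset"] == 23.5 and out.iloc[0]["sleep_duration"] == 8.0
    assert out.iloc[1]["sleep_onset"] == 23.5  # same-day prompts share proxies
    assert out.iloc[2]["sleep_onset"] == 25.0
    assert out.iloc[3]["sleep_onset"] == pytest.approx(24.25)  # person median
    assert bool(out.iloc[3]["sleep_missing"]) is True
    assert report.n_imputed == 1


# -------------------------------------------------------------------- time --


def test_time_features_weekend_and_lockdown_boundary():
    lock = T("2020-03-15T00:00:00")
    hour, weekend, dom, covid = time_features(T("2020-02-08T09:15:00"), lock)  # Saturday
    assert (hour, weekend, dom, covid) == (9, 1, 8, 0)
    hour, weekend, dom, covid = time_features(T("2020-02-10T12:00:00"), lock)  # Monday
    assert (weekend, covid) == (0, 0)
    # closed left boundary: the lockdown instant itself counts as lockdown
    assert time_features(lock, lock)[3] == 1
    assert time_features(lock - pd.Timedelta(seconds=1), lock)[3] == 0
    assert time_features(T("2020-02-10T12:00:00"), None)[3] == 0


# ----------------------------------------------------------------- scaling --


def test_minmax_train_bounds_and_no_clipping():
    train = pd.DataFrame({"x": [2.0, 4.0, 6.0], "c": [5.0, 5.0, 5.0]})
    test = pd.DataFrame({"x": [8.0], "c": [9.0]})
    [strain, stest], record = minmax_fit_apply(train, test)
    assert np.allclose(strain["x"], [0.0, 0.5, 1.0])
    assert stest["x"].iloc[0] == pytest.approx(1.5)  # outside [0,1], unclipped
    assert np.allclose(strain["c"], 0.0)  # constant column maps to 0
    assert stest["c"].iloc[0] == pytest.approx(0.0)
    assert record.columns == ["x", "c"]


def test_minmax_empty_train_rejected():
    with pytest.raises(ValueError):
        minmax_fit_apply(pd.DataFrame({"x": []}))


# ------------------------------------------------------ variance structure --


def test_variance_decomposition_pure_within():
    values = [1, 2, 3, 4, 2, 3, 4, 5]
    pids = ["a"] * 4 + ["b"] * 4
    # equal person means -> all variance is within-person
    vals = np.array([1.0, 3.0, 2.0, 4.0, 3.0, 1.0, 4.0, 2.0])
    assert variance_decomposition(vals, pids) == pytest.approx(1.0)


def test_variance_decomposition_degenerate():
    with pytest.raises(ValueError):
        variance_decomposition([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])


def test_variance_decomposition_matches_anova_oracle():
    """Equal between- and within-person variance gives a ~0.5 within share
    (one-way ANOVA identity on simulated data)."""
    rng = np.random.default_rng(7)
    n_persons, n_obs = 60, 40
    person_means = rng.normal(0, 1.0, n_persons)
    values = (person_means[:, None] + rng.normal(0, 1.0, (n_persons, n_obs))).ravel()
    pids = np.repeat(np.arange(n_persons), n_obs)
    share = variance_decomposition(values, pids)
    assert abs(share - 0.5) < 0.05


# ------------------------------------------------------------------ matrix --


def test_feature_matrix_column_order_and_ranges(demo_matrix):
    assert list(demo_matrix.columns[: len(FEATURE_COLUMNS)]) == FEATURE_COLUMNS
    assert demo_matrix["hour_of_day"].between(0, 23).all()
    assert demo_matrix["weekend"].isin([0, 1]).all()
    assert demo_matrix["covid"].isin([0, 1]).all()
    assert demo_matrix["sleep_duration"].ge(0).all()
    assert demo_matrix["sleep_onset"].between(18, 36).all()
    # centered outcome sums to ~0 within person
    gm = demo_matrix.groupby("person_id")["stress_centered"].mean().abs()
    assert (gm < 1e-9).all()
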