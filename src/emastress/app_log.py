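"""Reading, validating and categorizing raw smartphone app-use event logs.

An app-use event log has one row per app session: the person who used the
app, the app's name, and the session's start and end timestamps. Apps are
mapped onto 18 core categories (browser, calling, camera, dating, email,
exercise, food & drink, gallery, game, messenger, music & audio,
productivity, shared transportation, social network, tracker, video,
weather, work) through a name-based coding scheme; apps the scheme does not
know fall into ``"other"`` and are retained but excluded from the
category-level features downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

#: The 18 core app categories, alphabetical. This order is the canonical
#: column order for every per-category feature downstream.
CORE_CATEGORIES: tuple[str, ...] = (
    "browser",
    "calling",
    "camera",
    "dating",
    "email",
    "exercise",
    "food_drink",
    "gallery",
    "game",
    "messenger",
    "music_audio",
    "productivity",
    "shared_transportation",
    "social_network",
    "tracker",
    "video",
    "weather",
    "work",
)

#: Label for apps the coding scheme does not cover.
OTHER_CATEGORY = "other"

_NORMALIZE_RE = re.compile(r"[^a-z0-9]+")


def normalize_app_name(name: str) -> str:
    """Lowercase and strip non-alphanumerics: ``"WhatsApp Messenger"`` -> ``"whatsappmessenger"``."""
    return _NORMALIZE_RE.sub("", str(name).lower())


class CategoryMap:
    """Name-based mapping from apps to the 18 core categories.

    Lookup is case- and punctuation-insensitive (names are normalized with
    :func:`normalize_app_name`). Unknown apps map to ``"other"``.
    """

    def __init__(self, mapping: dict[str, str]):
        bad = set(mapping.values()) - set(CORE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown category labels: {sorted(bad)}")
        self._map = {normalize_app_name(k): v for k, v in mapping.items()}

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "CategoryMap":
        """Load a category -> [app names] YAML file; ``None`` loads the shipped seed map."""
        if path is None:
            text = (
                resources.files("emastress").joinpath("data/category_map.yaml").read_text()
            )
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        mapping: dict[str, str] = {}
        for category, names in raw.items():
            for name in names:
                mapping[str(name)] = category
        return cls(mapping)

    def categorize(self, app_name: str) -> str:
        return self._map.get(normalize_app_name(app_name), OTHER_CATEGORY)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, app_name: str) -> bool:
        return normalize_app_name(app_name) in self._map


def categorize_app(app_name: str, category_map: CategoryMap) -> str:
    """Map an app name to its category label, or ``"other"`` when unmapped."""
    return category_map.categorize(app_name)


EVENT_COLUMNS = ["person_id", "app_name", "category", "start", "end"]


@dataclass
class LoadReport:
    """Row-level account of what a log read kept and dropped."""

    n_read: int = 0
    n_kept: int = 0
    n_end_before_start: int = 0
    n_bad_timestamp: int = 0
    n_truncated_overlaps: int = 0
    rejected_rows: list[int] = field(default_factory=list)  # 0-based data row indices

    @property
    def n_rejected(self) -> int:
        return self.n_end_before_start + self.n_bad_timestamp


def load_events(
    path: str | Path, category_map: CategoryMap
) -> tuple[pd.DataFrame, LoadReport]:
    """Read an app-event CSV, attach categories, and sort by (person, start).

    The CSV must have columns ``person_id, app_name, start, end`` with
    ISO-8601 timestamps. Rows whose end precedes their start, or whose
    timestamps do not parse, are dropped and tallied in the returned
    :class:`LoadReport`. Overlapping sessions of one person (malformed logs)
    are truncated at the next session's start so durations stay additive.
    """
    df = pd.read_csv(path)
    required = {"person_id", "app_name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event log is missing columns: {sorted(missing)}")

    report = LoadReport(n_read=len(df))
    start = pd.to_datetime(df["start"], errors="coerce", format="ISO8601")
    end = pd.to_datetime(df["end"], errors="coerce", format="ISO8601")

    bad_ts = start.isna() | end.isna()
    inverted = ~bad_ts & (end < start)
    report.n_bad_timestamp = int(bad_ts.sum())
    report.n_end_before_start = int(inverted.sum())
    report.rejected_rows = sorted(df.index[bad_ts | inverted].tolist())

    keep = ~(bad_ts | inverted)
    events = pd.DataFrame(
        {
            "person_id": df.loc[keep, "person_id"],
            "app_name": df.loc[keep, "app_name"].astype(str),
            "category": df.loc[keep, "app_name"].astype(str).map(category_map.categorize),
            "start": start[keep],
            "end": end[keep],
        }
    )
    events = events.sort_values(["person_id", "start", "end"], kind="mergesort")
    events = events.reset_index(drop=True)

    # Truncate overlaps at the next event's start, per person.
    nxt_start = events.groupby("person_id", sort=False)["start"].shift(-1)
    overlap = nxt_start.notna() & (events["end"] > nxt_start)
    events.loc[overlap, "end"] = nxt_start[overlap]
    report.n_truncated_overlaps = int(overlap.sum())

    report.n_kept = len(events)
    return events[EVENT_COLUMNS], report


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as CSV with ISO-8601 timestamps (round-trips with :func:`load_events`)."""
    out = events[["person_id", "app_name", "start", "end"]].copy()
    out["start"] = out["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["end"] = out["end"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def coverage_report(events: pd.DataFrame) -> float:
    """Fraction of app events that fall in one of the 18 core categories."""
    if len(events) == 0:
        raise ValueError("coverage is undefined for an empty event table")
    return float((events["category"] != OTHER_CATEGORY).mean())
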