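"""Detection-event and video-metadata data model, CSV I/O and survey validation.

The atom of both survey methods is a *detection event*: one timestamped
sighting of one species with a count of individuals in the field of view.
Video metadata places each deployment in the study's factorial design:
protection status (``fished`` vs ``roa``, a two-level fixed factor), depth
class (``deep`` vs ``shallow``, fixed), and site (random, nested in status).
A *habitat* is one status x depth combination, so there are exactly four.

Events are carried as a pandas DataFrame with columns
``video_id, time_s, species, n_individuals`` sorted stably by
``(video_id, time_s)``; videos as a DataFrame with columns
``video_id, site_id, status, depth_class, duration_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

EVENT_COLUMNS = ["video_id", "time_s", "species", "n_individuals"]
VIDEO_COLUMNS = ["video_id", "site_id", "status", "depth_class", "duration_s"]

STATUS_LEVELS = ("fished", "roa")
DEPTH_LEVELS = ("deep", "shallow")

DEFAULT_DURATION_S = 3600.0


class FormatError(ValueError):
    """A file does not conform to the expected CSV schema."""


class ValidationError(ValueError):
    """Row-level content violates an invariant (negative time, count < 1, ...)."""


class Habitat(NamedTuple):
    """One status x depth combination (four possible)."""

    status: str
    depth_class: str

    @property
    def label(self) -> str:
        status = "ROA" if self.status == "roa" else "Fished"
        return f"{self.depth_class.capitalize()} {status}"


ALL_HABITATS = tuple(
    Habitat(status, depth) for depth in DEPTH_LEVELS for status in STATUS_LEVELS
)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (video_id, time_s); equal keys keep input order."""
    return events.sort_values(
        ["video_id", "time_s"], kind="stable", ignore_index=True
    )


def validate_events(events: pd.DataFrame, source: str = "events") -> pd.DataFrame:
    """Check event invariants, reporting the first offending data row.

    Row numbers are 1-based file rows counting the header, so the first data
    row is row 2 — matching what a user sees in a spreadsheet or editor.
    """
    _require_columns(events, EVENT_COLUMNS, source)
    events = events[EVENT_COLUMNS].copy()
    events["time_s"] = pd.to_numeric(events["time_s"])
    events["n_individuals"] = pd.to_numeric(events["n_individuals"])
    events["species"] = events["species"].astype(str)
    events["video_id"] = events["video_id"].astype(str)

    for pos, row in enumerate(events.itertuples(index=False)):
        file_row = pos + 2
        if row.time_s < 0:
            raise ValidationError(f"{source} row {file_row}: negative time_s ({row.time_s})")
        if row.n_individuals < 1:
            raise ValidationError(
                f"{source} row {file_row}: n_individuals must be >= 1 (got {row.n_individuals})"
            )
        if not row.species or row.species.strip() == "":
            raise ValidationError(f"{source} row {file_row}: empty species")
    events["n_individuals"] = events["n_individuals"].astype(int)
    return events


def read_events(path) -> pd.DataFrame:
    """Read a detection-event CSV, validate, and return sorted by (video_id, time_s)."""
    df = pd.read_csv(path, comment="#")
    df = validate_events(df, source=str(path))
    return sort_events(df)


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def read_videos(path) -> pd.DataFrame:
    """Read video metadata, normalising status/depth levels case-insensitively."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, VIDEO_COLUMNS[:4], path)
    if "duration_s" not in df.columns:
        df["duration_s"] = DEFAULT_DURATION_S
    return validate_videos(df, source=str(path))


def validate_videos(videos: pd.DataFrame, source: str = "videos") -> pd.DataFrame:
    videos = videos[VIDEO_COLUMNS].copy()
    videos["video_id"] = videos["video_id"].astype(str)
    videos["site_id"] = videos["site_id"].astype(str)
    videos["status"] = videos["status"].astype(str).str.strip().str.lower()
    videos["depth_class"] = videos["depth_class"].astype(str).str.strip().str.lower()
    videos["duration_s"] = pd.to_numeric(videos["duration_s"])

    dupes = videos["video_id"][videos["video_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{source}: duplicate video_id(s): {sorted(dupes)}")
    bad_status = sorted(set(videos["status"]) - set(STATUS_LEVELS))
    if bad_status:
        raise ValidationError(
            f"{source}: unknown status level(s) {bad_status}; allowed: {list(STATUS_LEVELS)}"
        )
    bad_depth = sorted(set(videos["depth_class"]) - set(DEPTH_LEVELS))
    if bad_depth:
        raise ValidationError(
            f"{source}: unknown depth_class level(s) {bad_depth}; allowed: {list(DEPTH_LEVELS)}"
        )
    if (videos["duration_s"] <= 0).any():
        raise ValidationError(f"{source}: duration_s must be positive")
    return videos.reset_index(drop=True)


def write_videos(videos: pd.DataFrame, path) -> None:
    videos[VIDEO_COLUMNS].to_csv(path, index=False)


def habitat_of(videos: pd.DataFrame) -> pd.Series:
    """Habitat of each video row, as a Series of :class:`Habitat`."""
    return pd.Series(
        [Habitat(s, d) for s, d in zip(videos["status"], videos["depth_class"])],
        index=videos.index,
        name="habitat",
    )


@dataclass
class SurveyReport:
    """Consistency findings for an (events, videos) pair.

    Empty findings iff the survey is internally consistent.
    """

    orphan_events: list[str] = field(default_factory=list)
    out_of_range_events: list[str] = field(default_factory=list)
    empty_videos: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.orphan_events or self.out_of_range_events or self.empty_videos)

    @property
    def findings(self) -> list[str]:
        return self.orphan_events + self.out_of_range_events + self.empty_videos


def validate_survey(events: pd.DataFrame, videos: pd.DataFrame) -> SurveyReport:
    """Cross-check events against video metadata (report-based, never raises)."""
    report = SurveyReport()
    known = dict(zip(videos["video_id"], videos["duration_s"]))
    for vid, group in events.groupby("video_id", sort=True):
        if vid not in known:
            report.orphan_events.append(
                f"{len(group)} event(s) reference unknown video {vid!r}"
            )
            continue
        over = group[group["time_s"] > known[vid]]
        for row in over.itertuples(index=False):
            report.out_of_range_events.append(
                f"video {vid!r}: event at t={row.time_s} s exceeds duration {known[vid]} s"
            )
    with_events = set(events["video_id"])
    for vid in videos["video_id"]:
        if vid not in with_events:
            report.empty_videos.append(f"video {vid!r} has zero detection events")
    return report
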