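"""Reading, filtering and time-indexing tweet tables.

Tweets arrive as JSONL (one object per line) or CSV with a declared column
mapping.  The pipeline works on original tweets only (retweets are dropped),
and every tweet is assigned to a local calendar day in a configurable
timezone — daily binning follows the affected community's local days
(default ``Europe/Paris``), with Monday as weekday 0.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Iterator, Mapping
from zoneinfo import ZoneInfo

log = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "StudyWindows",
    "read_tweets",
    "filter_original",
    "assign_day",
]

DEFAULT_TIMEZONE = "Europe/Paris"

_DEFAULT_COLUMNS = {"user_id": "user_id", "timestamp": "timestamp", "text": "text",
                    "is_retweet": "is_retweet"}


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One tweet: opaque user id, timezone-aware instant, raw text."""

    user_id: str
    timestamp: datetime
    text: str
    is_retweet: bool | None = None

    def __post_init__(self) -> None:
        if not self.user_id:
            raise ValueError("user_id must be non-empty")
        if self.timestamp.tzinfo is None:
            raise ValueError("timestamp must be timezone-aware")


@dataclass(frozen=True)
class StudyWindows:
    """The three analysis windows around the event day.

    ``baseline`` is the pre-event period used for per-user baselines and
    personality indicators, ``short`` the immediate post-event window in
    which emotional synchronization is measured, and ``long`` the follow-up
    period for solidarity outcomes.  All bounds are inclusive calendar dates.
    """

    baseline_start: date
    baseline_end: date
    event_day: date
    short_start: date
    short_end: date
    long_start: date
    long_end: date

    def __post_init__(self) -> None:
        if not (self.baseline_start <= self.baseline_end):
            raise ValueError("baseline_start must be <= baseline_end")
        if not (self.baseline_end < self.event_day <= self.short_start):
            raise ValueError("need baseline_end < event_day <= short_start")
        if not (self.short_start <= self.short_end < self.long_start <= self.long_end):
            raise ValueError("need short_start <= short_end < long_start <= long_end")

    @classmethod
    def default(cls) -> "StudyWindows":
        """The November-2015 study layout: 3-month baseline (Aug 13 – Nov 12),
        2 weeks post-event (Nov 13 – 27), then 3 months (Nov 28 – Feb 27)."""
        return cls(
            baseline_start=date(2015, 8, 13),
            baseline_end=date(2015, 11, 12),
            event_day=date(2015, 11, 13),
            short_start=date(2015, 11, 13),
            short_end=date(2015, 11, 27),
            long_start=date(2015, 11, 28),
            long_end=date(2016, 2, 27),
        )

    def classify(self, day: date) -> str | None:
        if self.baseline_start <= day <= self.baseline_end:
            return "baseline"
        if self.short_start <= day <= self.short_end:
            return "short"
        if self.long_start <= day <= self.long_end:
            return "long"
        return None

    @property
    def span(self) -> tuple[date, date]:
        return self.baseline_start, self.long_end


def _parse_timestamp(value: str) -> datetime:
    ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


def _to_bool(value) -> bool | None:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "t", "yes"}


def read_tweets(
    path,
    format: str | None = None,
    columns: Mapping[str, str] | None = None,
    max_bad_rows: int = 0,
) -> list[TweetRecord]:
    """Read a tweet table from JSONL or CSV.

    Parameters
    ----------
    format:
        ``"jsonl"`` or ``"csv"``; inferred from the file suffix if omitted.
    columns:
        Mapping from the record fields (``user_id``, ``timestamp``, ``text``,
        optionally ``is_retweet``) to the column/key names in the file.
    max_bad_rows:
        Unparseable rows are counted and logged; the read fails as soon as
        the count exceeds this tolerance, naming the offending line.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if format is None:
        suffix = str(path).rsplit(".", 1)[-1].lower()
        format = {"jsonl": "jsonl", "json": "jsonl", "csv": "csv"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}; pass format=")

    records: list[TweetRecord] = []
    n_bad = 0
    first_bad = None

    def handle_row(row: Mapping, lineno: int) -> None:
        nonlocal n_bad, first_bad
        try:
            rec = TweetRecord(
                user_id=str(row[colmap["user_id"]]),
                timestamp=_parse_timestamp(row[colmap["timestamp"]]),
                text=str(row[colmap["text"]]),
                is_retweet=_to_bool(row.get(colmap["is_retweet"])),
            )
        except (KeyError, ValueError, TypeError) as exc:
            n_bad += 1
            if first_bad is None:
                first_bad = (lineno, exc)
            if n_bad > max_bad_rows:
                raise ValueError(
                    f"{path}: line {lineno}: unparseable row ({exc}); "
                    f"{n_bad} bad rows exceeds tolerance {max_bad_rows}"
                ) from exc
            return
        records.append(rec)

    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    n_bad += 1
                    if n_bad > max_bad_rows:
                        raise ValueError(
                            f"{path}: line {lineno}: invalid JSON ({exc})"
                        ) from exc
                    continue
                handle_row(row, lineno)
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            fields = reader.fieldnames or []
            for key in ("user_id", "timestamp", "text"):
                if colmap[key] not in fields:
                    raise ValueError(
                        f"{path}: missing mandatory column {colmap[key]!r} "
                        f"(have {fields})"
                    )
            for lineno, row in enumerate(reader, start=2):
                handle_row(row, lineno)
    else:
        raise ValueError(f"unknown format {format!r}")

    if n_bad:
        log.warning("%s: skipped %d unparseable rows (first at line %s)", path, n_bad,
                    first_bad[0] if first_bad else "?")
    return records


def filter_original(records: Iterable[TweetRecord]) -> Iterator[TweetRecord]:
    """Keep original tweets only.

    Drops records flagged ``is_retweet``; when the flag is absent, drops
    records whose text starts with the literal prefix ``"RT @"``.
    Idempotent, and warns when everything was filtered away.
    """
    n_in = n_out = 0
    for rec in records:
        n_in += 1
        if rec.is_retweet is True:
            continue
        if rec.is_retweet is None and rec.text.startswith("RT @"):
            continue
        n_out += 1
        yield rec
    if n_in and not n_out:
        log.warning("filter_original: all %d records were retweets", n_in)


def assign_day(record: TweetRecord, tz: str = DEFAULT_TIMEZONE) -> tuple[date, int]:
    """Local calendar date and weekday index (Monday=0) of a tweet."""
    try:
        zone = ZoneInfo(tz)
    except Exception as exc:  # zoneinfo raises several lookup error types
        raise ValueError(f"unknown timezone {tz!r}") from exc
    local = record.timestamp.astimezone(zone)
    return local.date(), local.weekday()


def date_range(start: date, end: date) -> list[date]:
    """Inclusive list of calendar dates."""
    return [start + timedelta(days=i) for i in range((end - start).days + 1)]
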