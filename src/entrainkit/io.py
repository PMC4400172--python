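"""Readers and writers for annotations, message streams and rate tables.

Formats
-------
Annotation, single-file JSON::

    {"onset_timestamp": 1349830800.0, "duration_s": 5400.0,
     "speakers": ["obama", "romney", "moderator"],
     "turns": [{"speaker": "obama", "start_s": 0.0, "end_s": 24.3,
                "is_interruption": false}, ...],
     "salient_events": [{"label": "big bird", "onset_s": 1800.0,
                         "match_terms": ["big bird", "bigbird"]}, ...]}

Annotation, CSV + sidecar: a CSV with columns
``speaker,start_s,end_s,is_interruption`` (one row per turn) next to a JSON
sidecar ``<stem>.meta.json`` holding everything but the turns.

Messages: JSON Lines with fields ``timestamp`` (epoch float or ISO-8601),
``text`` and optional ``is_retweet``; or a CSV with the same columns.

Rate tables: tidy CSV with columns ``t_s,channel,count`` (``t_s`` = left bin
edge relative to event onset).

A minimal reader for Praat TextGrid interval tiers imports turns annotated in
phonetic software; non-empty interval labels become speaker names.
"""

from __future__ import annotations

import csv
import json
import re
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from entrainkit.timeline import (
    DebateAnnotation,
    Message,
    RateSeries,
    SalientEvent,
    SpeechTurn,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_annotation",
    "write_annotation",
    "read_messages",
    "write_messages",
    "read_rates",
    "write_rates",
    "read_textgrid_turns",
]


class ParseError(ValueError):
    """A file does not conform to its documented schema."""


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False, "": False}


def _parse_bool(raw: str | bool, where: str) -> bool:
    if isinstance(raw, bool):
        return raw
    try:
        return _BOOL[str(raw).strip().lower()]
    except KeyError:
        raise ParseError(f"{where}: cannot parse boolean {raw!r}") from None


def _parse_timestamp(raw: object, where: str) -> float:
    if isinstance(raw, (int, float)):
        return float(raw)
    text = str(raw).strip()
    try:
        return float(text)
    except ValueError:
        pass
    try:
        dt = datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError:
        raise ParseError(f"{where}: cannot parse timestamp {raw!r}") from None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


# ---------------------------------------------------------------------------
# annotations


def _annotation_from_dict(data: dict, source: str) -> DebateAnnotation:
    try:
        turns = [
            SpeechTurn(
                speaker=str(t["speaker"]),
                start_s=float(t["start_s"]),
                end_s=float(t["end_s"]),
                is_interruption=_parse_bool(t.get("is_interruption", False), source),
            )
            for t in data.get("turns", [])
        ]
        events = [
            SalientEvent(
                label=str(e["label"]),
                onset_s=float(e["onset_s"]),
                match_terms=tuple(e["match_terms"]),
            )
            for e in data.get("salient_events", [])
        ]
        return DebateAnnotation(
            onset_timestamp=float(data["onset_timestamp"]),
            duration_s=float(data["duration_s"]),
            speakers=tuple(data["speakers"]),
            turns=turns,
            salient_events=events,
        )
    except KeyError as exc:
        raise ParseError(f"{source}: missing required field {exc}") from None


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def read_annotation(path: str | Path, format: str | None = None) -> DebateAnnotation:
    """Read a :class:`DebateAnnotation` from JSON or CSV(+sidecar).

    ``format`` is ``"json"`` or ``"csv"``; inferred from the suffix when None.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        with open(path) as fh:
            data = json.load(fh)
        return _annotation_from_dict(data, str(path))
    if fmt != "csv":
        raise ValueError(f"unknown annotation format {format!r}")

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ParseError(f"annotation CSV {path} needs sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    turns = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"speaker", "start_s", "end_s", "is_interruption"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            try:
                turns.append(
                    SpeechTurn(
                        speaker=row["speaker"],
                        start_s=float(row["start_s"]),
                        end_s=float(row["end_s"]),
                        is_interruption=_parse_bool(row["is_interruption"], where),
                    )
                )
            except (TypeError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{where}: malformed turn row ({exc})") from None
    meta = dict(meta)
    meta["turns"] = []
    ann = _annotation_from_dict(meta, str(sidecar))
    ann.turns = sorted(turns, key=lambda t: (t.start_s, t.end_s))
    # re-validate with the turns attached
    return DebateAnnotation(
        onset_timestamp=ann.onset_timestamp,
        duration_s=ann.duration_s,
        speakers=ann.speakers,
        turns=ann.turns,
        salient_events=ann.salient_events,
    )


def _annotation_to_dict(ann: DebateAnnotation) -> dict:
    return {
        "onset_timestamp": ann.onset_timestamp,
        "duration_s": ann.duration_s,
        "speakers": list(ann.speakers),
        "turns": [
            {
                "speaker": t.speaker,
                "start_s": t.start_s,
                "end_s": t.end_s,
                "is_interruption": t.is_interruption,
            }
            for t in ann.turns
        ],
        "salient_events": [
            {"label": e.label, "onset_s": e.onset_s, "match_terms": list(e.match_terms)}
            for e in ann.salient_events
        ],
    }


def write_annotation(ann: DebateAnnotation, path: str | Path, format: str | None = None) -> None:
    """Write an annotation as single-file JSON or CSV + sidecar."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    data = _annotation_to_dict(ann)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
            fh.write("\n")
        return
    if fmt != "csv":
        raise ValueError(f"unknown annotation format {format!r}")
    turns = data.pop("turns")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["speaker", "start_s", "end_s", "is_interruption"])
        writer.writeheader()
        writer.writerows(turns)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# messages


def read_messages(path: str | Path, format: str | None = None) -> list[Message]:
    """Read a message stream from JSON Lines or CSV."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    msgs: list[Message] = []
    if fmt == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}:{lineno}: bad JSON ({exc})") from None
                msgs.append(
                    Message(
                        timestamp=_parse_timestamp(rec["timestamp"], f"{path}:{lineno}"),
                        text=str(rec.get("text", "")),
                        is_retweet=_parse_bool(rec.get("is_retweet", False), f"{path}:{lineno}"),
                    )
                )
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                msgs.append(
                    Message(
                        timestamp=_parse_timestamp(row["timestamp"], f"{path}:{lineno}"),
                        text=row.get("text", ""),
                        is_retweet=_parse_bool(row.get("is_retweet", False), f"{path}:{lineno}"),
                    )
                )
    else:
        raise ValueError(f"unknown message format {format!r}")
    return msgs


def write_messages(msgs: list[Message], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with open(path, "w") as fh:
            for m in msgs:
                fh.write(
                    json.dumps(
                        {"timestamp": m.timestamp, "text": m.text, "is_retweet": m.is_retweet}
                    )
                )
                fh.write("\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["timestamp", "text", "is_retweet"])
            writer.writeheader()
            for m in msgs:
                writer.writerow(
                    {"timestamp": m.timestamp, "text": m.text, "is_retweet": m.is_retweet}
                )
    else:
        raise ValueError(f"unknown message format {format!r}")


# ---------------------------------------------------------------------------
# rate tables


def write_rates(series: RateSeries, path: str | Path) -> None:
    """Write a rate series as a tidy CSV (t_s, channel, count)."""
    frames = []
    t = series.t0_s + np.arange(series.n_bins) * series.bin_width_s
    for name, vec in sorted(series.channels.items()):
        frames.append(pd.DataFrame({"t_s": t, "channel": name, "count": np.asarray(vec)}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rates(path: str | Path) -> RateSeries:
    """Read a tidy rate CSV back into a :class:`RateSeries`."""
    df = pd.read_csv(path)
    required = {"t_s", "channel", "count"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: rate table needs columns {sorted(required)}")
    channels = {}
    t0 = float(df["t_s"].min())
    n_bins = df.groupby("channel").size().max()
    widths = np.diff(np.sort(df["t_s"].unique()))
    bin_w = float(widths.min()) if widths.size else 1.0
    for name, grp in df.groupby("channel"):
        grp = grp.sort_values("t_s")
        vec = grp["count"].to_numpy()
        channels[str(name)] = vec.astype(np.int64) if np.allclose(vec, vec.round()) else vec
    return RateSeries(t0_s=t0, bin_width_s=bin_w, channels=channels, n_bins=int(n_bins))


# ---------------------------------------------------------------------------
# Praat TextGrid (interval tiers -> turns)

_TG_NUM = re.compile(r"(xmin|xmax)\s*=\s*([0-9.eE+-]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"((?:[^"]|"")*)"')


def read_textgrid_turns(
    path: str | Path,
    onset_timestamp: float = 0.0,
    tier: str | None = None,
) -> DebateAnnotation:
    """Read speech turns from a Praat TextGrid interval tier.

    Non-empty interval labels are taken as speaker names; empty intervals are
    silence.  Interruption flags are not represented in a plain TextGrid and
    default to False.  ``tier`` selects an interval tier by name (first
    interval tier when None).
    """
    text = Path(path).read_text()
    tiers: list[tuple[str, list[tuple[float, float, str]]]] = []
    # split on 'item [k]:' blocks; robust to both long and short TextGrid forms
    blocks = re.split(r"item\s*\[\d+\]\s*:", text)
    for block in blocks[1:]:
        mname = re.search(r'name\s*=\s*"((?:[^"]|"")*)"', block)
        if "IntervalTier" not in block:
            continue
        name = mname.group(1) if mname else ""
        intervals: list[tuple[float, float, str]] = []
        for chunk in re.split(r"intervals\s*\[\d+\]\s*:", block)[1:]:
            nums = dict(_TG_NUM.findall(chunk))
            mtext = _TG_TEXT.search(chunk)
            if "xmin" not in nums or "xmax" not in nums or mtext is None:
                raise ParseError(f"{path}: malformed TextGrid interval in tier {name!r}")
            intervals.append(
                (float(nums["xmin"]), float(nums["xmax"]), mtext.group(1).replace('""', '"'))
            )
        tiers.append((name, intervals))
    if not tiers:
        raise ParseError(f"{path}: no interval tier found")
    if tier is not None:
        match = [iv for (nm, iv) in tiers if nm == tier]
        if not match:
            raise ParseError(f"{path}: no interval tier named {tier!r}")
        intervals = match[0]
    else:
        intervals = tiers[0][1]
    turns = [
        SpeechTurn(speaker=label.strip().lower(), start_s=lo, end_s=hi)
        for (lo, hi, label) in intervals
        if label.strip() and hi > lo
    ]
    duration = max((hi for (_, hi, _) in intervals), default=0.0)
    speakers = tuple(sorted({t.speaker for t in turns}))
    return DebateAnnotation(
        onset_timestamp=onset_timestamp,
        duration_s=duration,
        speakers=speakers,
        turns=turns,
    )
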