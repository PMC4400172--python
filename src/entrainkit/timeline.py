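"""Conversational timeline model, message filtering, alignment and binning.

The central objects are :class:`DebateAnnotation` (the conversational timeline:
speech turns with interruption flags, plus salient-event onsets) and
:class:`RateSeries` (per-second message counts aligned to the event onset, one
channel per tracked term plus a ``"total"`` channel).

Conventions
-----------
* Times inside an annotation are seconds relative to the event onset; message
  timestamps are absolute epoch seconds.
* Bins are half-open ``[k*w, (k+1)*w)`` seconds, 0-based from event onset.
* Term matching is case-insensitive substring matching; hashtags match because
  ``'#'`` does not break a substring ("#obama2012" matches "obama").
* When turns overlap (interruptions), the floor-holder at second ``t`` is the
  turn with the latest start ``<= t`` that has not yet ended: the last starter
  wins, mirroring interruption semantics.
* Missing values are ``NaN``, never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "SpeechTurn",
    "SalientEvent",
    "DebateAnnotation",
    "Message",
    "FilterSpec",
    "RateSeries",
    "contains_url",
    "is_retweet_text",
    "filter_messages",
    "align_and_bin",
    "mention_proportion",
    "event_locked_window",
    "first_latency",
    "peak_latency",
]


class ValidationError(ValueError):
    """An input object violates a timeline invariant."""


@dataclass(frozen=True)
class SpeechTurn:
    """One contiguous interval in which a single speaker holds forth.

    ``start_s``/``end_s`` are seconds relative to the event onset.
    ``is_interruption`` marks a turn initiated before the previous speaker
    finished.
    """

    speaker: str
    start_s: float
    end_s: float
    is_interruption: bool = False

    def __post_init__(self) -> None:
        if not (self.start_s >= 0 and math.isfinite(self.start_s)):
            raise ValidationError(f"turn start_s must be finite and >= 0, got {self.start_s}")
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"turn end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SalientEvent:
    """A pointed remark whose key term may propagate as a meme.

    ``match_terms`` are lowercase root terms (e.g. ``["big bird", "bigbird"]``)
    used to pull the event's mentions out of the stream.
    """

    label: str
    onset_s: float
    match_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValidationError(f"salient event onset_s must be >= 0, got {self.onset_s}")
        terms = tuple(self.match_terms)
        if not terms:
            raise ValidationError("salient event needs at least one match term")
        if any(t != t.lower() or not t for t in terms):
            raise ValidationError("match_terms must be non-empty and lowercase")
        object.__setattr__(self, "match_terms", terms)


@dataclass
class DebateAnnotation:
    """The annotated conversational timeline of one broadcast event.

    Parameters
    ----------
    onset_timestamp : float
        Absolute epoch time (seconds) of the event onset; aligns the message
        stream with the annotation.
    duration_s : float
        Event length in seconds (a debate runs about 90 minutes).
    speakers : tuple of str
        Declared speaker set: two principals plus an optional moderator.
    turns : list of SpeechTurn
        Sorted by ``start_s`` on construction.
    salient_events : list of SalientEvent
    """

    onset_timestamp: float
    duration_s: float
    speakers: tuple[str, ...]
    turns: list[SpeechTurn] = field(default_factory=list)
    salient_events: list[SalientEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        self.speakers = tuple(self.speakers)
        self.turns = sorted(self.turns, key=lambda t: (t.start_s, t.end_s))
        known = set(self.speakers)
        for turn in self.turns:
            if turn.speaker not in known:
                raise ValidationError(
                    f"turn speaker {turn.speaker!r} not in declared speakers {sorted(known)}"
                )
            if turn.end_s > self.duration_s + 1e-9:
                raise ValidationError(
                    f"turn [{turn.start_s}, {turn.end_s}) extends past duration {self.duration_s}"
                )
        for ev in self.salient_events:
            if ev.onset_s > self.duration_s:
                raise ValidationError(
                    f"salient event {ev.label!r} onset {ev.onset_s} past duration"
                )

    def floor_holder_index(self, t_s: float) -> int:
        """Index (into ``turns``) of the turn holding the floor at time ``t_s``.

        Last starter wins among turns with ``start_s <= t_s < end_s``.
        Returns -1 when no turn covers ``t_s``.
        """
        best = -1
        for i, turn in enumerate(self.turns):
            if turn.start_s > t_s:
                break
            if turn.end_s > t_s:
                best = i  # turns are sorted by start, so later i = later start
        return best

    def floor_track(self, bin_width_s: float = 1.0) -> np.ndarray:
        """Vector of floor-holding turn indices, one per bin left edge.

        Entry ``k`` is the index of the turn holding the floor at second
        ``k * bin_width_s`` (−1 outside any turn).  Vectorised equivalent of
        :meth:`floor_holder_index` applied to every bin.
        """
        n = int(math.ceil(self.duration_s / bin_width_s))
        edges = np.arange(n) * bin_width_s
        track = np.full(n, -1, dtype=np.int64)
        # later turns in sorted order overwrite earlier ones: last starter wins
        for i, turn in enumerate(self.turns):
            track[(edges >= turn.start_s) & (edges < turn.end_s)] = i
        return track


@dataclass(frozen=True)
class Message:
    """A single timestamped message (e.g. one tweet)."""

    timestamp: float
    text: str
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.timestamp):
            raise ValidationError(f"message timestamp must be finite, got {self.timestamp}")


@dataclass(frozen=True)
class FilterSpec:
    """Which messages to keep and how to assign them to term channels.

    ``include_terms`` are lowercase root terms (candidate names, meme terms).
    URL-bearing messages are dropped when ``exclude_urls`` (a crude but
    effective spambot filter); retweets are dropped when ``exclude_retweets``
    so that bursts are not mere reposts of the same message.
    """

    include_terms: tuple[str, ...]
    exclude_urls: bool = True
    exclude_retweets: bool = True

    def __post_init__(self) -> None:
        terms = tuple(self.include_terms)
        if not terms:
            raise ValidationError("FilterSpec needs at least one include term")
        if any(t != t.lower() or not t for t in terms):
            raise ValidationError("include_terms must be non-empty and lowercase")
        object.__setattr__(self, "include_terms", terms)


_URL_MARKERS = ("http://", "https://", "www.")
_RT_PREFIX = "rt @"


def contains_url(text: str) -> bool:
    """True if the text carries a URL marker (http://, https://, www.)."""
    low = text.lower()
    return any(m in low for m in _URL_MARKERS)


def is_retweet_text(text: str) -> bool:
    """Fallback retweet detector for streams without retweet metadata."""
    return text.lower().startswith(_RT_PREFIX)


def _is_retweet(msg: Message) -> bool:
    return msg.is_retweet or is_retweet_text(msg.text)


def filter_messages(
    messages: list[Message], spec: FilterSpec
) -> dict[str, list[Message]]:
    """Assign messages to term channels, applying URL and retweet exclusions.

    A message lands under term ``T`` iff ``T`` occurs as a substring of the
    lowercased text (hashtags included).  A message may appear under several
    terms.  Returns ``{term: [messages...]}`` with every term present even if
    empty.
    """
    out: dict[str, list[Message]] = {t: [] for t in spec.include_terms}
    for msg in messages:
        if spec.exclude_retweets and _is_retweet(msg):
            continue
        if spec.exclude_urls and contains_url(msg.text):
            continue
        low = msg.text.lower()
        for term in spec.include_terms:
            if term in low:
                out[term].append(msg)
    return out


@dataclass
class RateSeries:
    """Per-bin message counts aligned to the event onset.

    ``channels`` maps a channel label (one per tracked term, plus ``"total"``)
    to a length-``n_bins`` count vector.  ``t0_s`` is the time of the left
    edge of bin 0 relative to the alignment origin (0 for a freshly binned
    series, negative after an event-locked window with a pre-onset margin).
    Counts are integers after binning; channels become floats after
    max-scaling.
    """

    t0_s: float
    bin_width_s: float
    channels: dict[str, np.ndarray]
    n_bins: int
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0:
            raise ValidationError("bin_width_s must be > 0")
        for name, vec in self.channels.items():
            vec = np.asarray(vec)
            if vec.shape != (self.n_bins,):
                raise ValidationError(
                    f"channel {name!r} has length {vec.shape}, expected ({self.n_bins},)"
                )
            if np.issubdtype(vec.dtype, np.integer) and (vec < 0).any():
                raise ValidationError(f"channel {name!r} has negative counts")
            self.channels[name] = vec

    def bin_centers(self) -> np.ndarray:
        return self.t0_s + (np.arange(self.n_bins) + 0.5) * self.bin_width_s

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise KeyError(f"unknown channel {label!r}; have {sorted(self.channels)}")
        return self.channels[label]


def align_and_bin(
    messages_by_term: dict[str, list[Message]],
    annotation: DebateAnnotation,
    bin_width_s: float = 1.0,
) -> RateSeries:
    """Bin filtered messages into per-term count channels aligned to onset.

    A message at absolute time tau falls in bin
    ``floor((tau - onset_timestamp) / bin_width_s)``.  Messages outside
    ``[0, duration_s)`` are dropped and tallied in ``RateSeries.dropped``.
    The ``"total"`` channel counts the union of all per-term matches, once
    per distinct message.
    """
    if bin_width_s <= 0:
        raise ValidationError("bin_width_s must be > 0")
    if annotation.duration_s <= 0:
        raise ValidationError("annotation duration_s must be > 0")
    n_bins = int(math.ceil(annotation.duration_s / bin_width_s))
    t_on = annotation.onset_timestamp
    dur = annotation.duration_s

    channels: dict[str, np.ndarray] = {}
    dropped: dict[str, int] = {}
    union: dict[int, Message] = {}
    for term, msgs in messages_by_term.items():
        counts = np.zeros(n_bins, dtype=np.int64)
        n_drop = 0
        for msg in msgs:
            off = msg.timestamp - t_on
            if off < 0 or off >= dur:
                n_drop += 1
                continue
            counts[int(off // bin_width_s)] += 1
            union[id(msg)] = msg
        channels[term] = counts
        dropped[term] = n_drop

    total = np.zeros(n_bins, dtype=np.int64)
    for msg in union.values():
        total[int((msg.timestamp - t_on) // bin_width_s)] += 1
    channels["total"] = total
    return RateSeries(
        t0_s=0.0, bin_width_s=bin_width_s, channels=channels, n_bins=n_bins, dropped=dropped
    )


def mention_proportion(
    series: RateSeries, term_a: str, term_b: str, smooth_bins: int = 0
) -> np.ndarray:
    """Per-bin share of attention to ``term_a``: ``a / (a + b)``.

    Counts are optionally smoothed with a centred moving average of
    ``smooth_bins`` bins before the ratio.  Bins where ``a + b == 0`` are NaN.
    """
    a = series.channel(term_a).astype(float)
    b = series.channel(term_b).astype(float)
    if smooth_bins and smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        a = np.convolve(a, kern, mode="same")
        b = np.convolve(b, kern, mode="same")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, a / denom, np.nan)
    return prop


def event_locked_window(
    series: RateSeries,
    onset_s: float,
    pre_s: float,
    post_s: float,
    max_scale: bool = False,
) -> RateSeries:
    """Slice a window around an event onset, optionally max-scaling channels.

    Returns a re-origined series with bin 0's left edge at ``onset_s - pre_s``
    and ``t0_s = -pre_s`` (time 0 = the event onset).  With ``max_scale`` each
    channel is divided by its window maximum, so the peristimulus profiles of
    events with very different raw rates can be overlaid.
    """
    w = series.bin_width_s
    lo = int(math.floor((onset_s - series.t0_s - pre_s) / w))
    hi = int(math.ceil((onset_s - series.t0_s + post_s) / w))
    if lo < 0 or hi > series.n_bins:
        import warnings

        warnings.warn(
            f"window [{lo}, {hi}) clipped to series extent [0, {series.n_bins})",
            stacklevel=2,
        )
        lo, hi = max(lo, 0), min(hi, series.n_bins)
    if hi <= lo:
        raise ValidationError("event-locked window is empty")
    channels: dict[str, np.ndarray] = {}
    for name, vec in series.channels.items():
        win = np.asarray(vec[lo:hi])
        if max_scale:
            m = win.max()
            if m == 0:
                raise ValidationError(
                    f"cannot max-scale channel {name!r}: window maximum is 0"
                )
            win = win / float(m)
        channels[name] = win
    return RateSeries(
        t0_s=series.t0_s + lo * w - onset_s,
        bin_width_s=w,
        channels=channels,
        n_bins=hi - lo,
    )


def first_latency(
    messages: list[Message], onset_s: float, origin_timestamp: float = 0.0
) -> float:
    """Seconds from an event onset to the first matching message at or after it.

    ``messages`` should already be filtered to the event's match terms.
    ``origin_timestamp`` converts absolute message timestamps to
    annotation-relative seconds (leave 0 if they already are).  Returns NaN
    when no message follows the onset.
    """
    best = math.inf
    for msg in messages:
        lat = (msg.timestamp - origin_timestamp) - onset_s
        if 0 <= lat < best:
            best = lat
    return best if math.isfinite(best) else math.nan


def peak_latency(series: RateSeries, channel: str) -> float:
    """Bin-centre time of the first maximal bin of a channel (NaN if all zero)."""
    vec = np.asarray(series.channel(channel))
    if vec.size == 0:
        raise ValidationError(f"channel {channel!r} is empty")
    if not np.any(vec):
        return math.nan
    k = int(np.argmax(vec))  # argmax takes the first maximal bin: ties go earliest
    return series.t0_s + (k + 0.5) * series.bin_width_s


def max_scaled(series: RateSeries) -> RateSeries:
    """Whole-series max-scaling convenience (see :func:`event_locked_window`)."""
    return event_locked_window(
        series,
        onset_s=series.t0_s,
        pre_s=0.0,
        post_s=series.n_bins * series.bin_width_s,
        max_scale=True,
    )
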