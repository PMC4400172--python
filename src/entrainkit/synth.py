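"""Synthetic debates and entrained message streams with known ground truth.

The original message streams behind this kind of analysis (a ~10% random
sample of public tweets during the 2012 US presidential debates) cannot be
redistributed, so this module generates structurally matched stand-ins:

* :func:`generate_debate` builds an annotated conversational timeline —
  two principals and a moderator alternating turns over ~90 minutes, with a
  realistic share of interruptions (real debates run roughly 200 turns of
  ~25 s mean length, about half of them interruptions);
* :func:`generate_messages` draws a per-second Poisson message stream whose
  log rate carries every effect the analysis models are built to detect:
  a speaker boost while a candidate holds the floor, within-turn
  speaking-time slopes (own channel up, opponent channel down), an
  interruption boost, a rise-and-fall quadratic trend over the event, and
  burst-decay meme kernels for salient remarks — plus retweets and
  URL-bearing spam to exercise the filters.

Counts are Poisson with a log link; the analysis models are Gaussian linear
models, as in the field, so the generator deliberately produces realistic
integer data those models only approximate.  All output is deterministic
given the seed carried by the config / truth object.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, replace

import numpy as np

from entrainkit.meme import MemeParams, composite
from entrainkit.timeline import (
    DebateAnnotation,
    Message,
    SalientEvent,
    SpeechTurn,
    ValidationError,
)

__all__ = [
    "MemeKernel",
    "GenerativeTruth",
    "DebateConfig",
    "generate_debate",
    "generate_messages",
    "truth_report",
    "truth_from_report",
]

_MAX_RATE = 1e6  # messages/s guard against runaway log rates


@dataclass(frozen=True)
class MemeKernel:
    """Ground-truth burst-decay kernel injected at a salient-event onset.

    The kernel contributes ``amplitude * M(t') * N(t')`` messages/s
    (``t'`` = seconds since onset) in its own term channel, where M is the
    logistic adoption sigmoid and N the exponential novelty decay — the same
    functional family the fitting stage estimates.
    """

    onset_s: float
    lambda_: float
    m: float
    s: float
    amplitude: float
    match_term: str = "bigbird"
    label: str = "salient"

    def params(self, b: float = 0.0) -> MemeParams:
        return MemeParams(lambda_=self.lambda_, m=self.m, s=self.s, b=b)

    def rate(self, t_s: np.ndarray) -> np.ndarray:
        tp = np.asarray(t_s, dtype=float) - self.onset_s
        out = np.zeros_like(tp)
        on = tp >= 0
        out[on] = self.amplitude * np.asarray(composite(tp[on], self.params(0.0)))
        return out


@dataclass(frozen=True)
class GenerativeTruth:
    """Every generative effect, expressed like the analysis models see them.

    Parameters
    ----------
    base_log_rate : log messages/s per candidate channel while nobody special
        is happening.
    speaker_boost : multiplicative rate factor on a candidate's own channel
        while he holds the floor (> 1 means speaking draws mentions).
    speaking_time_slope_own / _cross : per-second change in log rate as the
        current turn ages, applied to the floor-holder's own channel and the
        opposing candidate's channel respectively (attention accrues to the
        speaker and drains from the opponent).
    interruption_boost : multiplicative factor on both channels while the
        floor-holding turn is an interruption.
    quad_coeffs : (linear, quadratic) coefficients on centred normalised
        time x = (t - T/2)/(T/2) in [-1, 1], applied to log rate — the
        whole-event rise and fall of attention (the default gives a
        realistic ~2.3x swing peaking about two-thirds through the event).
    meme_kernels : burst-decay kernels for salient remarks.
    retweet_fraction : share of generated messages flagged/prefixed as
        retweets (the real streams are roughly half retweets).
    url_spam_rate : messages/s of URL-bearing spam mentioning a candidate.
    """

    base_log_rate: float = math.log(2.0)
    speaker_boost: float = 1.5
    speaking_time_slope_own: float = 0.01
    speaking_time_slope_cross: float = -0.01
    interruption_boost: float = 1.5
    quad_coeffs: tuple[float, float] = (0.3, -0.5)
    meme_kernels: tuple[MemeKernel, ...] = (
        MemeKernel(onset_s=1800.0, lambda_=0.01, m=0.2, s=60.0, amplitude=5.0),
    )
    retweet_fraction: float = 0.5
    url_spam_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.retweet_fraction <= 1.0):
            raise ValidationError("retweet_fraction must be in [0, 1]")
        if self.url_spam_rate < 0:
            raise ValidationError("url_spam_rate must be >= 0")
        if self.speaker_boost <= 0 or self.interruption_boost <= 0:
            raise ValidationError("multiplicative boosts must be > 0")
        object.__setattr__(self, "meme_kernels", tuple(self.meme_kernels))
        object.__setattr__(self, "quad_coeffs", tuple(self.quad_coeffs))

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "GenerativeTruth":
        """All effects off: flat Poisson base rate (for type-I error studies)."""
        base = cls(
            speaker_boost=1.0,
            speaking_time_slope_own=0.0,
            speaking_time_slope_cross=0.0,
            interruption_boost=1.0,
            quad_coeffs=(0.0, 0.0),
            meme_kernels=(),
            seed=seed,
        )
        return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class DebateConfig:
    """Shape of the synthetic conversational timeline.

    Defaults emulate a televised 90-minute debate: ~25 s mean turns
    (log-normal spread), about half the turns interruptions, and a moderator
    interjecting in about a quarter of the slots.
    """

    duration_s: float = 5400.0
    mean_turn_s: float = 25.0
    turn_sd_log: float = 0.6
    p_interrupt: float = 0.5
    p_moderator: float = 0.25
    speakers: tuple[str, str, str] = ("obama", "romney", "moderator")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        for p in (self.p_interrupt, self.p_moderator):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must be in [0, 1]")


def generate_debate(config: DebateConfig) -> DebateAnnotation:
    """Draw an annotated debate timeline; deterministic given ``config.seed``.

    Principals alternate turns, the moderator interjects with
    ``p_moderator`` (without breaking the alternation), each turn's length is
    log-normal with mean ``mean_turn_s``, and with ``p_interrupt`` a turn
    starts up to 2 s before the previous one ends.
    """
    rng = np.random.default_rng(config.seed)
    cand_a, cand_b, moderator = config.speakers
    mu = math.log(config.mean_turn_s) - config.turn_sd_log**2 / 2
    turns: list[SpeechTurn] = []
    next_principal = cand_a
    prev_end = 0.0
    prev_start = 0.0
    while prev_end < config.duration_s - 1.0:
        if rng.random() < config.p_moderator:
            speaker = moderator
        else:
            speaker = next_principal
            next_principal = cand_b if next_principal == cand_a else cand_a
        dur = max(1.0, rng.lognormal(mu, config.turn_sd_log))
        is_interruption = bool(turns) and (rng.random() < config.p_interrupt)
        if is_interruption:
            overlap = rng.uniform(0.0, 2.0)
            start = max(prev_end - overlap, prev_start + 0.05, 0.0)
        else:
            start = prev_end
        end = min(start + dur, config.duration_s)
        if end <= start:
            break
        turns.append(
            SpeechTurn(speaker=speaker, start_s=start, end_s=end, is_interruption=is_interruption)
        )
        prev_start, prev_end = start, end
    return DebateAnnotation(
        onset_timestamp=0.0,
        duration_s=config.duration_s,
        speakers=config.speakers,
        turns=turns,
        salient_events=[],
    )


def _per_second_covariates(
    annotation: DebateAnnotation,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """(floor speaker index per second or -1, speaking time, interruption flag)."""
    n = int(math.ceil(annotation.duration_s))
    track = annotation.floor_track(1.0)
    speakers = list(annotation.speakers)
    floor = np.full(n, -1, dtype=np.int64)
    speaking_time = np.zeros(n)
    interrupting = np.zeros(n)
    starts = np.array([t.start_s for t in annotation.turns]) if annotation.turns else np.zeros(0)
    for t in range(n):
        i = track[t]
        if i < 0:
            continue
        turn = annotation.turns[i]
        floor[t] = speakers.index(turn.speaker)
        speaking_time[t] = t - starts[i]
        interrupting[t] = float(turn.is_interruption)
    return floor, speaking_time, interrupting, speakers


def _spawn_messages(
    rng: np.random.Generator,
    rates: np.ndarray,
    onset_timestamp: float,
    make_text,
    retweet_fraction: float,
) -> list[Message]:
    """Poisson-draw per-second counts and materialise Message objects."""
    if np.any(rates > _MAX_RATE):
        t_bad = int(np.argmax(rates > _MAX_RATE))
        raise ValidationError(
            f"rate overflow at second {t_bad}: {rates[t_bad]:.3g} messages/s"
        )
    counts = rng.poisson(rates)
    seconds = np.repeat(np.arange(rates.size), counts)
    offsets = rng.random(seconds.size)
    is_rt = rng.random(seconds.size) < retweet_fraction
    msgs = []
    for sec, off, rt in zip(seconds, offsets, is_rt):
        text = make_text(int(sec))
        if rt:
            text = "RT @viewer " + text
        msgs.append(
            Message(timestamp=onset_timestamp + sec + off, text=text, is_retweet=bool(rt))
        )
    return msgs


def generate_messages(
    annotation: DebateAnnotation, truth: GenerativeTruth
) -> list[Message]:
    """Draw the entrained message stream for an annotated debate.

    Per second t and candidate channel c the count is
    Poisson(exp(log-rate)) with

        log rate = base + [floor==c]*log(speaker_boost)
                 + [floor==c]*slope_own*speaking_time
                 + [floor==opponent]*slope_cross*speaking_time
                 + [interrupting turn]*log(interruption_boost)
                 + lin*x + quad*x^2            (x = centred normalised time)

    Meme kernels contribute additional messages in their own term channel at
    ``amplitude * M(t') * N(t')`` messages/s.  ``retweet_fraction`` of all
    messages is flagged (and prefixed) as retweets; URL-bearing spam
    mentioning a candidate is appended at ``url_spam_rate`` messages/s.
    The stream is sorted by timestamp and deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    n = int(math.ceil(annotation.duration_s))
    floor, speaking_time, interrupting, speakers = _per_second_covariates(annotation)
    principals = [s for s in speakers if s != "moderator"][:2]
    if len(principals) < 2:
        principals = list(speakers[:2])
    t = np.arange(n, dtype=float)
    x = (t - annotation.duration_s / 2) / (annotation.duration_s / 2)
    lin, quad = truth.quad_coeffs
    trend = lin * x + quad * x * x

    msgs: list[Message] = []
    for ci, cand in enumerate(principals):
        other = principals[1 - ci]
        own = floor == speakers.index(cand)
        cross = floor == speakers.index(other)
        log_rate = (
            truth.base_log_rate
            + own * math.log(truth.speaker_boost)
            + own * truth.speaking_time_slope_own * speaking_time
            + cross * truth.speaking_time_slope_cross * speaking_time
            + interrupting * math.log(truth.interruption_boost)
            + trend
        )
        msgs.extend(
            _spawn_messages(
                rng,
                np.exp(log_rate),
                annotation.onset_timestamp,
                lambda sec, c=cand: f"watching {c} talk right now #debate",
                truth.retweet_fraction,
            )
        )

    for kernel in truth.meme_kernels:
        msgs.extend(
            _spawn_messages(
                rng,
                kernel.rate(t),
                annotation.onset_timestamp,
                lambda sec, k=kernel: f"did he just say {k.match_term} ?!",
                truth.retweet_fraction,
            )
        )

    if truth.url_spam_rate > 0:
        spam_counts = rng.poisson(truth.url_spam_rate, size=n)
        seconds = np.repeat(np.arange(n), spam_counts)
        offsets = rng.random(seconds.size)
        picks = rng.integers(0, len(principals), size=seconds.size)
        for sec, off, pick in zip(seconds, offsets, picks):
            msgs.append(
                Message(
                    timestamp=annotation.onset_timestamp + sec + off,
                    text=f"{principals[pick]} deals!! http://spam.example/{int(sec)}",
                    is_retweet=False,
                )
            )

    msgs.sort(key=lambda m: m.timestamp)
    return msgs


def truth_report(truth: GenerativeTruth) -> dict:
    """JSON-serialisable ground-truth record, stable across runs.

    Written next to generated files so recovery tests can compare estimates
    against what the generator actually did.  Includes a content hash.
    """
    record = asdict(truth)
    record["meme_kernels"] = [asdict(k) for k in truth.meme_kernels]
    record["quad_coeffs"] = list(truth.quad_coeffs)
    payload = json.dumps(record, sort_keys=True)
    record["content_sha1"] = hashlib.sha1(payload.encode()).hexdigest()
    return record


def truth_from_report(record: dict) -> GenerativeTruth:
    """Inverse of :func:`truth_report`."""
    record = dict(record)
    record.pop("content_sha1", None)
    record["meme_kernels"] = tuple(MemeKernel(**k) for k in record.get("meme_kernels", []))
    record["quad_coeffs"] = tuple(record.get("quad_coeffs", (0.0, 0.0)))
    return GenerativeTruth(**record)


def annotation_with_kernels(
    annotation: DebateAnnotation, truth: GenerativeTruth
) -> DebateAnnotation:
    """Copy of the annotation with the truth's kernels as salient events.

    Kernels whose onset falls outside the event are omitted (they never fire).
    """
    events = [
        SalientEvent(label=k.label, onset_s=k.onset_s, match_terms=(k.match_term,))
        for k in truth.meme_kernels
        if k.onset_s <= annotation.duration_s
    ]
    return DebateAnnotation(
        onset_timestamp=annotation.onset_timestamp,
        duration_s=annotation.duration_s,
        speakers=annotation.speakers,
        turns=list(annotation.turns),
        salient_events=events,
    )
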