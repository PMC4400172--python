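"""Convenience plumbing: simulate an event and run it through the pipeline.

Thin glue used by the analysis drivers and the acceptance script; every
computation lives in the dedicated modules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from entrainkit.synth import (
    DebateConfig,
    GenerativeTruth,
    annotation_with_kernels,
    generate_debate,
    generate_messages,
)
from entrainkit.timeline import (
    DebateAnnotation,
    FilterSpec,
    Message,
    RateSeries,
    align_and_bin,
    filter_messages,
)

__all__ = ["SimulatedEvent", "simulate_event", "default_filter_spec"]


@dataclass
class SimulatedEvent:
    """A generated debate with its filtered, binned message stream."""

    annotation: DebateAnnotation
    messages: list[Message]
    series: RateSeries
    truth: GenerativeTruth
    config: DebateConfig


def default_filter_spec(
    annotation: DebateAnnotation, truth: GenerativeTruth
) -> FilterSpec:
    """Candidate terms plus any meme match terms, URLs and retweets excluded."""
    principals = [s for s in annotation.speakers if s != "moderator"][:2]
    terms = tuple(principals) + tuple(k.match_term for k in truth.meme_kernels)
    return FilterSpec(include_terms=terms, exclude_urls=True, exclude_retweets=True)


def simulate_event(
    seed: int,
    config: DebateConfig | None = None,
    truth: GenerativeTruth | None = None,
    bin_width_s: float = 1.0,
) -> SimulatedEvent:
    """Generate a debate + stream at ``seed`` and bin it at ``bin_width_s``.

    The same seed drives both the timeline and the stream (offset so the two
    generators do not share a sequence).
    """
    config = replace(config or DebateConfig(), seed=seed)
    truth = replace(truth or GenerativeTruth(), seed=seed + 10_007)
    annotation = annotation_with_kernels(generate_debate(config), truth)
    messages = generate_messages(annotation, truth)
    spec = default_filter_spec(annotation, truth)
    series = align_and_bin(filter_messages(messages, spec), annotation, bin_width_s)
    return SimulatedEvent(
        annotation=annotation, messages=messages, series=series, truth=truth, config=config
    )
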