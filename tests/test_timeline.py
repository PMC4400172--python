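"""Timeline core: filtering, alignment, binning, windows, latencies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_bin
from entrainkit.pipeline import default_filter_spec, simulate_event
from entrainkit.synth import DebateConfig
from entrainkit.timeline import (
    DebateAnnotation,
    FilterSpec,
    Message,
    RateSeries,
    SpeechTurn,
    ValidationError,
    align_and_bin,
    event_locked_window,
    filter_messages,
    first_latency,
    mention_proportion,
    peak_latency,
)


class TestFilter:
    def test_hand_enumerated_assignment(self, filter_fixture_messages):
        spec = FilterSpec(include_terms=("obama", "romney"))
        out = filter_messages(filter_fixture_messages, spec)
        assert [m.text for m in out["obama"]] == ["Obama wins", "obama & romney"]
        assert [m.text for m in out["romney"]] == ["obama & romney"]

    def test_retweets_kept_when_flag_off(self, filter_fixture_messages):
        spec = FilterSpec(include_terms=("obama", "romney"), exclude_retweets=False)
        out = filter_messages(filter_fixture_messages, spec)
        assert "RT @x Obama" in [m.text for m in out["obama"]]

    def test_urls_kept_when_flag_off(self, filter_fixture_messages):
        spec = FilterSpec(include_terms=("romney",), exclude_urls=False)
        out = filter_messages(filter_fixture_messages, spec)
        assert [m.text for m in out["romney"]] == ["Romney http://a.b", "obama & romney"]

    def test_empty_input(self):
        out = filter_messages([], FilterSpec(include_terms=("obama",)))
        assert out == {"obama": []}

    def test_hashtag_substring_match(self):
        msgs = [Message(timestamp=0.0, text="vote! #obama2012")]
        out = filter_messages(msgs, FilterSpec(include_terms=("obama",)))
        assert len(out["obama"]) == 1

    def test_retweet_detected_from_text_prefix(self):
        msgs = [Message(timestamp=0.0, text="RT @y romney tonight", is_retweet=False)]
        out = filter_messages(msgs, FilterSpec(include_terms=("romney",)))
        assert out["romney"] == []

    def test_idempotence_on_synthetic_stream(self):
        ev = simulate_event(seed=4, config=DebateConfig(duration_s=600.0))
        spec = default_filter_spec(ev.annotation, ev.truth)
        once = filter_messages(ev.messages, spec)
        for term, msgs in once.items():
            again = filter_messages(msgs, spec)
            assert again[term] == msgs

    def test_uppercase_terms_rejected(self):
        with pytest.raises(ValidationError):
            FilterSpec(include_terms=("Obama",))


class TestBinning:
    def test_hand_binning(self, toy_annotation):
        msgs = [Message(timestamp=1000.0 + off, text="a") for off in (0.2, 0.9, 1.1)]
        series = align_and_bin({"a": msgs}, toy_annotation, 1.0)
        assert list(series.channels["a"][:3]) == [2, 1, 0]

    def test_no_messages_gives_zero_channels(self, toy_annotation):
        series = align_and_bin({"a": []}, toy_annotation, bin_width_s=3.0)
        assert series.n_bins == math.ceil(20 / 3)
        assert not series.channels["a"].any()
        assert not series.channels["total"].any()

    def test_out_of_window_dropped_and_logged(self, toy_annotation):
        msgs = [
            Message(timestamp=999.0, text="a"),  # before onset
            Message(timestamp=1020.0, text="a"),  # at duration (half-open: out)
            Message(timestamp=1005.0, text="a"),
        ]
        series = align_and_bin({"a": msgs}, toy_annotation, 1.0)
        assert series.channels["a"].sum() == 1
        assert series.dropped["a"] == 2

    def test_total_counts_shared_message_once(self, toy_annotation):
        shared = Message(timestamp=1001.0, text="a b")
        series = align_and_bin({"a": [shared], "b": [shared]}, toy_annotation, 1.0)
        assert series.channels["a"].sum() == 1
        assert series.channels["b"].sum() == 1
        assert series.channels["total"].sum() == 1

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        offsets=st.lists(st.floats(-5, 40, allow_nan=False), max_size=60),
        bin_width=st.sampled_from([0.5, 1.0, 2.0, 3.0]),
    )
    def test_agrees_with_brute_force_and_conserves(self, offsets, bin_width):
        """Binning matches a per-bin brute-force loop; counts are conserved."""
        annotation = DebateAnnotation(
            onset_timestamp=1000.0,
            duration_s=20.0,
            speakers=("a", "b"),
            turns=[
                SpeechTurn(speaker="a", start_s=0.0, end_s=10.0),
                SpeechTurn(speaker="b", start_s=10.0, end_s=20.0),
            ],
        )
        msgs = [Message(timestamp=1000.0 + off, text="a") for off in offsets]
        series = align_and_bin({"a": msgs}, annotation, bin_width)
        oracle, dropped = brute_force_bin(msgs, 1000.0, 20.0, bin_width)
        assert list(series.channels["a"]) == list(oracle)
        assert series.dropped["a"] == dropped
        in_window = sum(1 for m in msgs if 1000.0 <= m.timestamp < 1020.0)
        assert series.channels["a"].sum() == in_window

    def test_pipeline_conservation_on_synthetic_stream(self):
        ev = simulate_event(seed=9, config=DebateConfig(duration_s=900.0))
        spec = default_filter_spec(ev.annotation, ev.truth)
        by_term = filter_messages(ev.messages, spec)
        for term in spec.include_terms:
            in_window = sum(
                1
                for m in by_term[term]
                if 0 <= m.timestamp - ev.annotation.onset_timestamp < ev.annotation.duration_s
            )
            assert ev.series.channels[term].sum() == in_window


class TestProportionsWindowsLatencies:
    def _series(self, **channels):
        n = len(next(iter(channels.values())))
        return RateSeries(
            t0_s=0.0,
            bin_width_s=1.0,
            channels={k: np.asarray(v) for k, v in channels.items()},
            n_bins=n,
        )

    def test_proportion_symmetry_and_empty_bin(self):
        series = self._series(a=[2, 0], b=[2, 0])
        prop = mention_proportion(series, "a", "b")
        assert prop[0] == 0.5 and np.isnan(prop[1])

    def test_proportion_all_attention_to_a(self):
        series = self._series(a=[3, 1, 2], b=[0, 0, 0])
        assert np.allclose(mention_proportion(series, "a", "b"), 1.0)

    def test_proportion_unknown_channel_errors(self):
        with pytest.raises(KeyError):
            mention_proportion(self._series(a=[1]), "a", "zzz")

    def test_proportion_matches_generative_rate_ratio(self):
        """A 3:1 generative rate ratio yields mean proportion ~ 0.75."""
        rng = np.random.default_rng(0)
        a = rng.poisson(3.0, size=4000)
        b = rng.poisson(1.0, size=4000)
        series = self._series(a=a, b=b)
        prop = mention_proportion(series, "a", "b")
        # binomial error on the pooled proportion is < 0.01 at this size
        assert abs(np.nanmean(prop) - 0.75) < 0.02

    def test_window_slicing(self):
        vec = np.arange(200)
        series = self._series(x=vec)
        win = event_locked_window(series, onset_s=100.0, pre_s=0.0, post_s=10.0)
        assert win.n_bins == 10
        assert list(win.channels["x"]) == list(range(100, 110))
        assert win.t0_s == 0.0

    def test_window_max_scale_constant_is_one(self):
        series = self._series(x=np.full(50, 7))
        win = event_locked_window(series, 0.0, 0.0, 50.0, max_scale=True)
        assert np.allclose(win.channels["x"], 1.0)

    def test_window_max_scale_preserves_argmax(self):
        rng = np.random.default_rng(1)
        series = self._series(x=rng.poisson(4.0, 120) + 1)
        raw = event_locked_window(series, 10.0, 0.0, 100.0)
        scaled = event_locked_window(series, 10.0, 0.0, 100.0, max_scale=True)
        assert np.argmax(raw.channels["x"]) == np.argmax(scaled.channels["x"])

    def test_window_max_scale_zero_errors(self):
        series = self._series(x=np.zeros(10, dtype=int))
        with pytest.raises(ValidationError):
            event_locked_window(series, 0.0, 0.0, 10.0, max_scale=True)

    def test_window_clips_with_warning(self):
        series = self._series(x=np.arange(10))
        with pytest.warns(UserWarning):
            win = event_locked_window(series, 5.0, pre_s=10.0, post_s=10.0)
        assert win.n_bins == 10

    def test_first_latency_minimum_and_missing(self):
        msgs = [Message(timestamp=104.0, text="x"), Message(timestamp=142.0, text="x")]
        assert first_latency(msgs, onset_s=100.0) == 4.0
        assert math.isnan(first_latency([], onset_s=100.0))
        # matches strictly before the onset do not count
        assert math.isnan(first_latency([Message(timestamp=99.0, text="x")], 100.0))

    def test_first_latency_matches_generator_injection(self):
        """A kernel with midpoint right at onset produces a first mention
        within a few seconds of the event onset."""
        from entrainkit.synth import GenerativeTruth, MemeKernel

        truth = GenerativeTruth(
            meme_kernels=(
                MemeKernel(onset_s=300.0, lambda_=0.005, m=2.0, s=1.0, amplitude=20.0),
            ),
            retweet_fraction=0.0,
            url_spam_rate=0.0,
        )
        ev = simulate_event(seed=6, config=DebateConfig(duration_s=1200.0), truth=truth)
        spec = default_filter_spec(ev.annotation, ev.truth)
        meme_msgs = filter_messages(ev.messages, spec)["bigbird"]
        lat = first_latency(meme_msgs, 300.0, origin_timestamp=ev.annotation.onset_timestamp)
        assert 0 <= lat <= 5.0

    def test_peak_latency_tie_and_monotone(self):
        series = self._series(x=[1, 3, 3, 1])
        assert peak_latency(series, "x") == 1.5  # first maximal bin, centre time
        series = self._series(x=[1, 2, 3, 4])
        assert peak_latency(series, "x") == 3.5
        assert math.isnan(peak_latency(self._series(x=[0, 0]), "x"))

    def test_peak_latency_recovers_kernel_peak(self):
        """After standard moving-average smoothing, the binned peak of a
        known kernel lands within +-2 bins of the kernel's own peak."""
        from entrainkit.meme import MemeParams, composite

        t = np.arange(600, dtype=float)
        params = MemeParams(lambda_=0.05, m=1.0, s=10.0, b=0.0)
        curve = np.asarray(composite(t, params))
        kern = np.ones(11) / 11
        true_peak = np.argmax(np.convolve(curve, kern, "same")) + 0.5
        rng = np.random.default_rng(3)
        noisy = np.convolve(rng.poisson(curve * 400).astype(float), kern, "same")
        series = self._series(x=noisy)
        assert abs(peak_latency(series, "x") - true_peak) <= 2.0


class TestAnnotationInvariants:
    def test_reversed_turn_rejected(self):
        with pytest.raises(ValidationError):
            SpeechTurn(speaker="a", start_s=5.0, end_s=3.0)

    def test_undeclared_speaker_rejected(self):
        with pytest.raises(ValidationError):
            DebateAnnotation(
                onset_timestamp=0.0,
                duration_s=10.0,
                speakers=("a",),
                turns=[SpeechTurn(speaker="zzz", start_s=0.0, end_s=5.0)],
            )

    def test_turns_sorted_on_construction(self):
        ann = DebateAnnotation(
            onset_timestamp=0.0,
            duration_s=30.0,
            speakers=("a", "b"),
            turns=[
                SpeechTurn(speaker="b", start_s=10.0, end_s=20.0),
                SpeechTurn(speaker="a", start_s=0.0, end_s=10.0),
            ],
        )
        assert [t.speaker for t in ann.turns] == ["a", "b"]

    def test_overlap_floor_goes_to_last_starter(self):
        """During an interruption overlap, the interrupter holds the floor."""
        ann = DebateAnnotation(
            onset_timestamp=0.0,
            duration_s=30.0,
            speakers=("a", "b"),
            turns=[
                SpeechTurn(speaker="a", start_s=0.0, end_s=12.0),
                SpeechTurn(speaker="b", start_s=10.0, end_s=20.0, is_interruption=True),
            ],
        )
        assert ann.turns[ann.floor_holder_index(9.0)].speaker == "a"
        assert ann.turns[ann.floor_holder_index(10.0)].speaker == "b"
        assert ann.turns[ann.floor_holder_index(11.5)].speaker == "b"
        track = ann.floor_track(1.0)
        assert list(track[8:13]) == [0, 0, 1, 1, 1]
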