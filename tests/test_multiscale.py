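"""Combined multiscale regression: design, decomposition, transfer."""

import numpy as np
import pandas as pd
import pytest

from entrainkit.meme import MemeParams
from entrainkit.multiscale import (
    MultiScaleDesign,
    build_full_design,
    fit_multiscale,
    transfer_predict,
    unique_variance,
)
from entrainkit.pipeline import simulate_event
from entrainkit.synth import GenerativeTruth
from entrainkit.timeline import ValidationError


@pytest.fixture(scope="module")
def event_design(default_event):
    fits = [
        (k.onset_s, k.params(b=0.0)) for k in default_event.truth.meme_kernels
    ]
    return build_full_design(default_event.annotation, default_event.series, fits)


def _toy_design(seed=0, n=200, blocks=4, correlated=False):
    """Random 4-block design with one column per block plus interactions."""
    rng = np.random.default_rng(seed)
    names = [f"b{i}" for i in range(blocks)]
    cols = {nm: rng.normal(size=n) for nm in names}
    membership = {nm: frozenset({nm}) for nm in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            cols[f"{a}:{b}"] = cols[a] * cols[b]
            membership[f"{a}:{b}"] = frozenset({a, b})
    beta = rng.normal(size=len(cols))
    X = np.column_stack(list(cols.values()))
    y = X @ beta + rng.normal(0, 1.0 if correlated else 2.0, n)
    return MultiScaleDesign(
        frame=pd.DataFrame(cols), y=y, column_blocks=membership
    )


def _r2_oracle(X, y):
    """Independent R^2: residual sum of squares via lstsq on centred data."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return 1 - (resid @ resid) / (yc @ yc)


class TestBuildFullDesign:
    def test_row_count_equals_event_seconds(self, default_event, event_design):
        assert len(event_design.frame) == default_event.series.n_bins

    def test_no_salient_block_in_transfer_mode(self, default_event):
        design = build_full_design(default_event.annotation, default_event.series, None)
        assert "salient" not in design.frame.columns
        assert "salient" not in design.blocks

    def test_interaction_columns_are_products(self, event_design):
        frame = event_design.frame
        for col in frame.columns:
            if ":" not in col:
                continue
            a, b = col.split(":")
            assert np.allclose(frame[col], frame[a] * frame[b])

    def test_interactions_span_blocks_only(self, event_design):
        assert "t_lin:t_quad" not in event_design.frame.columns
        assert event_design.column_blocks["t_lin:interruption"] == frozenset(
            {"quadratic", "interruption"}
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            MultiScaleDesign(
                frame=pd.DataFrame({"a": [1.0, 2.0]}),
                y=np.zeros(3),
                column_blocks={"a": frozenset({"a"})},
            )


class TestFitMultiscale:
    def test_full_model_beats_quadratic_alone(self, default_event, event_design):
        """With every generative effect on, the combined model explains more
        variance than the quadratic block alone."""
        full = fit_multiscale(event_design, compute_unique=False)
        quad_cols = [
            c
            for c in event_design.frame.columns
            if event_design.column_blocks[c] == frozenset({"quadratic"})
        ]
        sub = MultiScaleDesign(
            frame=event_design.frame[quad_cols],
            y=event_design.y,
            column_blocks={c: event_design.column_blocks[c] for c in quad_cols},
        )
        quad_only = fit_multiscale(sub, compute_unique=False)
        assert full.r2 > quad_only.r2 + 0.05

    def test_nesting_monotonicity(self, event_design):
        """R^2 of the full model >= R^2 of any leave-one-block-out model."""
        full = fit_multiscale(event_design, compute_unique=False)
        for block in event_design.blocks:
            cols = event_design.columns_without(block)
            sub = MultiScaleDesign(
                frame=event_design.frame[cols],
                y=event_design.y,
                column_blocks={c: event_design.column_blocks[c] for c in cols},
            )
            assert full.r2 >= fit_multiscale(sub, compute_unique=False).r2 - 1e-10

    def test_pure_noise_r2_near_chance(self):
        """Under a pure-noise response, R^2 concentrates near k/(n-1)."""
        rng = np.random.default_rng(99)
        design = _toy_design(seed=8)
        k = design.frame.shape[1]
        n = len(design.y)
        r2s = []
        for _ in range(20):
            noise = MultiScaleDesign(
                frame=design.frame,
                y=rng.normal(size=n),
                column_blocks=design.column_blocks,
            )
            r2s.append(fit_multiscale(noise, compute_unique=False).r2)
        assert abs(np.mean(r2s) - k / (n - 1)) < 0.03

    def test_duplicated_column_leaves_fit_unchanged(self, event_design):
        frame = event_design.frame.copy()
        frame["dup"] = frame["t_lin"]
        membership = dict(event_design.column_blocks)
        membership["dup"] = frozenset({"quadratic"})
        dup_design = MultiScaleDesign(
            frame=frame, y=event_design.y, column_blocks=membership
        )
        base = fit_multiscale(event_design, compute_unique=False)
        dup = fit_multiscale(dup_design, compute_unique=False)
        assert "dup" in dup.dropped_columns
        assert dup.r2 == pytest.approx(base.r2, abs=1e-10)

    def test_coefficients_carry_pvalues(self, event_design):
        res = fit_multiscale(event_design, compute_unique=False)
        for _, _, p in res.coefficients:
            assert 0.0 <= p <= 1.0


class TestUniqueVariance:
    def test_matches_exhaustive_leave_one_block_out_oracle(self):
        """Delta-R^2 equals the brute-force full-vs-reduced computation."""
        design = _toy_design(seed=1)
        X_full = design.frame.to_numpy()
        full = _r2_oracle(X_full, design.y)
        for block in sorted(design.blocks):
            keep = [
                i
                for i, c in enumerate(design.frame.columns)
                if block not in design.column_blocks[c]
            ]
            oracle = full - _r2_oracle(X_full[:, keep], design.y)
            assert unique_variance(design, block) == pytest.approx(oracle, abs=1e-8)

    def test_orthogonal_block_unique_equals_marginal(self):
        """For an exactly orthogonalised column, Delta-R^2 = marginal R^2."""
        rng = np.random.default_rng(3)
        n = 500
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        # orthogonalise b against a (and both against the intercept)
        a = a - a.mean()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        y = a + 2 * b + rng.normal(0, 1, n)
        design = MultiScaleDesign(
            frame=pd.DataFrame({"a": a, "b": b}),
            y=y,
            column_blocks={"a": frozenset({"a"}), "b": frozenset({"b"})},
        )
        marginal = _r2_oracle(b.reshape(-1, 1), y)
        assert unique_variance(design, "b") == pytest.approx(marginal, abs=1e-10)

    def test_duplicated_block_has_no_unique_variance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = x + rng.normal(0, 1, 300)
        design = MultiScaleDesign(
            frame=pd.DataFrame({"a": x, "b": x.copy()}),
            y=y,
            column_blocks={"a": frozenset({"a"}), "b": frozenset({"b"})},
        )
        assert unique_variance(design, "b") == pytest.approx(0.0, abs=1e-10)

    def test_unknown_block_errors(self):
        with pytest.raises(KeyError):
            unique_variance(_toy_design(), "zzz")

    def test_nonnegative_and_bounded_by_full_r2(self, event_design):
        res = fit_multiscale(event_design)
        assert set(res.unique_r2) == event_design.blocks
        for block, delta in res.unique_r2.items():
            assert 0.0 <= delta <= res.r2 + 1e-12


class TestTransfer:
    def test_self_prediction_identity(self, default_event):
        """Predicting the source event with its own model gives r = sqrt(R^2)."""
        design = build_full_design(default_event.annotation, default_event.series, None)
        res = fit_multiscale(design, compute_unique=False)
        r = transfer_predict(res, design)
        assert r == pytest.approx(np.sqrt(res.r2), abs=1e-10)

    def test_shared_truth_pair_transfers(self):
        """Two debates from the same generative truth transfer with r >= 0.3
        (single pair; the acceptance suite runs 20)."""
        src = simulate_event(seed=101)
        tgt = simulate_event(seed=202)
        src_design = build_full_design(src.annotation, src.series, None)
        res = fit_multiscale(src_design, compute_unique=False)
        tgt_design = build_full_design(tgt.annotation, tgt.series, None)
        assert transfer_predict(res, tgt_design) >= 0.3

    def test_null_truth_target_gives_near_zero_r(self):
        """A target with no generative structure cannot be predicted."""
        src = simulate_event(seed=301)
        src_design = build_full_design(src.annotation, src.series, None)
        res = fit_multiscale(src_design, compute_unique=False)
        rs = []
        for seed in range(5):
            tgt = simulate_event(seed=400 + seed, truth=GenerativeTruth.null())
            tgt_design = build_full_design(tgt.annotation, tgt.series, None)
            rs.append(transfer_predict(res, tgt_design))
        assert abs(np.mean(rs)) < 0.1

    def test_schema_mismatch_errors(self, default_event, event_design):
        res = fit_multiscale(event_design, compute_unique=False)  # includes salient
        bare = build_full_design(default_event.annotation, default_event.series, None)
        with pytest.raises(ValidationError):
            transfer_predict(res, bare)

    def test_meme_params_accepted_in_design(self, default_event):
        fits = [(1800.0, MemeParams(lambda_=0.01, m=0.2, s=60.0, b=0.0))]
        design = build_full_design(default_event.annotation, default_event.series, fits)
        assert "salient" in design.frame.columns
        assert design.frame["salient"].iloc[:1800].eq(0).all()
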