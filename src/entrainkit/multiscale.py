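"""Combined multiscale regression, unique-variance decomposition, transfer.

One OLS model per event predicts the per-second total message rate from all
three timescales at once:

* ``quadratic``       — centred time and time-squared (whole-event trend);
* ``speaker_duration``— any-candidate speaking time within the current turn
                        plus an indicator that a candidate holds the floor;
* ``interruption``    — the floor-holding turn is an interruption;
* ``salient``         — the fitted burst-decay kernel value at t, summed over
                        events (0 outside their windows);

plus all pairwise interaction terms among the blocks.  Each block's *unique*
contribution is the semipartial delta-R^2 from entering it last: R^2 of the
full model minus R^2 after removing every column involving the block.

For cross-event transfer the source model's coefficients — and its
standardization statistics, so they keep their meaning — are applied to a
second event's covariates (built without the salient block, which is
post-hoc by nature) and the Pearson correlation between predicted and
observed rates is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from entrainkit.meme import MemeParams, composite
from entrainkit.timeline import DebateAnnotation, RateSeries, ValidationError

__all__ = [
    "MultiScaleDesign",
    "MultiScaleResult",
    "build_full_design",
    "fit_multiscale",
    "unique_variance",
    "transfer_predict",
]


@dataclass
class MultiScaleDesign:
    """Per-second covariate table with block bookkeeping.

    ``frame`` holds one row per second of the event; ``column_blocks`` maps
    each column to the set of primary blocks it involves (interaction columns
    belong to both parents).  ``y`` is the per-second total count.
    """

    frame: pd.DataFrame
    y: np.ndarray
    column_blocks: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.frame) != len(self.y):
            raise ValidationError(
                f"design has {len(self.frame)} rows but response has {len(self.y)}"
            )

    @property
    def blocks(self) -> set[str]:
        out: set[str] = set()
        for blocks in self.column_blocks.values():
            out |= blocks
        return out

    def columns_without(self, block: str) -> list[str]:
        return [c for c in self.frame.columns if block not in self.column_blocks[c]]


@dataclass
class MultiScaleResult:
    """Fitted combined model: R^2, coefficients, block decomposition."""

    r2: float
    coefficients: tuple[tuple[str, float, float], ...]  # (name, beta, p)
    intercept: float
    scaler: dict[str, tuple[float, float]]  # column -> (mean, sd) used to z-score
    columns: tuple[str, ...]
    dropped_columns: tuple[str, ...] = ()
    unique_r2: dict[str, float] = field(default_factory=dict)
    transfer_r: float | None = None

    def coef(self, name: str) -> tuple[float, float]:
        for nm, beta, p in self.coefficients:
            if nm == name:
                return beta, p
        raise KeyError(f"no coefficient {name!r}")

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "coefficients": [
                {"name": nm, "beta": b, "p": p} for nm, b, p in self.coefficients
            ],
            "intercept": self.intercept,
            "columns": list(self.columns),
            "dropped_columns": list(self.dropped_columns),
            "unique_r2": dict(self.unique_r2),
            "transfer_r": self.transfer_r,
            "scaler": {k: list(v) for k, v in self.scaler.items()},
        }


def build_full_design(
    annotation: DebateAnnotation,
    rates: RateSeries,
    meme_fits: list[tuple[float, MemeParams]] | None = None,
) -> MultiScaleDesign:
    """Assemble the per-second multiscale covariate table.

    ``meme_fits`` is a list of ``(onset_s, MemeParams)`` pairs (typically one
    fitted kernel per salient event); omit it to build a transfer-mode design
    with no salient block.  Interaction columns (named ``a:b``) are the
    elementwise products of every cross-block pair of main columns.
    """
    n = rates.n_bins
    t = np.arange(n, dtype=float) * rates.bin_width_s
    track = annotation.floor_track(rates.bin_width_s)[:n]
    principals = [s for s in annotation.speakers if s != "moderator"][:2]

    speaking_time = np.zeros(n)
    candidate_speaking = np.zeros(n)
    interruption = np.zeros(n)
    for k in range(n):
        i = track[k]
        if i < 0:
            continue
        turn = annotation.turns[i]
        if turn.speaker in principals:
            candidate_speaking[k] = 1.0
            speaking_time[k] = t[k] - turn.start_s
        interruption[k] = float(turn.is_interruption)

    tc = t - t.mean()
    cols: dict[str, np.ndarray] = {
        "t_lin": tc,
        "t_quad": tc * tc,
        "speaking_time": speaking_time,
        "candidate_speaking": candidate_speaking,
        "interruption": interruption,
    }
    membership: dict[str, frozenset[str]] = {
        "t_lin": frozenset({"quadratic"}),
        "t_quad": frozenset({"quadratic"}),
        "speaking_time": frozenset({"speaker_duration"}),
        "candidate_speaking": frozenset({"speaker_duration"}),
        "interruption": frozenset({"interruption"}),
    }
    if meme_fits is not None:
        salient = np.zeros(n)
        for onset_s, params in meme_fits:
            tp = t - onset_s
            on = tp >= 0
            salient[on] += np.asarray(composite(tp[on], params))
        cols["salient"] = salient
        membership["salient"] = frozenset({"salient"})

    mains = list(cols.items())
    for i, (name_a, col_a) in enumerate(mains):
        for name_b, col_b in mains[i + 1 :]:
            if membership[name_a] == membership[name_b]:
                continue  # within-block products (t_lin*t_quad etc.) are not interactions
            inter = f"{name_a}:{name_b}"
            cols[inter] = col_a * col_b
            membership[inter] = membership[name_a] | membership[name_b]

    frame = pd.DataFrame(cols)
    y = np.asarray(rates.channel("total"), dtype=float)
    return MultiScaleDesign(frame=frame, y=y, column_blocks=membership)


def _standardize(
    X: pd.DataFrame, scaler: dict[str, tuple[float, float]] | None = None
) -> tuple[np.ndarray, dict[str, tuple[float, float]], list[str]]:
    """Z-score columns; zero-variance columns are dropped (when fitting) or
    zeroed (when applying a foreign scaler)."""
    if scaler is None:
        scaler = {}
        keep = []
        arrs = []
        for c in X.columns:
            v = X[c].to_numpy(dtype=float)
            mu, sd = float(v.mean()), float(v.std(ddof=0))
            if sd == 0:
                continue
            scaler[c] = (mu, sd)
            keep.append(c)
            arrs.append((v - mu) / sd)
        return np.column_stack(arrs) if arrs else np.empty((len(X), 0)), scaler, keep
    arrs = []
    for c, (mu, sd) in scaler.items():
        v = X[c].to_numpy(dtype=float)
        arrs.append((v - mu) / sd if sd > 0 else np.zeros(len(X)))
    return np.column_stack(arrs), scaler, list(scaler)


def _independent_columns(X: np.ndarray, names: list[str]) -> list[int]:
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    if X.shape[1] == 0:
        return []
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return sorted(piv[:rank])


def _ols_r2(X: np.ndarray, y: np.ndarray) -> float:
    """R^2 of least squares with intercept; rank-deficiency safe (min-norm)."""
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0:
        raise ValidationError("response is constant; R^2 undefined")
    if X.shape[1] == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return 1.0 - float(resid @ resid) / sst


def fit_multiscale(
    design: MultiScaleDesign, compute_unique: bool = True
) -> MultiScaleResult:
    """OLS fit of the combined design; optionally fills ``unique_r2``.

    Covariates are z-scored (statistics retained for transfer); zero-variance
    and linearly dependent columns are dropped and logged in
    ``dropped_columns``.
    """
    X, scaler, kept = _standardize(design.frame)
    dropped = [c for c in design.frame.columns if c not in kept]
    idx = _independent_columns(X, kept)
    if len(idx) < len(kept):
        dropped += [kept[i] for i in range(len(kept)) if i not in idx]
        kept = [kept[i] for i in idx]
        X = X[:, idx]
        scaler = {c: scaler[c] for c in kept}
    if X.shape[1] == 0:
        raise ValidationError("design is rank-deficient beyond repair: no usable columns")

    fit = sm.OLS(design.y, sm.add_constant(X)).fit()
    coefs = tuple(
        (name, float(fit.params[i + 1]), float(fit.pvalues[i + 1]))
        for i, name in enumerate(kept)
    )
    result = MultiScaleResult(
        r2=float(fit.rsquared),
        coefficients=coefs,
        intercept=float(fit.params[0]),
        scaler=scaler,
        columns=tuple(kept),
        dropped_columns=tuple(dropped),
    )
    if compute_unique:
        for block in sorted(design.blocks):
            result.unique_r2[block] = unique_variance(design, block, full_r2=result.r2)
    return result


def unique_variance(
    design: MultiScaleDesign, block: str, full_r2: float | None = None
) -> float:
    """Semipartial delta-R^2 of a block: R^2(full) − R^2(without the block).

    "Without the block" removes every column involving it, interactions
    included.  Nonnegative up to numerical tolerance.
    """
    if block not in design.blocks:
        raise KeyError(f"unknown block {block!r}; have {sorted(design.blocks)}")
    if full_r2 is None:
        X_full, _, _ = _standardize(design.frame)
        full_r2 = _ols_r2(X_full, design.y)
    reduced_cols = design.columns_without(block)
    X_red, _, _ = _standardize(design.frame[reduced_cols])
    delta = full_r2 - _ols_r2(X_red, design.y)
    if delta < -1e-8:
        raise ValidationError(f"unique variance for {block!r} is negative: {delta}")
    return max(delta, 0.0)


def transfer_predict(
    source: MultiScaleResult, target_design: MultiScaleDesign
) -> float:
    """Apply a fitted model to another event; Pearson r of predicted vs observed.

    The target design must carry every column the source model uses (build it
    without the salient block, matching how the source was fitted for
    transfer).  Source standardization statistics are reused so the
    coefficients keep their meaning across events.
    """
    missing = [c for c in source.columns if c not in target_design.frame.columns]
    if missing:
        raise ValidationError(
            f"target design lacks columns required by the source model: {missing}"
        )
    X, _, cols = _standardize(target_design.frame[list(source.columns)], scaler=source.scaler)
    beta = np.array([dict((n, b) for n, b, _ in source.coefficients)[c] for c in cols])
    pred = source.intercept + X @ beta
    if np.std(pred) == 0 or np.std(target_design.y) == 0:
        raise ValidationError("constant prediction or response; correlation undefined")
    r, _ = stats.pearsonr(pred, target_design.y)
    return float(r)
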