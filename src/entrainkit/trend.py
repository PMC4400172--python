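"""Long-term attentional trend: quadratic rise-and-fall over the whole event.

Attention to a broadcast event builds from its onset and trails off toward
its end.  This is captured by an ordinary least-squares regression of the
per-second total rate on a second-order polynomial in time: a linear term
(overall drift) and a quadratic term (the inverted-U).  Time is centred
before squaring, and both predictors and the response are z-scored, so the
reported betas are standardized and the t/t^2 collinearity is tamed.

A dedicated *second-half decay test* checks that the downturn is not an
artefact of the opening build-up: restricted to the second half of the
event, the (centred) quadratic term alone — which over that range is purely
a decay — must still carry a significant negative-trend contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from entrainkit.timeline import RateSeries, ValidationError

__all__ = ["TrendResult", "fit_quadratic", "second_half_decay_test"]


@dataclass(frozen=True)
class TrendResult:
    """Standardized quadratic-trend fit plus the second-half decay test."""

    beta_linear: float
    beta_quadratic: float
    t_linear: float
    t_quadratic: float
    r2: float
    second_half: tuple[float, float, float] | None = None  # (beta, t, p)

    def to_dict(self) -> dict:
        return {
            "beta_linear": self.beta_linear,
            "beta_quadratic": self.beta_quadratic,
            "t_linear": self.t_linear,
            "t_quadratic": self.t_quadratic,
            "r2": self.r2,
            "second_half": (
                None
                if self.second_half is None
                else dict(zip(("beta", "t", "p"), self.second_half))
            ),
        }


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValidationError(f"{what} is constant; trend model is degenerate")
    return (x - x.mean()) / sd


def fit_quadratic(series: RateSeries, channel: str = "total") -> TrendResult:
    """OLS of per-bin count on standardized centred time and time-squared.

    Requires at least 3 bins.  Also runs :func:`second_half_decay_test` when
    the series is long enough (>= 4 bins) and attaches it to the result.
    """
    y = np.asarray(series.channel(channel), dtype=float)
    if y.size < 3:
        raise ValidationError(f"need >= 3 bins for a quadratic trend, got {y.size}")
    t = series.t0_s + np.arange(y.size) * series.bin_width_s
    tc = t - t.mean()
    X = sm.add_constant(
        np.column_stack([_zscore(tc, "time"), _zscore(tc * tc, "time^2")])
    )
    fit = sm.OLS(_zscore(y, "response"), X).fit()
    second = None
    if y.size >= 4:
        second = second_half_decay_test(series, channel)
    return TrendResult(
        beta_linear=float(fit.params[1]),
        beta_quadratic=float(fit.params[2]),
        t_linear=float(fit.tvalues[1]),
        t_quadratic=float(fit.tvalues[2]),
        r2=float(fit.rsquared),
        second_half=second,
    )


def second_half_decay_test(
    series: RateSeries, channel: str = "total"
) -> tuple[float, float, float]:
    """Does the quadratic term alone predict the second half's decline?

    The quadratic predictor is (t - t_mid)^2 with t_mid the midpoint of the
    *full* series, restricted to bins in the second half, z-scored, with an
    intercept.  Over that range the term is monotone, so a negative
    standardized beta is a pure decay.  Returns ``(beta, t, p)``.
    """
    y = np.asarray(series.channel(channel), dtype=float)
    if y.size < 4:
        raise ValidationError(f"need >= 4 bins for the second-half test, got {y.size}")
    t = series.t0_s + np.arange(y.size) * series.bin_width_s
    tc = t - t.mean()
    half = t >= series.t0_s + y.size * series.bin_width_s / 2
    quad = tc[half] ** 2
    X = sm.add_constant(_zscore(quad, "second-half time^2"))
    fit = sm.OLS(_zscore(y[half], "second-half response"), X).fit()
    return (float(fit.params[1]), float(fit.tvalues[1]), float(fit.pvalues[1]))
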