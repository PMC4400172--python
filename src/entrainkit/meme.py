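"""Burst-decay kinetics of salient remarks ("memes").

A pointed remark triggers a burst of mentions that decays as its novelty
fades, N(t) = exp(-lambda*t); if the burst is prominent enough, continued
mentions sustain it as a meme, modelled by a logistic adoption curve
M(t) = 1 / (1 + exp(-m*(t - s))).  The composite kernel is their product,

    f(t) = M(t) * (N(t) - b),

where b is the base mention rate estimated from the tail of the window.
The kernel is fitted to an event-locked rate series by exhaustive grid search
over (lambda, m, s), maximising the Pearson correlation between the kernel
and the observed counts — so the fit is invariant to any positive affine
rescaling of the observations, and max-scaled series give the same answer as
raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from entrainkit.timeline import RateSeries, ValidationError

__all__ = [
    "MemeParams",
    "MemeGrid",
    "MemeFit",
    "novelty",
    "meme_sigmoid",
    "composite",
    "estimate_base_rate",
    "fit_meme",
]


@dataclass(frozen=True)
class MemeParams:
    """Kernel parameters.

    lambda_ : decay rate of novelty (1/s, >= 0)
    m       : slope of the adoption sigmoid (1/s, >= 0)
    s       : sigmoid midpoint — the time of fastest adoption (s)
    b       : base mention rate, in the units of the fitted series
    """

    lambda_: float
    m: float
    s: float
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValidationError(f"decay rate lambda_ must be >= 0, got {self.lambda_}")
        if self.m < 0:
            raise ValidationError(f"sigmoid slope m must be >= 0, got {self.m}")


def novelty(t: np.ndarray | float, lambda_: float) -> np.ndarray | float:
    """Novelty decay N(t) = exp(-lambda * t)."""
    if lambda_ < 0:
        raise ValidationError(f"decay rate lambda_ must be >= 0, got {lambda_}")
    return np.exp(-lambda_ * np.asarray(t, dtype=float))


def meme_sigmoid(t: np.ndarray | float, m: float, s: float) -> np.ndarray | float:
    """Adoption sigmoid M(t) = 1 / (1 + exp(-m (t - s))), overflow-safe."""
    return special.expit(m * (np.asarray(t, dtype=float) - s))


def composite(t: np.ndarray | float, params: MemeParams) -> np.ndarray | float:
    """The meme kernel M(t) * (N(t) - b)."""
    return meme_sigmoid(t, params.m, params.s) * (novelty(t, params.lambda_) - params.b)


def estimate_base_rate(series: RateSeries, channel: str, tail_s: float = 100.0) -> float:
    """Mean rate over the final ``tail_s`` seconds of the series.

    After the initial burst has decayed the rate settles onto a sustained
    plateau; its mean anchors the kernel's ``b``.
    """
    n_tail = int(round(tail_s / series.bin_width_s))
    vec = np.asarray(series.channel(channel), dtype=float)
    if n_tail <= 0 or n_tail > vec.size:
        raise ValidationError(
            f"tail of {tail_s} s needs {n_tail} bins but series has {vec.size}"
        )
    return float(vec[-n_tail:].mean())


@dataclass(frozen=True)
class MemeGrid:
    """Search ranges for the grid fit.

    Defaults cover decay half-lives from ~7 s to ~2 h (lambda log-spaced in
    [1e-4, 0.1] 1/s), adoption slopes from gentle to near-step (m log-spaced
    in [0.01, 1] 1/s) and midpoints across the first five minutes
    (s linear in [0, 300] s).
    """

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, -1, 25)
    )
    m_grid: np.ndarray = field(default_factory=lambda: np.logspace(-2, 0, 25))
    s_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 300.0, 61))

    @property
    def n_points(self) -> int:
        return len(self.lambda_grid) * len(self.m_grid) * len(self.s_grid)


@dataclass(frozen=True)
class MemeFit:
    """Result of a kernel fit: parameters, achieved Pearson r and R^2 = r^2."""

    params: MemeParams
    r: float
    r2: float
    grid: MemeGrid
    n_evaluations: int
    refined: bool = False


def _grid_correlations(
    t: np.ndarray, y_centered: np.ndarray, y_norm: float, grid: MemeGrid, b: float
) -> tuple[float, tuple[float, float, float], int]:
    """Best Pearson r over the grid; ties go to smallest lambda, then s, then m."""
    best_r = -np.inf
    best = (grid.lambda_grid[0], grid.m_grid[0], grid.s_grid[0])
    n_eval = 0
    # M depends on (m, s) only; N on lambda only — precompute M once per (s, m)
    M = special.expit(
        grid.m_grid[None, :, None] * (t[None, None, :] - grid.s_grid[:, None, None])
    )  # (s, m, t)
    for lam in grid.lambda_grid:  # ascending: first strict improvement wins ties
        g = M * (np.exp(-lam * t) - b)[None, None, :]  # (s, m, t)
        gc = g - g.mean(axis=2, keepdims=True)
        num = gc @ y_centered
        den = np.sqrt((gc * gc).sum(axis=2)) * y_norm
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / den, -np.inf)
        n_eval += r.size
        k = int(np.argmax(r))  # C-order: smallest s, then smallest m, wins ties
        if r.flat[k] > best_r:
            i_s, i_m = divmod(k, len(grid.m_grid))
            best_r = float(r.flat[k])
            best = (float(lam), float(grid.m_grid[i_m]), float(grid.s_grid[i_s]))
    return best_r, best, n_eval


def fit_meme(
    series: RateSeries,
    channel: str,
    grid: MemeGrid | None = None,
    b: float | None = None,
    tail_s: float = 100.0,
    window_s: float | None = 600.0,
    refine: bool = True,
) -> MemeFit:
    """Fit the meme kernel to an event-locked rate channel.

    Exhaustively evaluates the Pearson correlation between ``composite(t)``
    and the observed counts over the parameter grid and returns the argmax
    (ties broken toward the smallest lambda, then the smallest s).  With
    ``refine`` (default) the grid optimum is polished by a bounded
    Nelder-Mead pass on the same objective, freeing the parameters from the
    grid resolution.

    ``b`` defaults to the tail mean of the fitted window
    (:func:`estimate_base_rate`).  ``window_s`` limits the fit to the first
    so-many seconds after the series origin (memes fade over roughly ten
    minutes); pass None to use the whole series.
    """
    grid = grid or MemeGrid()
    vec = np.asarray(series.channel(channel), dtype=float)
    t = series.t0_s + np.arange(series.n_bins) * series.bin_width_s
    keep = t >= 0 if window_s is None else (t >= 0) & (t < window_s)
    vec, t = vec[keep], t[keep]
    if vec.size < 3 or np.ptp(vec) == 0:
        raise ValidationError(
            "need >= 3 bins with at least 2 distinct values to fit (correlation undefined)"
        )
    sub = RateSeries(
        t0_s=float(t[0]),
        bin_width_s=series.bin_width_s,
        channels={channel: vec},
        n_bins=vec.size,
    )
    if b is None:
        b = estimate_base_rate(sub, channel, tail_s=min(tail_s, vec.size * sub.bin_width_s))

    yc = vec - vec.mean()
    y_norm = float(np.sqrt((yc * yc).sum()))
    best_r, (lam, m, s), n_eval = _grid_correlations(t, yc, y_norm, grid, b)

    refined = False
    if refine:

        def neg_r(theta: np.ndarray) -> float:
            lam_, m_, s_ = theta
            if lam_ < 0 or m_ < 0:
                return np.inf
            g = special.expit(m_ * (t - s_)) * (np.exp(-lam_ * t) - b)
            gc = g - g.mean()
            den = np.sqrt((gc * gc).sum()) * y_norm
            if den == 0:
                return np.inf
            return -float((gc @ yc) / den)

        res = optimize.minimize(
            neg_r, x0=[lam, m, s], method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12}
        )
        n_eval += int(res.nfev)
        if res.success and -res.fun >= best_r:
            lam, m, s = (float(res.x[0]), float(res.x[1]), float(res.x[2]))
            best_r = float(-res.fun)
            refined = True

    params = MemeParams(lambda_=lam, m=m, s=s, b=float(b))
    return MemeFit(
        params=params, r=best_r, r2=best_r**2, grid=grid, n_evaluations=n_eval, refined=refined
    )
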