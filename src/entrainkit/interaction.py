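"""Turn-taking entrainment: mixed-effects models of per-second mention rate.

The fastest timescale of collective entrainment: when a candidate takes the
floor, per-second mentions of that candidate rise within seconds.  Two linear
mixed-effects models capture this, both at 1-second resolution with the turn
as the grouping unit:

* the *speaker model* regresses a candidate's mention count on who holds the
  floor (``speaker``), how long the current turn has lasted
  (``speaking_time``) and their interaction;
* the *interruption model* regresses the overall mention count on whether the
  floor-holding turn is an interruption, speaking time and their interaction.

Both carry a random intercept per turn plus uncorrelated random slopes
(variance components) for the dichotomous factor and for speaking time,
estimated by REML.  Continuous variables (speaking time and the response) are
z-scored before fitting so the reported betas are standardized.  Goodness of
fit is summarised by the marginal R^2 (variance explained by fixed effects
alone) and conditional R^2 (fixed plus random), following the
Nakagawa-Schielzeth variance decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from entrainkit.timeline import DebateAnnotation, RateSeries, ValidationError

__all__ = [
    "DegenerateDesignError",
    "ConvergenceError",
    "MixedModelResult",
    "build_turn_design",
    "fit_speaker_model",
    "fit_interruption_model",
    "r2_mixed",
]


class DegenerateDesignError(ValueError):
    """A predictor has no variance, so its effect is not estimable."""


class ConvergenceError(RuntimeError):
    """The mixed model could not be fitted even after simplification."""


@dataclass(frozen=True)
class MixedModelResult:
    """Fitted mixed model summary.

    ``coefficients`` is a list of ``(name, beta_standardized, t, p)``.
    ``random_structure`` records whether the full random-slope structure was
    kept or the fit fell back to a random intercept only.
    """

    coefficients: tuple[tuple[str, float, float, float], ...]
    r2_marginal: float
    r2_conditional: float
    converged: bool
    n_obs: int
    random_structure: str = "intercept+slopes"

    def coef(self, name: str) -> tuple[float, float, float]:
        for nm, beta, t, p in self.coefficients:
            if nm == name:
                return beta, t, p
        raise KeyError(f"no coefficient {name!r}; have {[c[0] for c in self.coefficients]}")

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {"name": nm, "beta": b, "t": t, "p": p} for nm, b, t, p in self.coefficients
            ],
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "random_structure": self.random_structure,
        }


def build_turn_design(
    annotation: DebateAnnotation,
    rates: RateSeries,
    target: str,
    target_speaker: str | None = None,
) -> pd.DataFrame:
    """One row per second inside any speech turn, with turn-level covariates.

    Columns: ``t_s``, ``turn_id``, ``speaker_is_target`` (1 iff the
    floor-holder — last starter wins under overlap — is the target
    candidate; moderator seconds are 0), ``speaking_time_s`` (seconds since
    the floor-holding turn began), ``is_interruption``, ``count_target``
    (the target's channel) and ``count_total``.

    ``target`` names the rate channel; ``target_speaker`` the matching
    speaker label (defaults to ``target``).
    """
    if not annotation.turns:
        raise ValidationError("annotation has no turns; cannot build a turn design")
    target_speaker = target_speaker if target_speaker is not None else target
    counts_target = np.asarray(rates.channel(target))
    counts_total = np.asarray(rates.channel("total"))
    track = annotation.floor_track(rates.bin_width_s)
    n = min(track.size, rates.n_bins)
    rows = []
    for t in range(n):
        i = track[t]
        if i < 0:
            continue  # seconds outside any turn are excluded
        turn = annotation.turns[i]
        t_s = t * rates.bin_width_s
        rows.append(
            (
                t_s,
                int(i),
                int(turn.speaker == target_speaker),
                t_s - turn.start_s,
                int(turn.is_interruption),
                int(counts_target[t]),
                int(counts_total[t]),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "t_s",
            "turn_id",
            "speaker_is_target",
            "speaking_time_s",
            "is_interruption",
            "count_target",
            "count_total",
        ],
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise DegenerateDesignError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def r2_mixed(fitted) -> tuple[float, float]:
    """Nakagawa-Schielzeth marginal and conditional R^2 of a MixedLM fit.

    R^2_m = var(fixed) / (var(fixed) + var(random) + var(residual));
    R^2_c adds var(random) to the numerator.  var(fixed) is the population
    variance of the fixed-effect linear predictor; var(random) averages the
    per-observation random-effect variance diag(Z Sigma Z') (for variance
    components: sum_k sigma^2_k * mean(z_k^2)), which reduces to the
    intercept variance when only a random intercept is present.
    """
    model = fitted.model
    fe = np.asarray(fitted.fe_params)
    var_fixed = float(np.var(model.exog @ fe))

    var_random = 0.0
    if fitted.k_re > 0:
        cov_re = np.asarray(fitted.cov_re)
        exog_re = np.asarray(model.exog_re)
        var_random += float(np.mean(np.einsum("ij,jk,ik->i", exog_re, cov_re, exog_re)))
    if getattr(fitted, "vcomp", None) is not None and len(fitted.vcomp):
        vc = model.exog_vc
        for k, sigma2 in enumerate(np.asarray(fitted.vcomp)):
            z2 = np.concatenate(
                [np.asarray(mat).ravel() ** 2 for mat in vc.mats[k]]
            )
            # mean over *all* observations: groups lacking the column contribute 0
            var_random += float(sigma2) * float(z2.sum() / model.exog.shape[0])
    var_resid = float(fitted.scale)
    if var_random < -1e-10 or var_resid < 0:
        raise ValidationError("negative variance estimate in R^2 decomposition")
    total = var_fixed + var_random + var_resid
    return var_fixed / total, (var_fixed + var_random) / total


def _fit_mixed(
    df: pd.DataFrame,
    fixed_formula: str,
    factor: str,
) -> tuple[object, bool, str]:
    """REML fit with random intercept + uncorrelated slopes; graceful fallback."""
    vc = {"factor": f"0 + {factor}", "sptime": "0 + st_z"}
    # Powell is fast and robust near boundary (zero) variance components,
    # where the gradient-based default can return NaN standard errors.
    attempts = (
        ("intercept+slopes", dict(re_formula="1", vc_formula=vc), {"method": "powell"}),
        ("intercept", dict(re_formula="1"), {"method": "powell"}),
        ("intercept", dict(re_formula="1"), {}),
    )
    last = None
    for structure, spec, fitkw in attempts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(fixed_formula, df, groups=df["turn_id"], **spec)
                res = model.fit(reml=True, **fitkw)
            except (np.linalg.LinAlgError, ValueError):
                continue
        last = (res, structure)
        bse = np.asarray(res.bse_fe)
        if res.converged and np.all(np.isfinite(bse)) and np.all(bse > 0):
            return res, True, structure
    if last is None:
        raise ConvergenceError("mixed model could not be fitted under any structure")
    res, structure = last
    bse = np.asarray(res.bse_fe)
    if not (np.all(np.isfinite(bse)) and np.all(bse > 0)):
        raise ConvergenceError("singular mixed-model fit even after fallback")
    return res, bool(res.converged), structure


def _summarise(res, converged: bool, structure: str, rename: dict[str, str]) -> MixedModelResult:
    coefs = []
    for name in res.fe_params.index:
        beta = float(res.fe_params[name])
        t = beta / float(res.bse_fe[name])
        p = 2 * stats.norm.sf(abs(t))
        coefs.append((rename.get(name, name), beta, t, float(p)))
    r2m, r2c = r2_mixed(res)
    return MixedModelResult(
        coefficients=tuple(coefs),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=converged,
        n_obs=int(res.model.exog.shape[0]),
        random_structure=structure,
    )


def _prepare(design: pd.DataFrame, response: str, factor: str) -> pd.DataFrame:
    if design.empty:
        raise ValidationError("empty design")
    df = pd.DataFrame(
        {
            "turn_id": design["turn_id"].to_numpy(),
            factor: design[
                "speaker_is_target" if factor == "speaker" else "is_interruption"
            ].to_numpy(dtype=float),
            "st_z": _zscore(design["speaking_time_s"].to_numpy(dtype=float)),
            "y": _zscore(design[response].to_numpy(dtype=float)),
        }
    )
    levels = df.groupby(factor)["turn_id"].nunique()
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"{factor} takes a single value in this design; its effect is not estimable"
        )
    if (levels < 2).any():
        raise DegenerateDesignError(f"need >= 2 turns per {factor} level, got {dict(levels)}")
    return df


def fit_speaker_model(design: pd.DataFrame) -> MixedModelResult:
    """Mixed model: does holding the floor drive the candidate's mentions?

    Fixed effects: ``speaker`` (floor-holder is the target candidate),
    ``speaking_time`` (z-scored) and their interaction; random intercept and
    uncorrelated random slopes for both, grouped by turn.  Response:
    z-scored per-second target-channel count.
    """
    df = _prepare(design, "count_target", "speaker")
    res, converged, structure = _fit_mixed(df, "y ~ speaker * st_z", "speaker")
    rename = {
        "speaker": "speaker",
        "st_z": "speaking_time",
        "speaker:st_z": "speaker:speaking_time",
    }
    return _summarise(res, converged, structure, rename)


def fit_interruption_model(
    design: pd.DataFrame, rates_total: RateSeries | None = None
) -> MixedModelResult:
    """Mixed model: do interruptions drive overall attention?

    Fixed effects: ``interruption``, ``speaking_time`` (z-scored) and their
    interaction; same random structure as the speaker model.  Response:
    z-scored per-second total count (optionally re-supplied via
    ``rates_total``).
    """
    design = design.copy()
    if rates_total is not None:
        total = np.asarray(rates_total.channel("total"))
        idx = (design["t_s"].to_numpy() / rates_total.bin_width_s).astype(int)
        design["count_total"] = total[idx]
    df = _prepare(design, "count_total", "interrupt")
    res, converged, structure = _fit_mixed(df, "y ~ interrupt * st_z", "interrupt")
    rename = {
        "interrupt": "interruption",
        "st_z": "speaking_time",
        "interrupt:st_z": "interruption:speaking_time",
    }
    return _summarise(res, converged, structure, rename)
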