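"""Descriptive regressions and JZS Bayes factors.

The published mixed-effects analyses are implemented as a two-stage
procedure: ordinary least squares per participant on per-level summaries,
then one-sample default-Bayes-factor tests on the participant
coefficients against reference values (slope vs 1 or 0, intercept vs 0).
For balanced designs this is asymptotically equivalent to a
random-intercept/random-slope mixed model and keeps every step
transparent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "RegressionResult",
    "per_participant_fit",
    "population_regression",
    "jzs_bf_onesample",
    "condition_contrast",
]

DEFAULT_JZS_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class RegressionResult:
    """Population-level regression summary with Bayes factors.

    Slope/intercept are means of per-participant OLS coefficients; CIs are
    t-based from their SEM; BF10 values test the coefficients against the
    stated references with the JZS default prior.
    """

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    r2: float
    n_participants: int
    bf10_slope: float
    bf10_intercept: float
    slope_ref: float
    intercept_ref: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def per_participant_fit(
    summaries: pd.DataFrame,
    y: str = "mean",
    x: str = "target",
    condition: str | None = "direct",
) -> pd.DataFrame:
    """Per-participant OLS on level summaries.

    ``x`` selects the predictor: ``'target'`` (target force),
    ``'indirect_mean'`` (indirect mean matching force, paired by target
    level — the direct-vs-indirect comparison isolating attenuation), or
    ``'mean_match'`` (mean matching force, for SD-vs-mean regressions).
    ``y`` is ``'mean'`` or ``'sd'`` of the matching force.  Returns one
    row per participant with slope, intercept, r2 and n_points.
    """
    if y not in ("mean", "sd"):
        raise ValueError("y must be 'mean' or 'sd'")
    ycol = "mean_match" if y == "mean" else "sd_match"

    if x == "indirect_mean":
        d = summaries[summaries["condition"] == "direct"]
        i = summaries[summaries["condition"] == "indirect"]
        merged = d.merge(
            i[["participant_id", "gain", "target_force", "mean_match"]],
            on=["participant_id", "gain", "target_force"],
            suffixes=("", "_indirect"),
        )
        xv, yv = merged["mean_match_indirect"], merged[ycol]
        tab = merged.assign(_x=xv, _y=yv)
    else:
        if condition is not None:
            summaries = summaries[summaries["condition"] == condition]
        if x == "target":
            tab = summaries.assign(_x=summaries["target_force"], _y=summaries[ycol])
        elif x == "mean_match":
            tab = summaries.assign(_x=summaries["mean_match"], _y=summaries[ycol])
        else:
            raise ValueError(f"unknown x spec {x!r}")

    rows = []
    for pid, grp in tab.groupby("participant_id", sort=True):
        grp = grp.dropna(subset=["_x", "_y"])
        xa, ya = grp["_x"].to_numpy(float), grp["_y"].to_numpy(float)
        if np.unique(xa).size < 2:
            raise ValueError(f"participant {pid}: fewer than 2 distinct x values")
        slope, intercept, r2 = _ols(xa, ya)
        rows.append(
            {
                "participant_id": pid,
                "slope": slope,
                "intercept": intercept,
                "r2": r2,
                "n_points": len(xa),
            }
        )
    return pd.DataFrame(rows)


def _onesample_t(values: np.ndarray, ref: float) -> tuple[float, int]:
    n = len(values)
    sd = values.std(ddof=1)
    if sd == 0:
        return (0.0 if np.allclose(values, ref) else np.inf * np.sign(values.mean() - ref)), n
    return float((values.mean() - ref) / (sd / np.sqrt(n))), n


def jzs_bf_onesample(t: float, n: int, scale: float = DEFAULT_JZS_SCALE) -> float:
    """One-sample JZS Bayes factor BF10 from a t-statistic.

    The alternative places a Cauchy(0, scale) prior on the standardized
    effect size delta; BF10 is the ratio of the Cauchy-mixed noncentral-t
    marginal to the central-t density, computed by adaptive quadrature.
    BF10 > 1 favors a nonzero effect.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    df = n - 1
    null = stats.t.pdf(t, df)

    def integrand(delta):
        return stats.nct.pdf(t, df, np.sqrt(n) * delta) * stats.cauchy.pdf(
            delta, 0.0, scale
        )

    alt = 0.0
    for lo, hi in ((-np.inf, 0.0), (0.0, np.inf)):
        val, _ = integrate.quad(integrand, lo, hi, limit=200)
        alt += val
    if not np.isfinite(alt) or alt <= 0:
        raise ValueError("JZS marginal likelihood integral failed")
    return float(alt / null)


def population_regression(
    per_participant: pd.DataFrame,
    slope_ref: float = 1.0,
    intercept_ref: float = 0.0,
    scale: float = DEFAULT_JZS_SCALE,
) -> RegressionResult:
    """Population summary of per-participant coefficients with JZS tests."""
    n = len(per_participant)
    if n < 3:
        raise ValueError("need >= 3 participants")
    out = {}
    for name, ref in (("slope", slope_ref), ("intercept", intercept_ref)):
        vals = per_participant[name].to_numpy(float)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        ci = (mean - tcrit * sem, mean + tcrit * sem)
        tstat, _ = _onesample_t(vals, ref)
        bf = jzs_bf_onesample(tstat, n, scale) if np.isfinite(tstat) else np.inf
        out[name] = (mean, ci, bf)
    r2 = float(np.clip(per_participant["r2"].mean(), 0.0, 1.0)) if "r2" in per_participant else float("nan")
    return RegressionResult(
        slope=out["slope"][0],
        intercept=out["intercept"][0],
        slope_ci95=out["slope"][1],
        intercept_ci95=out["intercept"][1],
        r2=r2,
        n_participants=n,
        bf10_slope=out["slope"][2],
        bf10_intercept=out["intercept"][2],
        slope_ref=slope_ref,
        intercept_ref=intercept_ref,
    )


def condition_contrast(
    direct: pd.DataFrame,
    indirect: pd.DataFrame,
    quantity: str = "slope",
    scale: float = DEFAULT_JZS_SCALE,
) -> dict:
    """Paired direct-minus-indirect contrast of per-participant coefficients.

    Returns the mean paired difference, its SD, the one-sample t and the
    JZS BF10 against a zero difference.
    """
    if quantity not in ("slope", "intercept"):
        raise ValueError("quantity must be 'slope' or 'intercept'")
    d = direct.set_index("participant_id")[quantity]
    i = indirect.set_index("participant_id")[quantity]
    if set(d.index) != set(i.index):
        raise ValueError("participant sets differ between conditions")
    diff = (d - i.reindex(d.index)).to_numpy(float)
    tstat, n = _onesample_t(diff, 0.0)
    bf = jzs_bf_onesample(tstat, n, scale) if np.isfinite(tstat) else np.inf
    return {
        "quantity": quantity,
        "mean_difference": float(diff.mean()),
        "sd_difference": float(diff.std(ddof=1)),
        "t": tstat,
        "n": n,
        "bf10": bf,
    }
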