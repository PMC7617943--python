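"""Closed-form mathematics of subtractive and divisive sensory attenuation.

Both model variants describe the matching force a participant produces in
the *direct* condition (pressing on the passive finger) in terms of the
matching force distribution they produce in the *indirect* condition
(driving a motor), which carries every perceptual/memory/comparison
component except attenuation, plus a trial-to-trial attenuation factor
``K ~ Normal(mean_K, sd_K)``:

* subtractive:  F_D = K + F_I   (a fixed offset, independent of intensity)
* divisive:     F_D = K * F_I   (attenuation proportional to intensity)

The divisive direct force is a product of two independent normals, which
has no closed-form density; it is approximated by a skew-normal matched
for mean, SD and skewness.  The exact product-normal density is provided
separately (quadrature) for use as an independent oracle in tests; it is
never used in fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import log_ndtr

__all__ = [
    "AttenuationParams",
    "IndirectLevelParams",
    "MomentTriple",
    "SkewNormalParams",
    "SKEWNORM_MAX_SKEW",
    "subtractive_moments",
    "divisive_moments",
    "skewnormal_from_moments",
    "skewnormal_logdensity",
    "direct_force_loglik",
    "sample_direct",
    "attenuation_fraction",
    "attenuation_fraction_sd",
    "product_normal_logpdf",
]

_SQRT_2_PI = np.sqrt(2.0 / np.pi)

#: Supremum of |skewness| attainable by a skew-normal distribution
#: (~0.99527); requested skewness is clipped just below it.
SKEWNORM_MAX_SKEW = 0.995


@dataclass(frozen=True)
class AttenuationParams:
    """Trial-to-trial attenuation factor distribution K ~ N(mean_K, sd_K)."""

    mean_K: float
    sd_K: float

    def __post_init__(self) -> None:
        if self.sd_K < 0:
            raise ValueError("sd_K must be >= 0")


@dataclass(frozen=True)
class IndirectLevelParams:
    """Indirect matching force distribution F_I ~ N(mean_FI, sd_FI) at one level."""

    target_force: float
    mean_FI: float
    sd_FI: float

    def __post_init__(self) -> None:
        if self.sd_FI <= 0:
            raise ValueError("sd_FI must be > 0")


@dataclass(frozen=True)
class MomentTriple:
    """Mean (N), SD (N) and standardized skewness of a force distribution."""

    mean: float
    sd: float
    skew: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class SkewNormalParams:
    """Skew-normal parameters: location xi, scale omega > 0, shape alpha."""

    location: float
    scale: float
    shape: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


def subtractive_moments(
    att: AttenuationParams, ind: IndirectLevelParams
) -> MomentTriple:
    """Moments of the direct matching force under subtractive attenuation.

    F_D = K + F_I: mean = mean_K + mean_FI, sd = sqrt(sd_K^2 + sd_FI^2),
    and skewness identically zero (sum of independent normals is normal).
    """
    return MomentTriple(
        mean=att.mean_K + ind.mean_FI,
        sd=float(np.hypot(att.sd_K, ind.sd_FI)),
        skew=0.0,
    )


def _divisive_moments_arrays(mx, sx, my, sy):
    """Vectorized moments of Z = X*Y for independent X~N(mx,sx), Y~N(my,sy).

    Uses the explicit variance form sy^2*... which is well defined at
    sx = 0; skewness uses the explicit third-central-moment numerator
    6*mx*my*sx^2*sy^2 so the sx -> 0 limit is exact.
    """
    mx, sx, my, sy = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mx, sx, my, sy))
    )
    mean = mx * my
    var = my**2 * sx**2 + (mx**2 + sx**2) * sy**2
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(var > 0, 6.0 * mx * my * sx**2 * sy**2 / var**1.5, 0.0)
    return mean, sd, skew


def divisive_moments(att: AttenuationParams, ind: IndirectLevelParams) -> MomentTriple:
    """Moments of the direct matching force under divisive attenuation.

    F_D = K * F_I, a product of independent normals.  With
    delta_K = mean_K/sd_K and delta_FI = mean_FI/sd_FI:

        mean = mean_K * mean_FI
        sd   = sqrt(mean_FI^2 sd_K^2 + (mean_K^2 + sd_K^2) sd_FI^2)
             = sd_K sd_FI sqrt(1 + delta_K^2 + delta_FI^2)
        skew = 6 delta_K delta_FI / (1 + delta_K^2 + delta_FI^2)^{3/2}

    The sd_K = 0 case reduces to a scaled normal (zero skew).
    """
    mean, sd, skew = _divisive_moments_arrays(
        att.mean_K, att.sd_K, ind.mean_FI, ind.sd_FI
    )
    return MomentTriple(float(mean), float(sd), float(skew))


def _skewnorm_from_moments_arrays(mean, sd, skew, warn: bool = True):
    """Vectorized exact moment inversion for the skew-normal.

    Given target skewness g, the method-of-moments relation
    g = ((4-pi)/2) u^3 / (1-u^2)^{3/2} with u = delta*sqrt(2/pi) inverts
    in closed form: u^2 = c/(1+c), c = (2|g|/(4-pi))^{2/3}.  |g| above the
    skew-normal supremum is clipped to SKEWNORM_MAX_SKEW (with a warning),
    keeping the likelihood defined in extreme parameter corners.
    """
    mean, sd, skew = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mean, sd, skew))
    )
    if warn and np.any(np.abs(skew) > SKEWNORM_MAX_SKEW):
        warnings.warn(
            "requested skewness exceeds the skew-normal supremum; clipping to "
            f"+/-{SKEWNORM_MAX_SKEW}",
            RuntimeWarning,
            stacklevel=3,
        )
    g = np.clip(skew, -SKEWNORM_MAX_SKEW, SKEWNORM_MAX_SKEW)
    c = (2.0 * np.abs(g) / (4.0 - np.pi)) ** (2.0 / 3.0)
    u2 = c / (1.0 + c)
    delta = np.sign(g) * np.sqrt(u2 * np.pi / 2.0)
    with np.errstate(divide="ignore"):
        alpha = delta / np.sqrt(np.maximum(1.0 - delta**2, 1e-300))
    omega = sd / np.sqrt(1.0 - u2)
    xi = mean - omega * delta * _SQRT_2_PI
    return xi, omega, alpha


def skewnormal_from_moments(m: MomentTriple) -> SkewNormalParams:
    """Skew-normal parameters (xi, omega, alpha) matching mean, SD and skewness.

    The inversion is exact: the analytic moments of the returned
    parameters reproduce the inputs to machine precision.  Skewness with
    magnitude above the distributional supremum (~0.9953) is clipped to
    0.995 with a warning.
    """
    if not m.sd > 0:
        raise ValueError("sd must be > 0 to match a skew-normal")
    xi, omega, alpha = _skewnorm_from_moments_arrays(m.mean, m.sd, m.skew)
    return SkewNormalParams(float(xi), float(omega), float(alpha))


def skewnormal_moments(p: SkewNormalParams) -> MomentTriple:
    """Analytic mean/SD/skewness of a skew-normal — round-trip companion."""
    delta = p.shape / np.hypot(1.0, p.shape)
    u = delta * _SQRT_2_PI
    mean = p.location + p.scale * u
    sd = p.scale * np.sqrt(1.0 - u**2)
    skew = (4.0 - np.pi) / 2.0 * u**3 / (1.0 - u**2) ** 1.5
    return MomentTriple(float(mean), float(sd), float(skew))


def _skewnorm_logpdf_arrays(x, xi, omega, alpha):
    z = (np.asarray(x, dtype=float) - xi) / omega
    return (
        np.log(2.0)
        - np.log(omega)
        - 0.5 * (z**2 + np.log(2.0 * np.pi))
        + log_ndtr(alpha * z)
    )


def skewnormal_logdensity(x, p: SkewNormalParams):
    """Log-density log[ 2/omega phi((x-xi)/omega) Phi(alpha (x-xi)/omega) ].

    Uses ``log_ndtr`` for a numerically stable log-CDF; reduces exactly to
    the normal log-density at alpha = 0.
    """
    out = _skewnorm_logpdf_arrays(x, p.location, p.scale, p.shape)
    return float(out) if np.isscalar(x) else out


def direct_force_loglik(
    forces,
    att: AttenuationParams,
    ind: IndirectLevelParams,
    model: str,
) -> float:
    """Total log-likelihood of direct-condition forces at one target level.

    ``model='subtractive'`` uses the exact normal density implied by
    :func:`subtractive_moments`; ``model='divisive'`` uses the skew-normal
    approximation matched to :func:`divisive_moments`.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("forces must be nonempty")
    if model == "subtractive":
        m = subtractive_moments(att, ind)
        return float(np.sum(stats.norm.logpdf(forces, m.mean, m.sd)))
    if model == "divisive":
        m = divisive_moments(att, ind)
        sn = skewnormal_from_moments(m)
        return float(np.sum(skewnormal_logdensity(forces, sn)))
    raise ValueError(f"unknown model {model!r}")


def sample_direct(
    att: AttenuationParams,
    ind: IndirectLevelParams,
    model: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact generative draws of the direct matching force.

    Draws K_i ~ N(mean_K, sd_K) and F_I,i ~ N(mean_FI, sd_FI) independently
    and returns K_i * F_I,i (divisive) or K_i + F_I,i (subtractive) — the
    true generative process, not the skew-normal approximation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = rng.normal(att.mean_K, att.sd_K, size=n)
    fi = rng.normal(ind.mean_FI, ind.sd_FI, size=n)
    if model == "divisive":
        return k * fi
    if model == "subtractive":
        return k + fi
    raise ValueError(f"unknown model {model!r}")


def attenuation_fraction(mean_K: float) -> float:
    """Attenuation fraction 1 - 1/mean_K implied by a divisive factor.

    E.g. a mean attenuation factor of 1.61 corresponds to the directly
    self-generated force being attenuated by 1 - 1/1.61 = 0.38.
    """
    if not mean_K > 0:
        raise ValueError("mean_K must be > 0")
    return 1.0 - 1.0 / mean_K


def attenuation_fraction_sd(mean_K: float, sd_K: float) -> float:
    """First-order (delta-method) SD of the attenuation fraction.

    d/dK (1 - 1/K) = 1/K^2, so sd_fraction ~= sd_K / mean_K^2 — e.g.
    0.152 / 1.61^2 ~= 0.06, an attenuation of 38% +/- 6%.
    """
    if not mean_K > 0:
        raise ValueError("mean_K must be > 0")
    if sd_K < 0:
        raise ValueError("sd_K must be >= 0")
    return sd_K / mean_K**2


def product_normal_logpdf(
    x, mx: float, sx: float, my: float, sy: float, n_sigma: float = 10.0
):
    """Exact log-density of Z = X*Y (independent normals) by quadrature.

    f_Z(z) = int N(u; mx, sx) N(z/u; my, sy) / |u| du, integrated
    adaptively over u in [mx - n_sigma sx, mx + n_sigma sx].  Intended as
    an independent oracle for the skew-normal approximation; requires
    sx > 0 and X's mass to be bounded away from zero (mx >> sx), as holds
    for attenuation factors.
    """
    if sx <= 0 or sy <= 0:
        raise ValueError("sx and sy must be > 0")

    def _one(z: float) -> float:
        def integrand(u):
            return (
                stats.norm.pdf(u, mx, sx) * stats.norm.pdf(z / u, my, sy) / np.abs(u)
            )

        lo, hi = mx - n_sigma * sx, mx + n_sigma * sx
        if lo <= 0 < hi:
            lo = min(hi / 1e6, 1e-6)
        val, _ = integrate.quad(integrand, lo, hi, limit=200)
        return np.log(val) if val > 0 else -np.inf

    if np.isscalar(x):
        return _one(float(x))
    return np.array([_one(float(z)) for z in np.asarray(x, dtype=float)])
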