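"""Hierarchical Bayesian fitting of the attenuation models by MCMC.

The likelihood treats each participant's indirect matching forces at each
target level as Normal(mean_FI, sd_FI) with free per-participant-per-level
parameters, and the direct matching forces as either the exact normal
implied by subtractive attenuation or the moment-matched skew-normal
approximation of the divisive product model.  Per-participant attenuation
parameters (mean_K, sd_K) are tied by population-level hyperpriors:
mean_K_i ~ Normal(pop_mean_K, pop_sd_mean_K) (truncated > 0 for the
divisive model) and sd_K_i ~ half-Normal(pop_scale_sd_K).

Sampling uses adaptive random-walk Metropolis-within-Gibbs over parameter
blocks — a per-participant attenuation block, per-participant-per-level
indirect blocks, and one population block — with proposal scales adapted
during burn-in only toward a 0.25-0.45 acceptance rate.  Positive
parameters are sampled on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from . import diagnostics
from .models import (
    _divisive_moments_arrays,
    _skewnorm_from_moments_arrays,
    _skewnorm_logpdf_arrays,
)

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "FitResult",
    "build_model",
    "sample_posterior",
    "fit",
    "fit_gain_condition",
    "run_adaptive_mh",
]

_LOG_2PI = np.log(2.0 * np.pi)
_HALFNORM_C = 0.5 * np.log(2.0 / np.pi)


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _halfnorm_logpdf(x, scale):
    return _HALFNORM_C - np.log(scale) - 0.5 * (x / scale) ** 2


@dataclass(frozen=True)
class PriorSpec:
    """Priors for all population-level parameters.

    ``mean_K_pop_loc/scale`` parameterize the prior on the population mean
    attenuation factor (truncated > 0 when ``mean_K_pop_positive``);
    between-participant spread and all scale parameters get half-normal
    priors; indirect level means are Normal(level value, indirect_mean_scale).
    """

    mean_K_pop_loc: float = 1.0
    mean_K_pop_scale: float = 1.0
    mean_K_pop_positive: bool = True
    between_sd_scale: float = 1.0
    sd_K_scale_hyper: float = 1.0
    indirect_mean_scale: float = 2.0
    indirect_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "mean_K_pop_scale",
            "between_sd_scale",
            "sd_K_scale_hyper",
            "indirect_mean_scale",
            "indirect_sd_scale",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def default_for(cls, model_type: str) -> "PriorSpec":
        if model_type == "divisive":
            return cls(1.0, 1.0, True)
        if model_type == "subtractive":
            return cls(0.0, 2.0, False)
        raise ValueError(f"unknown model {model_type!r}")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout: kept draws per chain after burn-in and thinning."""

    n_chains: int = 3
    thin: int = 2
    burn_in: int = 1000
    samples_per_chain: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chains", "thin", "burn_in", "samples_per_chain"):
            if not getattr(self, name) >= 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def desk(cls, seed: int = 0) -> "MCMCConfig":
        """Reduced desk-scale settings used throughout the test suite."""
        return cls(n_chains=3, thin=1, burn_in=1000, samples_per_chain=2000, seed=seed)


@dataclass
class PosteriorSamples:
    """Named posterior draws, shape (n_chains, n_draws) per parameter."""

    draws: dict[str, np.ndarray]
    loglik: np.ndarray  # (n_chains, n_draws) total data log-likelihood
    acceptance: dict[str, float] = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()


def _lev_str(level: float) -> str:
    return f"{level:g}"


class HierarchicalModel:
    """Likelihood, priors and state layout for one dataset + model variant."""

    def __init__(self, dataset, model_type, priors=None, fixed_indirect=None):
        if model_type not in ("divisive", "subtractive"):
            raise ValueError(f"unknown model {model_type!r}")
        self.model_type = model_type
        self.priors = priors or PriorSpec.default_for(model_type)
        self.fixed_indirect = None

        d = dataset[dataset["condition"] == "direct"]
        ind = dataset[dataset["condition"] == "indirect"]
        if len(d) == 0:
            raise ValueError("dataset has no direct-condition trials")
        if len(ind) == 0 and fixed_indirect is None:
            raise ValueError(
                "dataset has no indirect trials; provide fixed indirect parameters"
            )

        self.pids = sorted(dataset["participant_id"].unique())
        self._pidx = {p: i for i, p in enumerate(self.pids)}
        self.levels = np.sort(dataset["target_force_N"].unique())
        self.P, self.L = len(self.pids), len(self.levels)
        self.ncells = self.P * self.L
        self.cell_p = np.repeat(np.arange(self.P), self.L)
        self.cell_l = np.tile(np.arange(self.L), self.P)

        if fixed_indirect is not None:
            mu = np.empty(self.L)
            sd = np.empty(self.L)
            for j, lev in enumerate(self.levels):
                match = [
                    k for k in fixed_indirect if abs(float(k) - lev) <= 1e-6
                ]
                if not match:
                    raise ValueError(
                        f"no fixed indirect parameters for level {lev:g} N"
                    )
                mu[j], sd[j] = fixed_indirect[match[0]]
            if np.any(sd <= 0):
                raise ValueError("fixed indirect SDs must be > 0")
            self.fixed_indirect = (mu, sd)

        def _cells(df):
            p = df["participant_id"].map(self._pidx).to_numpy()
            l = np.searchsorted(self.levels, df["target_force_N"].to_numpy())
            return df["matching_force_N"].to_numpy(float), p * self.L + l

        self.d_force, self.d_cell = _cells(d)
        self.i_force, self.i_cell = _cells(ind)

    # -- parameter transforms ------------------------------------------------

    def _mean_k(self, atten):
        col = atten[:, 0]
        return np.exp(col) if self.model_type == "divisive" else col

    def _indirect_params(self, state):
        if self.fixed_indirect is not None:
            mu, sd = self.fixed_indirect
            return mu[self.cell_l], sd[self.cell_l]
        ind = state["ind"]
        return ind[:, 0], np.exp(ind[:, 1])

    # -- likelihood ----------------------------------------------------------

    def direct_cell_loglik(self, state):
        atten = state["atten"]
        mean_k = self._mean_k(atten)[self.cell_p]
        sd_k = np.exp(atten[:, 1])[self.cell_p]
        mu_i, sd_i = self._indirect_params(state)
        with np.errstate(all="ignore"):
            if self.model_type == "divisive":
                m, s, g = _divisive_moments_arrays(mean_k, sd_k, mu_i, sd_i)
                xi, om, al = _skewnorm_from_moments_arrays(m, s, g, warn=False)
                lp = _skewnorm_logpdf_arrays(
                    self.d_force, xi[self.d_cell], om[self.d_cell], al[self.d_cell]
                )
            else:
                m = mean_k + mu_i
                s = np.hypot(sd_k, sd_i)
                lp = _norm_logpdf(self.d_force, m[self.d_cell], s[self.d_cell])
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return np.bincount(self.d_cell, weights=lp, minlength=self.ncells)

    def indirect_cell_loglik(self, state):
        if self.i_force.size == 0:
            return np.zeros(self.ncells)
        mu_i, sd_i = self._indirect_params(state)
        with np.errstate(all="ignore"):
            lp = _norm_logpdf(self.i_force, mu_i[self.i_cell], sd_i[self.i_cell])
        lp = np.where(np.isfinite(lp), lp, -np.inf)
        return np.bincount(self.i_cell, weights=lp, minlength=self.ncells)

    def total_loglik(self, state) -> float:
        return float(
            self.direct_cell_loglik(state).sum() + self.indirect_cell_loglik(state).sum()
        )

    # -- priors (log densities incl. Jacobians of the log-scale transforms) --

    def _atten_prior(self, state):
        atten, pop = state["atten"], state["pop"][0]
        mu_pop, tau, s_pop = pop[0], np.exp(pop[1]), np.exp(pop[2])
        mean_k = self._mean_k(atten)
        sd_k = np.exp(atten[:, 1])
        lp = _norm_logpdf(mean_k, mu_pop, tau)
        if self.model_type == "divisive":
            lp = lp - log_ndtr(mu_pop / tau) + atten[:, 0]  # truncation + Jacobian
        lp = lp + _halfnorm_logpdf(sd_k, s_pop) + atten[:, 1]
        return lp

    def _ind_prior(self, state):
        pr = self.priors
        ind = state["ind"]
        mu, log_sd = ind[:, 0], ind[:, 1]
        sd = np.exp(log_sd)
        levels = self.levels[self.cell_l]
        return (
            _norm_logpdf(mu, levels, pr.indirect_mean_scale)
            + _halfnorm_logpdf(sd, pr.indirect_sd_scale)
            + log_sd
        )

    def _pop_prior(self, state):
        pr = self.priors
        pop = state["pop"][0]
        mu_pop, tau, s_pop = pop[0], np.exp(pop[1]), np.exp(pop[2])
        if pr.mean_K_pop_positive and mu_pop <= 0:
            return -np.inf
        lp = _norm_logpdf(mu_pop, pr.mean_K_pop_loc, pr.mean_K_pop_scale)
        if pr.mean_K_pop_positive:
            lp -= log_ndtr(pr.mean_K_pop_loc / pr.mean_K_pop_scale)
        lp += _halfnorm_logpdf(tau, pr.between_sd_scale) + pop[1]
        lp += _halfnorm_logpdf(s_pop, pr.sd_K_scale_hyper) + pop[2]
        return lp

    # -- block log-targets (per-unit arrays) ----------------------------------

    def atten_logp(self, state):
        dcl = self.direct_cell_loglik(state).reshape(self.P, self.L).sum(axis=1)
        return dcl + self._atten_prior(state)

    def ind_logp(self, state):
        return (
            self.direct_cell_loglik(state)
            + self.indirect_cell_loglik(state)
            + self._ind_prior(state)
        )

    def pop_logp(self, state):
        return np.array([self._atten_prior(state).sum() + self._pop_prior(state)])

    # -- initialization -------------------------------------------------------

    def init_state(self, rng, jitter: float = 0.05):
        d_mean = np.bincount(self.d_cell, weights=self.d_force, minlength=self.ncells)
        d_n = np.bincount(self.d_cell, minlength=self.ncells)
        if self.fixed_indirect is not None:
            mu0 = self.fixed_indirect[0][self.cell_l]
            sd0 = self.fixed_indirect[1][self.cell_l]
            ind = None
        else:
            i_n = np.bincount(self.i_cell, minlength=self.ncells)
            i_sum = np.bincount(self.i_cell, weights=self.i_force, minlength=self.ncells)
            mu0 = np.where(i_n > 0, i_sum / np.maximum(i_n, 1), self.levels[self.cell_l])
            i_sq = np.bincount(
                self.i_cell, weights=self.i_force**2, minlength=self.ncells
            )
            var = np.where(
                i_n > 1,
                (i_sq - i_n * mu0**2) / np.maximum(i_n - 1, 1),
                0.04,
            )
            sd0 = np.sqrt(np.maximum(var, 0.0025))
            ind = np.column_stack([mu0, np.log(sd0)])

        with np.errstate(all="ignore"):
            d_bar = np.where(d_n > 0, d_mean / np.maximum(d_n, 1), np.nan)
        per_p_direct = np.nanmean(d_bar.reshape(self.P, self.L), axis=1)
        per_p_ind = np.nanmean(
            np.where(d_n > 0, mu0, np.nan).reshape(self.P, self.L), axis=1
        )
        if self.model_type == "divisive":
            k0 = np.clip(per_p_direct / per_p_ind, 0.2, 5.0)
            col0 = np.log(k0)
        else:
            col0 = per_p_direct - per_p_ind
        atten = np.column_stack([col0, np.full(self.P, np.log(0.1))])

        if self.model_type == "divisive":
            mu_pop0 = max(float(np.mean(np.exp(col0))), 0.2)
        else:
            mu_pop0 = float(np.mean(col0))
        tau0 = max(float(np.std(np.exp(col0) if self.model_type == "divisive" else col0)), 0.05)
        pop = np.array([[mu_pop0, np.log(tau0), np.log(0.15)]])

        state = {"atten": atten, "pop": pop}
        if ind is not None:
            state["ind"] = ind
        if jitter > 0:
            for k in state:
                state[k] = state[k] + rng.normal(0.0, jitter, size=state[k].shape)
        return state

    # -- posterior draw naming -----------------------------------------------

    def param_names(self):
        names = ["pop_mean_K", "pop_sd_mean_K", "pop_scale_sd_K"]
        names += [f"mean_K[{p}]" for p in self.pids]
        names += [f"sd_K[{p}]" for p in self.pids]
        if self.fixed_indirect is None:
            for p in self.pids:
                for lev in self.levels:
                    names.append(f"mean_FI[{p},{_lev_str(lev)}]")
                    names.append(f"sd_FI[{p},{_lev_str(lev)}]")
        return names

    def positive_names(self) -> frozenset[str]:
        """Parameters sampled on the log scale (posterior means for DIC)."""
        out = {"pop_sd_mean_K", "pop_scale_sd_K"}
        out |= {f"sd_K[{p}]" for p in self.pids}
        if self.model_type == "divisive":
            out |= {f"mean_K[{p}]" for p in self.pids}
        if self.fixed_indirect is None:
            out |= {
                f"sd_FI[{p},{_lev_str(lev)}]"
                for p in self.pids
                for lev in self.levels
            }
        return frozenset(out)

    def named_draws(self, atten, ind, pop):
        """Convert snapshot arrays (kept, ...) to the named, natural scale."""
        out = {
            "pop_mean_K": pop[:, 0, 0],
            "pop_sd_mean_K": np.exp(pop[:, 0, 1]),
            "pop_scale_sd_K": np.exp(pop[:, 0, 2]),
        }
        mean_k = (
            np.exp(atten[:, :, 0]) if self.model_type == "divisive" else atten[:, :, 0]
        )
        for i, p in enumerate(self.pids):
            out[f"mean_K[{p}]"] = mean_k[:, i]
            out[f"sd_K[{p}]"] = np.exp(atten[:, i, 1])
        if ind is not None:
            for i, p in enumerate(self.pids):
                for j, lev in enumerate(self.levels):
                    c = i * self.L + j
                    out[f"mean_FI[{p},{_lev_str(lev)}]"] = ind[:, c, 0]
                    out[f"sd_FI[{p},{_lev_str(lev)}]"] = np.exp(ind[:, c, 1])
        return out

    def loglik_from_params(self, params: dict) -> float:
        """Total data log-likelihood from a named parameter dict.

        Unknown names are ignored, so draws may carry extra entries.
        """
        atten = np.empty((self.P, 2))
        for i, p in enumerate(self.pids):
            mk = params[f"mean_K[{p}]"]
            atten[i, 0] = np.log(mk) if self.model_type == "divisive" else mk
            atten[i, 1] = np.log(params[f"sd_K[{p}]"])
        state = {"atten": atten, "pop": np.array([[1.0, 0.0, 0.0]])}
        if self.fixed_indirect is None:
            ind = np.empty((self.ncells, 2))
            for i, p in enumerate(self.pids):
                for j, lev in enumerate(self.levels):
                    c = i * self.L + j
                    ind[c, 0] = params[f"mean_FI[{p},{_lev_str(lev)}]"]
                    ind[c, 1] = np.log(params[f"sd_FI[{p},{_lev_str(lev)}]"])
            state["ind"] = ind
        return self.total_loglik(state)


def build_model(
    dataset,
    model_type: str,
    priors: PriorSpec | None = None,
    fixed_indirect: dict | None = None,
) -> HierarchicalModel:
    """Build the hierarchical model for a dataset and attenuation variant."""
    return HierarchicalModel(dataset, model_type, priors, fixed_indirect)


def run_adaptive_mh(
    blocks,
    state,
    rng,
    n_sweeps: int,
    burn_in: int,
    thin: int = 1,
    init_scale: float = 0.1,
    adapt_window: int = 25,
    target_accept: float = 0.35,
    record=None,
):
    """Generic blocked adaptive random-walk Metropolis sampler.

    ``blocks`` maps a state key to a log-target callable returning one
    value per unit (row) of ``state[key]``; units are updated with
    independent accept/reject decisions, which is valid when units are
    conditionally independent given the rest of the state.  Per-unit
    proposal scales adapt toward ``target_accept`` during burn-in only.
    Returns (snapshots, acceptance rates) where snapshots stacks
    ``record(state)`` at every kept sweep.
    """
    scales = {k: np.full(state[k].shape[0], init_scale) for k in blocks}
    acc_cnt = {k: np.zeros(state[k].shape[0]) for k in blocks}
    acc_tot = {k: 0.0 for k in blocks}
    n_prop = {k: 0 for k in blocks}
    kept = []
    for sweep in range(n_sweeps):
        for key, logp in blocks.items():
            cur = state[key]
            cur_lp = logp(state)
            prop = cur + scales[key][:, None] * rng.standard_normal(cur.shape)
            state[key] = prop
            prop_lp = logp(state)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(cur.shape[0])) < (prop_lp - cur_lp)
            accept &= np.isfinite(prop_lp)
            new = np.where(accept[:, None], prop, cur)
            state[key] = new
            acc_cnt[key] += accept
            acc_tot[key] += accept.mean()
            n_prop[key] += 1
            if sweep < burn_in and (sweep + 1) % adapt_window == 0:
                rate = acc_cnt[key] / adapt_window
                scales[key] = np.clip(
                    scales[key] * np.exp(0.6 * (rate - target_accept)), 1e-4, 5.0
                )
                acc_cnt[key][:] = 0.0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            kept.append(record(state) if record else {k: v.copy() for k, v in state.items()})
    rates = {k: acc_tot[k] / max(n_prop[k], 1) for k in blocks}
    return kept, rates


def sample_posterior(model: HierarchicalModel, config: MCMCConfig) -> PosteriorSamples:
    """Draw posterior samples for a built model; deterministic under seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    n_sweeps = config.burn_in + config.thin * config.samples_per_chain
    all_named: dict[str, list[np.ndarray]] = {}
    ll_chains = []
    rates = {}
    for ci, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        state = None
        for _ in range(10):
            cand = model.init_state(rng)
            blocks = {"atten": model.atten_logp, "pop": model.pop_logp}
            if "ind" in cand:
                blocks = {"atten": model.atten_logp, "ind": model.ind_logp, "pop": model.pop_logp}
            if all(np.all(np.isfinite(b(cand))) for b in blocks.values()):
                state = cand
                break
        if state is None:
            raise RuntimeError("could not find a finite starting point")

        snaps, rate = run_adaptive_mh(
            blocks,
            state,
            rng,
            n_sweeps=n_sweeps,
            burn_in=config.burn_in,
            thin=config.thin,
            record=lambda s: (
                s["atten"].copy(),
                s.get("ind").copy() if "ind" in s else None,
                s["pop"].copy(),
                model.total_loglik(s),
            ),
        )
        atten = np.stack([s[0] for s in snaps])
        ind = np.stack([s[1] for s in snaps]) if snaps[0][1] is not None else None
        pop = np.stack([s[2] for s in snaps])
        ll_chains.append(np.array([s[3] for s in snaps]))
        for name, arr in model.named_draws(atten, ind, pop).items():
            all_named.setdefault(name, []).append(arr)
        for k, v in rate.items():
            rates[f"{k}_chain{ci}"] = float(v)
    draws = {k: np.stack(v) for k, v in all_named.items()}
    return PosteriorSamples(draws=draws, loglik=np.stack(ll_chains), acceptance=rates)


@dataclass
class FitResult:
    """Posterior samples plus DIC decomposition and convergence diagnostics."""

    model_type: str
    samples: PosteriorSamples
    dic: float
    p_d: float
    dbar: float
    rhat: dict[str, float]
    convergence_flags: list[str]
    config: MCMCConfig
    priors: PriorSpec

    @property
    def converged(self) -> bool:
        return not self.convergence_flags

    def population_rhat(self) -> dict[str, float]:
        return {k: v for k, v in self.rhat.items() if k.startswith("pop_")}

    def median(self, name: str) -> float:
        return float(np.median(self.samples.draws[name]))

    def hdi(self, name: str, mass: float = 0.90) -> tuple[float, float]:
        return diagnostics.hdi(self.samples.draws[name], mass)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        rows = []
        for name, arr in self.samples.draws.items():
            lo, hi = diagnostics.hdi(arr, mass)
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(arr)),
                    f"hdi{int(mass * 100)}_lo": lo,
                    f"hdi{int(mass * 100)}_hi": hi,
                    "rhat": self.rhat.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)


_RHAT_FLAG = 1.1


def _assemble(model, samples, config) -> FitResult:
    rh = {}
    for name, arr in samples.draws.items():
        if np.ptp(arr) == 0:
            rh[name] = float("nan")
            continue
        rh[name] = diagnostics.rhat(arr)
    flags = [
        k
        for k, v in rh.items()
        if k.startswith("pop_") and (not np.isfinite(v) or v >= _RHAT_FLAG)
    ]
    dic_val, p_d, dbar = diagnostics.dic(
        samples.draws,
        model.loglik_from_params,
        pointwise_loglik=samples.loglik,
        positive=model.positive_names(),
    )
    return FitResult(
        model_type=model.model_type,
        samples=samples,
        dic=dic_val,
        p_d=p_d,
        dbar=dbar,
        rhat=rh,
        convergence_flags=flags,
        config=config,
        priors=model.priors,
    )


def fit(
    dataset,
    model_type: str,
    config: MCMCConfig,
    priors: PriorSpec | None = None,
) -> FitResult:
    """Build and fit one attenuation model to a trials dataset."""
    model = build_model(dataset, model_type, priors)
    samples = sample_posterior(model, config)
    return _assemble(model, samples, config)


def fit_gain_condition(
    dataset,
    fixed_indirect: dict,
    config: MCMCConfig,
    model_type: str = "divisive",
    priors: PriorSpec | None = None,
) -> FitResult:
    """Fit attenuation parameters to direct-only data with indirect fixed.

    ``fixed_indirect`` maps target level (N) to (mean_FI, sd_FI), e.g. the
    population-level posterior medians of a reference fit; only the
    attenuation parameters are sampled.
    """
    direct = dataset[dataset["condition"] == "direct"]
    model = build_model(direct, model_type, priors, fixed_indirect=fixed_indirect)
    samples = sample_posterior(model, config)
    return _assemble(model, samples, config)
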