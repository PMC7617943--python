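"""Synthetic force-matching cohorts with known ground truth.

The generator implements the noise-pathway account of the task: the
participant perceives the target force (perceptual noise), holds it in
memory (contraction toward the session mean plus memory noise), and
adjusts their output until the — possibly attenuated — sensation of the
matching force equals the remembered target (comparison noise, plus a
signal-dependent component that grows with output amplitude).  The direct
condition additionally passes the output through the trial-to-trial
attenuation factor K (divisive or subtractive), exactly as in
:mod:`forcematch.models`.

Study designs mirror the four published force-matching designs: 6 levels
1-3.5 N x 72 trials; 4 levels 1-2.5 N x 64; 5 levels 0.5-2.75 N x 160;
and a direct-only gain-manipulation design (0.5x/1x/2x, 50 trials each).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data import TRIAL_COLUMNS, StudyDesign
from .models import AttenuationParams

__all__ = [
    "PathwayParams",
    "ParticipantTruth",
    "PopulationTruth",
    "DESIGN_PRESETS",
    "draw_participants",
    "simulate_indirect",
    "simulate_direct",
    "simulate_study",
    "simulate_gain_study",
    "simulate_trace",
    "write_truth",
    "read_truth",
]

#: The four bundled study designs (force range, levels, trials, conditions).
DESIGN_PRESETS: dict[str, StudyDesign] = {
    "study1": StudyDesign(1.0, 3.5, 6, 72),
    "study2": StudyDesign(1.0, 2.5, 4, 64),
    "study3": StudyDesign(0.5, 2.75, 5, 160),
    "study4": StudyDesign(1.0, 3.0, 5, 150, conditions=("direct",), gains=(0.5, 1.0, 2.0)),
}


@dataclass(frozen=True)
class PathwayParams:
    """Non-attenuation noise sources shared by both conditions.

    ``memory_contraction`` c pulls the remembered target toward the mean of
    the presented levels (contraction bias): m_T = (1-c) F_T + c L_mean.
    Constant noise SDs (N) add in quadrature; ``signal_dependent_coef``
    adds an SD component proportional to the expected output, reproducing
    the growth of variability with force amplitude.
    """

    perceptual_noise_sd: float = 0.08
    memory_contraction: float = 0.15
    memory_noise_sd: float = 0.10
    comparison_noise_sd: float = 0.08
    signal_dependent_coef: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "perceptual_noise_sd",
            "memory_noise_sd",
            "comparison_noise_sd",
            "signal_dependent_coef",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.memory_contraction <= 1.0:
            raise ValueError("memory_contraction must be in [0, 1]")

    @property
    def constant_noise_sd(self) -> float:
        """Quadrature sum of the constant (level-independent) noise SDs."""
        return float(
            np.sqrt(
                self.perceptual_noise_sd**2
                + self.memory_noise_sd**2
                + self.comparison_noise_sd**2
            )
        )


@dataclass(frozen=True)
class ParticipantTruth:
    participant_id: str
    attenuation: AttenuationParams
    pathway: PathwayParams


@dataclass(frozen=True)
class PopulationTruth:
    """Population-level generative truth.

    Per-participant mean_K is drawn Normal(mean_K_mean, mean_K_sd)
    truncated > 0; sd_K is half-normal with scale ``sd_K_scale``; pathway
    parameters are Normal around ``pathway`` with the spreads in
    ``pathway_spread``, truncated to their valid ranges.
    """

    mean_K_mean: float = 1.6
    mean_K_sd: float = 0.2
    sd_K_scale: float = 0.15
    pathway: PathwayParams = field(default_factory=PathwayParams)
    pathway_spread: PathwayParams = field(
        default_factory=lambda: PathwayParams(0.02, 0.05, 0.03, 0.02, 0.01)
    )

    def __post_init__(self) -> None:
        if self.mean_K_sd < 0 or self.sd_K_scale < 0:
            raise ValueError("population scales must be >= 0")


def _truncated_normal(rng, mean, sd, size, low=0.0, high=np.inf):
    """Rejection-sampled truncated normal; exact for the mild truncations used."""
    out = rng.normal(mean, sd, size=size)
    bad = (out <= low) | (out > high)
    while np.any(bad):
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], sd, size=bad.sum())
        bad = (out <= low) | (out > high)
    return out


def draw_participants(
    pop: PopulationTruth, n: int, rng: np.random.Generator
) -> list[ParticipantTruth]:
    """Draw ``n`` participants from the population-level distributions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mean_k = _truncated_normal(rng, pop.mean_K_mean, pop.mean_K_sd, n) \
        if pop.mean_K_sd > 0 else np.full(n, pop.mean_K_mean)
    sd_k = np.abs(rng.normal(0.0, pop.sd_K_scale, size=n)) \
        if pop.sd_K_scale > 0 else np.zeros(n)
    out = []
    pw, sp = pop.pathway, pop.pathway_spread
    for i in range(n):
        fields = {}
        for name, hi in (
            ("perceptual_noise_sd", np.inf),
            ("memory_contraction", 1.0),
            ("memory_noise_sd", np.inf),
            ("comparison_noise_sd", np.inf),
            ("signal_dependent_coef", np.inf),
        ):
            m, s = getattr(pw, name), getattr(sp, name)
            if s > 0:
                fields[name] = float(
                    _truncated_normal(rng, m, s, 1, low=-1e-12, high=hi)[0]
                )
            else:
                fields[name] = m
        out.append(
            ParticipantTruth(
                participant_id=f"P{i:03d}",
                attenuation=AttenuationParams(float(mean_k[i]), float(sd_k[i])),
                pathway=PathwayParams(**fields),
            )
        )
    return out


def _level_sequence(design: StudyDesign, n_trials: int, rng) -> np.ndarray:
    """Blocked pseudorandom level order: repeated permutations of the levels."""
    levels = design.levels
    reps = n_trials // design.n_levels
    seq = np.concatenate([rng.permutation(levels) for _ in range(reps)])
    return seq


def _latent_output(p: ParticipantTruth, targets, level_mean, rng):
    """Indirect-equivalent output forces for an array of target forces."""
    pw = p.pathway
    c = pw.memory_contraction
    expected = (1.0 - c) * targets + c * level_mean
    total_sd = np.sqrt(
        pw.constant_noise_sd**2 + (pw.signal_dependent_coef * expected) ** 2
    )
    return expected + rng.normal(0.0, 1.0, size=len(targets)) * total_sd


def _records(pid, subgroup, cond, gain, targets, forces, extra=None):
    n = len(targets)
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "subgroup": subgroup,
            "condition": cond,
            "gain": gain,
            "target_force_N": targets,
            "matching_force_N": forces,
            "trial_index": np.arange(n),
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def simulate_indirect(
    p: ParticipantTruth,
    design: StudyDesign,
    rng: np.random.Generator,
    subgroup: str = "synthetic",
) -> pd.DataFrame:
    """Simulate the indirect condition: unattenuated reproduction."""
    if "indirect" not in design.conditions:
        raise ValueError("design has no indirect condition")
    n = design.trials_per_participant // len(design.conditions)
    targets = _level_sequence(design, n, rng)
    forces = _latent_output(p, targets, float(design.levels.mean()), rng)
    return _records(p.participant_id, subgroup, "indirect", 1.0, targets, forces)


def simulate_direct(
    p: ParticipantTruth,
    design: StudyDesign,
    model: str,
    rng: np.random.Generator,
    subgroup: str = "synthetic",
    gain: float = 1.0,
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Simulate the direct condition: latent indirect output through K.

    Per trial a latent indirect-equivalent force F is drawn (identical
    pipeline to :func:`simulate_indirect`) together with
    K ~ N(mean_K, sd_K); the matching force is K*F (divisive) or K+F
    (subtractive).
    """
    if "direct" not in design.conditions:
        raise ValueError("design has no direct condition")
    if model not in ("divisive", "subtractive"):
        raise ValueError(f"unknown model {model!r}")
    if n_trials is None:
        n_trials = design.trials_per_participant // (
            len(design.conditions) * len(design.gains)
        )
    targets = _level_sequence(design, n_trials, rng)
    latent = _latent_output(p, targets, float(design.levels.mean()), rng)
    k = rng.normal(p.attenuation.mean_K, p.attenuation.sd_K, size=n_trials)
    forces = k * latent if model == "divisive" else k + latent
    return _records(p.participant_id, subgroup, "direct", gain, targets, forces)


def simulate_study(
    pop: PopulationTruth,
    design: StudyDesign,
    model: str,
    n_participants: int,
    seed: int,
    subgroup: str = "synthetic",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort; returns (trials DataFrame, truth sidecar dict).

    Fully reproducible under ``seed``.  The sidecar records the population
    truth and every participant's generating parameters keyed by id.
    """
    rng = np.random.default_rng(seed)
    participants = draw_participants(pop, n_participants, rng)
    frames = []
    for p in participants:
        if "direct" in design.conditions:
            frames.append(simulate_direct(p, design, model, rng, subgroup))
        if "indirect" in design.conditions:
            frames.append(simulate_indirect(p, design, rng, subgroup))
    dataset = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    truth = {
        "seed": int(seed),
        "model": model,
        "design": design.to_dict(),
        "population": dataclasses.asdict(pop),
        "participants": {
            p.participant_id: {
                "attenuation": dataclasses.asdict(p.attenuation),
                "pathway": dataclasses.asdict(p.pathway),
            }
            for p in participants
        },
    }
    return dataset, truth


def simulate_gain_study(
    pop: PopulationTruth,
    design: StudyDesign,
    seed: int,
    model: str = "divisive",
    n_participants: int = 16,
    subgroup: str = "synthetic",
) -> tuple[pd.DataFrame, dict]:
    """Simulate a direct-only gain-manipulation study.

    Attenuation applies to the predicted force on the *passive* finger, so
    the passive-finger matching force distribution is the same in every
    gain block; the recorded active-finger force is passive/gain (column
    ``active_force_N``).
    """
    if design.conditions != ("direct",):
        raise ValueError("gain study design must be direct-only")
    rng = np.random.default_rng(seed)
    participants = draw_participants(pop, n_participants, rng)
    n_per_gain = design.trials_per_participant // (len(design.gains) * 1)
    frames = []
    for p in participants:
        blocks = []
        for gain in design.gains:
            df = simulate_direct(
                p, design, model, rng, subgroup, gain=gain, n_trials=n_per_gain
            )
            df["active_force_N"] = df["matching_force_N"] / gain
            blocks.append(df)
        block = pd.concat(blocks, ignore_index=True)
        block["trial_index"] = np.arange(len(block))
        frames.append(block)
    dataset = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS + ["active_force_N"]]
    truth = {
        "seed": int(seed),
        "model": model,
        "design": design.to_dict(),
        "population": dataclasses.asdict(pop),
        "participants": {
            p.participant_id: {
                "attenuation": dataclasses.asdict(p.attenuation),
                "pathway": dataclasses.asdict(p.pathway),
            }
            for p in participants
        },
    }
    return dataset, truth


def simulate_trace(
    matching_force: float,
    rate: float,
    rng: np.random.Generator,
    plateau_noise_sd: float = 0.0,
    duration: float = 3.0,
    ramp_time: float = 1.5,
) -> pd.DataFrame:
    """Simulate a 3-s reproduction force trace sampled at ``rate`` Hz.

    The force ramps linearly to a plateau at ``matching_force``; plateau
    noise is mean-centered within the [2.0, 2.5) s analysis window so the
    window mean equals ``matching_force`` exactly.
    """
    if rate < 20:
        raise ValueError("rate must be >= 20 Hz")
    t = np.arange(0.0, duration, 1.0 / rate)
    f = matching_force * np.clip(t / ramp_time, 0.0, 1.0)
    if plateau_noise_sd > 0:
        plateau = t >= ramp_time
        noise = np.zeros_like(f)
        noise[plateau] = rng.normal(0.0, plateau_noise_sd, size=plateau.sum())
        win = (t >= 2.0) & (t < 2.5)
        noise[win] -= noise[win].mean()
        f = f + noise
    return pd.DataFrame({"time_s": t, "force_N": f})


def write_truth(truth: dict, path) -> None:
    """Write a ground-truth sidecar as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
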