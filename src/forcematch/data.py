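"""Trial-level force-matching data: schema, IO, validation and summaries.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns of :data:`TRIAL_COLUMNS`; one row per trial.  Forces are in newtons
throughout and no unit column is carried.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "CONDITIONS",
    "TrialRecord",
    "StudyDesign",
    "read_trials",
    "write_trials",
    "validate",
    "extract_matching_force",
    "qc_exclude",
    "summarize_levels",
]

#: Canonical column order of the trials CSV.
TRIAL_COLUMNS = [
    "participant_id",
    "subgroup",
    "condition",
    "gain",
    "target_force_N",
    "matching_force_N",
    "trial_index",
]

CONDITIONS = ("direct", "indirect")

# Matching force is defined as the mean force in this window of the 3 s
# reproduction phase.
MATCH_WINDOW = (2.0, 2.5)


@dataclass(frozen=True)
class TrialRecord:
    """One force-matching trial.

    ``target_force`` is the force delivered to the passive finger by the
    torque motor; ``matching_force`` is the force the participant produced
    in reproduction.  ``gain`` is the ratio of passive-finger force to
    active-finger force (1.0 except in gain-manipulation blocks).
    """

    participant_id: str
    subgroup: str
    condition: str
    gain: float
    target_force: float
    matching_force: float
    trial_index: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.target_force > 0:
            raise ValueError("target_force must be > 0")
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    """A force-matching study design.

    Target levels are the ``n_levels`` equally spaced forces spanning
    ``[force_min, force_max]``, each tested equally often in every
    condition x gain block.
    """

    force_min: float
    force_max: float
    n_levels: int
    trials_per_participant: int
    conditions: tuple[str, ...] = ("direct", "indirect")
    gains: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.trials_per_participant < 1:
            raise ValueError("n_levels and trials_per_participant must be positive")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")
        n_cells = self.n_levels * len(self.conditions) * len(self.gains)
        if self.trials_per_participant % n_cells:
            raise ValueError(
                f"trials_per_participant={self.trials_per_participant} not divisible "
                f"by n_levels x conditions x gains = {n_cells}"
            )

    @property
    def levels(self) -> np.ndarray:
        """Equally spaced target force levels (N)."""
        return np.linspace(self.force_min, self.force_max, self.n_levels)

    @property
    def trials_per_cell(self) -> int:
        return self.trials_per_participant // (
            self.n_levels * len(self.conditions) * len(self.gains)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["subgroup"] = df["subgroup"].astype(str)
    df["condition"] = df["condition"].astype(str).str.strip().str.lower()
    return df


def read_trials(path) -> pd.DataFrame:
    """Read a trials CSV, validating schema and values.

    Condition labels are case-insensitive and normalized to lower case.
    Raises ``ValueError`` naming the offending column or row on malformed
    input.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "subgroup": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = _normalize(df[TRIAL_COLUMNS])
    for col in ("gain", "target_force_N", "matching_force_N"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if df[col].isna().any() or len(bad):
            row = int((bad[0] if len(bad) else df[col].isna().idxmax())) + 2
            raise ValueError(f"unparseable or missing value in {col!r} (file row {row})")
        df[col] = vals.astype(float)
    df["trial_index"] = pd.to_numeric(df["trial_index"], downcast=None).astype(int)
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(bad_cond.idxmax()) + 2
        raise ValueError(
            f"unknown condition {df.loc[bad_cond.idxmax(), 'condition']!r} (file row {row})"
        )
    if (df["target_force_N"] <= 0).any():
        raise ValueError("target_force_N must be > 0")
    if (df["gain"] <= 0).any():
        raise ValueError("gain must be > 0")
    dup = df.duplicated(subset=["participant_id", "condition", "trial_index"])
    if dup.any():
        raise ValueError(
            "duplicate (participant_id, condition, trial_index) at file row "
            f"{int(dup.idxmax()) + 2}"
        )
    return df


def write_trials(dataset: pd.DataFrame, path) -> None:
    """Write trials to CSV in the canonical column order."""
    dataset[TRIAL_COLUMNS].to_csv(path, index=False)


def validate(dataset: pd.DataFrame, design: StudyDesign, atol: float = 1e-6) -> list[str]:
    """Check a dataset against a design; return a list of violation strings.

    The report is empty iff every participant has exactly the design's trial
    count, all target forces sit on the design's level grid, and every
    design condition is present for every participant.
    """
    report: list[str] = []
    levels = design.levels
    for pid, grp in dataset.groupby("participant_id", sort=True):
        n = len(grp)
        if n != design.trials_per_participant:
            report.append(
                f"participant {pid}: {n} trials != {design.trials_per_participant}"
            )
        off = grp.loc[
            np.abs(grp["target_force_N"].to_numpy()[:, None] - levels).min(axis=1) > atol
        ]
        for f in sorted(set(off["target_force_N"])):
            report.append(f"participant {pid}: target force {f} N not a design level")
        conds = set(grp["condition"])
        for c in design.conditions:
            if c not in conds:
                report.append(f"participant {pid}: condition {c!r} missing")
        for g in sorted(set(grp["gain"])):
            if not np.any(np.abs(np.asarray(design.gains) - g) <= atol):
                report.append(f"participant {pid}: gain {g} not in design")
    return report


def extract_matching_force(time_s, force_n) -> float:
    """Mean force over the [2.0, 2.5) s window of a reproduction trace.

    ``time_s`` must cover the window (max(time) >= 2.5 s); the mean is the
    arithmetic mean of samples whose timestamps fall in the half-open
    window.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(force_n, dtype=float)
    if t.shape != f.shape:
        raise ValueError("time and force arrays must have the same shape")
    if t.size == 0 or t.max() < MATCH_WINDOW[1]:
        raise ValueError(
            f"trace must extend to {MATCH_WINDOW[1]} s (got max t = "
            f"{t.max() if t.size else float('nan')} s)"
        )
    in_win = (t >= MATCH_WINDOW[0]) & (t < MATCH_WINDOW[1])
    if not in_win.any():
        raise ValueError("no samples fall in the matching window")
    return float(f[in_win].mean())


def qc_exclude(
    dataset: pd.DataFrame, min_r: float = 0.0
) -> tuple[pd.DataFrame, list[str]]:
    """Exclude participants whose matching forces do not track target forces.

    A participant is dropped when the Pearson correlation between target and
    matching force, pooled across conditions, is <= ``min_r`` or undefined
    (zero variance).  Returns (kept dataset, excluded participant ids).
    """
    excluded: list[str] = []
    for pid, grp in dataset.groupby("participant_id", sort=True):
        x = grp["target_force_N"].to_numpy()
        y = grp["matching_force_N"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            excluded.append(pid)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if not np.isfinite(r) or r <= min_r:
            excluded.append(pid)
    kept = dataset[~dataset["participant_id"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def summarize_levels(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition x gain x target level mean/SD of matching force.

    SD uses the n-1 denominator and is NaN for single-trial cells.
    """
    g = dataset.groupby(
        ["participant_id", "condition", "gain", "target_force_N"], sort=True
    )["matching_force_N"]
    out = g.agg(n="size", mean_match="mean", sd_match=lambda s: s.std(ddof=1))
    out = out.reset_index().rename(columns={"target_force_N": "target_force"})
    sub = dataset.groupby("participant_id")["subgroup"].first()
    out.insert(1, "subgroup", out["participant_id"].map(sub))
    return out
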