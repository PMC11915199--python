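"""Thermal tolerance (time to immobilization) data preparation and ramp schedules.

T_imm records arrive at the individual-animal level; this module applies the
analysis exclusion rules (males and egg-bearing females out, clones with too
few remaining replicates dropped, the reference clone subsampled to a fixed
replicate count) and encodes the CT_max ramp / assay protocol as checkable
schedule tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RampSchedule",
    "apply_exclusions",
    "ramp_to_assay",
    "ctmax_from_trial",
    "assay_temperature",
]

SUBPOPULATIONS = ("historical", "modern")
GENETIC_CLUSTERS = ("historical", "mixed", "modern")

REQUIRED_COLUMNS = ("clone", "sex", "has_eggs")


def apply_exclusions(
    records: pd.DataFrame,
    min_replicates: int = 3,
    reference_clone: str | None = None,
    reference_n: int = 6,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the T_imm analysis exclusion rules; returns (clean, exclusion log).

    Rules, in order: drop males; drop egg-bearing females; drop whole clones
    left with fewer than ``min_replicates`` records; subsample the reference
    clone uniformly without replacement to ``reference_n`` replicates using
    ``seed``.  Row indices of ``records`` are preserved so the log can be
    joined back.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records must carry a {col!r} column")
    df = records.copy()
    log_rows = []

    males = df.index[df["sex"] == "male"]
    for idx in males:
        log_rows.append({"index": idx, "clone": df.at[idx, "clone"], "reason": "male"})
    df = df.drop(males)

    eggs = df.index[df["has_eggs"].astype(bool)]
    for idx in eggs:
        log_rows.append({"index": idx, "clone": df.at[idx, "clone"], "reason": "egg_bearing"})
    df = df.drop(eggs)

    counts = df["clone"].value_counts()
    thin = counts.index[counts < min_replicates]
    for clone in thin:
        for idx in df.index[df["clone"] == clone]:
            log_rows.append({"index": idx, "clone": clone, "reason": "clone_below_min_replicates"})
    df = df[~df["clone"].isin(thin)]

    if reference_clone is not None:
        ref_idx = df.index[df["clone"] == reference_clone]
        if len(ref_idx) == 0:
            raise ValueError(f"reference clone {reference_clone!r} absent after exclusions")
        if len(ref_idx) > reference_n:
            rng = np.random.default_rng(seed)
            keep = rng.choice(np.asarray(ref_idx), size=reference_n, replace=False)
            drop = [i for i in ref_idx if i not in set(keep)]
            for idx in drop:
                log_rows.append({"index": idx, "clone": reference_clone,
                                 "reason": "reference_subsampled"})
            df = df.drop(drop)

    log = pd.DataFrame(log_rows, columns=["index", "clone", "reason"])
    return df, log


@dataclass(frozen=True)
class RampSchedule:
    """Stepwise temperature ramp: ``step`` degrees every ``interval_min`` minutes."""

    start_temp: float
    end_temp: float
    step: float = 1.0
    interval_min: float = 6.0

    def __post_init__(self) -> None:
        if self.step == 0 and self.start_temp != self.end_temp:
            raise ValueError("step 0 with unequal start and end temperatures")
        if self.step != 0 and (self.end_temp - self.start_temp) * self.step < 0:
            raise ValueError("step sign must move the temperature towards the endpoint")

    @property
    def n_steps(self) -> int:
        if self.step == 0:
            return 0
        n = (self.end_temp - self.start_temp) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("endpoint is not reachable by an integer number of steps")
        return int(round(n))

    @property
    def duration_min(self) -> float:
        return self.n_steps * self.interval_min

    @property
    def mean_slope(self) -> float:
        """Mean heating rate in degrees C per minute."""
        if self.duration_min == 0:
            return 0.0
        return (self.end_temp - self.start_temp) / self.duration_min


def ramp_to_assay(schedule: RampSchedule) -> pd.DataFrame:
    """Discrete (time, temperature) event table for a ramp schedule.

    The first row is the starting temperature at time 0; each subsequent row
    is one step.  A start == end schedule yields a single row.
    """
    n = schedule.n_steps
    times = np.arange(n + 1) * schedule.interval_min
    temps = schedule.start_temp + np.arange(n + 1) * schedule.step
    if n > 0:
        temps[-1] = schedule.end_temp  # guard against float accumulation
    return pd.DataFrame({"time_min": times, "temp_c": temps})


def ctmax_from_trial(immobilization_temps: Sequence[float]) -> float:
    """CT_max: the ramp temperature at which the last animal immobilized."""
    temps = np.asarray(list(immobilization_temps), dtype=float)
    if temps.size == 0:
        raise ValueError("ctmax_from_trial requires at least one animal")
    return float(temps.max())


def assay_temperature(ctmax: float, offset: float = 2.0) -> float:
    """Assay temperature for the T_imm test: ``offset`` degrees below CT_max."""
    return ctmax - offset
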