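"""Modified Balloon Analogue Risk Task (BART) environment.

The task: on each trial the participant pumps a virtual balloon; every pump
earns points but the balloon bursts once the (hidden) burst threshold is
reached, forfeiting the trial's points.  Two 30-trial blocks differ in the
burst penalty: the low-cost (LC) block loses only the trial's points, the
high-cost (HC) block additionally deducts a fixed number of points from the
running total.  Burst thresholds for a block come from a fixed master array,
re-shuffled independently for every participant.

This module defines the task configuration, the per-balloon trial record,
threshold-array generation matching published summary statistics, trial
scoring, and CSV round-trip of trial data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LC",
    "HC",
    "BLOCKS",
    "TaskConfig",
    "TrialRecord",
    "make_burst_array",
    "score_trial",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "TRIALS_COLUMNS",
]

LC = "LC"
HC = "HC"
BLOCKS = (LC, HC)

#: column order of the trials CSV contract
TRIALS_COLUMNS = [
    "participant_id",
    "block",
    "trial_index",
    "n_pumps",
    "burst",
    "burst_threshold",
    "points_earned",
]

# Published burst-array summary statistics: (mean, sd, (min, max)).
# The LC block of the pilot used a narrower array than every other block.
MAIN_ARRAY_STATS = (12.23, 4.72, (1, 19))
PILOT_LC_ARRAY_STATS = (12.37, 3.49, (6, 18))


@dataclass(frozen=True)
class TaskConfig:
    """Block structure and scoring of the modified BART.

    Parameters
    ----------
    n_trials_per_block
        Number of balloons per block (30 in both studies).
    points_per_pump
        Points gained by each pump (10).
    low_cost_penalty
        Extra deduction after a burst in the LC block (0: only the trial's
        accumulated points are lost).
    high_cost_penalty
        Extra deduction after a burst in the HC block (1000 in the main
        study, 200 in the pilot).
    burst_thresholds
        Master array of burst thresholds for one block; a per-participant
        permutation of this array is used at run time.
    shuffle_seed
        Base seed for the per-participant shuffles.
    """

    n_trials_per_block: int = 30
    points_per_pump: int = 10
    low_cost_penalty: int = 0
    high_cost_penalty: int = 1000
    burst_thresholds: tuple[int, ...] = ()
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_block < 1:
            raise ValueError("n_trials_per_block must be positive")
        thr = tuple(int(t) for t in self.burst_thresholds)
        if not thr:
            thr = tuple(
                int(t)
                for t in make_burst_array(
                    *MAIN_ARRAY_STATS[:2],
                    MAIN_ARRAY_STATS[2],
                    self.n_trials_per_block,
                    seed=self.shuffle_seed,
                )
            )
        if len(thr) != self.n_trials_per_block:
            raise ValueError(
                "burst_thresholds length must equal n_trials_per_block"
            )
        if any(t < 1 for t in thr):
            raise ValueError("every burst threshold must be >= 1")
        object.__setattr__(self, "burst_thresholds", thr)

    def penalty(self, block: str) -> int:
        """Extra point deduction applied after a burst in *block*."""
        if block == LC:
            return self.low_cost_penalty
        if block == HC:
            return self.high_cost_penalty
        raise ValueError(f"unknown block {block!r}")

    def participant_thresholds(self, participant_index: int) -> np.ndarray:
        """Master array re-shuffled for one participant (deterministic)."""
        rng = np.random.default_rng(
            np.random.SeedSequence([self.shuffle_seed, participant_index])
        )
        return rng.permutation(np.asarray(self.burst_thresholds, dtype=int))

    # -- presets and serialization -------------------------------------

    @classmethod
    def preset(cls, name: str, shuffle_seed: int = 0) -> "TaskConfig":
        """Named task presets: ``"main"`` (HC penalty 1000) and ``"pilot"``
        (HC penalty 200, narrower LC array)."""
        if name == "main":
            return cls(high_cost_penalty=1000, shuffle_seed=shuffle_seed)
        if name == "pilot":
            return cls(high_cost_penalty=200, shuffle_seed=shuffle_seed)
        if name == "pilot-lc":
            return cls(
                high_cost_penalty=200,
                burst_thresholds=tuple(
                    make_burst_array(
                        *PILOT_LC_ARRAY_STATS[:2],
                        PILOT_LC_ARRAY_STATS[2],
                        30,
                        seed=shuffle_seed,
                    )
                ),
                shuffle_seed=shuffle_seed,
            )
        raise ValueError(f"unknown preset {name!r}")

    def to_dict(self) -> dict:
        return {
            "n_trials_per_block": self.n_trials_per_block,
            "points_per_pump": self.points_per_pump,
            "low_cost_penalty": self.low_cost_penalty,
            "high_cost_penalty": self.high_cost_penalty,
            "burst_thresholds": list(self.burst_thresholds),
            "shuffle_seed": self.shuffle_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        return cls(**{k: (tuple(v) if k == "burst_thresholds" else v) for k, v in d.items()})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in {".yml", ".yaml"}
            else json.dumps(self.to_dict(), indent=2)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "TaskConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.from_dict(d)


@dataclass(frozen=True)
class TrialRecord:
    """One balloon: how many pumps were made and how the trial ended."""

    participant_id: str
    block: str
    trial_index: int  # 1-based
    n_pumps: int
    burst: bool
    burst_threshold: int
    points_earned: int

    def validate(self, points_per_pump: int | None = None) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"{self._where()}: unknown block {self.block!r}")
        if self.trial_index < 1:
            raise ValueError(f"{self._where()}: trial_index must be 1-based")
        if self.burst_threshold < 1:
            raise ValueError(f"{self._where()}: burst_threshold must be >= 1")
        if self.n_pumps < 0:
            raise ValueError(f"{self._where()}: n_pumps must be non-negative")
        if self.burst and self.n_pumps != self.burst_threshold:
            raise ValueError(
                f"{self._where()}: burst trials must have n_pumps == burst_threshold"
            )
        if not self.burst and self.n_pumps >= self.burst_threshold:
            raise ValueError(
                f"{self._where()}: non-burst trials must have n_pumps < burst_threshold"
            )
        if points_per_pump is not None and not self.burst:
            if self.points_earned != self.n_pumps * points_per_pump:
                raise ValueError(
                    f"{self._where()}: points_earned inconsistent with n_pumps"
                )

    def _where(self) -> str:
        return f"participant {self.participant_id}, block {self.block}, trial {self.trial_index}"


def make_burst_array(
    target_mean: float,
    target_sd: float,
    target_range: Sequence[int],
    length: int,
    seed: int = 0,
    tol: float = 0.5,
    max_iter: int = 20000,
) -> np.ndarray:
    """Generate an integer burst-threshold array matching summary statistics.

    The returned array has ``min == target_range[0]`` and
    ``max == target_range[1]`` exactly, and mean and (population) SD within
    ``tol`` of the targets.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If the targets are infeasible (mean outside the range, min < 1,
        length < 2 with distinct endpoints, ...).
    """
    lo, hi = int(target_range[0]), int(target_range[1])
    if lo < 1:
        raise ValueError("burst thresholds must be >= 1")
    if lo > hi:
        raise ValueError("target_range must satisfy min <= max")
    if not (lo <= target_mean <= hi):
        raise ValueError("target_mean outside target_range: infeasible")
    if target_sd < 0:
        raise ValueError("target_sd must be non-negative")
    if lo == hi:
        if target_sd > tol:
            raise ValueError("zero range incompatible with target_sd")
        return np.full(length, lo, dtype=int)
    if length < 2:
        raise ValueError("length must be >= 2 to pin both range endpoints")

    rng = np.random.default_rng(seed)
    # start: pin the endpoints, fill the rest from a rounded normal
    x = np.clip(
        np.round(rng.normal(target_mean, max(target_sd, 0.5), size=length)), lo, hi
    ).astype(int)
    x[0], x[1] = lo, hi

    def sd(a: np.ndarray) -> float:
        return float(np.std(a))

    for _ in range(max_iter):
        mean_err = float(np.mean(x)) - target_mean
        sd_err = sd(x) - target_sd
        if abs(mean_err) <= tol * 0.8 and abs(sd_err) <= tol * 0.8:
            break
        # adjust a random free element by +/-1; accept if the move lowers
        # the (scaled) distance to the targets while preserving the pins
        i = int(rng.integers(2, length)) if length > 2 else int(rng.integers(0, 2))
        step = -1 if (mean_err > 0) else 1
        if abs(mean_err) <= tol * 0.5:
            # mean fine: do a mean-neutral spread move to fix the SD
            j = int(rng.integers(2, length)) if length > 2 else i
            if i == j:
                continue
            a, b = (i, j) if x[i] >= x[j] else (j, i)
            if sd_err < 0 and x[a] < hi and x[b] > lo:  # spread apart
                cand = x.copy()
                cand[a] += 1
                cand[b] -= 1
            elif sd_err > 0 and x[a] > x[b]:  # pull together
                cand = x.copy()
                cand[a] -= 1
                cand[b] += 1
            else:
                continue
        else:
            cand = x.copy()
            cand[i] = np.clip(cand[i] + step, lo, hi)
        d_old = (np.mean(x) - target_mean) ** 2 + (sd(x) - target_sd) ** 2
        d_new = (np.mean(cand) - target_mean) ** 2 + (sd(cand) - target_sd) ** 2
        if d_new < d_old:
            x = cand

    if abs(float(np.mean(x)) - target_mean) > tol or abs(sd(x) - target_sd) > tol:
        raise ValueError(
            "could not reach target mean/SD within tolerance; targets may be "
            f"infeasible for integer arrays of length {length}"
        )
    if x.min() != lo or x.max() != hi:
        raise ValueError("range endpoints lost during adjustment")
    rng.shuffle(x)
    return x


def score_trial(
    n_pumps: int,
    burst_threshold: int,
    block: str,
    config: TaskConfig,
    participant_id: str = "p0",
    trial_index: int = 1,
) -> TrialRecord:
    """Score one balloon.

    A trial ends in a burst exactly when the participant pumps up to the
    threshold; the trial's accumulated points are then lost and the block's
    additional penalty (0 in LC) is deducted, so ``points_earned`` is 0 minus
    the penalty.  Otherwise the participant banks ``n_pumps`` x
    ``points_per_pump``.
    """
    if n_pumps < 0:
        raise ValueError("n_pumps must be non-negative")
    if n_pumps > burst_threshold:
        raise ValueError(
            f"impossible observation: n_pumps ({n_pumps}) exceeds burst "
            f"threshold ({burst_threshold})"
        )
    burst = n_pumps == burst_threshold
    points = -config.penalty(block) if burst else n_pumps * config.points_per_pump
    rec = TrialRecord(
        participant_id=str(participant_id),
        block=block,
        trial_index=trial_index,
        n_pumps=n_pumps,
        burst=burst,
        burst_threshold=burst_threshold,
        points_earned=points,
    )
    rec.validate(config.points_per_pump)
    return rec


def trials_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Trial records as a long-format DataFrame (one row per balloon)."""
    rows = [
        {
            "participant_id": r.participant_id,
            "block": r.block,
            "trial_index": r.trial_index,
            "n_pumps": r.n_pumps,
            "burst": r.burst,
            "burst_threshold": r.burst_threshold,
            "points_earned": r.points_earned,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write trial records to the trials CSV contract (UTF-8, header row)."""
    trials_to_frame(records).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read and validate a trials CSV; raises with the offending row named."""
    df = pd.read_csv(path)
    missing = [c for c in TRIALS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        burst_raw = row["burst"]
        burst = (
            bool(burst_raw)
            if not isinstance(burst_raw, str)
            else burst_raw.strip().lower() in {"true", "1", "yes"}
        )
        rec = TrialRecord(
            participant_id=str(row["participant_id"]),
            block=str(row["block"]),
            trial_index=int(row["trial_index"]),
            n_pumps=int(row["n_pumps"]),
            burst=burst,
            burst_threshold=int(row["burst_threshold"]),
            points_earned=int(row["points_earned"]),
        )
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records
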