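"""Block-design paradigms and behavioral percept reports.

Two block-design tasks drive the method: a binocular non-rivalry (BNR)
localizer in which faces and houses alternate with rest, giving labeled
training data, and a binocular rivalry (BR) run in which a face is shown to
one eye and a house to the other, so conscious perception alternates
stochastically while the retinal input is constant.  Subjects report each
perceptual switch with a button press; those time-stamped reports are turned
into a per-volume percept vector used to score the decoder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "BlockDesign",
    "BehavioralLog",
    "PerceptVector",
    "ParadigmError",
    "UndefinedStatisticError",
    "build_design",
    "bnr_design",
    "br_design",
    "condition_labels",
    "behavioral_to_percept_vector",
    "phase_duration_stats",
    "read_behavioral_csv",
]

CONDITIONS = ("face", "house", "picture", "rest")
PERCEPTS = ("face", "house")

#: label used for task time points that precede the first behavioral report
UNKNOWN = "unknown"


class ParadigmError(ValueError):
    """Structural problem in a block design or behavioral log."""


class UndefinedStatisticError(ValueError):
    """A requested summary statistic is undefined for the given input."""


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class BlockDesign:
    """A timed block design: TR, ordered blocks, and the implied volume count.

    Volumes are 0-based; volume ``t`` covers the half-open interval
    ``[t*tr, (t+1)*tr)``, so a block boundary time belongs to the block that
    starts there.
    """

    task_name: str
    tr: float
    blocks: tuple[Block, ...]
    n_volumes: int

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def block_at(self, time_s: float) -> Block:
        for blk in self.blocks:
            if blk.onset <= time_s < blk.end:
                return blk
        raise ParadigmError(f"time {time_s} s outside the run [0, {self.duration})")


@dataclass(frozen=True)
class BehavioralLog:
    """Ordered button-press events: (time in seconds, reported percept)."""

    events: tuple[tuple[float, str], ...]

    def __post_init__(self):
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParadigmError("behavioral event times must be strictly increasing")
        for t, percept in self.events:
            if percept not in PERCEPTS:
                raise ParadigmError(f"unknown percept code {percept!r} at t={t}")
            if t < 0:
                raise ParadigmError(f"negative event time {t}")


@dataclass
class PerceptVector:
    """Per-task-time-point percept labels plus the dominance phases behind them.

    ``labels`` has one entry per task (non-rest) volume, in temporal order;
    values are 'face', 'house' or 'unknown' (before the first report).
    ``dominance_phases`` are the (percept, duration-in-seconds) intervals
    between reports, truncated at picture-block boundaries.
    """

    labels: np.ndarray
    dominance_phases: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_task_points(self) -> int:
        return len(self.labels)


def build_design(task_name: str, tr: float, block_spec: Iterable[tuple[str, float, float]]) -> BlockDesign:
    """Validate a block specification and derive the volume count.

    ``block_spec`` is an ordered iterable of ``(condition, onset_s, duration_s)``.
    Blocks must tile ``[0, total)`` without gap or overlap and every duration
    must be a positive multiple of ``tr``.
    """
    if tr <= 0:
        raise ParadigmError("tr must be positive")
    blocks = tuple(Block(c, float(o), float(d)) for c, o, d in block_spec)
    if not blocks:
        raise ParadigmError("block list is empty")
    cursor = 0.0
    for blk in blocks:
        if blk.condition not in CONDITIONS:
            raise ParadigmError(f"unknown condition {blk.condition!r}")
        if blk.duration <= 0:
            raise ParadigmError(f"non-positive duration for block at {blk.onset}")
        if not math.isclose(blk.onset, cursor, abs_tol=1e-9):
            raise ParadigmError(
                f"blocks do not tile: expected onset {cursor}, got {blk.onset}"
            )
        ratio = blk.duration / tr
        if not math.isclose(ratio, round(ratio), abs_tol=1e-9):
            raise ParadigmError(
                f"block duration {blk.duration} not a multiple of tr={tr}"
            )
        cursor = blk.end
    n_volumes = round(cursor / tr)
    return BlockDesign(task_name=task_name, tr=tr, blocks=blocks, n_volumes=n_volumes)


def _alternating_spec(conditions: Sequence[str], block_s: float, n_pairs: int):
    spec = []
    t = 0.0
    for _ in range(n_pairs):
        for cond in conditions:
            spec.append((cond, t, block_s))
            t += block_s
    return spec


def bnr_design() -> BlockDesign:
    """Canonical localizer: 5 face + 5 house + 10 rest blocks of 30 s, TR 3 s.

    Faces and houses alternate, each stimulus block followed by rest, giving
    200 volumes in 600 s.
    """
    spec = []
    t = 0.0
    for i in range(10):
        cond = "face" if i % 2 == 0 else "house"
        spec.append((cond, t, 30.0))
        t += 30.0
        spec.append(("rest", t, 30.0))
        t += 30.0
    return build_design("BNR", 3.0, spec)


def br_design() -> BlockDesign:
    """Canonical rivalry run: 15 picture + 15 rest blocks of 20 s, TR 1 s (600 volumes)."""
    return build_design("BR", 1.0, _alternating_spec(("picture", "rest"), 20.0, 15))


def condition_labels(design: BlockDesign) -> np.ndarray:
    """Per-volume condition label (the block containing each volume's onset time)."""
    labels = np.empty(design.n_volumes, dtype=object)
    for t in range(design.n_volumes):
        labels[t] = design.block_at(t * design.tr).condition
    return labels


def task_volume_indices(design: BlockDesign) -> np.ndarray:
    """Indices of non-rest volumes, in temporal order."""
    labels = condition_labels(design)
    return np.flatnonzero(labels != "rest")


def behavioral_to_percept_vector(log: BehavioralLog, design: BlockDesign) -> PerceptVector:
    """Turn button presses into per-task-volume percept labels and dominance phases.

    Each task volume takes the percept of the most recent report at or before
    its onset; task volumes preceding the first report are 'unknown' and are
    excluded from downstream success scoring.  Dominance phases are the
    intervals between consecutive reports, clipped to picture blocks (a
    percept spanning a rest break contributes one phase per picture block).
    """
    events = list(log.events)
    labels = []
    times = design.volume_times()
    conds = condition_labels(design)
    ev_times = np.array([t for t, _ in events]) if events else np.empty(0)
    for t, cond in zip(times, conds):
        if cond == "rest":
            continue
        if events:
            i = int(np.searchsorted(ev_times, t, side="right")) - 1
        else:
            i = -1
        labels.append(events[i][1] if i >= 0 else UNKNOWN)

    phases: list[tuple[str, float]] = []
    for blk in design.blocks:
        if blk.condition == "rest":
            continue
        # boundaries inside this block: block start, in-block events, block end
        cuts = [blk.onset]
        cuts += [t for t, _ in events if blk.onset < t < blk.end]
        cuts.append(blk.end)
        for a, b in zip(cuts, cuts[1:]):
            if events:
                i = int(np.searchsorted(ev_times, a, side="right")) - 1
            else:
                i = -1
            if i < 0:
                continue  # pre-first-report stretch: unknown, not a phase
            percept = events[i][1]
            if b > a:
                phases.append((percept, b - a))
    return PerceptVector(labels=np.array(labels, dtype=object), dominance_phases=phases)


def phase_duration_stats(vectors: Sequence[PerceptVector]):
    """Group summary of dominance-phase durations.

    Per subject: the arithmetic mean over all of that subject's phases (both
    percepts pooled).  Group mean is the mean of per-subject means; group SD
    is the n-1 sample SD over per-subject means.  With a single subject the
    group SD is undefined and returned as NaN with a warning.

    Returns a dict with ``per_subject_means``, ``group_mean``, ``group_sd``,
    ``min`` and ``max`` (the true range of the per-subject means).
    """
    if len(vectors) == 0:
        raise UndefinedStatisticError("no subjects supplied")
    means = []
    for i, v in enumerate(vectors):
        if not v.dominance_phases:
            raise UndefinedStatisticError(f"subject {i} has no dominance phases")
        means.append(float(np.mean([d for _, d in v.dominance_phases])))
    means_arr = np.asarray(means)
    if len(means) >= 2:
        sd = float(np.std(means_arr, ddof=1))
    else:
        warnings.warn("group SD undefined for a single subject", stacklevel=2)
        sd = float("nan")
    return {
        "per_subject_means": means_arr,
        "group_mean": float(means_arr.mean()),
        "group_sd": sd,
        "min": float(means_arr.min()),
        "max": float(means_arr.max()),
    }


def read_behavioral_csv(path) -> BehavioralLog:
    """Read a behavioral log CSV with columns ``time_s,percept``."""
    df = pd.read_csv(path)
    if not {"time_s", "percept"} <= set(df.columns):
        raise ParadigmError("behavioral CSV needs columns 'time_s' and 'percept'")
    return BehavioralLog(tuple(zip(df["time_s"].astype(float), df["percept"].astype(str))))


def write_behavioral_csv(log: BehavioralLog, path) -> None:
    pd.DataFrame(log.events, columns=["time_s", "percept"]).to_csv(path, index=False)
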