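"""Learning-phase criteria and the exposure-phase perturbation schedule.

Two practice regimes define the study groups. The stabilization group (SG)
practices until it intercepts the target on three consecutive attempts
within the 5-cm error bandwidth (one block), capped at 200 attempts. The
superstabilization group (SSG) must accrue six such blocks — counted as
non-overlapping runs of three hits — within 320 attempts. Participants who
exhaust the cap are excluded.

The exposure phase is a fixed plan of 129 trials: 111 controls at the base
target speed plus 9 fast (200 cm/s) and 9 slow (90 cm/s) perturbation
trials placed pseudorandomly so that every perturbation is flanked by
control trials (the analysis needs well-defined Pre and Post neighbors).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InvalidParameterError

__all__ = [
    "MtFeedback",
    "categorize_mt",
    "StabilizationCriterion",
    "StabilizationResult",
    "check_stabilization",
    "ScheduleEntry",
    "ExposureSchedule",
    "generate_exposure_schedule",
    "assign_groups",
]


class MtFeedback(enum.Enum):
    """Verbal movement-time feedback categories."""

    VERY_FAST = "very_fast"
    FAST = "fast"
    GOOD = "good"
    SLOW = "slow"
    VERY_SLOW = "very_slow"


def categorize_mt(mt: float) -> MtFeedback:
    """Map a movement time (ms) to its feedback category.

    The instructed categories are anchored at integers (<179, 180-199,
    200-250, 251-270, >271 ms); half-open bins close the 1-ms gaps so
    every positive real MT maps to exactly one category:
    mt < 180 very_fast; 180 <= mt < 200 fast; 200 <= mt <= 250 good;
    250 < mt <= 270 slow; mt > 270 very_slow.
    """
    if mt <= 0:
        raise InvalidParameterError("mt must be > 0")
    if mt < 180:
        return MtFeedback.VERY_FAST
    if mt < 200:
        return MtFeedback.FAST
    if mt <= 250:
        return MtFeedback.GOOD
    if mt <= 270:
        return MtFeedback.SLOW
    return MtFeedback.VERY_SLOW


@dataclass(frozen=True)
class StabilizationCriterion:
    """Performance criterion: ``blocks_required`` non-overlapping runs of
    ``run_length`` consecutive hits within ``max_attempts``."""

    run_length: int = 3
    blocks_required: int = 1
    max_attempts: int = 200
    error_bandwidth: float = 5.0

    def __post_init__(self) -> None:
        if self.run_length < 1 or self.blocks_required < 1:
            raise InvalidParameterError("run_length and blocks_required must be >= 1")
        if self.max_attempts < self.run_length * self.blocks_required:
            raise InvalidParameterError(
                "max_attempts must allow blocks_required runs of run_length"
            )
        if self.error_bandwidth <= 0:
            raise InvalidParameterError("error_bandwidth must be > 0")

    @classmethod
    def sg(cls) -> "StabilizationCriterion":
        return cls(run_length=3, blocks_required=1, max_attempts=200)

    @classmethod
    def ssg(cls) -> "StabilizationCriterion":
        return cls(run_length=3, blocks_required=6, max_attempts=320)


@dataclass(frozen=True)
class StabilizationResult:
    satisfied: bool
    attempt_satisfied: Optional[int]   # 1-based index of the crediting trial
    blocks_credited: int


def check_stabilization(hit_sequence: Sequence[bool],
                        criterion: StabilizationCriterion) -> StabilizationResult:
    """Scan a hit/miss sequence for the stabilization criterion.

    Left-to-right scan; every time ``run_length`` consecutive hits
    accumulate, one block is credited and the run counter resets
    (non-overlapping runs: six straight hits credit exactly two blocks).
    """
    hits = list(hit_sequence)
    if len(hits) > criterion.max_attempts:
        raise InvalidParameterError(
            f"sequence length {len(hits)} exceeds max_attempts "
            f"{criterion.max_attempts}"
        )
    run = 0
    blocks = 0
    for i, h in enumerate(hits, start=1):
        run = run + 1 if h else 0
        if run == criterion.run_length:
            blocks += 1
            run = 0
            if blocks == criterion.blocks_required:
                return StabilizationResult(True, i, blocks)
    return StabilizationResult(False, None, blocks)


TRIAL_KINDS = ("control", "fast", "slow")


@dataclass(frozen=True)
class ScheduleEntry:
    index: int                 # 1-based trial index within the exposure phase
    kind: str                  # control | fast | slow
    perturbation_ordinal: Optional[int]  # 1..n within kind, None for control


@dataclass(frozen=True)
class ExposureSchedule:
    """Ordered plan for the exposure phase."""

    entries: Tuple[ScheduleEntry, ...]
    min_gap: int = 2

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.entries)
        if [e.index for e in self.entries] != list(range(1, n + 1)):
            raise DataError("entries must be consecutively indexed from 1")
        for e in self.entries:
            if e.kind not in TRIAL_KINDS:
                raise DataError(f"unknown trial kind {e.kind!r}")
            if (e.kind == "control") != (e.perturbation_ordinal is None):
                raise DataError("ordinal present iff trial is perturbed")
        perturbed = [e for e in self.entries if e.kind != "control"]
        if perturbed:
            if self.entries[0].kind != "control" or self.entries[-1].kind != "control":
                raise DataError("first and last trials must be control")
            idx = [e.index for e in perturbed]
            if min(np.diff(idx), default=self.min_gap + 1) < self.min_gap + 1:
                raise DataError(
                    f"perturbations closer than min_gap={self.min_gap} controls"
                )
        for kind in ("fast", "slow"):
            ords = [e.perturbation_ordinal for e in self.entries if e.kind == kind]
            if ords != list(range(1, len(ords) + 1)):
                raise DataError(f"{kind} ordinals must run 1..n in trial order")

    # -- convenience ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def counts(self) -> Dict[str, int]:
        c = {k: 0 for k in TRIAL_KINDS}
        for e in self.entries:
            c[e.kind] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self.entries],
                "kind": [e.kind for e in self.entries],
                "perturbation_ordinal": [
                    e.perturbation_ordinal for e in self.entries
                ],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_gap: int = 2) -> "ExposureSchedule":
        required = {"index", "kind", "perturbation_ordinal"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"schedule table missing columns: {sorted(missing)}")
        entries = tuple(
            ScheduleEntry(
                int(r["index"]),
                str(r["kind"]),
                None if pd.isna(r["perturbation_ordinal"])
                else int(r["perturbation_ordinal"]),
            )
            for _, r in df.iterrows()
        )
        return cls(entries, min_gap=min_gap)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, min_gap: int = 2) -> "ExposureSchedule":
        return cls.from_frame(pd.read_csv(path), min_gap=min_gap)


def generate_exposure_schedule(seed: Union[int, np.random.Generator],
                               n_trials: int = 129,
                               n_fast: int = 9,
                               n_slow: int = 9,
                               min_gap: int = 2) -> ExposureSchedule:
    """Deterministic pseudorandom exposure plan.

    Perturbation positions are drawn uniformly over all index sets in
    ``[2, n_trials-1]`` whose consecutive positions are separated by at
    least ``min_gap`` control trials, via the gap-removal bijection
    (draw sorted positions in the compressed space, then re-expand); this
    is exact and needs no rejection loop. Fast/slow labels are then a
    seeded shuffle over the chosen positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pert = n_fast + n_slow
    if min(n_trials, n_fast, n_slow) < 0 or min_gap < 1:
        raise ConfigurationError("counts must be >= 0 and min_gap >= 1")
    # admissible interior positions after removing mandatory gaps
    span = (n_trials - 2) - (n_pert - 1) * min_gap
    if n_pert > 0 and span < n_pert:
        raise ConfigurationError(
            f"cannot place {n_pert} perturbations in {n_trials} trials "
            f"with min_gap={min_gap}"
        )
    if n_pert > 0:
        compressed = np.sort(rng.choice(span, size=n_pert, replace=False))
        positions = compressed + 2 + min_gap * np.arange(n_pert)  # 1-based, in [2, n-1]
        kinds = np.array(["fast"] * n_fast + ["slow"] * n_slow)
        rng.shuffle(kinds)
    else:
        positions = np.array([], dtype=int)
        kinds = np.array([], dtype=str)
    kind_at = dict(zip(positions.tolist(), kinds.tolist()))
    entries: List[ScheduleEntry] = []
    next_ordinal = {"fast": 1, "slow": 1}
    for i in range(1, n_trials + 1):
        kind = kind_at.get(i, "control")
        if kind == "control":
            entries.append(ScheduleEntry(i, "control", None))
        else:
            entries.append(ScheduleEntry(i, kind, next_ordinal[kind]))
            next_ordinal[kind] += 1
    return ExposureSchedule(tuple(entries), min_gap=min_gap)


def assign_groups(participants: Sequence[Tuple[str, str]],
                  seed: Union[int, np.random.Generator]) -> Dict[str, str]:
    """Sex-stratified balanced random assignment to SG / SSG.

    ``participants`` is a sequence of ``(participant_id, sex)`` pairs.
    Within each stratum, a seeded shuffle is split half/half; for an odd
    stratum the extra member goes to alternating groups across strata
    (deterministic rounding rule), and the imbalance is recorded in the
    returned mapping's order only, not hidden.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_sex: Dict[str, List[str]] = {}
    for pid, sex in participants:
        by_sex.setdefault(str(sex), []).append(str(pid))
    if len(set(pid for pid, _ in participants)) != len(participants):
        raise DataError("duplicate participant ids")
    assignment: Dict[str, str] = {}
    extra_to_sg = True
    for sex in sorted(by_sex):
        ids = sorted(by_sex[sex])
        rng.shuffle(ids)
        half = len(ids) // 2
        n_sg = half + (1 if (len(ids) % 2 and extra_to_sg) else 0)
        if len(ids) % 2:
            extra_to_sg = not extra_to_sg
        for pid in ids[:n_sg]:
            assignment[pid] = "SG"
        for pid in ids[n_sg:]:
            assignment[pid] = "SSG"
    return assignment
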