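"""Age-group assignment and cohort partitioning.

Trial-arm populations are binned by their reported mean age into eight
groups: seven 10-year bins (0-9 … 60-69) and a terminal 70-100 bin.  Bins
are half-open ``[L, L+10)`` except the last, which is closed at 100 so that
the bins tile ``[0, 100]`` exactly.  Arms without a reported mean age, or
with a mean age outside ``[0, 100]``, cannot be binned; they are excluded
from group-wise analyses and accounted for in an exclusion report rather
than silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .registry_io import ArmRecord, TrialRecord

__all__ = [
    "AgeGroup",
    "AGE_GROUPS",
    "GROUP_LABELS",
    "assign_age_group",
    "partition_arms",
    "ArmExclusion",
    "CohortPartition",
]


@dataclass(frozen=True)
class AgeGroup:
    """One of the eight analysis age bins, in years."""

    label: str
    lower: float
    upper: float  # inclusive only for the terminal bin

    def contains(self, age: float) -> bool:
        if self.upper == 100.0:
            return self.lower <= age <= self.upper
        return self.lower <= age < self.upper


AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("0-9", 0.0, 10.0),
    AgeGroup("10-19", 10.0, 20.0),
    AgeGroup("20-29", 20.0, 30.0),
    AgeGroup("30-39", 30.0, 40.0),
    AgeGroup("40-49", 40.0, 50.0),
    AgeGroup("50-59", 50.0, 60.0),
    AgeGroup("60-69", 60.0, 70.0),
    AgeGroup("70-100", 70.0, 100.0),
)

GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in AGE_GROUPS)
_GROUP_BY_LABEL = {g.label: g for g in AGE_GROUPS}


def age_group(label: str) -> AgeGroup:
    """Look up an :class:`AgeGroup` by its label (e.g. ``"20-29"``)."""
    try:
        return _GROUP_BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown age group label {label!r}; expected one of {GROUP_LABELS}")


def assign_age_group(mean_age: float | None) -> AgeGroup | None:
    """Bin a mean age into its age group, or ``None`` if it cannot be binned.

    ``None`` is returned both for a missing mean age and for ages outside
    ``[0, 100]``; callers record the reason via :func:`partition_arms`.
    """
    if mean_age is None:
        return None
    for group in AGE_GROUPS:
        if group.contains(mean_age):
            return group
    return None


@dataclass(frozen=True)
class ArmExclusion:
    trial_id: str
    arm_id: str
    reason: str  # "missing_mean_age" or "age_out_of_range"
    mean_age: float | None = None


@dataclass
class CohortPartition:
    """Arms partitioned by age group, plus the exclusion report.

    ``groups`` maps every one of the eight group labels (always all eight,
    possibly to empty lists) to ``(trial_id, ArmRecord)`` pairs.
    """

    groups: dict[str, list[tuple[str, ArmRecord]]]
    exclusions: list[ArmExclusion] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def exclusion_summary(self) -> dict[str, int]:
        return dict(Counter(e.reason for e in self.exclusions))


def partition_arms(records: Iterable[TrialRecord]) -> CohortPartition:
    """Partition every arm of a cohort into its age group.

    Each arm with an in-range mean age lands in exactly one group; the rest
    are listed in ``exclusions`` with a reason.  Group lists preserve input
    order, so the partition is deterministic.
    """
    groups: dict[str, list[tuple[str, ArmRecord]]] = {lbl: [] for lbl in GROUP_LABELS}
    exclusions: list[ArmExclusion] = []
    for trial in records:
        for arm in trial.arms:
            if arm.mean_age is None:
                exclusions.append(
                    ArmExclusion(trial.trial_id, arm.arm_id, "missing_mean_age")
                )
                continue
            group = assign_age_group(arm.mean_age)
            if group is None:
                exclusions.append(
                    ArmExclusion(
                        trial.trial_id, arm.arm_id, "age_out_of_range", arm.mean_age
                    )
                )
                continue
            groups[group.label].append((trial.trial_id, arm))
    return CohortPartition(groups=groups, exclusions=exclusions)
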