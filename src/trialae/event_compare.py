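"""Per-event incidence contrasts between an age group and the rest of the cohort.

For each (event, age group) pair, the target cohort is the set of trials
whose arms in that group report the event; each trial contributes its mean
event incidence (``subjects_affected / subjects_at_risk``, averaged over the
trial's in-group arms reporting the event).  The comparison cohort is the
set of trials reporting the same event through arms *outside* the group.  A
trial with in-group arms is assigned to the target side only, so the two
trial sets are disjoint — a requirement for a valid two-sample test.  The
two per-trial incidence samples are compared with a Welch t-test, and
events significantly elevated in a group (p below ``alpha``, default .01)
are ranked after removing commonly shared nonserious events on a
user-supplied filter list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortPartition, GROUP_LABELS
from .errors import ValidationError
from .incidence_stats import ComparisonResult, welch_t_test
from .vocabulary import UNCLASSIFIED, map_to_soc, normalize_term

__all__ = [
    "EventCohortPair",
    "TopEventResult",
    "event_incidence_table",
    "build_event_cohorts",
    "compare_event_across_groups",
    "all_event_comparisons",
    "top_events",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class EventCohortPair:
    """Target vs comparison per-trial incidence samples for one (event, group)."""

    event: str
    group: str
    target: dict[str, float]       # trial_id -> per-trial mean incidence in group
    comparison: dict[str, float]   # trial_id -> per-trial mean incidence outside
    flagged: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.target) & set(self.comparison)
        if overlap:
            raise ValidationError(
                f"event {self.event!r}, group {self.group}: target and comparison "
                f"trial sets overlap: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class TopEventResult:
    """One selected significantly elevated event in a group."""

    event: str
    group: str
    soc: str
    n_target: int
    mean_target: float
    n_comparison: int
    mean_comparison: float
    p_value: float


def event_incidence_table(
    partition: CohortPartition, term_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Long table of per-(trial, group, event) mean incidence.

    One row per trial × age group × canonical event term, with the incidence
    averaged over that trial's arms in that group reporting the event, and
    the event's SOC.  This is the shared substrate for all event cohorts.
    """
    rows = []
    for label in GROUP_LABELS:
        for trial_id, arm in partition.groups[label]:
            per_term: dict[str, list[float]] = {}
            hints: dict[str, str | None] = {}
            for ev in arm.events:
                canonical = normalize_term(ev.term)
                per_term.setdefault(canonical, []).append(
                    ev.subjects_affected / ev.subjects_at_risk
                )
                hints.setdefault(canonical, ev.soc_hint)
            for canonical, incidences in per_term.items():
                soc = (
                    map_to_soc(canonical, term_map, soc_hint=hints[canonical])
                    if term_map is not None
                    else UNCLASSIFIED
                )
                rows.append(
                    (trial_id, label, canonical, soc, float(np.mean(incidences)))
                )
    frame = pd.DataFrame(
        rows, columns=["trial_id", "group", "event", "soc", "incidence"]
    )
    if frame.empty:
        return frame
    # trial-level mean over the trial's arms in the group reporting the event
    return (
        frame.groupby(["trial_id", "group", "event"], as_index=False)
        .agg(soc=("soc", "first"), incidence=("incidence", "mean"))
    )


def build_event_cohorts(
    event: str,
    group: str,
    partition: CohortPartition,
    table: pd.DataFrame | None = None,
) -> EventCohortPair:
    """Assemble the disjoint target/comparison per-trial incidence samples.

    ``table`` may be a precomputed :func:`event_incidence_table` to avoid
    rescanning the cohort.  An event absent from the cohort yields an empty,
    flagged pair; an event with no out-of-group reports is flagged
    untestable.
    """
    if table is None:
        table = event_incidence_table(partition)
    canonical = normalize_term(event)
    sub = table[table["event"] == canonical] if not table.empty else table
    if sub is None or len(sub) == 0:
        return EventCohortPair(canonical, group, {}, {}, flagged="event absent from cohort")
    in_group = sub[sub["group"] == group]
    target = dict(zip(in_group["trial_id"], in_group["incidence"]))
    out_group = sub[(sub["group"] != group) & ~sub["trial_id"].isin(target)]
    # a trial reporting the event in several other groups contributes one value
    comparison = {
        tid: float(vals.mean())
        for tid, vals in out_group.groupby("trial_id")["incidence"]
    }
    flagged = ""
    if not target:
        flagged = "event absent from target group"
    elif not comparison:
        flagged = "untestable: no out-of-group trials report the event"
    return EventCohortPair(canonical, group, target, comparison, flagged=flagged)


def compare_event_across_groups(pair: EventCohortPair) -> ComparisonResult:
    """Welch t-test of the target vs comparison per-trial incidence samples.

    Sides with fewer than two trials produce a flagged result without a
    p-value.
    """
    res = welch_t_test(list(pair.target.values()), list(pair.comparison.values()))
    note = pair.flagged or res.note
    return ComparisonResult(
        group_a=pair.group,
        group_b="other-groups",
        estimate=res.estimate,
        se=res.se,
        t_stat=res.t_stat,
        df=res.df,
        p_value=res.p_value,
        note=note,
    )


def all_event_comparisons(
    partition: CohortPartition,
    term_map: Mapping[str, str] | None = None,
    min_trials: int = 2,
) -> list[TopEventResult]:
    """Candidate results for every testable (event, group) pair.

    A pair is testable when both sides have at least ``min_trials`` trials
    and the Welch test yields a p-value.  Returned candidates are *not* yet
    thresholded; feed them to :func:`top_events`.
    """
    table = event_incidence_table(partition, term_map)
    candidates: list[TopEventResult] = []
    if table.empty:
        return candidates
    soc_by_event = dict(zip(table["event"], table["soc"]))
    grouped = {
        (group, event): frame
        for (group, event), frame in table.groupby(["group", "event"])
    }
    by_event = dict(tuple(table.groupby("event")))
    for (group, event), in_group in grouped.items():
        target_ids = set(in_group["trial_id"])
        rest = by_event[event]
        out_group = rest[(rest["group"] != group) & ~rest["trial_id"].isin(target_ids)]
        if len(target_ids) < min_trials:
            continue
        comparison = out_group.groupby("trial_id")["incidence"].mean()
        if len(comparison) < min_trials:
            continue
        target_vals = in_group["incidence"].to_numpy()
        res = welch_t_test(target_vals, comparison.to_numpy())
        if res.p_value is None:
            continue
        candidates.append(
            TopEventResult(
                event=event,
                group=group,
                soc=soc_by_event[event],
                n_target=len(target_ids),
                mean_target=float(target_vals.mean()),
                n_comparison=int(len(comparison)),
                mean_comparison=float(comparison.mean()),
                p_value=res.p_value,
            )
        )
    return candidates


def top_events(
    candidates: Iterable[TopEventResult],
    alpha: float = DEFAULT_ALPHA,
    filter_list: frozenset[str] | Sequence[str] = frozenset(),
    elevated_only: bool = True,
) -> dict[str, list[TopEventResult]]:
    """Select and rank significantly elevated events per age group.

    Drops events on ``filter_list`` (canonical terms), keeps results with
    ``p_value < alpha`` (and, by default, a target mean above the comparison
    mean), and ranks within each group by ascending p-value, ties broken by
    descending target-group incidence.
    """
    filters = {normalize_term(t) for t in filter_list}
    selected: dict[str, list[TopEventResult]] = {label: [] for label in GROUP_LABELS}
    for cand in candidates:
        if cand.event in filters:
            continue
        if not (cand.p_value < alpha):
            continue
        if elevated_only and not (cand.mean_target > cand.mean_comparison):
            continue
        selected.setdefault(cand.group, []).append(cand)
    for group, results in selected.items():
        results.sort(key=lambda r: (r.p_value, -r.mean_target))
    return selected
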