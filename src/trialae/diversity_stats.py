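"""Adverse-event diversity: distinct event types per trial arm.

The diversity of a trial arm is the number of distinct adverse-event types
it reports (an arm reporting heart failure, dizziness and nausea has
diversity 3).  Distinctness is decided on canonical term strings
(:func:`trialae.vocabulary.normalize_term`), so case/punctuation variants
of the same event count once.  Group diversity is the arm-level mean, with
``se = sd / sqrt(n_arms)`` and a Wald 95% CI.

The per-organ-system view is a 26 × 8 matrix: for each system organ class
(SOC) and age group, the mean over the group's arms of the number of
distinct event types in that arm belonging to that SOC.  Cells backed by
fewer than 30 distinct trials are flagged low-support.  Events that resolve
to no SOC are tracked in a separate UNCLASSIFIED diagnostic row, excluded
from the 26-row matrix, so that per arm

    total diversity = Σ_SOC per-SOC diversity + unclassified count

holds exactly.  Rankings within each age group use competition ("min")
ranking by descending diversity; the total rank orders SOCs by the
unweighted mean of their eight group values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortPartition, GROUP_LABELS
from .incidence_stats import rate_ratio, wald_ci, welch_t_test
from .registry_io import ArmRecord
from .vocabulary import SOC_CLASSES, UNCLASSIFIED, map_to_soc, normalize_term

__all__ = [
    "LOW_SUPPORT_TRIALS",
    "GroupDiversitySummary",
    "SOCDiversityMatrix",
    "RankTable",
    "arm_diversity",
    "arm_soc_diversity",
    "group_diversity_summary",
    "summarize_diversity",
    "diversity_comparisons",
    "soc_diversity_matrix",
    "rank_soc_diversity",
]

#: Cells supported by fewer than this many distinct trials are flagged.
LOW_SUPPORT_TRIALS = 30


@dataclass(frozen=True)
class GroupDiversitySummary:
    """Arm-level mean diversity of one age group."""

    group: str
    n_arms: int
    mean_events_per_arm: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    empty: bool = False


@dataclass(frozen=True)
class SOCDiversityMatrix:
    """26 SOC rows × 8 age-group columns of mean distinct events per arm.

    ``support`` counts distinct trials contributing ≥1 event of the SOC in
    the group; ``low_support_mask`` flags ``support < LOW_SUPPORT_TRIALS``.
    ``unclassified`` is the diagnostic row of mean unclassified events/arm.
    """

    values: pd.DataFrame
    support: pd.DataFrame
    low_support_mask: pd.DataFrame
    unclassified: pd.Series


@dataclass(frozen=True)
class RankTable:
    """Competition ranks of the SOC diversity matrix (1 = most diverse)."""

    per_group_ranks: pd.DataFrame
    total_rank: pd.Series
    tie_flags: pd.DataFrame
    total_tie_flags: pd.Series


def _distinct_terms(arm: ArmRecord) -> list[tuple[str, str | None]]:
    """Distinct canonical terms of an arm, each with the SOC hint of its
    first occurrence."""
    seen: dict[str, str | None] = {}
    for ev in arm.events:
        canonical = normalize_term(ev.term)
        if canonical not in seen:
            seen[canonical] = ev.soc_hint
    return list(seen.items())


def arm_diversity(arm: ArmRecord, term_map: Mapping[str, str] | None = None) -> int:
    """Number of distinct adverse-event types reported by an arm.

    Distinctness is by canonical term string; ``term_map`` is accepted for
    interface symmetry with the SOC breakdown but does not affect the count.
    """
    return len(_distinct_terms(arm))


def arm_soc_diversity(arm: ArmRecord, term_map: Mapping[str, str]) -> dict[str, int]:
    """Distinct event types of an arm broken down by system organ class.

    Keys are the SOCs present in the arm (plus ``UNCLASSIFIED`` if any event
    resolves nowhere); values sum to :func:`arm_diversity`.
    """
    counts: dict[str, int] = {}
    for canonical, hint in _distinct_terms(arm):
        soc = map_to_soc(canonical, term_map, soc_hint=hint)
        counts[soc] = counts.get(soc, 0) + 1
    return counts


def group_diversity_summary(
    arms: Sequence[ArmRecord],
    term_map: Mapping[str, str] | None = None,
    group: str = "",
    level: float = 0.95,
) -> GroupDiversitySummary:
    """Mean, SE and CI of arm diversity over a group of arms.

    ``se`` is the sample standard deviation divided by ``sqrt(n_arms)``.
    With a single arm the mean is that arm's diversity and SE/CI are
    unavailable (``None``); an empty group yields a flagged empty summary.
    """
    if not arms:
        return GroupDiversitySummary(group, 0, math.nan, None, None, None, empty=True)
    values = np.array([arm_diversity(a, term_map) for a in arms], dtype=float)
    mean = float(values.mean())
    if values.size < 2:
        return GroupDiversitySummary(group, 1, mean, None, None, None)
    se = float(values.std(ddof=1) / math.sqrt(values.size))
    low, high = wald_ci(mean, se, level)
    return GroupDiversitySummary(group, int(values.size), mean, se, low, high)


def summarize_diversity(
    partition: CohortPartition,
    term_map: Mapping[str, str] | None = None,
    level: float = 0.95,
) -> dict[str, GroupDiversitySummary]:
    """Group diversity summary for each of the eight age groups."""
    return {
        label: group_diversity_summary(
            [arm for _, arm in partition.groups[label]], term_map, group=label, level=level
        )
        for label in GROUP_LABELS
    }


def diversity_comparisons(
    partition: CohortPartition,
    reference: str = "20-29",
) -> list[dict]:
    """Welch t-tests of each group's arm diversities against the reference
    group, with the mean-diversity ratio."""
    samples = {
        label: [float(arm_diversity(arm)) for _, arm in partition.groups[label]]
        for label in GROUP_LABELS
    }
    ref = samples[reference]
    rows = []
    for label in GROUP_LABELS:
        if label == reference:
            continue
        row: dict = {"group": label, "reference": reference}
        if not samples[label] or not ref:
            row["note"] = "empty group; no comparison"
        else:
            res = welch_t_test(samples[label], ref)
            mean_ref = float(np.mean(ref))
            row.update(
                diff=res.estimate,
                se=res.se,
                t=res.t_stat,
                df=res.df,
                p=res.p_value,
                ratio_vs_reference=rate_ratio(float(np.mean(samples[label])), mean_ref),
                note=res.note,
            )
        rows.append(row)
    return rows


def soc_diversity_matrix(
    partition: CohortPartition, term_map: Mapping[str, str]
) -> SOCDiversityMatrix:
    """Mean distinct events per arm for every (SOC, age group) cell.

    The cell mean is taken over *all* arms of the group (arms without events
    in the SOC contribute 0), matching the group-level events-per-arm
    normalization.  Support counts distinct trials with ≥1 event of the SOC
    in the group.
    """
    values = pd.DataFrame(0.0, index=list(SOC_CLASSES), columns=list(GROUP_LABELS))
    support = pd.DataFrame(0, index=list(SOC_CLASSES), columns=list(GROUP_LABELS))
    unclassified = pd.Series(0.0, index=list(GROUP_LABELS))
    for label in GROUP_LABELS:
        arms = partition.groups[label]
        if not arms:
            continue
        totals = {soc: 0 for soc in SOC_CLASSES}
        unc_total = 0
        trials_by_soc: dict[str, set[str]] = {soc: set() for soc in SOC_CLASSES}
        for trial_id, arm in arms:
            for soc, count in arm_soc_diversity(arm, term_map).items():
                if soc == UNCLASSIFIED:
                    unc_total += count
                else:
                    totals[soc] += count
                    trials_by_soc[soc].add(trial_id)
        n = len(arms)
        for soc in SOC_CLASSES:
            values.loc[soc, label] = totals[soc] / n
            support.loc[soc, label] = len(trials_by_soc[soc])
        unclassified[label] = unc_total / n
    mask = support < LOW_SUPPORT_TRIALS
    return SOCDiversityMatrix(
        values=values, support=support, low_support_mask=mask, unclassified=unclassified
    )


def rank_soc_diversity(matrix: SOCDiversityMatrix) -> RankTable:
    """Rank SOCs by diversity within each age group (competition ranking).

    Within each column, rank 1 is the highest diversity; tied values share
    the minimum applicable rank and are flagged.  ``total_rank`` ranks the
    26 SOCs by the unweighted mean of their eight group values.
    """
    values = matrix.values
    ranks = values.rank(axis=0, method="min", ascending=False).astype(int)
    tie_flags = values.apply(lambda col: col.duplicated(keep=False), axis=0)
    row_means = values.mean(axis=1)
    total_rank = row_means.rank(method="min", ascending=False).astype(int)
    total_ties = row_means.duplicated(keep=False)
    return RankTable(
        per_group_ranks=ranks,
        total_rank=total_rank,
        tie_flags=tie_flags,
        total_tie_flags=total_ties,
    )
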