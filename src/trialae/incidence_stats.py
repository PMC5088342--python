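"""Adverse-event incidence statistics across age groups.

Incidence within a stratum is summarized by the micro-average (pooled
proportion): total participants affected divided by total participants at
risk over all arms of the stratum.  Groups are contrasted against a
reference group (by default 20-29 years, the lowest-incidence group) with

* the risk difference between pooled proportions, with standard error
  ``sqrt(p_a(1-p_a)/n_a + p_b(1-p_b)/n_b)``,
* the incidence-rate ratio ``p_a / p_b``, and
* a two-sided Welch (unequal-variance) t-test on the per-arm incidence
  values, with Welch–Satterthwaite degrees of freedom.

Confidence intervals are normal-approximation (Wald) intervals with
``z = 1.96`` at the 95% level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortPartition, GROUP_LABELS
from .errors import ValidationError
from .registry_io import ArmRecord, effective_overall_affected

__all__ = [
    "GroupIncidenceSummary",
    "ComparisonResult",
    "arm_incidence",
    "group_micro_average",
    "risk_difference",
    "rate_ratio",
    "welch_t_test",
    "wald_ci",
    "summarize_incidence",
    "incidence_comparisons",
    "per_arm_rates",
]

DEFAULT_REFERENCE_GROUP = "20-29"


@dataclass(frozen=True)
class GroupIncidenceSummary:
    """Pooled incidence of one age group."""

    group: str
    n_arms: int
    total_at_risk: int
    total_affected: int
    micro_average: float
    arm_rates: tuple[float, ...]
    ci_low: float
    ci_high: float
    empty: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group contrast (difference or t-test)."""

    group_a: str
    group_b: str
    estimate: float
    se: float
    t_stat: float | None = None
    df: float | None = None
    p_value: float | None = None
    note: str = ""


def arm_incidence(affected: int, at_risk: int) -> float:
    """Proportion of at-risk participants affected, ``affected / at_risk``."""
    if at_risk <= 0:
        raise ValidationError(f"at_risk must be positive, got {at_risk}")
    if affected < 0 or affected > at_risk:
        raise ValidationError(
            f"affected must be in [0, at_risk]; got affected={affected}, at_risk={at_risk}"
        )
    return affected / at_risk


def wald_ci(mean: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval ``mean ± z(level)·se``.

    The 95% multiplier is fixed at 1.96; other levels use the exact normal
    quantile.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    if se < 0:
        raise ValidationError(f"standard error must be non-negative, got {se}")
    z = 1.96 if abs(level - 0.95) < 1e-12 else float(stats.norm.ppf(0.5 + level / 2.0))
    return mean - z * se, mean + z * se


def group_micro_average(
    arms: Sequence[tuple[ArmRecord, int]],
    group: str = "",
    level: float = 0.95,
) -> GroupIncidenceSummary:
    """Micro-average incidence of a group of arms.

    ``arms`` pairs each arm with its effective overall-affected count (see
    :func:`trialae.registry_io.effective_overall_affected`).  The
    micro-average is ``Σ affected / Σ enrolled``; the CI is a Wald interval
    on the pooled proportion with ``se = sqrt(p(1-p)/N)``.  An empty group
    yields a flagged empty summary with no statistics.
    """
    if not arms:
        return GroupIncidenceSummary(
            group, 0, 0, 0, math.nan, (), math.nan, math.nan, empty=True
        )
    total_at_risk = 0
    total_affected = 0
    rates = []
    for arm, affected in arms:
        if affected < 0 or affected > arm.enrolled:
            raise ValidationError(
                f"arm '{arm.arm_id}': affected count {affected} outside [0, {arm.enrolled}]"
            )
        total_at_risk += arm.enrolled
        total_affected += affected
        rates.append(affected / arm.enrolled)
    p = total_affected / total_at_risk
    se = math.sqrt(p * (1.0 - p) / total_at_risk)
    low, high = wald_ci(p, se, level)
    return GroupIncidenceSummary(
        group=group,
        n_arms=len(arms),
        total_at_risk=total_at_risk,
        total_affected=total_affected,
        micro_average=p,
        arm_rates=tuple(rates),
        ci_low=low,
        ci_high=high,
    )


def risk_difference(
    summary_a: GroupIncidenceSummary, summary_b: GroupIncidenceSummary
) -> ComparisonResult:
    """Difference of pooled proportions ``p_a − p_b`` with its standard error.

    The accompanying statistic is the normal z-test on the difference
    (``df`` reported as infinity).
    """
    if summary_a.empty or summary_b.empty:
        raise ValidationError("risk_difference requires two non-empty groups")
    p_a, n_a = summary_a.micro_average, summary_a.total_at_risk
    p_b, n_b = summary_b.micro_average, summary_b.total_at_risk
    estimate = p_a - p_b
    se = math.sqrt(p_a * (1 - p_a) / n_a + p_b * (1 - p_b) / n_b)
    if se > 0:
        z = estimate / se
        p_value = 2.0 * float(stats.norm.sf(abs(z)))
    else:
        z, p_value = 0.0, 1.0
    return ComparisonResult(
        group_a=summary_a.group,
        group_b=summary_b.group,
        estimate=estimate,
        se=se,
        t_stat=z,
        df=math.inf,
        p_value=p_value,
    )


def rate_ratio(p_a: float, p_b: float) -> float:
    """Incidence ratio ``p_a / p_b``; NaN (undefined) when ``p_b == 0``."""
    if p_b == 0:
        return math.nan
    return p_a / p_b


def welch_t_test(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> ComparisonResult:
    """Two-sided Welch (unequal-variance) t-test on two value collections.

    Degenerate inputs — fewer than two values on a side, or zero variance in
    both samples — yield a flagged result carrying the mean difference but no
    p-value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    estimate = float(a.mean() - b.mean()) if a.size and b.size else math.nan
    if a.size < 2 or b.size < 2:
        return ComparisonResult(
            "a", "b", estimate, math.nan, note="degenerate: fewer than 2 values per side"
        )
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    se = math.sqrt(var_a / a.size + var_b / b.size)
    if var_a == 0.0 and var_b == 0.0:
        return ComparisonResult(
            "a", "b", estimate, 0.0, note="degenerate: zero variance in both samples"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(
        group_a="a",
        group_b="b",
        estimate=estimate,
        se=se,
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Partition-level convenience layer
# ---------------------------------------------------------------------------


def per_arm_rates(
    partition: CohortPartition, unit: str = "arm"
) -> dict[str, list[float]]:
    """Per-group overall-incidence samples used by the group t-tests.

    ``unit="arm"`` (default) gives one value per arm
    (effective affected / enrolled); ``unit="trial"`` first averages a
    trial's arms within the group, matching an incidence-per-study reading.
    """
    if unit not in ("arm", "trial"):
        raise ValidationError(f"unit must be 'arm' or 'trial', got {unit!r}")
    out: dict[str, list[float]] = {}
    for label, arms in partition.groups.items():
        if unit == "arm":
            out[label] = [
                effective_overall_affected(arm)[0] / arm.enrolled for _, arm in arms
            ]
        else:
            per_trial: dict[str, list[float]] = {}
            for trial_id, arm in arms:
                per_trial.setdefault(trial_id, []).append(
                    effective_overall_affected(arm)[0] / arm.enrolled
                )
            out[label] = [float(np.mean(v)) for v in per_trial.values()]
    return out


def summarize_incidence(
    partition: CohortPartition, level: float = 0.95
) -> dict[str, GroupIncidenceSummary]:
    """Micro-average incidence summary for each of the eight age groups."""
    summaries = {}
    for label in GROUP_LABELS:
        arms = [
            (arm, effective_overall_affected(arm)[0])
            for _, arm in partition.groups[label]
        ]
        summaries[label] = group_micro_average(arms, group=label, level=level)
    return summaries


def incidence_comparisons(
    partition: CohortPartition,
    summaries: Mapping[str, GroupIncidenceSummary] | None = None,
    reference: str = DEFAULT_REFERENCE_GROUP,
    unit: str = "arm",
) -> list[dict]:
    """Contrast every non-reference group against the reference group.

    Returns one row per non-reference group with the risk difference (in
    percentage points), its SE, the Welch t-test on per-arm (or per-trial)
    incidence values, and the micro-average ratio versus the reference.
    Groups that cannot be compared (either side empty) are flagged.
    """
    if summaries is None:
        summaries = summarize_incidence(partition)
    if reference not in GROUP_LABELS:
        raise ValidationError(f"unknown reference group {reference!r}")
    samples = per_arm_rates(partition, unit=unit)
    ref = summaries[reference]
    rows = []
    for label in GROUP_LABELS:
        if label == reference:
            continue
        summary = summaries[label]
        row: dict = {"group": label, "reference": reference}
        if summary.empty or ref.empty:
            row["note"] = "empty group; no comparison"
            rows.append(row)
            continue
        diff = risk_difference(summary, ref)
        ttest = welch_t_test(samples[label], samples[reference])
        row.update(
            diff_pp=100.0 * diff.estimate,
            se=diff.se,
            t=ttest.t_stat,
            df=ttest.df,
            p=ttest.p_value,
            ratio_vs_reference=rate_ratio(summary.micro_average, ref.micro_average),
            note=ttest.note,
        )
        rows.append(row)
    return rows
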