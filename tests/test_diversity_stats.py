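import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import competition_ranks_desc, distinct_event_count, mean_and_se
from trialae.cohort import GROUP_LABELS, partition_arms
from trialae.diversity_stats import (
    LOW_SUPPORT_TRIALS,
    SOCDiversityMatrix,
    arm_diversity,
    arm_soc_diversity,
    group_diversity_summary,
    rank_soc_diversity,
    soc_diversity_matrix,
    summarize_diversity,
)
from trialae.registry_io import ArmRecord, EventRecord, TrialRecord
from trialae.vocabulary import SOC_CLASSES, UNCLASSIFIED


def _arm(*terms, arm_id="A1", mean_age=45.0):
    return ArmRecord(
        arm_id=arm_id,
        enrolled=100,
        mean_age=mean_age,
        events=tuple(
            EventRecord(term=t, serious=False, subjects_affected=1, subjects_at_risk=100)
            for t in terms
        ),
    )


def test_arm_diversity_worked_example():
    assert arm_diversity(_arm("heart failure", "dizziness", "nausea")) == 3


def test_arm_diversity_empty_and_dedup():
    assert arm_diversity(_arm()) == 0
    assert arm_diversity(_arm("Nausea", "nausea  ")) == 1


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.sampled_from(["a", "b", "c", "d e", "f"]), max_size=6),
    st.lists(st.sampled_from(["a", "b", "c", "d e", "f"]), max_size=4),
)
def test_arm_diversity_monotone_under_event_addition(terms, extra):
    """Adding events to an arm never decreases its diversity."""
    assert arm_diversity(_arm(*terms, *extra)) >= arm_diversity(_arm(*terms))


def test_group_summary_mean_and_single_arm():
    two = group_diversity_summary([_arm("a", "b"), _arm("a", "b", "c", "d")])
    assert two.mean_events_per_arm == 3.0
    single = group_diversity_summary([_arm("a", "b")])
    assert single.mean_events_per_arm == 2.0
    assert single.se is None and single.ci_low is None
    empty = group_diversity_summary([])
    assert empty.empty


def test_group_summary_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    pool = [f"term {i}" for i in range(40)]
    arms = [
        _arm(*rng.choice(pool, size=rng.integers(0, 25), replace=False), arm_id=f"A{i}")
        for i in range(50)
    ]
    summary = group_diversity_summary(arms)
    values = [distinct_event_count(a) for a in arms]
    mean, se = mean_and_se(values)
    assert summary.mean_events_per_arm == pytest.approx(mean, abs=1e-10)
    assert summary.se == pytest.approx(se, abs=1e-10)


def test_soc_conservation_on_synthetic_cohort(demo_cohort, term_map):
    """Per arm, Σ per-SOC distinct counts (+ unclassified) = total diversity."""
    records, _ = demo_cohort
    for trial in records:
        for arm in trial.arms:
            by_soc = arm_soc_diversity(arm, term_map)
            assert sum(by_soc.values()) == arm_diversity(arm)


def test_soc_matrix_single_soc_cohort(term_map):
    trial = TrialRecord(
        "T1", arms=(_arm("nausea", "vomiting"), _arm("diarrhea", arm_id="A2"))
    )
    matrix = soc_diversity_matrix(partition_arms([trial]), term_map)
    gi = matrix.values.loc["Gastrointestinal disorders"]
    assert gi["40-49"] == pytest.approx(1.5)
    others = matrix.values.drop(index="Gastrointestinal disorders")
    assert (others.to_numpy() == 0).all()
    assert matrix.support.loc["Gastrointestinal disorders", "40-49"] == 1


def test_unclassified_tracked_outside_matrix(term_map):
    trial = TrialRecord("T1", arms=(_arm("nausea", "made-up mystery event"),))
    matrix = soc_diversity_matrix(partition_arms([trial]), term_map)
    assert matrix.unclassified["40-49"] == pytest.approx(1.0)
    assert matrix.values.sum().sum() == pytest.approx(1.0)
    assert UNCLASSIFIED not in matrix.values.index


def test_low_support_mask_below_30_trials(term_map):
    trials = [
        TrialRecord(f"T{i}", arms=(_arm("nausea", arm_id="A1"),)) for i in range(29)
    ]
    matrix = soc_diversity_matrix(partition_arms(trials), term_map)
    assert matrix.support.loc["Gastrointestinal disorders", "40-49"] == 29
    assert bool(matrix.low_support_mask.loc["Gastrointestinal disorders", "40-49"])
    assert (matrix.low_support_mask == (matrix.support < LOW_SUPPORT_TRIALS)).all().all()


def _matrix_from_values(values: np.ndarray) -> SOCDiversityMatrix:
    frame = pd.DataFrame(values, index=list(SOC_CLASSES), columns=list(GROUP_LABELS))
    support = pd.DataFrame(100, index=frame.index, columns=frame.columns)
    return SOCDiversityMatrix(
        values=frame,
        support=support,
        low_support_mask=support < LOW_SUPPORT_TRIALS,
        unclassified=pd.Series(0.0, index=list(GROUP_LABELS)),
    )


def test_rank_strictly_decreasing_column():
    values = np.tile(np.arange(26, 0, -1, dtype=float)[:, None], (1, 8))
    ranks = rank_soc_diversity(_matrix_from_values(values))
    assert list(ranks.per_group_ranks.iloc[:, 0]) == list(range(1, 27))
    assert not ranks.tie_flags.any().any()
    assert list(ranks.total_rank) == list(range(1, 27))


def test_rank_ties_share_min_rank_and_are_flagged():
    values = np.tile(np.arange(26, 0, -1, dtype=float)[:, None], (1, 8))
    values[1, :] = values[2, :]  # tie for second place in every column
    ranks = rank_soc_diversity(_matrix_from_values(values))
    col = ranks.per_group_ranks.iloc[:, 0]
    assert col.iloc[1] == col.iloc[2] == 2
    assert col.iloc[3] == 4  # competition ranking skips the tied slot
    assert bool(ranks.tie_flags.iloc[1, 0]) and bool(ranks.tie_flags.iloc[2, 0])
    assert not bool(ranks.tie_flags.iloc[0, 0])
    assert bool(ranks.total_tie_flags.iloc[1])


def test_rank_random_matrix_agrees_with_sort_oracle():
    rng = np.random.default_rng(17)
    values = rng.integers(0, 8, size=(26, 8)).astype(float)  # integer grid forces ties
    ranks = rank_soc_diversity(_matrix_from_values(values))
    for j in range(8):
        assert list(ranks.per_group_ranks.iloc[:, j]) == competition_ranks_desc(
            list(values[:, j])
        )
    assert list(ranks.total_rank) == competition_ranks_desc(list(values.mean(axis=1)))


def test_summarize_diversity_covers_all_groups(demo_cohort, term_map):
    records, _ = demo_cohort
    summaries = summarize_diversity(partition_arms(records), term_map)
    assert set(summaries) == set(GROUP_LABELS)
    for s in summaries.values():
        if not s.empty and s.se is not None:
            assert s.ci_low <= s.mean_events_per_arm <= s.ci_high
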