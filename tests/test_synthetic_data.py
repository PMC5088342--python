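import math

import pytest

from trialae.cohort import GROUP_LABELS, partition_arms
from trialae.errors import ValidationError
from trialae.incidence_stats import summarize_incidence
from trialae.registry_io import write_trial_records
from trialae.synthetic_data import (
    SimulationConfig,
    apply_reporting_threshold,
    generate_cohort,
)


def test_same_seed_gives_byte_identical_cohorts(tmp_path):
    cfg = SimulationConfig(n_trials=15, seed=77)
    records_a, truth_a = generate_cohort(cfg)
    records_b, truth_b = generate_cohort(SimulationConfig(n_trials=15, seed=77))
    assert records_a == records_b
    assert truth_a.to_json() == truth_b.to_json()
    pa, pb = tmp_path / "a.xml", tmp_path / "b.xml"
    write_trial_records(records_a, pa)
    write_trial_records(records_b, pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_arm_and_trial_counts():
    records, _ = generate_cohort(SimulationConfig(n_trials=10, arms_per_trial=2, seed=1))
    assert len(records) == 10
    assert sum(len(t.arms) for t in records) == 20


def test_generated_cohorts_pass_registry_validation():
    for seed in (0, 1, 2):
        records, _ = generate_cohort(
            SimulationConfig(n_trials=10, arms_per_trial=(1, 4), seed=seed)
        )
        for trial in records:
            trial.validate()  # raises on any invariant violation


def test_overall_affected_consistent_with_events():
    records, _ = generate_cohort(SimulationConfig(n_trials=20, seed=3))
    for trial in records:
        for arm in trial.arms:
            if not arm.events:
                assert arm.overall_affected == 0
                continue
            largest = max(ev.subjects_affected for ev in arm.events)
            total = sum(ev.subjects_affected for ev in arm.events)
            assert largest <= arm.overall_affected <= min(arm.enrolled, total)


def test_mean_ages_land_in_assigned_bins():
    records, truth = generate_cohort(SimulationConfig(n_trials=30, seed=4))
    part = partition_arms(records)
    for label, arms in part.groups.items():
        for trial_id, arm in arms:
            assert truth.arm_groups[f"{trial_id}/{arm.arm_id}"] == label


def test_single_group_incidence_recovery():
    """A group generated with p=0.30 recovers it within 3 binomial SEs."""
    target = dict.fromkeys(GROUP_LABELS, 0.25) | {"50-59": 0.30}
    cfg = SimulationConfig(n_trials=200, seed=5, group_incidence=target)
    records, truth = generate_cohort(cfg)
    assert truth.overall_incidence["50-59"] == pytest.approx(0.30, abs=1e-9)
    summary = summarize_incidence(partition_arms(records))["50-59"]
    se = math.sqrt(0.30 * 0.70 / summary.total_at_risk)
    assert abs(summary.micro_average - 0.30) <= 3 * se


def test_expected_diversity_grows_with_pool_richness():
    """At equal overall incidence, groups whose effective event pools are
    richer (rare events up-weighted with group index) have strictly larger
    expected diversity."""
    from trialae.synthetic_data import default_group_effect

    cfg = SimulationConfig(
        n_trials=5,
        seed=6,
        group_incidence={g: 0.25 for g in GROUP_LABELS},
        group_effect=default_group_effect(),
    )
    _, truth = generate_cohort(cfg)
    values = [truth.expected_diversity[g] for g in GROUP_LABELS]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_zero_multiplier_removes_terms_from_a_group():
    pool = {"Gastrointestinal disorders": [("nausea", 0.3), ("vomiting", 0.2)]}
    effect = {("vomiting", g): 0.0 for g in GROUP_LABELS}
    cfg = SimulationConfig(
        n_trials=20, seed=8, event_pool=pool, group_effect=effect, group_incidence=None
    )
    records, truth = generate_cohort(cfg)
    assert all(truth.event_probs[g]["vomiting"] == 0.0 for g in GROUP_LABELS)
    terms = {ev.term for t in records for arm in t.arms for ev in arm.events}
    assert terms <= {"nausea"}


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_trials=0),
        dict(enrollment=(100, 50)),
        dict(arms_per_trial=0),
        dict(serious_fraction=1.5),
        dict(reporting_threshold=-0.1),
        dict(age_group_weights={g: 1.0 for g in GROUP_LABELS}),
        dict(group_incidence={g: 1.5 for g in GROUP_LABELS}),
        dict(event_pool={}),
    ],
)
def test_invalid_configs_rejected_before_generation(kwargs):
    with pytest.raises(ValidationError):
        generate_cohort(SimulationConfig(**kwargs))


# ---------------------------------------------------------------------------
# reporting threshold
# ---------------------------------------------------------------------------


def _threshold_cohort():
    return generate_cohort(SimulationConfig(n_trials=25, seed=9))[0]


def test_threshold_zero_is_identity():
    records = _threshold_cohort()
    assert apply_reporting_threshold(records, 0.0) == list(records)


def test_threshold_rule_per_trial():
    records = apply_reporting_threshold(_threshold_cohort(), 0.05)
    original = {t.trial_id: t for t in _threshold_cohort()}
    for trial in records:
        orig = original[trial.trial_id]
        max_freq = {}
        for arm in orig.arms:
            for ev in arm.events:
                if not ev.serious:
                    freq = ev.subjects_affected / ev.subjects_at_risk
                    max_freq[ev.term] = max(max_freq.get(ev.term, 0.0), freq)
        for arm in trial.arms:
            for ev in arm.events:
                # every surviving nonserious event exceeds 5% in some arm
                assert ev.serious or max_freq[ev.term] > 0.05
        for arm_orig, arm_new in zip(orig.arms, trial.arms):
            kept = {ev.term for ev in arm_new.events}
            for ev in arm_orig.events:
                if ev.serious:
                    assert ev.term in kept  # serious events always retained
                elif max_freq.get(ev.term, 0.0) > 0.05:
                    assert ev.term in kept  # above-threshold events retained
            # overall_affected untouched, counts never increase
            assert arm_new.overall_affected == arm_orig.overall_affected
            assert len(arm_new.events) <= len(arm_orig.events)
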