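"""Synthetic registry-dialect trial cohorts with known ground truth.

The generator emulates the structure of registry results data: trials with
one or more arms, per-arm enrollment and mean age, per-event
affected/at-risk counts, serious vs nonserious events, and (optionally) the
registry convention of omitting nonserious events below a 5% frequency.

Per arm, the mechanics are participant-level: the arm draws an age group
(by the configured weights) and a mean age uniformly inside its bin, an
enrollment, and then an enrollment × events Bernoulli matrix in which
participant i experiences event j with the group's event probability.
Column sums give ``subjects_affected`` (marginally Binomial), the row-wise
"any event" count gives a consistent ``overall_affected``, and events with
zero affected participants are omitted, as a registry table would.  Events
are independent across participants and across event types.

When a per-group overall incidence ``p_g`` is configured, the group's event
probabilities are rescaled by a common factor so that the probability a
participant experiences at least one event, ``1 − Π_j (1 − q_j)``, equals
``p_g`` exactly; relative differences between events (and any group-effect
multipliers) are preserved.  The resolved probabilities, the exact overall
incidence and the expected arm diversity per group are serialized as ground
truth, sufficient to score parameter recovery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import AGE_GROUPS, GROUP_LABELS
from .errors import ValidationError
from .registry_io import ArmRecord, EventRecord, TrialRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "apply_reporting_threshold",
    "default_event_pool",
    "DEFAULT_GROUP_INCIDENCE",
    "DEFAULT_AGE_GROUP_WEIGHTS",
]

# Registry-style cohort shape: pediatric trials are comparatively rare and
# middle-aged adult trials dominate.
DEFAULT_AGE_GROUP_WEIGHTS: dict[str, float] = {
    "0-9": 0.04,
    "10-19": 0.05,
    "20-29": 0.10,
    "30-39": 0.15,
    "40-49": 0.20,
    "50-59": 0.20,
    "60-69": 0.16,
    "70-100": 0.10,
}

# Illustrative overall-incidence profile: peaks in young children and the
# fifties, trough in young adults.  Not calibrated to any corpus.
DEFAULT_GROUP_INCIDENCE: dict[str, float] = {
    "0-9": 0.3141,
    "10-19": 0.24,
    "20-29": 0.2076,
    "30-39": 0.25,
    "40-49": 0.28,
    "50-59": 0.3009,
    "60-69": 0.29,
    "70-100": 0.28,
}


def default_event_pool() -> dict[str, list[tuple[str, float]]]:
    """Illustrative per-SOC event pool: {soc: [(term, base probability)]}.

    Common events carry base probabilities of a few percent; a tail of rarer
    events fills out the diversity spectrum.  All terms are present in the
    packaged default term map.
    """
    return {
        "Infections and infestations": [
            ("nasopharyngitis", 0.06),
            ("pharyngitis", 0.03),
            ("upper respiratory tract infection", 0.04),
            ("urinary tract infection", 0.02),
            ("pneumonia", 0.012),
            ("influenza", 0.02),
            ("sinusitis", 0.015),
            ("bronchitis", 0.012),
        ],
        "Gastrointestinal disorders": [
            ("nausea", 0.08),
            ("diarrhea", 0.06),
            ("vomiting", 0.04),
            ("constipation", 0.03),
            ("abdominal pain", 0.025),
            ("dyspepsia", 0.012),
        ],
        "General disorders": [
            ("fatigue", 0.07),
            ("pyrexia", 0.03),
            ("asthenia", 0.02),
            ("edema peripheral", 0.012),
            ("chills", 0.01),
        ],
        "Nervous system disorders": [
            ("headache", 0.10),
            ("dizziness", 0.05),
            ("somnolence", 0.015),
            ("tremor", 0.008),
            ("syncope", 0.005),
        ],
        "Cardiac disorders": [
            ("palpitations", 0.01),
            ("atrial fibrillation", 0.006),
            ("tachycardia", 0.008),
            ("myocardial infarction", 0.004),
            ("heart failure", 0.004),
        ],
        "Vascular disorders": [
            ("hypertension", 0.03),
            ("hypotension", 0.012),
            ("flushing", 0.01),
            ("deep vein thrombosis", 0.004),
        ],
        "Respiratory, thoracic and mediastinal disorders": [
            ("cough", 0.04),
            ("dyspnea", 0.02),
            ("oropharyngeal pain", 0.015),
            ("epistaxis", 0.008),
        ],
        "Musculoskeletal and connective tissue disorders": [
            ("back pain", 0.04),
            ("arthralgia", 0.035),
            ("myalgia", 0.02),
            ("pain in extremity", 0.015),
            ("muscle spasms", 0.01),
        ],
        "Psychiatric disorders": [
            ("insomnia", 0.03),
            ("anxiety", 0.015),
            ("depression", 0.012),
            ("agitation", 0.005),
        ],
        "Skin and subcutaneous tissue disorders": [
            ("rash", 0.035),
            ("pruritus", 0.02),
            ("alopecia", 0.01),
            ("dry skin", 0.008),
        ],
        "Metabolism and nutrition disorders": [
            ("decreased appetite", 0.025),
            ("hyperglycemia", 0.01),
            ("hypokalemia", 0.008),
            ("dehydration", 0.006),
        ],
        "Blood and lymphatic system disorders": [
            ("anemia", 0.02),
            ("neutropenia", 0.01),
            ("thrombocytopenia", 0.008),
        ],
        "Investigations": [
            ("weight decreased", 0.012),
            ("alanine aminotransferase increased", 0.01),
            ("weight increased", 0.01),
        ],
        "Renal and urinary disorders": [
            ("dysuria", 0.006),
            ("hematuria", 0.005),
        ],
        "Injury, poisoning and procedural complications": [
            ("fall", 0.012),
            ("contusion", 0.008),
            ("procedural pain", 0.01),
        ],
        "Eye disorders": [
            ("conjunctivitis", 0.008),
            ("vision blurred", 0.006),
        ],
        "Ear and labyrinth disorders": [
            ("vertigo", 0.008),
            ("tinnitus", 0.005),
        ],
        "Immune system disorders": [
            ("hypersensitivity", 0.006),
            ("seasonal allergy", 0.005),
        ],
        "Endocrine disorders": [
            ("hypothyroidism", 0.004),
        ],
        "Reproductive system and breast disorders": [
            ("dysmenorrhea", 0.005),
            ("breast pain", 0.003),
        ],
        "Pregnancy, puerperium and perinatal conditions": [
            ("abortion spontaneous", 0.003),
        ],
        "Congenital, familial and genetic disorders": [
            ("congenital anomaly", 0.002),
        ],
        "Neoplasms benign, malignant and unspecified": [
            ("basal cell carcinoma", 0.003),
        ],
        "Hepatobiliary disorders": [
            ("hyperbilirubinemia", 0.004),
            ("cholelithiasis", 0.003),
        ],
        "Surgical and medical procedures": [
            ("blood transfusion", 0.004),
        ],
        "Social circumstances": [
            ("alcohol use", 0.002),
        ],
    }


def default_group_effect() -> dict[tuple[str, str], float]:
    """Illustrative age effects: rare events (base probability < 0.02) grow
    more likely with age, so arm diversity rises across the age groups even
    at a fixed overall incidence."""
    effect: dict[tuple[str, str], float] = {}
    pool = default_event_pool()
    for g_idx, label in enumerate(GROUP_LABELS):
        mult = 0.55 + 0.28 * g_idx
        for terms in pool.values():
            for term, base in terms:
                if base < 0.02:
                    effect[(term, label)] = mult
    return effect


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``group_incidence`` maps each age-group label to the target probability
    that a participant experiences at least one event; set it to ``None``
    to use the raw event probabilities without calibration.
    ``group_effect`` maps ``(term, group label)`` to a probability
    multiplier applied before calibration.
    """

    n_trials: int = 200
    arms_per_trial: int | tuple[int, int] = 2
    enrollment: tuple[int, int] = (50, 200)
    age_group_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_GROUP_WEIGHTS)
    )
    group_incidence: Mapping[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_GROUP_INCIDENCE)
    )
    event_pool: Mapping[str, Sequence[tuple[str, float]]] = field(
        default_factory=default_event_pool
    )
    group_effect: Mapping[tuple[str, str], float] = field(
        default_factory=default_group_effect
    )
    serious_fraction: float = 0.10
    reporting_threshold: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValidationError("n_trials must be positive")
        arms = self.arms_per_trial
        if isinstance(arms, int):
            if arms <= 0:
                raise ValidationError("arms_per_trial must be positive")
        else:
            lo, hi = arms
            if lo <= 0 or hi < lo:
                raise ValidationError(f"invalid arms_per_trial range {arms}")
        lo, hi = self.enrollment
        if lo <= 0 or hi < lo:
            raise ValidationError(f"invalid enrollment range {self.enrollment}")
        weights = [self.age_group_weights.get(lbl, 0.0) for lbl in GROUP_LABELS]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("age_group_weights must be non-negative and sum to 1")
        if self.group_incidence is not None:
            for lbl in GROUP_LABELS:
                p = self.group_incidence.get(lbl)
                if p is None or not 0.0 < p < 1.0:
                    raise ValidationError(
                        f"group_incidence['{lbl}'] must be in (0, 1), got {p}"
                    )
        if not self.event_pool or not any(self.event_pool.values()):
            raise ValidationError("event_pool must contain at least one term")
        for soc, terms in self.event_pool.items():
            for term, prob in terms:
                if not 0.0 <= prob <= 1.0:
                    raise ValidationError(
                        f"base probability of {term!r} must be in [0, 1], got {prob}"
                    )
        if not 0.0 <= self.serious_fraction <= 1.0:
            raise ValidationError("serious_fraction must be in [0, 1]")
        if not 0.0 <= self.reporting_threshold <= 1.0:
            raise ValidationError("reporting_threshold must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generator ground truth, sufficient to score parameter recovery."""

    arm_groups: dict[str, str]               # "trial_id/arm_id" -> group label
    event_probs: dict[str, dict[str, float]]  # group label -> {term: probability}
    overall_incidence: dict[str, float]       # group label -> P(>=1 event)
    expected_diversity: dict[str, float]      # group label -> E[distinct events/arm]
    serious_terms: list[str]
    term_soc: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "arm_groups": self.arm_groups,
                "event_probs": self.event_probs,
                "overall_incidence": self.overall_incidence,
                "expected_diversity": self.expected_diversity,
                "serious_terms": self.serious_terms,
                "term_soc": self.term_soc,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _calibrate_scale(q: np.ndarray, target: float) -> float:
    """Common scale ``s`` such that ``1 - prod(1 - clip(s*q, 0, 1)) == target``.

    Monotone bisection; warns and returns the clipping limit if the target
    is unreachable even with every probability at 1 (only possible when the
    pool is empty of positive probabilities).
    """
    q = np.asarray(q, dtype=float)
    positive = q[q > 0]
    if positive.size == 0:
        raise ValidationError("cannot calibrate: all event probabilities are zero")

    def miss(s: float) -> float:
        clipped = np.clip(s * q, 0.0, 1.0)
        if np.any(clipped >= 1.0):
            return 1.0 - target
        return 1.0 - float(np.exp(np.sum(np.log1p(-clipped)))) - target

    lo, hi = 0.0, 1.0
    while miss(hi) < 0.0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid targets < 1
            warnings.warn("incidence target unreachable; probabilities clipped at 1")
            return hi
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if miss(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expected_diversity(q: np.ndarray, enrollment: tuple[int, int]) -> float:
    """E over enrollment n ~ U{lo..hi} of Σ_j (1 − (1 − q_j)^n)."""
    lo, hi = enrollment
    n = np.arange(lo, hi + 1)
    # (n_enroll, n_terms) survival matrix; pools are small so this is cheap
    surv = np.power.outer(1.0 - np.asarray(q, dtype=float), n.astype(float))
    return float(np.mean(np.sum(1.0 - surv, axis=0)))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[TrialRecord], GroundTruth]:
    """Draw a synthetic cohort and its ground truth.

    Deterministic under a fixed ``config.seed``: the same configuration
    yields a field-identical cohort on every call.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    terms: list[str] = []
    socs: list[str] = []
    base: list[float] = []
    for soc in sorted(config.event_pool):
        for term, prob in config.event_pool[soc]:
            terms.append(term)
            socs.append(soc)
            base.append(prob)
    base_arr = np.array(base, dtype=float)
    n_terms = len(terms)
    term_soc = dict(zip(terms, socs))

    serious_mask = rng.random(n_terms) < config.serious_fraction

    # Resolve per-group event probabilities (with calibration when a target
    # overall incidence is configured).
    q_by_group: dict[str, np.ndarray] = {}
    overall: dict[str, float] = {}
    expected_div: dict[str, float] = {}
    for label in GROUP_LABELS:
        mult = np.array(
            [config.group_effect.get((term, label), 1.0) for term in terms]
        )
        q = np.clip(base_arr * mult, 0.0, 1.0)
        if config.group_incidence is not None:
            scale = _calibrate_scale(q, config.group_incidence[label])
            q = np.clip(scale * q, 0.0, 1.0)
        q_by_group[label] = q
        overall[label] = 1.0 - float(np.exp(np.sum(np.log1p(-np.minimum(q, 1.0 - 1e-15)))))
        expected_div[label] = _expected_diversity(q, config.enrollment)

    weights = np.array([config.age_group_weights.get(lbl, 0.0) for lbl in GROUP_LABELS])
    weights = weights / weights.sum()
    e_lo, e_hi = config.enrollment

    trials: list[TrialRecord] = []
    arm_groups: dict[str, str] = {}
    for t_idx in range(config.n_trials):
        trial_id = f"T{t_idx:05d}"
        if isinstance(config.arms_per_trial, int):
            n_arms = config.arms_per_trial
        else:
            a_lo, a_hi = config.arms_per_trial
            n_arms = int(rng.integers(a_lo, a_hi + 1))
        arms = []
        for a_idx in range(n_arms):
            g_idx = int(rng.choice(len(GROUP_LABELS), p=weights))
            group = AGE_GROUPS[g_idx]
            mean_age = float(rng.uniform(group.lower, group.upper))
            enrolled = int(rng.integers(e_lo, e_hi + 1))
            q = q_by_group[group.label]
            matrix = rng.random((enrolled, n_terms)) < q
            affected = matrix.sum(axis=0)
            overall_affected = int(matrix.any(axis=1).sum())
            events = tuple(
                EventRecord(
                    term=terms[j],
                    serious=bool(serious_mask[j]),
                    subjects_affected=int(affected[j]),
                    subjects_at_risk=enrolled,
                    soc_hint=socs[j],
                )
                for j in range(n_terms)
                if affected[j] > 0
            )
            arm_id = f"A{a_idx + 1}"
            arm_groups[f"{trial_id}/{arm_id}"] = group.label
            arms.append(
                ArmRecord(
                    arm_id=arm_id,
                    title=f"Arm {a_idx + 1}",
                    enrolled=enrolled,
                    mean_age=mean_age,  # unrounded so bin recovery is exact
                    overall_affected=overall_affected,
                    events=events,
                )
            )
        trials.append(TrialRecord(trial_id=trial_id, arms=tuple(arms)))

    truth = GroundTruth(
        arm_groups=arm_groups,
        event_probs={
            lbl: {terms[j]: float(q_by_group[lbl][j]) for j in range(n_terms)}
            for lbl in GROUP_LABELS
        },
        overall_incidence=overall,
        expected_diversity=expected_div,
        serious_terms=[terms[j] for j in range(n_terms) if serious_mask[j]],
        term_soc=term_soc,
    )
    if config.reporting_threshold > 0:
        trials = apply_reporting_threshold(trials, config.reporting_threshold)
    return trials, truth


def apply_reporting_threshold(
    records: Sequence[TrialRecord], threshold: float
) -> list[TrialRecord]:
    """Emulate the registry's nonserious-event reporting threshold.

    A nonserious event is kept in a trial iff its frequency
    (affected/at-risk) exceeds ``threshold`` in at least one arm of that
    trial; serious events are always kept.  ``overall_affected`` is left
    unchanged (the registry total reflects all occurrences, reported or
    not).  ``threshold == 0`` is the identity.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    if threshold == 0.0:
        return list(records)
    out = []
    for trial in records:
        keep: set[str] = set()
        for arm in trial.arms:
            for ev in arm.events:
                if not ev.serious and ev.subjects_affected / ev.subjects_at_risk > threshold:
                    keep.add(ev.term)
        new_arms = tuple(
            ArmRecord(
                arm_id=arm.arm_id,
                title=arm.title,
                enrolled=arm.enrolled,
                mean_age=arm.mean_age,
                overall_affected=arm.overall_affected,
                events=tuple(
                    ev for ev in arm.events if ev.serious or ev.term in keep
                ),
            )
            for arm in trial.arms
        )
        out.append(
            TrialRecord(
                trial_id=trial.trial_id,
                sponsor_type=trial.sponsor_type,
                intervention=trial.intervention,
                arms=new_arms,
            )
        )
    return out
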