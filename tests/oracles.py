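"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written from first principles with plain loops so the
checks stay independent of the implementation path they verify.
"""

from __future__ import annotations

import math

from scipy import stats


def pooled_proportion(pairs):
    """Σ affected / Σ at-risk over (affected, at_risk) pairs."""
    num = 0
    den = 0
    for affected, at_risk in pairs:
        num += affected
        den += at_risk
    return num / den


def mean_and_se(values):
    """Sample mean and standard error (sd / sqrt(n)) by explicit loops."""
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


def welch_t(sample_a, sample_b):
    """Textbook Welch t statistic, Welch–Satterthwaite df and two-sided p."""
    na, nb = len(sample_a), len(sample_b)
    ma = sum(sample_a) / na
    mb = sum(sample_b) / nb
    va = sum((x - ma) ** 2 for x in sample_a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in sample_b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def competition_ranks_desc(values):
    """Competition ("min") ranks of a sequence, 1 = largest value.

    Rank of x = 1 + number of values strictly greater than x.
    """
    return [1 + sum(1 for other in values if other > v) for v in values]


def distinct_event_count(arm):
    """Arm diversity recomputed with an inline normalizer."""
    import re

    seen = set()
    for ev in arm.events:
        canon = re.sub(r"\s+", " ", re.sub(r"[^\w\s]+", " ", ev.term.lower())).strip()
        seen.add(canon)
    return len(seen)
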