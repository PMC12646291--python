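"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

import itertools
import math

import numpy as np


def enumerate_totals(weights, record_factory, compute):
    """All achievable totals by exhaustive product over factor levels."""
    reps = [factor.representatives() for factor in weights]
    fields = [factor.field for factor in weights]
    totals = []
    for combo in itertools.product(*reps):
        record = record_factory(**dict(zip(fields, combo)))
        totals.append(compute(record, weights).total)
    return totals


def chi2_2x2_closed_form(a, b, c, d):
    """N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (mass rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    return sum(table_prob(x) for x in range(lo, hi + 1)
               if table_prob(x) <= p_obs * (1 + 1e-9))


def mann_whitney_pair_count(x, y):
    """U = min(U1, U2) by O(n1*n2) pair counting with half-ties."""
    u1 = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u1 += 1.0
            elif xi == yj:
                u1 += 0.5
    return min(u1, len(x) * len(y) - u1)


def auc_pair_count(scores, labels):
    """Concordance probability: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_valid_record_kwargs(rng):
    """Random factor values spanning every level (for property tests)."""
    return dict(
        sex=str(rng.choice(["male", "female"])),
        age=int(rng.integers(18, 46)),
        bmi=float(rng.uniform(19, 41)),
        hairy_back=bool(rng.random() < 0.5),
        diabetes=bool(rng.random() < 0.5),
        prior_recurrence=bool(rng.random() < 0.5),
        n_midline_pits=int(rng.integers(0, 16)),
        lateral_pits=bool(rng.random() < 0.5),
        distance_to_anus_cm=float(rng.uniform(1, 10)),
        prior_abscess=bool(rng.random() < 0.5),
    )
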