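"""Synthetic patient cohorts.

Three generators live here:

* :func:`reconstruct_fixture` — a deterministic 156-patient cohort whose
  per-group categorical counts match the published two-group comparison
  exactly, and in which exactly 12 recurrent and 2 non-recurrent patients
  reach the high-risk cutoff of 21.  The joint covariate structure is not
  published, so this is one admissible completion of the printed margins:
  constrained greedy assignment for the categorical factors, quantile
  spacing of clipped normals for the continuous fields.
* :func:`simulate_conditional` — outcome first, then covariates drawn
  independently given the outcome (prevalences/moments from a spec).
* :func:`simulate_prospective` — covariates first from marginal
  prevalences, then outcome from a logistic link on the score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy import stats as sps
from scipy.special import expit

from .errors import ConfigError
from .records import FEMALE, MALE, PatientRecord
from .score import DEFAULT_CUTOFF, WeightTable, compute_score, default_weight_table

FIXTURE_VERSION = "1.0.0"
FIXTURE_PROVENANCE = "deterministic-margin-completion"

CONDITIONAL = "conditional"
PROSPECTIVE = "prospective"

#: Binary covariates a spec may parameterise (record field or derived flag).
_BINARY_FIELDS = {
    "male": None,  # handled via sex
    "diabetes": "diabetes",
    "prior_recurrence": "prior_recurrence",
    "postop_infection": "postop_infection",
    "lateral_pits": "lateral_pits",
    "hairy_back": "hairy_back",
    "distance_lt5": None,  # handled via distance_to_anus_cm
    "prior_abscess": "prior_abscess",
    "wound_dehiscence": "wound_dehiscence",
}


# ---------------------------------------------------------------------------
# specs

@dataclass
class CohortSpec:
    """Generative parameters for the stochastic simulators."""

    mode: str
    n_total: int
    binary: dict
    pits: object  # conditional: {"p_not": [...], "p_rec": [...]}; prospective: [...]
    continuous: dict
    n_recurrent: Optional[int] = None
    beta0: Optional[float] = None
    beta1: Optional[float] = None
    target_prevalence: Optional[float] = None

    def validate(self) -> None:
        if self.mode not in (CONDITIONAL, PROSPECTIVE):
            raise ConfigError(f"mode: must be '{CONDITIONAL}' or '{PROSPECTIVE}'")
        if not isinstance(self.n_total, int) or self.n_total < 2:
            raise ConfigError("n_total: must be an integer >= 2")
        for name in self.binary:
            if name not in _BINARY_FIELDS:
                raise ConfigError(f"binary.{name}: unknown covariate")
        if self.mode == CONDITIONAL:
            if self.n_recurrent is None or not 0 < self.n_recurrent < self.n_total:
                raise ConfigError("n_recurrent: must satisfy 0 < n_recurrent < n_total")
            for name, p in self.binary.items():
                for key in ("p_not", "p_rec"):
                    v = p.get(key) if isinstance(p, dict) else None
                    if v is None or not 0 <= v <= 1:
                        raise ConfigError(f"binary.{name}.{key}: must be in [0, 1]")
            for key in ("p_not", "p_rec"):
                probs = self.pits.get(key) if isinstance(self.pits, dict) else None
                if probs is None or len(probs) != 3 or abs(sum(probs) - 1) > 1e-6 \
                        or min(probs) < 0:
                    raise ConfigError(f"pits.{key}: must be 3 probabilities summing to 1")
        else:
            for name, p in self.binary.items():
                if not isinstance(p, (int, float)) or not 0 <= p <= 1:
                    raise ConfigError(f"binary.{name}: must be a probability")
            if len(self.pits) != 3 or abs(sum(self.pits) - 1) > 1e-6 or min(self.pits) < 0:
                raise ConfigError("pits: must be 3 probabilities summing to 1")
            if self.beta1 is None:
                raise ConfigError("beta1: required in prospective mode")
            if self.beta0 is None and self.target_prevalence is None:
                raise ConfigError("beta0 or target_prevalence required in prospective mode")
        for name, c in self.continuous.items():
            for key in ("lo", "hi"):
                if key not in c:
                    raise ConfigError(f"continuous.{name}.{key}: missing")
            moment_keys = ("not", "rec") if self.mode == CONDITIONAL else ("marginal",)
            for key in moment_keys:
                ms = c.get(key)
                if ms is None or len(ms) != 2 or ms[1] < 0:
                    raise ConfigError(f"continuous.{name}.{key}: must be [mean, sd>=0]")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        logistic = d.get("logistic", {})
        spec = cls(mode=d.get("mode", ""),
                   n_total=d.get("n_total", 0),
                   binary=dict(d.get("binary", {})),
                   pits=d.get("pits"),
                   continuous=dict(d.get("continuous", {})),
                   n_recurrent=d.get("n_recurrent"),
                   beta0=logistic.get("beta0"),
                   beta1=logistic.get("beta1"),
                   target_prevalence=logistic.get("target_prevalence"))
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def packaged(cls, name: str) -> "CohortSpec":
        """Load one of the shipped specs: ``conditional`` or ``prospective``."""
        ref = importlib.resources.files("piloscore.data") / f"cohort_{name}.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass
class FixtureCohort:
    records: list[PatientRecord]
    provenance: str = FIXTURE_PROVENANCE
    version: str = FIXTURE_VERSION

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------------------
# deterministic fixture

def _quantile_values(n: int, mu: float, sd: float, lo: float, hi: float,
                     integer: bool = False, decimals: int = 1) -> np.ndarray:
    """Evenly spaced normal quantiles, clipped and rounded."""
    if n == 0:
        return np.zeros(0)
    q = (np.arange(n) + 0.5) / n
    vals = np.clip(sps.norm.ppf(q, mu, sd), lo, hi)
    return np.round(vals) if integer else np.round(vals, decimals)


def _split_bmi_values(n: int, n_high: int, mu: float, sd: float,
                      lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """BMI values for ``n_high`` patients at >= 30 and the rest below 30.

    Each side uses quantiles of the matching truncated normal, so the group
    mean stays close to ``mu`` while every value respects its flag.
    """
    n_low = n - n_high
    out_high = np.zeros(0)
    out_low = np.zeros(0)
    if n_high:
        a, b = (30.0 - mu) / sd, (hi - mu) / sd
        q = (np.arange(n_high) + 0.5) / n_high
        out_high = np.maximum(30.0, np.round(sps.truncnorm.ppf(q, a, b, mu, sd), 1))
    if n_low:
        a, b = (lo - mu) / sd, (30.0 - mu) / sd
        q = (np.arange(n_low) + 0.5) / n_low
        out_low = np.minimum(29.9, np.round(sps.truncnorm.ppf(q, a, b, mu, sd), 1))
    return out_low, out_high


def _greedy_assign(n: int, targets: np.ndarray, attributes: Sequence[tuple],
                   cap: float) -> dict[str, np.ndarray]:
    """Place every attribute instance, steering per-patient extras to targets.

    ``attributes`` is an ordered list ``(name, count, delta, conflicts)``.
    Each instance goes to the eligible patient with the largest remaining
    deficit (ties -> lowest index); a patient may hold at most one instance
    of an attribute, none of a conflicting one, and never exceeds ``cap``.
    """
    extras = np.zeros(n)
    held = {name: np.zeros(n, dtype=bool) for name, _, _, _ in attributes}
    for name, count, delta, conflicts in attributes:
        for _ in range(count):
            eligible = ~held[name] & (extras + delta <= cap + 1e-9)
            for other in conflicts:
                eligible &= ~held[other]
            if not eligible.any():
                raise AssertionError(
                    f"fixture construction infeasible while placing {name!r}")
            idx = np.flatnonzero(eligible)
            best = idx[np.argmax((targets - extras)[idx])]
            held[name][best] = True
            extras[best] += delta
    return held


def _fixture_group_records(prefix: str, start_id: int, recurrent: bool,
                           flags: dict[str, np.ndarray], n: int,
                           bmi: np.ndarray, age: np.ndarray,
                           optime: np.ndarray) -> list[PatientRecord]:
    records = []
    for i in range(n):
        if flags["pits_gt10"][i]:
            pits = 12
        elif flags["pits_5_10"][i]:
            pits = 7
        else:
            pits = 3
        records.append(PatientRecord(
            patient_id=f"{prefix}{start_id + i:03d}",
            sex=MALE if flags["male"][i] else FEMALE,
            age=int(age[i]),
            bmi=float(bmi[i]),
            hairy_back=bool(flags["hairy"][i]),
            diabetes=bool(flags["diabetes"][i]),
            prior_recurrence=bool(flags["prior"][i]),
            n_midline_pits=pits,
            lateral_pits=bool(flags["lateral"][i]),
            distance_to_anus_cm=3.0 if flags["dist"][i] else 7.0,
            prior_abscess=bool(flags["abscess"][i]),
            recurrence=recurrent,
            wound_dehiscence=bool(flags["dehiscence"][i]),
            postop_infection=bool(flags["infection"][i]),
            operative_time_min=float(optime[i]),
            hospital_stay_days=int(flags["stay"][i]),
            drain_removal_day=0,  # filled cohort-wide afterwards
        ))
    return records


def _empty_flags(n: int) -> dict[str, np.ndarray]:
    names = ("male", "hairy", "diabetes", "prior", "pits_gt10", "pits_5_10",
             "lateral", "dist", "abscess", "bmi_high", "dehiscence", "infection")
    flags = {name: np.zeros(n, dtype=bool) for name in names}
    flags["stay"] = np.ones(n, dtype=int)
    return flags


def reconstruct_fixture(weights: Optional[WeightTable] = None) -> FixtureCohort:
    """Deterministic 156-patient reconstruction cohort.

    Guarantees (asserted before returning): 137/19 outcome split, every
    published per-group categorical count, exactly 12 recurrent and 2
    non-recurrent patients at score >= 21, and all records valid.
    Continuous moments are best effort (group means within 0.5).
    """
    weights = weights if weights is not None else default_weight_table()

    # --- recurrent group (19): 12 high scorers, 7 low scorers -------------
    n_rec = 19
    rf = _empty_flags(n_rec)
    # patient 0 sits exactly on the cutoff boundary region (score 21)
    rf["male"][0:12] = True
    rf["pits_gt10"][0:12] = True
    rf["lateral"][0:12] = True
    rf["dist"][0:12] = True
    rf["abscess"][0:12] = True
    rf["hairy"][1:12] = True
    rf["bmi_high"][1:12] = True
    rf["prior"][1:12] = True
    rf["diabetes"][1:11] = True
    # low scorers (indices 12..18): remaining counts, capped at score 17
    low_attrs = [
        ("pits_5_10", 3, 2, ()),
        ("lateral", 3, 2, ()),
        ("dist", 3, 2, ()),
        ("abscess", 2, 2, ()),
        ("male", 6, 1, ()),
        ("hairy", 5, 1, ()),
        ("bmi_high", 3, 1, ()),
    ]
    low_targets = np.array([7.0, 7.0, 6.0, 5.0, 4.0, 4.0, 3.0])
    held = _greedy_assign(7, low_targets, low_attrs, cap=7.0)
    for name, flag in held.items():
        rf[name][12:] |= flag
    rf["infection"][0:3] = True
    rf["dehiscence"][:] = True

    n_rec_bmi_high = int(rf["bmi_high"].sum())
    rec_bmi_low, rec_bmi_high = _split_bmi_values(n_rec, n_rec_bmi_high,
                                                  32.79, 4.52, 21.0, 40.0)
    rec_bmi = np.zeros(n_rec)
    rec_bmi[rf["bmi_high"]] = rec_bmi_high
    rec_bmi[~rf["bmi_high"]] = rec_bmi_low
    rec_age = _quantile_values(n_rec, 27.47, 6.88, 19, 40, integer=True)
    rec_optime = _quantile_values(n_rec, 55.32, 13.59, 26.0, 74.0)

    # --- non-recurrent group (137): 2 high scorers at exactly 21 ----------
    n_not = 137
    nf = _empty_flags(n_not)
    for name in ("male", "hairy", "bmi_high", "pits_gt10", "lateral", "dist"):
        nf[name][0:2] = True
    not_attrs = [
        ("pits_gt10", 9, 4, ()),
        ("diabetes", 11, 2, ()),
        ("prior", 15, 2, ()),
        ("pits_5_10", 47, 2, ("pits_gt10",)),
        ("lateral", 25, 2, ()),
        ("dist", 21, 2, ()),
        ("abscess", 35, 2, ()),
        ("male", 88, 1, ()),
        ("hairy", 46, 1, ()),
        ("bmi_high", 50, 1, ()),
    ]
    not_targets = np.clip(sps.norm.ppf((np.arange(135) + 0.5) / 135, 13.96, 3.07),
                          10.0, 20.0) - 10.0
    held = _greedy_assign(135, not_targets, not_attrs, cap=10.0)
    for name, flag in held.items():
        nf[name][2:] |= flag
    nf["dehiscence"][2:9] = True
    nf["stay"][100] = 2
    nf["stay"][101] = 3

    n_not_bmi_high = int(nf["bmi_high"].sum())
    not_bmi_low, not_bmi_high = _split_bmi_values(n_not, n_not_bmi_high,
                                                  28.61, 4.43, 19.0, 41.0)
    not_bmi = np.zeros(n_not)
    not_bmi[nf["bmi_high"]] = not_bmi_high
    not_bmi[~nf["bmi_high"]] = not_bmi_low
    not_age = _quantile_values(n_not, 27.29, 6.44, 18, 45, integer=True)
    not_optime = _quantile_values(n_not, 42.91, 11.77, 21.0, 75.0)

    records = _fixture_group_records("P", 1, False, nf, n_not,
                                     not_bmi, not_age, not_optime)
    records += _fixture_group_records("P", n_not + 1, True, rf, n_rec,
                                      rec_bmi, rec_age, rec_optime)

    drain = _quantile_values(len(records), 7.39, 1.34, 7, 14, integer=True)
    for rec, d in zip(records, drain):
        rec.drain_removal_day = int(d)

    _assert_fixture_invariants(records, weights)
    return FixtureCohort(records=records)


#: Published per-group categorical cell counts (not recurrent, recurrent).
FIXTURE_MARGINS = {
    "male": (90, 18),
    "diabetes": (11, 10),
    "prior_recurrence": (15, 11),
    "postop_infection": (0, 3),
    "pits_lt5": (79, 4),
    "pits_5_10": (47, 3),
    "pits_gt10": (11, 12),
    "lateral_pits": (27, 15),
    "hairy_back": (48, 16),
    "distance_lt5": (23, 15),
    "prior_abscess": (35, 14),
}


def _fixture_cell_counts(records: Sequence[PatientRecord]) -> dict:
    def count(pred):
        not_rec = sum(1 for r in records if not r.recurrence and pred(r))
        rec = sum(1 for r in records if r.recurrence and pred(r))
        return (not_rec, rec)

    return {
        "male": count(lambda r: r.sex == MALE),
        "diabetes": count(lambda r: r.diabetes),
        "prior_recurrence": count(lambda r: r.prior_recurrence),
        "postop_infection": count(lambda r: r.postop_infection),
        "pits_lt5": count(lambda r: r.n_midline_pits < 5),
        "pits_5_10": count(lambda r: 5 <= r.n_midline_pits <= 10),
        "pits_gt10": count(lambda r: r.n_midline_pits > 10),
        "lateral_pits": count(lambda r: r.lateral_pits),
        "hairy_back": count(lambda r: r.hairy_back),
        "distance_lt5": count(lambda r: r.distance_to_anus_cm <= 5),
        "prior_abscess": count(lambda r: r.prior_abscess),
    }


def _assert_fixture_invariants(records, weights) -> None:
    from .records import validate_record

    assert len(records) == 156
    assert sum(1 for r in records if r.recurrence) == 19
    for r in records:
        assert not validate_record(r), f"invalid fixture record {r.patient_id}"
    counts = _fixture_cell_counts(records)
    for name, want in FIXTURE_MARGINS.items():
        assert counts[name] == want, f"{name}: {counts[name]} != {want}"
    totals = [compute_score(r, weights).total for r in records]
    high_rec = sum(1 for r, t in zip(records, totals)
                   if r.recurrence and t >= DEFAULT_CUTOFF)
    high_not = sum(1 for r, t in zip(records, totals)
                   if not r.recurrence and t >= DEFAULT_CUTOFF)
    assert (high_rec, high_not) == (12, 2), (high_rec, high_not)


# ---------------------------------------------------------------------------
# stochastic simulators

def _draw_continuous(rng, n, mean, sd, lo, hi, integer=False):
    vals = np.clip(rng.normal(mean, sd, size=n), lo, hi)
    return np.round(vals).astype(int) if integer else np.round(vals, 1)


def _pits_from_bin(rng, bins: np.ndarray) -> np.ndarray:
    counts = np.empty(bins.size, dtype=int)
    counts[bins == 0] = rng.integers(0, 5, size=(bins == 0).sum())
    counts[bins == 1] = rng.integers(5, 11, size=(bins == 1).sum())
    counts[bins == 2] = rng.integers(11, 16, size=(bins == 2).sum())
    return counts


def _distance_from_flag(rng, flag: np.ndarray) -> np.ndarray:
    out = np.empty(flag.size)
    out[flag] = np.round(rng.uniform(1.5, 4.9, size=flag.sum()), 1)
    out[~flag] = np.round(rng.uniform(5.5, 10.0, size=(~flag).sum()), 1)
    return out


def _records_from_arrays(prefix, start, n, sex_male, age, bmi, hairy, dm, prior,
                         pits, lateral, dist, abscess, recurrence, dehiscence,
                         infection, optime, drain) -> list[PatientRecord]:
    return [PatientRecord(
        patient_id=f"{prefix}{start + i:05d}",
        sex=MALE if sex_male[i] else FEMALE,
        age=int(age[i]),
        bmi=float(bmi[i]),
        hairy_back=bool(hairy[i]),
        diabetes=bool(dm[i]),
        prior_recurrence=bool(prior[i]),
        n_midline_pits=int(pits[i]),
        lateral_pits=bool(lateral[i]),
        distance_to_anus_cm=float(dist[i]),
        prior_abscess=bool(abscess[i]),
        recurrence=bool(recurrence[i]),
        wound_dehiscence=bool(dehiscence[i]),
        postop_infection=bool(infection[i]),
        operative_time_min=float(optime[i]),
        hospital_stay_days=1,
        drain_removal_day=int(drain[i]),
    ) for i in range(n)]


def simulate_conditional(spec: CohortSpec, seed: int,
                         n: Optional[int] = None) -> list[PatientRecord]:
    """Outcome by group size, then covariates independently given outcome."""
    spec.validate()
    if spec.mode != CONDITIONAL:
        raise ConfigError("simulate_conditional requires a conditional-mode spec")
    n = int(n) if n is not None else spec.n_total
    n_rec = int(round(n * spec.n_recurrent / spec.n_total))
    n_rec = min(max(n_rec, 1), n - 1)
    rng = np.random.default_rng(seed)
    records = []
    start = 1
    for recurrent, size, pkey in ((False, n - n_rec, "p_not"), (True, n_rec, "p_rec")):
        def pb(name, default=0.0):
            entry = spec.binary.get(name)
            return float(entry[pkey]) if entry is not None else default

        male = rng.random(size) < pb("male")
        dm = rng.random(size) < pb("diabetes")
        prior = rng.random(size) < pb("prior_recurrence")
        infection = rng.random(size) < pb("postop_infection")
        lateral = rng.random(size) < pb("lateral_pits")
        hairy = rng.random(size) < pb("hairy_back")
        dist_flag = rng.random(size) < pb("distance_lt5")
        abscess = rng.random(size) < pb("prior_abscess")
        dehiscence = rng.random(size) < pb("wound_dehiscence")
        bins = rng.choice(3, size=size, p=np.asarray(spec.pits[pkey], dtype=float))
        pits = _pits_from_bin(rng, bins)
        dist = _distance_from_flag(rng, dist_flag)

        ckey = "rec" if recurrent else "not"

        def cont(name, default, integer=False):
            c = spec.continuous.get(name)
            if c is None:
                return np.full(size, default)
            mean, sd = c[ckey]
            return _draw_continuous(rng, size, mean, sd, c["lo"], c["hi"], integer)

        age = cont("age", 30, integer=True)
        bmi = cont("bmi", 25.0)
        optime = cont("operative_time_min", 45.0)
        drain = cont("drain_removal_day", 7, integer=True)
        records += _records_from_arrays(
            "S", start, size, male, age, bmi, hairy, dm, prior, pits, lateral,
            dist, abscess, np.full(size, recurrent), dehiscence, infection,
            optime, drain)
        start += size
    return records


def score_distribution(spec: CohortSpec, weights: Optional[WeightTable] = None) -> dict:
    """Exact pmf of the score under a prospective spec (independent factors)."""
    weights = weights if weights is not None else default_weight_table()
    b = spec.binary
    bmi_c = spec.continuous.get("bmi", {"marginal": [29.12, 4.63]})
    mu, sd = bmi_c["marginal"]
    p_bmi_high = float(sps.norm.sf(30.0, mu, sd))
    factor_pmfs = [
        {2.0: p_bmi_high, 1.0: 1 - p_bmi_high},
        {2.0: b["male"], 1.0: 1 - b["male"]},
        {2.0: b["hairy_back"], 1.0: 1 - b["hairy_back"]},
        {3.0: b["diabetes"], 1.0: 1 - b["diabetes"]},
        {3.0: b["prior_recurrence"], 1.0: 1 - b["prior_recurrence"]},
        {2.0: spec.pits[0], 4.0: spec.pits[1], 6.0: spec.pits[2]},
        {3.0: b["lateral_pits"], 1.0: 1 - b["lateral_pits"]},
        {3.0: b["distance_lt5"], 1.0: 1 - b["distance_lt5"]},
        {3.0: b["prior_abscess"], 1.0: 1 - b["prior_abscess"]},
    ]
    pmf = {0.0: 1.0}
    for fp in factor_pmfs:
        nxt: dict[float, float] = {}
        for s, p in pmf.items():
            for pts, q in fp.items():
                if q > 0:
                    nxt[s + pts] = nxt.get(s + pts, 0.0) + p * q
        pmf = nxt
    return pmf


def calibrate_intercept(spec: CohortSpec, beta1: float,
                        target_prevalence: float) -> float:
    """Solve for the logistic intercept giving the target outcome prevalence.

    Uses the exact score pmf (factors independent), so the result is
    deterministic.
    """
    pmf = score_distribution(spec)

    def prevalence(b0):
        return sum(p * expit(b0 + beta1 * s) for s, p in pmf.items())

    lo, hi = -200.0, 200.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if prevalence(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_prospective(spec: CohortSpec, seed: int, n: Optional[int] = None,
                         weights: Optional[WeightTable] = None) -> list[PatientRecord]:
    """Covariates from marginals, outcome ~ Bernoulli(logistic(b0 + b1*score))."""
    spec.validate()
    if spec.mode != PROSPECTIVE:
        raise ConfigError("simulate_prospective requires a prospective-mode spec")
    weights = weights if weights is not None else default_weight_table()
    n = int(n) if n is not None else spec.n_total
    beta1 = float(spec.beta1)
    beta0 = (float(spec.beta0) if spec.beta0 is not None
             else calibrate_intercept(spec, beta1, float(spec.target_prevalence)))
    rng = np.random.default_rng(seed)
    b = spec.binary

    def pb(name, default=0.0):
        return float(b.get(name, default))

    male = rng.random(n) < pb("male")
    dm = rng.random(n) < pb("diabetes")
    prior = rng.random(n) < pb("prior_recurrence")
    lateral = rng.random(n) < pb("lateral_pits")
    hairy = rng.random(n) < pb("hairy_back")
    dist_flag = rng.random(n) < pb("distance_lt5")
    abscess = rng.random(n) < pb("prior_abscess")
    dehiscence = rng.random(n) < pb("wound_dehiscence")
    bins = rng.choice(3, size=n, p=np.asarray(spec.pits, dtype=float))
    pits = _pits_from_bin(rng, bins)
    dist = _distance_from_flag(rng, dist_flag)

    def cont(name, default, integer=False):
        c = spec.continuous.get(name)
        if c is None:
            return np.full(n, default)
        mean, sd = c["marginal"]
        return _draw_continuous(rng, n, mean, sd, c["lo"], c["hi"], integer)

    age = cont("age", 30, integer=True)
    bmi = cont("bmi", 25.0)
    optime = cont("operative_time_min", 45.0)
    drain = cont("drain_removal_day", 7, integer=True)

    records = _records_from_arrays(
        "S", 1, n, male, age, bmi, hairy, dm, prior, pits, lateral, dist,
        abscess, np.zeros(n, dtype=bool), dehiscence, np.zeros(n, dtype=bool),
        optime, drain)
    totals = np.array([compute_score(r, weights).total for r in records])
    p_rec = expit(beta0 + beta1 * totals)
    recurrence = rng.random(n) < p_rec
    for rec, flag in zip(records, recurrence):
        rec.recurrence = bool(flag)
    return records
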