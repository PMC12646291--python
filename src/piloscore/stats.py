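"""Two-group statistical battery and comparison report.

Implements the test-selection rules used throughout the cohort analysis:

* categorical variables — uncorrected Pearson chi-square when at most 20%
  of cells have expected counts below 5; otherwise Fisher's exact test for
  2x2 tables and a fixed-margins Monte-Carlo chi-square for larger tables;
* continuous variables — Shapiro-Wilk normality gate, then a pooled-variance
  Student t (normal) or a Mann-Whitney U (non-normal).

No continuity correction is applied anywhere, and all p-values are
two-sided.  This layer is deliberately independent of the scoring layer:
it reads record fields only, never the weight table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError
from .records import PatientRecord

logger = logging.getLogger(__name__)

ALPHA = 0.05

CHI_SQUARE = "chi_square"
FISHER_EXACT = "fisher_exact"
MONTE_CARLO = "monte_carlo_chi_square"
STUDENT_T = "student_t"
MANN_WHITNEY = "mann_whitney"

NORMAL = "normal"
NON_NORMAL = "non_normal"


# ---------------------------------------------------------------------------
# domain types

@dataclass
class ContingencyTable:
    """r x c observed counts with labels."""

    observed: np.ndarray
    row_labels: Sequence[str]
    col_labels: Sequence[str]

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.observed.ndim != 2:
            raise DegenerateDataError("contingency table must be 2-dimensional")
        if (self.observed < 0).any():
            raise DegenerateDataError("contingency table counts must be non-negative")
        if self.observed.sum() < 1:
            raise DegenerateDataError("contingency table must contain at least one count")
        if len(self.row_labels) != self.observed.shape[0]:
            raise DegenerateDataError("row_labels length mismatch")
        if len(self.col_labels) != self.observed.shape[1]:
            raise DegenerateDataError("col_labels length mismatch")

    @property
    def shape(self):
        return self.observed.shape

    def expected(self) -> np.ndarray:
        """Expected counts under independence: row total x col total / N."""
        o = self.observed
        return np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()


@dataclass
class ContinuousSummary:
    n: int
    min: float
    max: float
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TestResult:
    test_name: str
    statistic: float
    dof: Optional[int]
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha

    def as_dict(self) -> dict:
        return {"test": self.test_name, "statistic": self.statistic, "dof": self.dof,
                "p_value": self.p_value, "significant": self.significant}


# ---------------------------------------------------------------------------
# descriptives

def describe_continuous(values: Sequence[float]) -> ContinuousSummary:
    """Range, mean, sample SD (n-1), median and IQR (linear interpolation)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DegenerateDataError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return ContinuousSummary(n=int(x.size), min=float(x.min()), max=float(x.max()),
                             mean=float(x.mean()), sd=sd, median=float(med),
                             iqr_low=float(q1), iqr_high=float(q3))


# ---------------------------------------------------------------------------
# categorical tests

def _check_margins(table: ContingencyTable) -> None:
    rows = table.observed.sum(axis=1)
    cols = table.observed.sum(axis=0)
    if (rows == 0).any():
        bad = [table.row_labels[i] for i in np.flatnonzero(rows == 0)]
        raise DegenerateDataError(f"empty row margin(s): {bad}")
    if (cols == 0).any():
        bad = [table.col_labels[i] for i in np.flatnonzero(cols == 0)]
        raise DegenerateDataError(f"empty column margin(s): {bad}")


def _chi_square_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    return float(((observed - expected) ** 2 / expected).sum())


def pearson_chi_square(table: ContingencyTable, alpha: float = ALPHA) -> TestResult:
    """Uncorrected Pearson chi-square with (r-1)(c-1) degrees of freedom."""
    r, c = table.shape
    if r < 2 or c < 2:
        raise DegenerateDataError("chi-square needs at least a 2x2 table")
    _check_margins(table)
    expected = table.expected()
    stat = _chi_square_statistic(table.observed, expected)
    dof = (r - 1) * (c - 1)
    p = float(sps.chi2.sf(stat, dof))
    return TestResult(CHI_SQUARE, stat, dof, p, alpha)


def fisher_exact_2x2(table: ContingencyTable, alpha: float = ALPHA) -> TestResult:
    """Two-sided Fisher exact test (probability-mass criterion).

    The statistic field carries the hypergeometric probability of the
    observed table under fixed margins.
    """
    if table.shape != (2, 2):
        raise DegenerateDataError(
            "Fisher exact test requires a 2x2 table; use monte_carlo_p for larger tables")
    _check_margins(table)
    o = table.observed
    n = int(o.sum())
    prob = float(sps.hypergeom.pmf(o[0, 0], n, o[0, :].sum(), o[:, 0].sum()))
    _, p = sps.fisher_exact(o, alternative="two-sided")
    return TestResult(FISHER_EXACT, prob, None, float(min(p, 1.0)), alpha)


def monte_carlo_p(table: ContingencyTable, reps: int = 10000, seed: int = 0,
                  alpha: float = ALPHA) -> TestResult:
    """Monte-Carlo chi-square p-value under fixed row and column margins.

    Tables are sampled by Patefield-style fixed-margin generation; the
    p-value uses the add-one estimator ``(1 + #{stat >= observed}) / (reps + 1)``.
    """
    if reps < 100:
        raise DegenerateDataError("Monte-Carlo p needs at least 100 replicates")
    _check_margins(table)
    expected = table.expected()
    obs_stat = _chi_square_statistic(table.observed, expected)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(table.observed.sum(axis=1), table.observed.sum(axis=0))
    sims = dist.rvs(reps, random_state=rng)
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    exceed = int((sim_stats >= obs_stat - 1e-9).sum())
    p = (1 + exceed) / (reps + 1)
    return TestResult(MONTE_CARLO, obs_stat, None, p, alpha)


def choose_categorical_test(table: ContingencyTable) -> str:
    """Apply the expected-count rule.

    Chi-square when at most 20% of cells have expected counts below 5,
    else Fisher exact (2x2) or Monte-Carlo chi-square (larger tables).
    """
    expected = table.expected()
    frac_small = float((expected < 5).mean())
    if frac_small <= 0.20:
        choice = CHI_SQUARE
    elif table.shape == (2, 2):
        choice = FISHER_EXACT
    else:
        choice = MONTE_CARLO
    logger.info("test selection: %.0f%% of cells have E<5 -> %s",
                100 * frac_small, choice)
    return choice


# ---------------------------------------------------------------------------
# continuous tests

def student_t_from_summary(mean1: float, sd1: float, n1: int,
                           mean2: float, sd2: float, n2: int,
                           alpha: float = ALPHA) -> TestResult:
    """Pooled-variance two-sample t test from group summaries."""
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("Student t needs at least two observations per group")
    if sd1 < 0 or sd2 < 0:
        raise DegenerateDataError("standard deviations must be non-negative")
    dof = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(STUDENT_T, 0.0, dof, 1.0, alpha)
        raise DegenerateDataError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(STUDENT_T, float(t), dof, float(p), alpha)


def student_t(values1: Sequence[float], values2: Sequence[float],
              alpha: float = ALPHA) -> TestResult:
    """Pooled-variance t test from raw values (delegates to the summary form)."""
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("Student t needs at least two observations per group")
    return student_t_from_summary(float(x.mean()), float(np.std(x, ddof=1)), int(x.size),
                                  float(y.mean()), float(np.std(y, ddof=1)), int(y.size),
                                  alpha=alpha)


def mann_whitney_u(values1: Sequence[float], values2: Sequence[float],
                   alpha: float = ALPHA) -> TestResult:
    """Mann-Whitney test reporting U = min(U1, U2).

    Exact enumeration when there are no ties and n1*n2 <= 400; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("Mann-Whitney needs non-empty groups")
    n1, n2 = int(x.size), int(y.size)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(MANN_WHITNEY, n1 * n2 / 2.0, None, 1.0, alpha)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and n1 * n2 <= 400) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return TestResult(MANN_WHITNEY, u, None, float(res.pvalue), alpha)


def normality_gate(values: Sequence[float], alpha: float = ALPHA) -> str:
    """Shapiro-Wilk gate: ``non_normal`` iff p < alpha."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise DegenerateDataError(
            f"normality gate supports 3 <= n <= 5000, got n={x.size}")
    if np.all(x == x[0]):
        return NON_NORMAL
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.shapiro(x)
    return NON_NORMAL if p < alpha else NORMAL


# ---------------------------------------------------------------------------
# variable plans and the comparison report

@dataclass
class CategoricalVariable:
    """A variable summarised as level counts; levels are predicates."""

    name: str
    levels: Sequence[tuple[str, Callable[[PatientRecord], bool]]]

    kind = "categorical"

    def level_of(self, record: PatientRecord) -> Optional[str]:
        for label, pred in self.levels:
            try:
                if pred(record):
                    return label
            except TypeError:
                return None
        return None


@dataclass
class ContinuousVariable:
    name: str
    getter: Callable[[PatientRecord], Optional[float]]

    kind = "continuous"


def recurrence_panel() -> list:
    """The standard cohort comparison panel (demographics + disease factors)."""
    def _not_none(get):
        def pred_factory(test):
            def pred(r):
                v = get(r)
                if v is None:
                    raise TypeError
                return test(v)
            return pred
        return pred_factory

    sex = _not_none(lambda r: r.sex)
    dm = _not_none(lambda r: r.diabetes)
    prior = _not_none(lambda r: r.prior_recurrence)
    infection = _not_none(lambda r: r.postop_infection)
    pits = _not_none(lambda r: r.n_midline_pits)
    lateral = _not_none(lambda r: r.lateral_pits)
    hairy = _not_none(lambda r: r.hairy_back)
    dist = _not_none(lambda r: r.distance_to_anus_cm)
    abscess = _not_none(lambda r: r.prior_abscess)

    return [
        CategoricalVariable("sex", [("male", sex(lambda v: v == "male")),
                                    ("female", sex(lambda v: v == "female"))]),
        ContinuousVariable("age", lambda r: r.age),
        ContinuousVariable("bmi", lambda r: r.bmi),
        ContinuousVariable("operative_time_min", lambda r: r.operative_time_min),
        CategoricalVariable("diabetes", [("yes", dm(bool)), ("no", dm(lambda v: not v))]),
        CategoricalVariable("prior_recurrence", [("yes", prior(bool)),
                                                 ("no", prior(lambda v: not v))]),
        CategoricalVariable("postop_infection", [("yes", infection(bool)),
                                                 ("no", infection(lambda v: not v))]),
        CategoricalVariable("midline_pits", [("<5", pits(lambda v: v < 5)),
                                             ("5-10", pits(lambda v: 5 <= v <= 10)),
                                             (">10", pits(lambda v: v > 10))]),
        CategoricalVariable("lateral_pits", [("yes", lateral(bool)),
                                             ("no", lateral(lambda v: not v))]),
        CategoricalVariable("hairy_back", [("yes", hairy(bool)),
                                           ("no", hairy(lambda v: not v))]),
        CategoricalVariable("distance_lt_5cm", [("yes", dist(lambda v: v <= 5)),
                                                ("no", dist(lambda v: v > 5))]),
        CategoricalVariable("prior_abscess", [("yes", abscess(bool)),
                                              ("no", abscess(lambda v: not v))]),
    ]


@dataclass
class ComparisonRow:
    variable: str
    kind: str
    group_summaries: dict
    result: Optional[TestResult]
    chi_square_statistic: Optional[float] = None
    n_excluded: int = 0
    warnings: list = field(default_factory=list)
    table: Optional[ContingencyTable] = None

    def as_dict(self) -> dict:
        d = {"variable": self.variable, "kind": self.kind,
             "group_summaries": self.group_summaries,
             "result": self.result.as_dict() if self.result else None,
             "n_excluded": self.n_excluded, "warnings": list(self.warnings)}
        if self.kind == "categorical":
            d["chi_square_statistic"] = self.chi_square_statistic
        return d


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow]
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    alpha: float
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"group_labels": list(self.group_labels),
                "group_sizes": list(self.group_sizes),
                "alpha": self.alpha,
                "rows": [r.as_dict() for r in self.rows],
                "notes": list(self.notes)}

    def to_tsv(self) -> str:
        header = ["variable", "kind", "level", self.group_labels[0], self.group_labels[1],
                  "test", "statistic", "dof", "p_value", "significant", "n_excluded"]
        lines = ["\t".join(header)]
        for row in self.rows:
            res = row.result
            test_cols = ([res.test_name, f"{res.statistic:.4f}",
                          "" if res.dof is None else str(res.dof),
                          f"{res.p_value:.6g}", str(res.significant)]
                         if res else ["", "", "", "", ""])
            if row.kind == "categorical":
                first = True
                for label in row.group_summaries["levels"]:
                    g0 = row.group_summaries["counts"][label][0]
                    g1 = row.group_summaries["counts"][label][1]
                    p0 = row.group_summaries["percent"][label][0]
                    p1 = row.group_summaries["percent"][label][1]
                    cols = [row.variable if first else "", row.kind if first else "", label,
                            f"{g0} ({p0:.1f}%)", f"{g1} ({p1:.1f}%)"]
                    cols += test_cols if first else ["", "", "", "", ""]
                    cols += [str(row.n_excluded) if first else ""]
                    lines.append("\t".join(cols))
                    first = False
            else:
                cells = []
                for key in ("group0", "group1"):
                    s = row.group_summaries[key]
                    cells.append("" if s is None else
                                 f"{s['mean']:.2f}±{s['sd']:.2f}; "
                                 f"{s['median']:.1f} ({s['iqr_low']:.1f}-{s['iqr_high']:.1f}); "
                                 f"{s['min']:.1f}-{s['max']:.1f}")
                cols = [row.variable, row.kind, ""] + cells + test_cols + [str(row.n_excluded)]
                lines.append("\t".join(cols))
        for note in self.notes:
            lines.append("# " + note)
        return "\n".join(lines) + "\n"


def _compare_categorical(var: CategoricalVariable, groups, alpha, mc_reps, rng_seed):
    labels = [label for label, _ in var.levels]
    counts = {}
    excluded = 0
    per_group_levels = []
    for recs in groups:
        assigned = [var.level_of(r) for r in recs]
        excluded += sum(1 for a in assigned if a is None)
        per_group_levels.append([a for a in assigned if a is not None])
    for label in labels:
        counts[label] = [sum(1 for a in g if a == label) for g in per_group_levels]
    totals = [len(g) for g in per_group_levels]
    percent = {label: [100.0 * c / t if t else 0.0 for c, t in zip(counts[label], totals)]
               for label in labels}
    summaries = {"levels": labels, "counts": counts, "percent": percent}

    observed = np.array([counts[label] for label in labels], dtype=np.int64)
    keep = observed.sum(axis=1) > 0
    row_warnings = []
    if keep.sum() < 2 or (observed.sum(axis=0) == 0).any():
        row_warnings.append("degenerate variable: fewer than two populated levels")
        result = TestResult(CHI_SQUARE, 0.0, None, 1.0, alpha)
        return ComparisonRow(var.name, "categorical", summaries, result,
                             chi_square_statistic=0.0, n_excluded=excluded,
                             warnings=row_warnings)
    table = ContingencyTable(observed[keep],
                             [l for l, k in zip(labels, keep) if k],
                             ["group0", "group1"])
    chi_stat = _chi_square_statistic(table.observed, table.expected())
    choice = choose_categorical_test(table)
    if choice == CHI_SQUARE:
        result = pearson_chi_square(table, alpha)
    elif choice == FISHER_EXACT:
        result = fisher_exact_2x2(table, alpha)
    else:
        result = monte_carlo_p(table, reps=mc_reps, seed=rng_seed, alpha=alpha)
    logger.info("variable %s: selected %s (p=%.4g)", var.name, result.test_name,
                result.p_value)
    return ComparisonRow(var.name, "categorical", summaries, result,
                         chi_square_statistic=chi_stat, n_excluded=excluded,
                         warnings=row_warnings, table=table)


def _compare_continuous(var: ContinuousVariable, groups, alpha):
    vals = []
    excluded = 0
    for recs in groups:
        got = [var.getter(r) for r in recs]
        excluded += sum(1 for v in got if v is None)
        vals.append(np.asarray([v for v in got if v is not None], dtype=float))
    summaries = {"group0": describe_continuous(vals[0]).as_dict() if vals[0].size else None,
                 "group1": describe_continuous(vals[1]).as_dict() if vals[1].size else None}
    row_warnings = []
    pooled = np.concatenate(vals)
    if pooled.size == 0 or vals[0].size == 0 or vals[1].size == 0:
        row_warnings.append("degenerate variable: empty group after exclusions")
        return ComparisonRow(var.name, "continuous", summaries, None,
                             n_excluded=excluded, warnings=row_warnings)
    if np.all(pooled == pooled[0]):
        row_warnings.append("degenerate variable: constant values")
        result = TestResult(STUDENT_T, 0.0, pooled.size - 2, 1.0, alpha)
        return ComparisonRow(var.name, "continuous", summaries, result,
                             n_excluded=excluded, warnings=row_warnings)
    try:
        gate = normality_gate(pooled, alpha)
    except DegenerateDataError:
        gate = NON_NORMAL
        row_warnings.append("normality gate skipped (n outside range); using Mann-Whitney")
    if gate == NORMAL and vals[0].size >= 2 and vals[1].size >= 2:
        result = student_t(vals[0], vals[1], alpha)
    else:
        result = mann_whitney_u(vals[0], vals[1], alpha)
    logger.info("variable %s: normality=%s -> %s (p=%.4g)", var.name, gate,
                result.test_name, result.p_value)
    return ComparisonRow(var.name, "continuous", summaries, result,
                         n_excluded=excluded, warnings=row_warnings)


def compare_groups(cohort: Sequence[PatientRecord], outcome_field: str = "recurrence",
                   plan: Optional[list] = None, alpha: float = ALPHA,
                   mc_reps: int = 10000, seed: int = 0) -> ComparisonReport:
    """Compare every variable in the plan between the two outcome groups.

    Records with a missing outcome are dropped; records with a missing value
    for a given variable are excluded for that row only (pairwise deletion)
    and counted in ``n_excluded``.
    """
    plan = plan if plan is not None else recurrence_panel()
    known = [r for r in cohort if getattr(r, outcome_field, None) is not None]
    group0 = [r for r in known if not getattr(r, outcome_field)]
    group1 = [r for r in known if getattr(r, outcome_field)]
    if not group0 or not group1:
        raise DegenerateDataError(
            f"outcome {outcome_field!r} must have both groups non-empty "
            f"(got {len(group0)} / {len(group1)})")
    groups = (group0, group1)
    rows = []
    for i, var in enumerate(plan):
        if var.kind == "categorical":
            rows.append(_compare_categorical(var, groups, alpha, mc_reps,
                                             rng_seed=seed * 100003 + i))
        elif var.kind == "continuous":
            rows.append(_compare_continuous(var, groups, alpha))
        else:
            raise DegenerateDataError(f"unknown variable kind {var.kind!r}")
    notes = [
        "No multiple-testing correction applied.",
        "Normality gate applied to pooled values per variable (assumption).",
        "Chi-square statistics are uncorrected (no continuity correction).",
    ]
    return ComparisonReport(rows=rows,
                            group_labels=(f"{outcome_field}=no", f"{outcome_field}=yes"),
                            group_sizes=(len(group0), len(group1)),
                            alpha=alpha, notes=notes)
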