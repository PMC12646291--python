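"""The additive nine-factor severity score.

Each factor maps a record field onto one of a small set of levels, each
level carrying a point weight.  The total is the plain sum of the nine
per-factor points; risk stratification is a simple threshold on the total
(``total >= cutoff`` is high risk).

The default weight table:

========================  =============================  ======
factor                    level                          points
========================  =============================  ======
bmi                       >= 30 / < 30                   2 / 1
sex                       male / female                  2 / 1
hairy_back                yes / no                       2 / 1
diabetes                  yes / no                       3 / 1
prior_recurrence          yes / no                       3 / 1
midline pits              < 5 / 5-10 / > 10              2 / 4 / 6
lateral_pits              yes / no                       3 / 1
distance to anus (cm)     <= 5 / > 5                     3 / 1
prior_abscess             yes / no                       3 / 1
========================  =============================  ======

The boundary conventions (BMI exactly 30 scores high, distance exactly
5 cm scores high, a pit count of exactly 5 falls in the middle bin) are
explicit, configurable predicates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ConfigError, RecordValidationError
from .records import PatientRecord, Violation, validate_record

SCHEMA_VERSION = 1
DEFAULT_CUTOFF = 21

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class Level:
    """One level of a factor: a human-readable label and its weight."""

    label: str
    points: float


class Factor:
    """Base class: a named mapping from a record field to a level."""

    kind = "abstract"

    def __init__(self, name: str, field: str):
        self.name = name
        self.field = field

    @property
    def levels(self) -> tuple[Level, ...]:
        raise NotImplementedError

    def level_index(self, value) -> int:
        """Index of the (unique) level covering ``value``."""
        raise NotImplementedError

    def representatives(self) -> tuple:
        """One valid field value per level, in level order (for enumeration)."""
        raise NotImplementedError

    def validate(self) -> None:
        if any(lv.points < 0 for lv in self.levels):
            raise ConfigError(f"factor {self.name!r}: negative points are not allowed")

    def points_for(self, value) -> float:
        return self.levels[self.level_index(value)].points

    def to_dict(self) -> dict:
        raise NotImplementedError


class CategoricalFactor(Factor):
    """Finite value set, e.g. sex."""

    kind = "categorical"

    def __init__(self, name: str, field: str, points: dict):
        super().__init__(name, field)
        self.points = dict(points)
        self._order = list(self.points)

    @property
    def levels(self) -> tuple[Level, ...]:
        return tuple(Level(str(k), float(v)) for k, v in self.points.items())

    def level_index(self, value) -> int:
        try:
            return self._order.index(value)
        except ValueError:
            raise ConfigError(
                f"factor {self.name!r}: value {value!r} not covered by levels {self._order}"
            ) from None

    def representatives(self) -> tuple:
        return tuple(self._order)

    def validate(self) -> None:
        super().validate()
        if len(self._order) < 2:
            raise ConfigError(f"factor {self.name!r}: needs at least two levels")

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "field": self.field,
                "points": dict(self.points)}


class BooleanFactor(Factor):
    kind = "boolean"

    def __init__(self, name: str, field: str, points_true: float, points_false: float):
        super().__init__(name, field)
        self.points_true = float(points_true)
        self.points_false = float(points_false)

    @property
    def levels(self) -> tuple[Level, ...]:
        return (Level("yes", self.points_true), Level("no", self.points_false))

    def level_index(self, value) -> int:
        if value is True or value == 1:
            return 0
        if value is False or value == 0:
            return 1
        raise ConfigError(f"factor {self.name!r}: value {value!r} is not a boolean")

    def representatives(self) -> tuple:
        return (True, False)

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "field": self.field,
                "points_true": self.points_true, "points_false": self.points_false}


class ThresholdFactor(Factor):
    """Two levels split at a numeric threshold.

    ``boundary`` says which side the threshold value itself belongs to:
    ``"high"`` means ``value >= threshold`` takes ``points_high`` (BMI
    convention), ``"low"`` means ``value <= threshold`` takes
    ``points_low`` (distance convention).
    """

    kind = "threshold"

    def __init__(self, name: str, field: str, threshold: float,
                 points_low: float, points_high: float, boundary: str = "high"):
        super().__init__(name, field)
        if boundary not in ("high", "low"):
            raise ConfigError(f"factor {name!r}: boundary must be 'high' or 'low'")
        self.threshold = float(threshold)
        self.points_low = float(points_low)
        self.points_high = float(points_high)
        self.boundary = boundary

    @property
    def levels(self) -> tuple[Level, ...]:
        t = self.threshold
        if self.boundary == "high":
            return (Level(f"<{t:g}", self.points_low), Level(f">={t:g}", self.points_high))
        return (Level(f"<={t:g}", self.points_low), Level(f">{t:g}", self.points_high))

    def level_index(self, value) -> int:
        v = float(value)
        if self.boundary == "high":
            return 1 if v >= self.threshold else 0
        return 1 if v > self.threshold else 0

    def representatives(self) -> tuple:
        if self.boundary == "high":
            return (self.threshold - 1.0, self.threshold)
        return (self.threshold, self.threshold + 1.0)

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "field": self.field,
                "threshold": self.threshold, "points_low": self.points_low,
                "points_high": self.points_high, "boundary": self.boundary}


class BinsFactor(Factor):
    """Ordered numeric bins; the last bin is unbounded above.

    Each bin is ``(label, points, upper, inclusive)``; a value falls into
    the first bin whose upper bound it does not exceed (strictly below if
    ``inclusive`` is false).  The last bin has ``upper = None``.
    """

    kind = "bins"

    def __init__(self, name: str, field: str, bins: Sequence[dict]):
        super().__init__(name, field)
        self.bins = [dict(b) for b in bins]

    @property
    def levels(self) -> tuple[Level, ...]:
        return tuple(Level(str(b["label"]), float(b["points"])) for b in self.bins)

    def level_index(self, value) -> int:
        v = float(value)
        for i, b in enumerate(self.bins):
            upper = b.get("upper")
            if upper is None:
                return i
            if (v <= upper) if b.get("inclusive", False) else (v < upper):
                return i
        raise ConfigError(f"factor {self.name!r}: value {value!r} not covered")  # pragma: no cover

    def representatives(self) -> tuple:
        reps, lower = [], 0.0
        for b in self.bins:
            reps.append(lower)
            if b.get("upper") is not None:
                lower = b["upper"] + 1 if b.get("inclusive", False) else b["upper"]
        return tuple(reps)

    def validate(self) -> None:
        super().validate()
        if len(self.bins) < 2:
            raise ConfigError(f"factor {self.name!r}: needs at least two bins")
        if self.bins[-1].get("upper") is not None:
            raise ConfigError(f"factor {self.name!r}: last bin must be unbounded")
        uppers = [b["upper"] for b in self.bins[:-1]]
        if any(b.get("upper") is None for b in self.bins[:-1]):
            raise ConfigError(f"factor {self.name!r}: only the last bin may be unbounded")
        if sorted(uppers) != uppers or len(set(uppers)) != len(uppers):
            raise ConfigError(f"factor {self.name!r}: bin bounds must be strictly increasing")

    def to_dict(self) -> dict:
        return {"name": self.name, "kind": self.kind, "field": self.field,
                "bins": [dict(b) for b in self.bins]}


_FACTOR_KINDS = {
    "categorical": CategoricalFactor,
    "boolean": BooleanFactor,
    "threshold": ThresholdFactor,
    "bins": BinsFactor,
}


class WeightTable:
    """Ordered collection of factors; the score is the sum of their points."""

    def __init__(self, factors: Sequence[Factor], schema_version: int = SCHEMA_VERSION):
        self.schema_version = schema_version
        self.factors = list(factors)
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate factor names in weight table")
        self.validate()

    def __iter__(self):
        return iter(self.factors)

    def __len__(self):
        return len(self.factors)

    def validate(self) -> None:
        if not self.factors:
            raise ConfigError("weight table has no factors")
        for f in self.factors:
            f.validate()

    def bounds(self) -> tuple[float, float]:
        """(min, max) achievable total — per-factor extremes summed.

        Valid because the model is additive with independent factors.
        """
        lo = sum(min(lv.points for lv in f.levels) for f in self.factors)
        hi = sum(max(lv.points for lv in f.levels) for f in self.factors)
        return lo, hi

    def to_dict(self) -> dict:
        return {"schema_version": self.schema_version,
                "factors": [f.to_dict() for f in self.factors]}

    @classmethod
    def from_dict(cls, d: dict) -> "WeightTable":
        try:
            version = int(d.get("schema_version", SCHEMA_VERSION))
            raw = d["factors"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed weight table config: {exc}") from exc
        factors = []
        for item in raw:
            item = dict(item)
            kind = item.pop("kind", None)
            if kind not in _FACTOR_KINDS:
                raise ConfigError(f"unknown factor kind {kind!r}")
            try:
                factors.append(_FACTOR_KINDS[kind](**item))
            except TypeError as exc:
                raise ConfigError(f"malformed factor {item.get('name')!r}: {exc}") from exc
        return cls(factors, schema_version=version)

    def sha256(self) -> str:
        """Stable content hash, for report provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_weight_table() -> WeightTable:
    """The shipped default weights (see module docstring)."""
    return WeightTable([
        ThresholdFactor("bmi", "bmi", 30.0, points_low=1, points_high=2, boundary="high"),
        CategoricalFactor("sex", "sex", {"male": 2, "female": 1}),
        BooleanFactor("hairy_back", "hairy_back", points_true=2, points_false=1),
        BooleanFactor("diabetes", "diabetes", points_true=3, points_false=1),
        BooleanFactor("prior_recurrence", "prior_recurrence", points_true=3, points_false=1),
        BinsFactor("midline_pits", "n_midline_pits", [
            {"label": "<5", "points": 2, "upper": 5, "inclusive": False},
            {"label": "5-10", "points": 4, "upper": 10, "inclusive": True},
            {"label": ">10", "points": 6},
        ]),
        BooleanFactor("lateral_pits", "lateral_pits", points_true=3, points_false=1),
        ThresholdFactor("distance", "distance_to_anus_cm", 5.0,
                        points_low=3, points_high=1, boundary="low"),
        BooleanFactor("prior_abscess", "prior_abscess", points_true=3, points_false=1),
    ])


@dataclass
class ScoreBreakdown:
    """Per-factor points, their total, and (optionally) the risk class."""

    points: dict[str, float]
    total: float
    risk_class: Optional[str] = None

    def as_dict(self) -> dict:
        return {"points": dict(self.points), "total": self.total,
                "risk_class": self.risk_class}


def compute_score(record: PatientRecord, weights: Optional[WeightTable] = None,
                  cutoff: Optional[int] = None) -> ScoreBreakdown:
    """Score one record.

    Deterministic, reads only the nine factor fields (never outcomes).
    Raises :class:`RecordValidationError` if the record is invalid and
    :class:`ConfigError` if the weight table does not cover a value.
    """
    weights = weights if weights is not None else default_weight_table()
    violations = validate_record(record)
    if violations:
        raise RecordValidationError(violations)
    points: dict[str, float] = {}
    for factor in weights:
        value = getattr(record, factor.field, None)
        if value is None:
            raise RecordValidationError(
                [Violation(factor.field, f"required by factor {factor.name!r} but missing")])
        points[factor.name] = factor.points_for(value)
    total = sum(points.values())
    risk = classify_risk(total, cutoff) if cutoff is not None else None
    return ScoreBreakdown(points=points, total=total, risk_class=risk)


def classify_risk(total: float, cutoff: int = DEFAULT_CUTOFF) -> str:
    """``high`` iff ``total >= cutoff``, else ``low``."""
    return HIGH if total >= cutoff else LOW


def score_bounds(weights: WeightTable) -> tuple[float, float]:
    """Minimum and maximum achievable totals for a weight table."""
    weights.validate()
    return weights.bounds()
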