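"""TRISS probability-of-survival model.

The Trauma and Injury Severity Score methodology predicts in-hospital
survival from a logistic model on the Revised Trauma Score (RTS), the
Injury Severity Score (ISS) and an age indicator, with separate published
coefficient sets for blunt and penetrating trauma::

    logit = b0 + b1 * RTS + b2 * ISS + b3 * age_point
    Ps    = 1 / (1 + exp(-logit))

``age_point`` is 1 for patients at or above the age cutoff (default 55
years, the Major Trauma Outcome Study convention) and 0 below it.
Children under 15 with penetrating trauma are scored with the blunt
coefficients, as the penetrating model was not fitted for that group.

Coefficient sets are data, not code constants: two published sets ship
built in ("table2", the default, and "mtos_formulaAB") and arbitrary sets
can be loaded from flat JSON.  Sign conventions are enforced (b1 > 0,
b2 < 0, b3 < 0) so predicted survival always rises with RTS and falls
with injury severity and age — published transcriptions that print the
ISS and age terms with positive signs must be sign-corrected before use.

A patient with Ps > 0.5 is classified as an expected survivor; Ps <= 0.5
is an expected death.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "TraumaCoefficients", "CoefficientSet", "TABLE2", "MTOS_FORMULA_AB",
    "BUILTIN_COEFFICIENT_SETS", "PEDIATRIC_AGE",
    "age_point", "triss_logit", "probability_of_survival",
    "classify_expected", "predict_frame",
]

#: Below this age the blunt model is used regardless of trauma type.
PEDIATRIC_AGE = 15


@dataclass(frozen=True)
class TraumaCoefficients:
    """Logit coefficients for one trauma type: intercept, RTS, ISS, age."""

    b0: float
    b1: float  # RTS weight, > 0
    b2: float  # ISS weight, < 0
    b3: float  # age-point weight, < 0

    def __post_init__(self):
        if not self.b1 > 0:
            raise ValueError(f"b1 (RTS weight) must be > 0, got {self.b1}")
        if not self.b2 < 0:
            raise ValueError(f"b2 (ISS weight) must be < 0, got {self.b2}")
        if not self.b3 < 0:
            raise ValueError(f"b3 (age weight) must be < 0, got {self.b3}")


@dataclass(frozen=True)
class CoefficientSet:
    """A named pair of blunt/penetrating coefficient vectors.

    ``age_cutoff`` is the age (years) at which the age point switches from
    0 to 1 (inclusive at the cutoff).
    """

    name: str
    blunt: TraumaCoefficients
    penetrating: TraumaCoefficients
    age_cutoff: float = 55.0

    def __post_init__(self):
        if not self.age_cutoff > 0:
            raise ValueError("age_cutoff must be positive")

    def for_type(self, trauma_type: str) -> TraumaCoefficients:
        if trauma_type == "blunt":
            return self.blunt
        if trauma_type == "penetrating":
            return self.penetrating
        raise ValueError(f"unknown trauma type {trauma_type!r}")

    def to_json(self, path) -> None:
        flat = {
            "name": self.name, "age_cutoff": self.age_cutoff,
            **{f"blunt_{k}": v for k, v in asdict(self.blunt).items()},
            **{f"penetrating_{k}": v for k, v in asdict(self.penetrating).items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(flat, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path, encoding="utf-8") as fh:
            flat = json.load(fh)
        return cls(
            name=flat.get("name", "custom"),
            blunt=TraumaCoefficients(*(flat[f"blunt_b{i}"] for i in range(4))),
            penetrating=TraumaCoefficients(*(flat[f"penetrating_b{i}"] for i in range(4))),
            age_cutoff=flat.get("age_cutoff", 55.0),
        )


TABLE2 = CoefficientSet(
    name="table2",
    blunt=TraumaCoefficients(b0=-1.2470, b1=0.9544, b2=-0.0768, b3=-1.9052),
    penetrating=TraumaCoefficients(b0=-0.6029, b1=1.1430, b2=-0.1516, b3=-2.6676),
)

# The widely reprinted MTOS fit; ISS and age terms sign-corrected to
# negative so that Ps decreases with severity and age.
MTOS_FORMULA_AB = CoefficientSet(
    name="mtos_formulaAB",
    blunt=TraumaCoefficients(b0=-0.4499, b1=0.8085, b2=-0.0835, b3=-1.7430),
    penetrating=TraumaCoefficients(b0=-2.5355, b1=0.9934, b2=-0.0651, b3=-1.1360),
)

BUILTIN_COEFFICIENT_SETS = {c.name: c for c in (TABLE2, MTOS_FORMULA_AB)}


def resolve_coefficients(spec) -> CoefficientSet:
    """Accept a CoefficientSet, a built-in name, or a JSON file path."""
    if isinstance(spec, CoefficientSet):
        return spec
    if spec in BUILTIN_COEFFICIENT_SETS:
        return BUILTIN_COEFFICIENT_SETS[spec]
    try:
        return CoefficientSet.from_json(spec)
    except OSError:
        raise ValueError(
            f"unknown coefficient set {spec!r}; "
            f"built-ins: {sorted(BUILTIN_COEFFICIENT_SETS)}"
        ) from None


def age_point(age, cutoff: float = 55.0):
    """Age indicator: 0 below the cutoff, 1 at or above it. Vectorised."""
    a = np.asarray(age)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    pt = (a >= cutoff).astype(int)
    return int(pt) if np.isscalar(age) else pt


def triss_logit(rts, iss, trauma_type, age, coeffs: CoefficientSet = TABLE2):
    """TRISS logit for one patient.

    Applies the pediatric rule: penetrating trauma under age
    :data:`PEDIATRIC_AGE` uses the blunt coefficients.
    """
    if trauma_type not in ("blunt", "penetrating"):
        raise ValueError(f"unknown trauma type {trauma_type!r}")
    effective = "blunt" if (trauma_type == "penetrating" and age < PEDIATRIC_AGE) else trauma_type
    c = coeffs.for_type(effective)
    return c.b0 + c.b1 * rts + c.b2 * iss + c.b3 * age_point(age, coeffs.age_cutoff)


def probability_of_survival(logit):
    """Logistic transform of the logit; strictly increasing, Ps(0) = 0.5."""
    return expit(logit)


def classify_expected(ps) -> str:
    """Expected outcome: 'lived' iff Ps > 0.5, 'died' otherwise (tie dies)."""
    if not 0 < ps < 1:
        raise ValueError(f"Ps must be in (0, 1), got {ps!r}")
    return "lived" if ps > 0.5 else "died"


def predict_frame(df: pd.DataFrame, coeffs: CoefficientSet = TABLE2) -> pd.DataFrame:
    """Append ``logit``, ``ps`` and ``expected_outcome`` to a scored frame.

    Requires columns ``rts``, ``iss``, ``trauma_type`` and ``age``.
    """
    for col in ("rts", "iss", "trauma_type", "age"):
        if col not in df.columns:
            raise ValueError(f"predict_frame requires a scored frame with column {col!r}")
    out = df.copy()
    bad = set(df["trauma_type"]) - {"blunt", "penetrating"}
    if bad:
        raise ValueError(f"unknown trauma type(s) {sorted(bad)!r}")
    age = df["age"].to_numpy()
    penetrating = (df["trauma_type"] == "penetrating").to_numpy() & (age >= PEDIATRIC_AGE)
    b = np.where(penetrating[:, None],
                 [[coeffs.penetrating.b0, coeffs.penetrating.b1,
                   coeffs.penetrating.b2, coeffs.penetrating.b3]],
                 [[coeffs.blunt.b0, coeffs.blunt.b1, coeffs.blunt.b2, coeffs.blunt.b3]])
    apt = age_point(age, coeffs.age_cutoff)
    logit = (b[:, 0] + b[:, 1] * df["rts"].to_numpy()
             + b[:, 2] * df["iss"].to_numpy() + b[:, 3] * apt)
    ps = probability_of_survival(logit)
    out["logit"] = logit
    out["ps"] = ps
    out["expected_outcome"] = np.where(ps > 0.5, "lived", "died")
    return out
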