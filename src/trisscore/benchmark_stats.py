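"""Cohort-level outcome audit statistics.

Given per-patient survival probabilities (Ps) and observed outcomes, this
module computes the standard trauma-audit quantities used to compare a
cohort's outcomes against the expectation of the TRISS model:

* expected deaths ``E = sum(1 - Ps_i)`` (probability scale) and the
  threshold-classified expected-death count (``Ps <= 0.5``);
* SMR, the standardized mortality ratio ``observed / expected`` deaths;
* W, the excess survivors per 100 patients,
  ``(observed_survivors - expected_survivors) / (n / 100)``;
* Z (Flora's Z), the standardized survivor excess
  ``(observed_survivors - sum Ps_i) / sqrt(sum Ps_i (1 - Ps_i))``,
  approximately standard normal when outcomes are Bernoulli(Ps_i);
* M, the case-mix match: cohort and reference Ps distributions are binned
  into six survival-probability bands and ``M = sum_bands min(f_cohort,
  f_reference)``; M = 1 means identical case mix, values well below 1 mean
  W and Z comparisons against that reference are not meaningful.

Ps bands follow the conventional presentation 0.96-1.00, 0.91-0.95,
0.76-0.90, 0.51-0.75, 0.26-0.50, 0.00-0.25.  Binning operates on the
unrounded Ps with half-open interiors — [0, 0.255), [0.255, 0.505),
[0.505, 0.755), [0.755, 0.905), [0.905, 0.955), [0.955, 1] — which makes
results bit-reproducible without a rounding step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PS_BAND_EDGES", "PS_BAND_LABELS",
    "expected_deaths", "smr", "w_statistic", "z_statistic",
    "ps_band_fractions", "m_statistic",
    "OutcomeTable", "outcome_table", "BenchmarkReport", "benchmark_report",
]

#: Interior edges of the six Ps bands, lowest band first.
PS_BAND_EDGES = np.array([0.0, 0.255, 0.505, 0.755, 0.905, 0.955, 1.0])
#: Labels for the six bands, lowest survival first (matches the edges).
PS_BAND_LABELS = ("0.00-0.25", "0.26-0.50", "0.51-0.75",
                  "0.76-0.90", "0.91-0.95", "0.96-1.00")


def _check_ps(ps_list) -> np.ndarray:
    ps = np.asarray(ps_list, dtype=float)
    if ps.size == 0:
        raise ValueError("empty cohort: no survival probabilities")
    if np.any(~np.isfinite(ps)) or np.any(ps <= 0) or np.any(ps >= 1):
        raise ValueError("all survival probabilities must lie strictly in (0, 1)")
    return ps


def expected_deaths(ps_list) -> float:
    """Model-expected death count on the probability scale, sum(1 - Ps)."""
    ps = _check_ps(ps_list)
    return float(np.sum(1.0 - ps))


def smr(observed_deaths: float, expected: float) -> float:
    """Standardized mortality ratio, observed / expected deaths."""
    if not expected > 0:
        raise ValueError("expected deaths must be > 0 for an SMR")
    if observed_deaths < 0:
        raise ValueError("observed deaths must be >= 0")
    return observed_deaths / expected


def w_statistic(observed_survivors: float, expected_survivors: float, n: int) -> float:
    """Excess survivors per 100 patients; positive when care beats the model."""
    if not n > 0:
        raise ValueError("cohort size must be > 0")
    return (observed_survivors - expected_survivors) / (n / 100.0)


def z_statistic(observed_survivors: float, ps_list) -> float:
    """Flora's Z: standardized survivor excess, ~ N(0, 1) under the model."""
    ps = _check_ps(ps_list)
    var = float(np.sum(ps * (1.0 - ps)))
    if var <= 0:
        raise ValueError("degenerate cohort: zero outcome variance")
    return float((observed_survivors - np.sum(ps)) / np.sqrt(var))


def ps_band_fractions(ps_list) -> np.ndarray:
    """Fraction of patients in each of the six Ps bands, lowest band first."""
    ps = _check_ps(ps_list)
    counts, _ = np.histogram(ps, bins=PS_BAND_EDGES)
    return counts / ps.size


def m_statistic(ps_list, baseline_fractions) -> float:
    """Case-mix match against a reference band distribution, in [0, 1].

    ``baseline_fractions`` gives the reference cohort's fraction in each of
    the six Ps bands, ordered lowest band first (same order as
    :data:`PS_BAND_LABELS`), and must sum to 1.
    """
    baseline = np.asarray(baseline_fractions, dtype=float)
    if baseline.shape != (6,):
        raise ValueError("baseline_fractions must have six entries (one per Ps band)")
    if np.any(baseline < 0) or abs(baseline.sum() - 1.0) > 1e-9:
        raise ValueError("baseline_fractions must be non-negative and sum to 1")
    cohort = ps_band_fractions(ps_list)
    return float(np.sum(np.minimum(cohort, baseline)))


_LEVELS = {"expected": ("died", "lived"),
           "observed": ("died", "lived"),
           "trauma_type": ("penetrating", "blunt")}


@dataclass(frozen=True, eq=False)
class OutcomeTable:
    """Expected x observed x trauma-type outcome counts.

    ``counts[i, j, k]`` indexes (expected died/lived, observed died/lived,
    penetrating/blunt) in the level order of the class attributes.
    """

    counts: np.ndarray = field()

    expected_levels = _LEVELS["expected"]
    observed_levels = _LEVELS["observed"]
    trauma_levels = _LEVELS["trauma_type"]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2, 2) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 2x2x2 array")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def expected_deaths(self) -> int:
        """Threshold-classified expected-death count (both trauma types)."""
        return int(self.counts[0].sum())

    @property
    def expected_survivors(self) -> int:
        return int(self.counts[1].sum())

    @property
    def observed_deaths(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def observed_survivors(self) -> int:
        return int(self.counts[:, 1].sum())

    def to_frame(self) -> pd.DataFrame:
        """Flat tidy frame with one row per (expected, observed, type) cell."""
        rows = [
            {"expected": e, "observed": o, "trauma_type": t,
             "count": int(self.counts[i, j, k])}
            for i, e in enumerate(self.expected_levels)
            for j, o in enumerate(self.observed_levels)
            for k, t in enumerate(self.trauma_levels)
        ]
        return pd.DataFrame(rows)

    def margins_frame(self) -> pd.DataFrame:
        """Expected and observed death/survival counts by trauma type."""
        idx = pd.Index(["died", "lived"], name="outcome")
        data = {
            ("expected", t): self.counts[:, :, k].sum(axis=1)
            for k, t in enumerate(self.trauma_levels)
        } | {
            ("observed", t): self.counts[:, :, k].sum(axis=0)
            for k, t in enumerate(self.trauma_levels)
        }
        return pd.DataFrame(data, index=idx)


def outcome_table(expected_outcomes, observed_outcomes, trauma_types) -> OutcomeTable:
    """Cross-tabulate expected vs observed outcome by trauma type."""
    exp = np.asarray(expected_outcomes)
    obs = np.asarray(observed_outcomes)
    typ = np.asarray(trauma_types)
    if not (exp.shape == obs.shape == typ.shape):
        raise ValueError("expected, observed and trauma_type inputs must have equal length")
    for name, arr, levels in (("expected", exp, _LEVELS["expected"]),
                              ("observed", obs, _LEVELS["observed"]),
                              ("trauma_type", typ, _LEVELS["trauma_type"])):
        bad = set(arr) - set(levels)
        if bad:
            raise ValueError(f"unknown {name} level(s) {sorted(bad)!r}")
    counts = np.zeros((2, 2, 2), dtype=int)
    for i, e in enumerate(_LEVELS["expected"]):
        for j, o in enumerate(_LEVELS["observed"]):
            for k, t in enumerate(_LEVELS["trauma_type"]):
                counts[i, j, k] = int(np.sum((exp == e) & (obs == o) & (typ == t)))
    return OutcomeTable(counts)


@dataclass(frozen=True)
class BenchmarkReport:
    """Cohort-level audit summary.

    ``expected_deaths`` is the probability-scale count sum(1 - Ps);
    ``expected_deaths_classified`` counts patients with Ps <= 0.5.  The SMR
    uses the probability-scale expectation.  ``m`` is None when no reference
    case mix was supplied.
    """

    n: int
    observed_deaths: int
    expected_deaths: float
    expected_deaths_classified: int
    smr: float
    w: float
    z: float
    m: float | None
    outcome_table: OutcomeTable

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "observed_deaths": self.observed_deaths,
            "expected_deaths": self.expected_deaths,
            "expected_deaths_classified": self.expected_deaths_classified,
            "smr": self.smr,
            "w": self.w,
            "z": self.z,
            "m": self.m,
            "outcome_table": self.outcome_table.to_frame().to_dict(orient="records"),
        }


def benchmark_report(ps_list, observed_outcomes, trauma_types,
                     baseline_fractions=None) -> BenchmarkReport:
    """Full audit of a predicted cohort against its observed outcomes."""
    ps = _check_ps(ps_list)
    obs = np.asarray(observed_outcomes)
    n = ps.size
    if obs.shape != ps.shape:
        raise ValueError("ps and observed outcomes must have equal length")
    expected = [("lived" if p > 0.5 else "died") for p in ps]
    table = outcome_table(expected, obs, trauma_types)
    observed_deaths = int(np.sum(obs == "died"))
    e_deaths = expected_deaths(ps)
    return BenchmarkReport(
        n=n,
        observed_deaths=observed_deaths,
        expected_deaths=e_deaths,
        expected_deaths_classified=table.expected_deaths,
        smr=smr(observed_deaths, e_deaths),
        w=w_statistic(n - observed_deaths, float(np.sum(ps)), n),
        z=z_statistic(n - observed_deaths, ps),
        m=None if baseline_fractions is None else m_statistic(ps, baseline_fractions),
        outcome_table=table,
    )
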