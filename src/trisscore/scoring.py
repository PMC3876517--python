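"""Physiological and anatomical trauma severity scores.

Three admission measurements — Glasgow Coma Scale (GCS), systolic blood
pressure (SBP) and respiratory rate (RR) — are each coded on an ordinal
0 (worst) to 4 (best) scale:

    ========  =========  ==========  ====
    GCS       SBP, mmHg  RR, /min    code
    ========  =========  ==========  ====
    13-15     > 89       10-29       4
    9-12      76-89      > 29        3
    6-8       50-75      6-9         2
    4-5       1-49       1-5         1
    3         0          0           0
    ========  =========  ==========  ====

The Revised Trauma Score (RTS) is the weighted sum of the three codes with
default weights 0.9368 (GCS), 0.7328 (SBP), 0.2908 (RR), range 0-7.8416.
The unweighted code sum is the triage RTS, range 0-12.

The Injury Severity Score (ISS) is computed from the worst AIS grade in each
of six body regions: the three highest grades are squared and summed
(range 0-75); any unsurvivable injury (AIS 6) forces ISS = 75.

Non-integer SBP/RR are rounded to the nearest integer (halves away from
zero) before coding, because the coding table is stated over integers and
leaves gaps for real-valued inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry_io import AIS_COLUMNS, Registry

__all__ = [
    "CodedPhysiology", "ScoreWeights", "DEFAULT_WEIGHTS",
    "code_gcs", "code_sbp", "code_rr",
    "revised_trauma_score", "triage_rts", "injury_severity_score",
    "score_frame", "score_registry",
]


@dataclass(frozen=True)
class CodedPhysiology:
    """The coded (0-4) GCS / SBP / RR triple for one patient."""

    gcs_code: int
    sbp_code: int
    rr_code: int

    def __post_init__(self):
        for name in ("gcs_code", "sbp_code", "rr_code"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"{name} must be in 0..4, got {v!r}")


@dataclass(frozen=True)
class ScoreWeights:
    """RTS weights for the coded GCS, SBP and RR values."""

    w_gcs: float = 0.9368
    w_sbp: float = 0.7328
    w_rr: float = 0.2908

    def __post_init__(self):
        if not (self.w_gcs > 0 and self.w_sbp > 0 and self.w_rr > 0):
            raise ValueError("score weights must all be positive")

    @property
    def max_rts(self) -> float:
        return 4 * (self.w_gcs + self.w_sbp + self.w_rr)


DEFAULT_WEIGHTS = ScoreWeights()


def _round_half_away(x):
    """Round to nearest integer, halves away from zero (not banker's)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def code_gcs(gcs):
    """Code a Glasgow Coma Scale value (3-15) to 0-4. Vectorised."""
    g = np.asarray(gcs)
    if np.any((g < 3) | (g > 15) | (g != np.round(g))):
        raise ValueError(f"GCS must be an integer in [3, 15], got {gcs!r}")
    code = np.select([g >= 13, g >= 9, g >= 6, g >= 4], [4, 3, 2, 1], default=0)
    return int(code) if np.isscalar(gcs) else code


def code_sbp(sbp):
    """Code a systolic blood pressure (mmHg, >= 0) to 0-4. Vectorised."""
    s = np.asarray(sbp, dtype=float)
    if np.any(~np.isfinite(s) | (s < 0)):
        raise ValueError(f"SBP must be a finite number >= 0, got {sbp!r}")
    s = _round_half_away(s)
    code = np.select([s > 89, s >= 76, s >= 50, s >= 1], [4, 3, 2, 1], default=0)
    return int(code) if np.isscalar(sbp) else code


def code_rr(rr):
    """Code a respiratory rate (breaths/min, >= 0) to 0-4. Vectorised.

    Note the non-monotone top of the scale: 10-29 codes to 4 while
    tachypnoea above 29 codes to 3.
    """
    r = np.asarray(rr, dtype=float)
    if np.any(~np.isfinite(r) | (r < 0)):
        raise ValueError(f"RR must be a finite number >= 0, got {rr!r}")
    r = _round_half_away(r)
    code = np.select([r > 29, r >= 10, r >= 6, r >= 1], [3, 4, 2, 1], default=0)
    return int(code) if np.isscalar(rr) else code


def revised_trauma_score(codes: CodedPhysiology,
                         weights: ScoreWeights = DEFAULT_WEIGHTS) -> float:
    """Weighted RTS for one coded triple; in [0, 7.8416] with defaults."""
    return (weights.w_gcs * codes.gcs_code
            + weights.w_sbp * codes.sbp_code
            + weights.w_rr * codes.rr_code)


def triage_rts(codes: CodedPhysiology) -> int:
    """Unweighted sum of the three physiological codes, range 0-12."""
    return codes.gcs_code + codes.sbp_code + codes.rr_code


def injury_severity_score(ais) -> int:
    """ISS from the per-region maximum AIS grades of the six body regions.

    ``ais`` is a mapping region -> grade or a length-6 sequence of grades
    in [0, 6].  Any grade of 6 (unsurvivable) forces the maximum ISS of 75;
    otherwise ISS is the sum of squares of the three highest grades.
    """
    from collections.abc import Mapping
    grades = np.asarray(
        [ais[k] for k in sorted(ais)] if isinstance(ais, Mapping) else list(ais)
    )
    if grades.shape != (6,):
        raise ValueError("ISS requires exactly six per-region AIS grades")
    if np.any((grades < 0) | (grades > 6) | (grades != np.round(grades))):
        raise ValueError(f"AIS grades must be integers in [0, 6], got {list(grades)}")
    if np.any(grades == 6):
        return 75
    top3 = np.sort(grades)[-3:]
    return int(np.sum(top3 ** 2))


def _iss_array(ais_matrix: np.ndarray) -> np.ndarray:
    """Vectorised ISS over an (n, 6) grade matrix."""
    if np.any((ais_matrix < 0) | (ais_matrix > 6)):
        raise ValueError("AIS grades must be in [0, 6]")
    top3 = np.sort(ais_matrix, axis=1)[:, -3:]
    iss = np.sum(top3 ** 2, axis=1)
    iss[np.any(ais_matrix == 6, axis=1)] = 75
    return iss.astype(int)


def score_frame(df: pd.DataFrame,
                weights: ScoreWeights = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Append score columns to a registry frame.

    Adds ``gcs_code``, ``sbp_code``, ``rr_code``, ``rts``, ``triage_rts``
    and ``iss``; returns a new DataFrame, input untouched.
    """
    out = df.copy()
    g = code_gcs(df["gcs"].to_numpy())
    s = code_sbp(df["sbp"].to_numpy())
    r = code_rr(df["rr"].to_numpy())
    out["gcs_code"] = g
    out["sbp_code"] = s
    out["rr_code"] = r
    out["rts"] = weights.w_gcs * g + weights.w_sbp * s + weights.w_rr * r
    out["triage_rts"] = g + s + r
    out["iss"] = _iss_array(out[list(AIS_COLUMNS)].to_numpy())
    return out


def score_registry(registry: Registry,
                   weights: ScoreWeights = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Score every record of a registry; see :func:`score_frame`."""
    return score_frame(registry.to_frame(), weights=weights)
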