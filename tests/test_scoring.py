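"""Physiological coding, RTS and ISS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisscore.scoring import (
    CodedPhysiology,
    ScoreWeights,
    code_gcs,
    code_rr,
    code_sbp,
    injury_severity_score,
    revised_trauma_score,
    score_frame,
    triage_rts,
)

from conftest import make_frame, make_row


@pytest.mark.parametrize("gcs,code", [
    (15, 4), (13, 4), (12, 3), (9, 3), (8, 2), (6, 2), (5, 1), (4, 1), (3, 0),
])
def test_gcs_coding_table(gcs, code):
    assert code_gcs(gcs) == code


@pytest.mark.parametrize("sbp,code", [
    (120, 4), (90, 4), (89, 3), (76, 3), (75, 2), (50, 2), (49, 1), (1, 1), (0, 0),
    # non-integer inputs are rounded half away from zero before coding
    (89.5, 4), (89.4, 3), (75.5, 3), (0.4, 0), (0.5, 1),
])
def test_sbp_coding_table(sbp, code):
    assert code_sbp(sbp) == code


@pytest.mark.parametrize("rr,code", [
    (16, 4), (29, 4), (10, 4), (30, 3), (35, 3), (9, 2), (6, 2), (5, 1), (1, 1), (0, 0),
    (9.5, 4), (29.5, 3), (0.5, 1),
])
def test_rr_coding_table(rr, code):
    """Includes the non-monotone top: 10-29 codes 4, above 29 codes 3."""
    assert code_rr(rr) == code


@pytest.mark.parametrize("fn,bad", [
    (code_gcs, 2), (code_gcs, 16), (code_gcs, 7.5),
    (code_sbp, -1), (code_rr, -0.1),
])
def test_coding_rejects_out_of_range(fn, bad):
    with pytest.raises(ValueError):
        fn(bad)


@given(st.integers(3, 15), st.integers(0, 300), st.integers(0, 80))
def test_coding_partitions_domain(gcs, sbp, rr):
    """Every admissible input maps to exactly one code in 0..4."""
    assert code_gcs(gcs) in range(5)
    assert code_sbp(sbp) in range(5)
    assert code_rr(rr) in range(5)


@pytest.mark.parametrize("codes,rts", [
    ((0, 0, 0), 0.0),
    ((4, 4, 4), 7.8416),       # 4 * (0.9368 + 0.7328 + 0.2908)
    ((4, 3, 4), 7.1088),       # 4*0.9368 + 3*0.7328 + 4*0.2908
])
def test_revised_trauma_score(codes, rts):
    assert revised_trauma_score(CodedPhysiology(*codes)) == pytest.approx(rts)


@pytest.mark.parametrize("codes,total", [((4, 4, 4), 12), ((0, 0, 0), 0), ((4, 3, 2), 9)])
def test_triage_rts_is_code_sum(codes, total):
    assert triage_rts(CodedPhysiology(*codes)) == total


def test_rts_bounds_and_monotonicity():
    w = ScoreWeights()
    for triple in [(0, 0, 0), (4, 4, 4), (1, 2, 3), (4, 0, 2)]:
        rts = revised_trauma_score(CodedPhysiology(*triple), w)
        assert 0 <= rts <= w.max_rts
    # raising any one code raises the RTS
    base = revised_trauma_score(CodedPhysiology(2, 2, 2), w)
    for better in [(3, 2, 2), (2, 3, 2), (2, 2, 3)]:
        assert revised_trauma_score(CodedPhysiology(*better), w) > base


def test_score_weights_must_be_positive():
    with pytest.raises(ValueError):
        ScoreWeights(w_gcs=0.0)


def _iss_oracle(grades):
    """Brute force: sort, square the top three; any AIS 6 is unsurvivable."""
    if 6 in grades:
        return 75
    top = sorted(grades)[-3:]
    return sum(g * g for g in top)


@pytest.mark.parametrize("grades,iss", [
    ((6, 0, 0, 0, 0, 0), 75),
    ((0, 0, 0, 0, 0, 0), 0),
    ((3, 4, 2, 0, 0, 0), 29),     # 16 + 9 + 4
    ((5, 5, 5, 5, 5, 5), 75),     # sum of squares path, no AIS 6
    ((1, 0, 0, 0, 0, 0), 1),
])
def test_iss_examples(grades, iss):
    assert injury_severity_score(grades) == iss
    assert _iss_oracle(grades) == iss


def test_iss_accepts_region_mapping():
    ais = {"head_neck": 3, "face": 0, "chest": 4, "abdomen": 2,
           "extremities": 0, "external": 0}
    assert injury_severity_score(ais) == 29


@pytest.mark.parametrize("grades", [(7, 0, 0, 0, 0, 0), (-1, 0, 0, 0, 0, 0),
                                    (1, 1, 1, 1, 1), (1,) * 7])
def test_iss_rejects_bad_profiles(grades):
    with pytest.raises(ValueError):
        injury_severity_score(grades)


@settings(deadline=None)
@given(st.tuples(*[st.integers(0, 6)] * 6))
def test_iss_matches_brute_force_oracle(grades):
    assert injury_severity_score(grades) == _iss_oracle(grades)


@settings(deadline=None)
@given(st.tuples(*[st.integers(0, 6)] * 6), st.integers(0, 5), st.data())
def test_iss_monotone_in_each_grade(grades, region, data):
    """Raising any single AIS grade never decreases the ISS."""
    g = list(grades)
    if g[region] == 6:
        return
    raised = list(g)
    raised[region] = data.draw(st.integers(g[region] + 1, 6))
    assert injury_severity_score(raised) >= injury_severity_score(g)


def test_iss_value_set_excludes_non_sums_of_squares():
    """7 is not a sum of at most three squares of grades 1-5."""
    reachable = {
        injury_severity_score((a, b, c, 0, 0, 0))
        for a in range(6) for b in range(6) for c in range(6)
    }
    assert {7, 15, 23, 28} & reachable == set()
    assert {0, 1, 2, 3, 29, 75} <= reachable  # 75 via three grade-5 injuries


def test_score_frame_appends_expected_columns(tiny_frame):
    scored = score_frame(tiny_frame)
    for col in ("gcs_code", "sbp_code", "rr_code", "rts", "triage_rts", "iss"):
        assert col in scored.columns
    # row P1: gcs 15 / sbp 120 / rr 16 -> codes (4, 4, 4)
    assert scored.loc[0, "rts"] == pytest.approx(7.8416)
    assert scored.loc[0, "triage_rts"] == 12
    assert scored.loc[0, "iss"] == 14  # grades 2, 3, 1 -> 4 + 9 + 1
    # row P2: gcs 8 / sbp 70 / rr 4 -> codes (2, 2, 1)
    assert scored.loc[1, "rts"] == pytest.approx(2 * 0.9368 + 2 * 0.7328 + 0.2908)
    assert scored.loc[1, "iss"] == 26  # grades 4, 3, 1 -> 16 + 9 + 1


def test_score_frame_matches_scalar_path():
    rows = [make_row(f"P{i}", gcs=g, sbp=s, rr=r)
            for i, (g, s, r) in enumerate([(3, 0, 0), (9, 76, 30), (13, 95, 10)])]
    scored = score_frame(make_frame(rows))
    for i, row in scored.iterrows():
        codes = CodedPhysiology(code_gcs(int(row.gcs)), code_sbp(row.sbp),
                                code_rr(row.rr))
        assert row.rts == pytest.approx(revised_trauma_score(codes))
        assert row.triage_rts == triage_rts(codes)
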