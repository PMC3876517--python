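"""Cohort audit statistics: expected deaths, SMR, W, Z, M, outcome table."""

import numpy as np
import pytest

from trisscore.benchmark_stats import (
    PS_BAND_EDGES,
    benchmark_report,
    expected_deaths,
    m_statistic,
    outcome_table,
    ps_band_fractions,
    smr,
    w_statistic,
    z_statistic,
)


def test_expected_deaths_hand_value():
    assert expected_deaths([0.9, 0.7, 0.5]) == pytest.approx(0.9)


def test_expected_deaths_limits():
    eps = 1e-9
    assert expected_deaths([1 - eps] * 50) == pytest.approx(0.0, abs=1e-6)
    assert expected_deaths([0.915] * 200) == pytest.approx(0.085 * 200)
    with pytest.raises(ValueError):
        expected_deaths([])
    with pytest.raises(ValueError):
        expected_deaths([0.5, 1.0])


def test_smr_examples():
    assert smr(97, 85) == pytest.approx(97 / 85)
    assert smr(12.0, 12.0) == 1.0
    assert smr(0, 5.0) == 0.0
    with pytest.raises(ValueError):
        smr(3, 0.0)


@pytest.mark.parametrize("obs,exp,n,w", [
    (915, 915.0, 1000, 0.0),
    (903, 915.0, 1000, -1.2),
    (93, 91.5, 100, 1.5),
])
def test_w_statistic_hand_values(obs, exp, n, w):
    assert w_statistic(obs, exp, n) == pytest.approx(w)


def test_z_statistic_hand_values():
    ps = np.full(100, 0.8)
    assert z_statistic(float(ps.sum()), ps) == pytest.approx(0.0)
    assert z_statistic(1, [0.5]) == pytest.approx(1.0)  # (1 - 0.5) / 0.5
    with pytest.raises(ValueError):
        z_statistic(1, [1.0, 0.0])  # degenerate all-certain limit


def test_z_statistic_null_distribution():
    """Z is approximately standard normal for Bernoulli(Ps) outcomes."""
    rng = np.random.default_rng(42)
    ps = rng.uniform(0.6, 0.99, size=1000)
    zs = []
    for _ in range(300):
        survived = rng.random(1000) < ps
        zs.append(z_statistic(int(survived.sum()), ps))
    assert abs(np.mean(zs)) < 3 / np.sqrt(300)
    assert 0.85 < np.std(zs) < 1.15


def test_band_edges_are_half_open_below_upper():
    fractions = ps_band_fractions([0.2549, 0.255, 0.5049, 0.96, 0.999])
    assert fractions.sum() == pytest.approx(1.0)
    assert fractions[0] == pytest.approx(1 / 5)   # 0.2549
    assert fractions[1] == pytest.approx(2 / 5)   # 0.255 and 0.5049
    assert fractions[5] == pytest.approx(2 / 5)   # 0.96 and 0.999


def test_m_statistic_examples():
    ps_top = [0.97] * 10
    identical = ps_band_fractions(ps_top)
    assert m_statistic(ps_top, identical) == pytest.approx(1.0)
    disjoint = [1.0, 0, 0, 0, 0, 0]  # all baseline mass in the lowest band
    assert m_statistic(ps_top, disjoint) == pytest.approx(0.0)
    # cohort (.5, .5, 0...) vs baseline (.25, .25, .5, 0...) -> 0.5
    cohort = [0.1] * 5 + [0.3] * 5
    baseline = [0.25, 0.25, 0.5, 0, 0, 0]
    assert m_statistic(cohort, baseline) == pytest.approx(0.5)


def test_m_statistic_validates_baseline():
    with pytest.raises(ValueError):
        m_statistic([0.9], [0.5, 0.5])
    with pytest.raises(ValueError):
        m_statistic([0.9], [0.5, 0.5, 0.1, 0, 0, 0])


def test_m_statistic_symmetric_and_order_invariant():
    rng = np.random.default_rng(3)
    ps_a = rng.uniform(0.01, 0.99, 400)
    ps_b = rng.beta(8, 1, 400).clip(0.01, 0.99)
    m_ab = m_statistic(ps_a, ps_band_fractions(ps_b))
    m_ba = m_statistic(ps_b, ps_band_fractions(ps_a))
    assert m_ab == pytest.approx(m_ba)
    shuffled = rng.permutation(ps_a)
    assert m_statistic(shuffled, ps_band_fractions(ps_b)) == pytest.approx(m_ab)


def test_outcome_table_direct_tally():
    expected = ["died"] * 3 + ["lived"] * 7
    observed = ["died"] * 3 + ["lived"] * 7
    types = ["blunt"] * 10
    table = outcome_table(expected, observed, types)
    blunt = table.counts[:, :, 1]
    assert blunt[0, 0] == 3 and blunt[1, 1] == 7
    assert blunt[0, 1] == 0 and blunt[1, 0] == 0
    # empty penetrating stratum, margins still consistent
    assert table.counts[:, :, 0].sum() == 0
    assert table.n == 10
    assert table.expected_deaths == table.observed_deaths == 3


def test_outcome_table_margins_reconcile():
    rng = np.random.default_rng(0)
    n = 200
    expected = rng.choice(["died", "lived"], n)
    observed = rng.choice(["died", "lived"], n)
    types = rng.choice(["blunt", "penetrating"], n)
    table = outcome_table(expected, observed, types)
    assert table.expected_deaths + table.expected_survivors == n
    assert table.observed_deaths + table.observed_survivors == n
    margins = table.margins_frame()
    assert margins[("expected", "blunt")].sum() == int(np.sum(types == "blunt"))


def test_outcome_table_rejects_bad_input():
    with pytest.raises(ValueError):
        outcome_table(["died"], ["died", "lived"], ["blunt", "blunt"])
    with pytest.raises(ValueError):
        outcome_table(["died"], ["maybe"], ["blunt"])


def test_benchmark_report_consistency():
    rng = np.random.default_rng(11)
    ps = rng.uniform(0.05, 0.99, 500)
    observed = np.where(rng.random(500) < ps, "lived", "died")
    types = np.where(rng.random(500) < 0.1, "penetrating", "blunt")
    rep = benchmark_report(ps, observed, types)
    assert rep.n == 500
    assert rep.smr == pytest.approx(rep.observed_deaths / rep.expected_deaths)
    assert rep.expected_deaths + float(np.sum(ps)) == pytest.approx(500)
    assert rep.expected_deaths_classified == int(np.sum(ps <= 0.5))
    assert rep.outcome_table.observed_deaths == rep.observed_deaths
    assert rep.m is None
    with_m = benchmark_report(ps, observed, types, ps_band_fractions(ps))
    assert with_m.m == pytest.approx(1.0)
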