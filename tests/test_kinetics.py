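"""Receptor scheme construction and single-receptor stochastic stepping."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from spinesim import kinetics as kin


@pytest.mark.parametrize("subtype", kin.SUBTYPES)
def test_scheme_structural_invariants(subtype):
    """Each scheme has one unbound resting state, one conducting state,
    positive rates, and ligand-consistent transitions."""
    sch = kin.build_scheme(subtype)
    assert sum(s.ligand_count == 0 for s in sch.states) == 1
    assert sum(s.open for s in sch.states) == 1
    idx = {s.name: s for s in sch.states}
    for t in sch.transitions:
        assert t.rate > 0
        dlig = idx[t.target].ligand_count - idx[t.source].ligand_count
        if t.order == kin.BIMOLECULAR:
            assert dlig == 1
            # its reverse (same pair, swapped) must shed one ligand
            rev = [u for u in sch.transitions
                   if u.source == t.target and u.target == t.source]
            assert rev and rev[0].order == kin.UNIMOLECULAR


def test_published_rate_values():
    """Spot-checks of the transcribed rate table against the published
    constants, including the glutamate-dependent AMPAR D1->D2 step."""
    nr2a = kin.build_scheme("NR2A")
    k_off = [t for t in nr2a.transitions if t.source == "RA"
             and t.target == "R"][0]
    assert k_off.rate == 1.010
    d2_rec = [t for t in nr2a.transitions if t.source == "D2"][0]
    assert d2_rec.rate == 0.00101
    ampar = kin.build_scheme("AMPAR")
    d1d2 = [t for t in ampar.transitions if t.source == "D1"
            and t.target == "D2"][0]
    assert d1d2.order == kin.BIMOLECULAR and d1d2.rate == 2108.2


def test_triheteromeric_rates_are_subtype_means():
    """Every shared gating/desensitization rate of the triheteromeric
    receptor equals the arithmetic mean of the NR2A and NR2B values."""
    for sym in kin.NMDAR_SHARED_SYMBOLS:
        expected = (kin.RATE_TABLE["NR2A"][sym]
                    + kin.RATE_TABLE["NR2B"][sym]) / 2.0
        # the tabulated triheteromeric values are rounded to the printed
        # precision (e.g. 0.318 for mean(0.0851, 0.550) = 0.31755)
        assert kin.RATE_TABLE["NR2A_NR2B"][sym] == pytest.approx(
            expected, rel=2e-3)
    tri = kin.build_scheme("NR2A_NR2B")
    ks = [t for t in tri.transitions if t.symbol == "k_s+"][0]
    assert ks.rate == 0.139


def test_unknown_subtype_rejected():
    with pytest.raises(ValueError):
        kin.build_scheme("NR2C")


def test_resting_receptor_inert_without_glutamate():
    """All exits from the unbound state are bimolecular, so a receptor
    never leaves rest without free glutamate."""
    rng = np.random.default_rng(0)
    for subtype in kin.SUBTYPES:
        rec = kin.ReceptorInstance(kin.build_scheme(subtype),
                                   np.zeros(3))
        for _ in range(500):
            kin.step_first_order(rec, 1.0, rng)
        assert rec.current_state == rec.scheme.resting_state.name
        assert len(rec.state_history) == 1


def test_step_exit_probability_matches_analytic():
    """Empirical exit frequency from the conducting state equals
    1 - exp(-K dt) within 3 binomial SEs."""
    sch = kin.build_scheme("NR2A")
    rng = np.random.default_rng(7)
    dt = 0.5
    k = sch.open_exit_rate()
    p_true = 1.0 - math.exp(-k * dt)
    n = 20_000
    exits = 0
    for _ in range(n):
        rec = kin.ReceptorInstance(sch, np.zeros(3), current_state="O")
        kin.step_first_order(rec, dt, rng)
        exits += rec.current_state != "O"
    se = math.sqrt(p_true * (1 - p_true) / n)
    assert abs(exits / n - p_true) < 3 * se


def test_stationary_distribution_eigenvector_vs_gillespie():
    """Long-run occupancy of the bound 5-state chain (unbinding removed)
    matches the linear-algebra stationary distribution."""
    sch = kin.build_scheme("NR2A")
    keep = ["RA2", "RA2s", "O", "D1", "D2"]
    pi = sch.stationary_distribution(keep=keep)
    # independent route: time-weighted occupancy of a long exact CTMC path
    rates = {}
    for t in sch.transitions:
        if t.source in keep and t.target in keep \
                and t.order == kin.UNIMOLECULAR:
            rates.setdefault(t.source, []).append((t.rate, t.target))
    rng = np.random.default_rng(3)
    occ = dict.fromkeys(keep, 0.0)
    state, t_total = "RA2", 0.0
    for _ in range(200_000):
        exits = rates[state]
        tot = sum(r for r, _ in exits)
        dwell = rng.exponential(1.0 / tot)
        occ[state] += dwell
        t_total += dwell
        u = rng.random() * tot
        acc = 0.0
        for r, tgt in exits:
            acc += r
            if u <= acc:
                state = tgt
                break
    emp = np.array([occ[s] / t_total for s in keep])
    assert np.allclose(emp, pi, atol=0.02)
    # conducting-state occupancy specifically
    assert abs(emp[keep.index("O")] - pi[keep.index("O")]) < 0.01


def test_open_time_distribution_exponential_mean():
    """Open-event durations are exponential with mean 1/(total exit rate)."""
    rng = np.random.default_rng(11)
    for subtype in ("NR2A", "AMPAR"):
        sch = kin.build_scheme(subtype)
        d = kin.open_time_distribution(sch, 100_000, rng)
        mu = 1.0 / sch.open_exit_rate()
        se = d.std(ddof=1) / math.sqrt(len(d))
        assert abs(d.mean() - mu) < 2 * se
    assert len(kin.open_time_distribution(sch, 1, rng)) == 1
    assert kin.open_time_distribution(sch, 1, rng)[0] > 0
    with pytest.raises(ValueError):
        kin.open_time_distribution(sch, 0, rng)


def test_open_durations_nmdar_longer_than_ampar():
    """Single-opening durations of every NMDAR subtype stochastically
    dominate AMPAR openings (KS, p < 0.01)."""
    rng = np.random.default_rng(5)
    ampar = kin.open_time_distribution(kin.build_scheme("AMPAR"), 5000, rng)
    for subtype in ("NR2A", "NR2B", "NR2A_NR2B"):
        nmdar = kin.open_time_distribution(kin.build_scheme(subtype), 5000,
                                           rng)
        res = sps.ks_2samp(nmdar, ampar)
        assert res.pvalue < 0.01
        assert nmdar.mean() > ampar.mean()


def test_activation_periods_nr2a_longer_than_nr2b():
    """Whole activation periods (gated intermediate + open, with
    flickering) are significantly longer for NR2A than NR2B receptors."""
    rng = np.random.default_rng(6)
    a = kin.activation_period_distribution(kin.build_scheme("NR2A"), 4000,
                                           rng)
    b = kin.activation_period_distribution(kin.build_scheme("NR2B"), 4000,
                                           rng)
    assert sps.ks_2samp(a, b).pvalue < 0.01
    assert a.mean() > b.mean()
    # analytic sojourn mean: (1 + kf+/kf-) / ks-
    r = kin.RATE_TABLE["NR2A"]
    mu = (1.0 + r["k_f+"] / r["k_f-"]) / r["k_s-"]
    assert a.mean() == pytest.approx(mu, rel=0.1)


def test_scheme_yaml_roundtrip_bit_exact():
    for subtype in kin.SUBTYPES:
        sch = kin.build_scheme(subtype)
        back = kin.ReceptorScheme.from_yaml(sch.to_yaml())
        assert back.to_dict() == sch.to_dict()
        for t1, t2 in zip(sch.transitions, back.transitions):
            assert t1.rate == t2.rate  # bit-exact float round trip
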