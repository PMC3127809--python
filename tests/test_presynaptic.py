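"""Vesicle release protocols and short-term presynaptic dynamics."""

import numpy as np
import pytest
from scipy import stats as sps

from spinesim import geometry as geo, presynaptic as presyn


@pytest.fixture(scope="module")
def g():
    return geo.build_geometry()


def test_single_release_basic(g):
    tr = presyn.single_release(1500, g)
    assert tr.n_releases == 1
    assert tr.events[0].time == 0.0
    assert tr.events[0].molecules == 1500
    assert tr.protocol == "single"
    mv = presyn.single_release(10000, g)
    assert mv.total_molecules == 10000
    assert mv.protocol == "multivesicular"


@pytest.mark.parametrize("bad", [0, -5, 200_000])
def test_single_release_rejects_bad_counts(g, bad):
    with pytest.raises(ValueError):
        presyn.single_release(bad, g)


def test_release_train_csv_roundtrip(g):
    tr = presyn.frequency_train(50, 200.0, g,
                                rng=np.random.default_rng(1))
    back = presyn.ReleaseTrain.from_csv(tr.to_csv(), "frequency_train",
                                        50, 200.0)
    assert [e.time for e in back.events] == [e.time for e in tr.events]
    assert [e.molecules for e in back.events] == \
        [e.molecules for e in tr.events]


def test_frequency_train_grid_and_bounds(g):
    tr = presyn.frequency_train(100, 1000.0, g,
                                rng=np.random.default_rng(2))
    assert tr.n_releases <= 100
    times = np.array([e.time for e in tr.events])
    # releases happen on the regular 10 ms spike grid
    assert np.allclose(times % 10.0, 0.0)
    assert all(e.molecules == presyn.TRAIN_VESICLE for e in tr.events)
    with pytest.raises(ValueError):
        presyn.frequency_train(0.5, 1000.0, g)
    with pytest.raises(ValueError):
        presyn.frequency_train(50, -1.0, g)


def test_release_count_binomial_with_dynamics_disabled(g):
    """With facilitation/augmentation/depletion off and fixed Pr, the
    number of releases per train is Binomial(n_spikes, Pr)."""
    params = presyn.PresynapticParams(pr0=0.3, facilitation=False,
                                      augmentation=False, deplete=False,
                                      refill=False)
    rng = np.random.default_rng(3)
    n_spikes, p = 20, 0.3
    counts = np.array([
        presyn.frequency_train(100, 200.0, g, params=params,
                               rng=rng).n_releases
        for _ in range(4000)])
    k = np.arange(n_spikes + 1)
    pmf = sps.binom.pmf(k, n_spikes, p)
    obs = np.bincount(counts, minlength=n_spikes + 1)
    # pool tail bins with expected < 5
    keep = pmf * len(counts) >= 5
    obs_p = np.append(obs[keep], obs[~keep].sum())
    exp_p = np.append(pmf[keep], pmf[~keep].sum()) * len(counts)
    chi2, pval = sps.chisquare(obs_p, exp_p)
    assert pval > 1e-3


def test_mean_release_count_monotone_in_frequency(g):
    rng = np.random.default_rng(4)
    means = []
    for f in (5, 10, 25, 50, 100):
        n = [presyn.frequency_train(f, 1000.0, g, rng=rng).n_releases
             for _ in range(400)]
        means.append(np.mean(n))
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


def test_pool_conservation_without_refill(g):
    params = presyn.PresynapticParams(refill=False)
    initial = params.rrp0 + params.recycling0
    for seed in range(5):
        tr, state = presyn.frequency_train(
            100, 1000.0, g, params=params,
            rng=np.random.default_rng(seed), return_state=True)
        assert state.rrp + state.recycling + tr.n_releases == initial
        assert state.rrp >= 0


def test_release_probability_clipped():
    params = presyn.PresynapticParams(pr0=0.9)
    st = presyn.PresynapticState(F=5.0, A=2.0)
    assert st.pr(params) == 1.0
    st = presyn.PresynapticState(F=1.0, A=1.0)
    assert 0.0 <= st.pr(params) <= 1.0


def test_facilitation_raises_release_probability(g):
    """At high frequency, facilitation accumulates and drives Pr (and the
    realized release rate) above the non-facilitated level."""
    base = presyn.PresynapticParams(facilitation=False, augmentation=False,
                                    deplete=False)
    fac = presyn.PresynapticParams(facilitation=True, augmentation=False,
                                   deplete=False)
    rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
    n_base = np.mean([presyn.frequency_train(100, 1000.0, g, params=base,
                                             rng=rng1).n_releases
                      for _ in range(200)])
    n_fac = np.mean([presyn.frequency_train(100, 1000.0, g, params=fac,
                                            rng=rng2).n_releases
                     for _ in range(200)])
    assert n_fac > n_base


def test_event_time_ordering_validated():
    with pytest.raises(ValueError):
        presyn.ReleaseTrain(
            [presyn.ReleaseEvent(5.0, 100, (0, 0, 9)),
             presyn.ReleaseEvent(1.0, 100, (0, 0, 9))], "single")
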