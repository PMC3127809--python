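"""Brownian-dynamics engine: binding-radius calibration, diffusion
statistics, conservation, determinism and dt-convergence."""

import math

import numpy as np
import pytest
from numba import njit

from spinesim import geometry as geo, presynaptic as presyn
from spinesim.engine import (SimulationConfig, binding_radius,
                             run_simulation, EV_BIND)
from conftest import single_release_runs


# ---------------------------------------------------------------------------
# binding radius
# ---------------------------------------------------------------------------

def test_binding_radius_limits_and_monotonicity():
    assert binding_radius(0.0, 0.2, 0.01) == 0.0
    radii = [binding_radius(k, 0.2, 0.01)
             for k in (2108.2, 4698.0, 7619.4, 47144.0, 52456.0)]
    assert all(b > a for a, b in zip(radii, radii[1:]))
    with pytest.raises(ValueError):
        binding_radius(-1.0, 0.2, 0.01)
    with pytest.raises(ValueError):
        binding_radius(1e12, 0.2, 0.01)  # beyond the diffusion limit


@njit(cache=True)
def _capture_mc(seed, n_part, box, rb, sigma, n_steps):
    """Independent well-mixed oracle: absorbing sphere at the centre of a
    periodic box; absorbed particles are re-injected uniformly."""
    np.random.seed(seed)
    x = np.random.uniform(-box / 2, box / 2, n_part)
    y = np.random.uniform(-box / 2, box / 2, n_part)
    z = np.random.uniform(-box / 2, box / 2, n_part)
    events = 0
    rb2 = rb * rb
    for _ in range(n_steps):
        for i in range(n_part):
            xi = x[i] + sigma * np.random.normal()
            yi = y[i] + sigma * np.random.normal()
            zi = z[i] + sigma * np.random.normal()
            # periodic wrap
            if xi > box / 2:
                xi -= box
            elif xi < -box / 2:
                xi += box
            if yi > box / 2:
                yi -= box
            elif yi < -box / 2:
                yi += box
            if zi > box / 2:
                zi -= box
            elif zi < -box / 2:
                zi += box
            if xi * xi + yi * yi + zi * zi < rb2:
                events += 1
                xi = np.random.uniform(-box / 2, box / 2)
                yi = np.random.uniform(-box / 2, box / 2)
                zi = np.random.uniform(-box / 2, box / 2)
            x[i] = xi
            y[i] = yi
            z[i] = zi
    return events


@pytest.mark.parametrize("k_on,box,n_steps", [
    (4698.0, 200.0, 400_000),     # small radius: denser box, longer run
    (52456.0, 300.0, 120_000),
])
def test_binding_radius_recovers_rate_within_5pct(k_on, box, n_steps):
    """A particle simulation with the calibrated radius reproduces the
    requested mass-action volume rate within 5%."""
    D, dt = 0.2, 0.01
    rb = binding_radius(k_on, D, dt)
    sigma = math.sqrt(2.0 * D * 1e6 * dt)
    n_part = 800
    events = _capture_mc(42, n_part, box, rb, sigma, n_steps)
    conc = n_part / box ** 3
    k_est = events / (n_steps * dt * conc)
    assert abs(k_est - k_on) / k_on < 0.05


# ---------------------------------------------------------------------------
# engine invariants
# ---------------------------------------------------------------------------

def test_msd_free_diffusion():
    """Mean-squared displacement of free particles equals 6 D t within 2%."""
    g = geo.build_geometry({"sleeve": False,
                            "box_size": (30000.0, 30000.0, 30000.0)})
    start = np.array([0.0, 0.0, 5000.0])
    train = presyn.ReleaseTrain(
        [presyn.ReleaseEvent(0.0, 20000, tuple(start))], "single")
    layout = geo.place_receptors(g, {"NR2B": 1}, np.random.default_rng(0))
    cfg = SimulationConfig(geometry=g, layout=layout, release=train,
                           duration=1.0, seed=5, adaptive=False,
                           record_cleft=False)
    tr = run_simulation(cfg)
    disp2 = np.sum((tr.final_positions - start) ** 2, axis=1)
    expected = 6.0 * 0.2e6 * 1.0
    assert abs(disp2.mean() - expected) / expected < 0.02


def test_no_release_stays_resting():
    g = geo.build_geometry()
    layout = geo.place_receptors(g, {"AMPAR": 40, "NR2A": 10},
                                 np.random.default_rng(1))
    train = presyn.ReleaseTrain([], "single")
    tr = run_simulation(SimulationConfig(geometry=g, layout=layout,
                                         release=train, duration=20.0,
                                         seed=9))
    assert len(tr.events["time"]) == 0
    assert tr.open_count("NR2A").max() == 0
    assert tr.open_count("AMPAR").max() == 0
    assert tr.free_count[-1] == 0


def test_glutamate_conservation_every_frame(nr2a_1500_runs):
    """Free + receptor-bound molecules equal cumulative released at every
    recorded frame (no uptake is modelled)."""
    for tr in nr2a_1500_runs[:4]:
        lhs = tr.free_count + tr.bound_ligands()
        assert np.array_equal(lhs.astype(int), tr.released)


def test_determinism_and_seed_sensitivity():
    g = geo.build_geometry()
    layout = geo.place_receptors(g, {"AMPAR": 20, "NR2A": 10},
                                 np.random.default_rng(3))
    train = presyn.single_release(800, g)

    def run(seed):
        return run_simulation(SimulationConfig(
            geometry=g, layout=layout, release=train, duration=20.0,
            seed=seed))

    a, b, c = run(11), run(11), run(12)
    assert np.array_equal(a.counts, b.counts)
    assert np.array_equal(a.events["time"], b.events["time"])
    assert not np.array_equal(a.counts, c.counts)


def test_cleft_transient_decays_rapidly(nr2a_1500_runs):
    """Cleft glutamate falls below 10% of its peak within 5 ms of a
    single vesicular release."""
    fracs = []
    for tr in nr2a_1500_runs:
        c = tr.cleft_count.astype(float)
        i5 = int(np.searchsorted(tr.times, 5.0))
        fracs.append(c[i5] / c.max())
    assert np.mean(fracs) < 0.10


def test_dt_convergence():
    """Peak open fractions at dt = 0.01 and 0.002 ms agree within
    replicate error."""
    peaks = {}
    for dt in (0.01, 0.002):
        runs = single_release_runs(1500, {"NR2A": 20}, 6, 40.0,
                                   seed_base=500, dt=dt)
        peaks[dt] = np.array([100 * r.open_count("NR2A").max() / 20
                              for r in runs])
    se = math.sqrt(peaks[0.01].var(ddof=1) / 6 + peaks[0.002].var(ddof=1) / 6)
    assert abs(peaks[0.01].mean() - peaks[0.002].mean()) <= 3 * se + 1e-9


def test_binding_events_reference_valid_receptors(nr2a_1500_runs):
    tr = nr2a_1500_runs[0]
    ev = tr.events
    n_rec = len(tr.rec_subtype)
    assert ev["receptor"].min() >= 0 and ev["receptor"].max() < n_rec
    binds = (ev["kind"] == EV_BIND).sum()
    assert binds > 0
    # time stamps non-decreasing
    assert np.all(np.diff(ev["time"]) >= 0)


def test_two_receptor_competition_fixture():
    """Two receptors straddling the release point both get bound over
    replicates (nearest-first assignment does not starve either)."""
    g = geo.build_geometry()
    z = -g.cleft_width / 2
    layout = geo.ReceptorLayout(
        positions=np.array([[-6.0, 0.0, z], [6.0, 0.0, z]]),
        normals=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
        subtypes=["NR2A", "NR2A"], regions=["synaptic", "synaptic"],
        populations=["NR2A", "NR2A"])
    bound = np.zeros(2)
    for seed in range(6):
        tr = run_simulation(SimulationConfig(
            geometry=g, layout=layout,
            release=presyn.single_release(2000, g), duration=5.0,
            seed=seed))
        ev = tr.events
        for r in (0, 1):
            bound[r] += ((ev["receptor"] == r)
                         & (ev["kind"] == EV_BIND)).sum()
    assert bound.min() > 0


def test_invalid_config_rejected():
    g = geo.build_geometry()
    layout = geo.place_receptors(g, {"NR2A": 5}, np.random.default_rng(0))
    train = presyn.single_release(100, g)
    with pytest.raises(ValueError):
        SimulationConfig(geometry=g, layout=layout, release=train,
                         duration=10.0, dt=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(geometry=g, layout=layout, release=train,
                         duration=-1.0)
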