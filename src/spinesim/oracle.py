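"""Independent well-mixed references for validating the particle engine.

Two routes that share no code with the spatial engine:

* a mean-field master-equation ODE integrator driven by a free-glutamate
  concentration waveform, and
* an exact stochastic simulation (Gillespie) of a single receptor under a
  piecewise-constant waveform.

Plus a registry of small deterministic fixture scenarios used by the test
suite.  All fixtures are generated programmatically; nothing is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .kinetics import ReceptorScheme, build_scheme


@dataclass
class WellMixedSystem:
    """A receptor scheme exposed to a spatially uniform glutamate
    concentration.

    The waveform is given on a time grid in ms with concentrations in
    molecules nm^-3 (1 mM ~ 6.022e-7 nm^-3); between grid points it is
    linearly interpolated for the ODE route and held piecewise-constant
    (left value) for the Gillespie route.
    """

    scheme: ReceptorScheme
    t_grid: np.ndarray              # ms
    conc: np.ndarray                # molecules / nm^3
    n_receptors: int = 1

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.t_grid.shape != self.conc.shape:
            raise ValueError("waveform grid and values must align")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")

    def conc_at(self, t: float) -> float:
        return float(np.interp(t, self.t_grid, self.conc))


MM_TO_NM3 = 6.02214076e-7   # molecules nm^-3 per mM


def ode_occupancy(system: WellMixedSystem,
                  t_eval: np.ndarray) -> np.ndarray:
    """Master-equation mean-field state probabilities on ``t_eval``.

    Solves dP/dt = Q(c(t))^T P with a stiff integrator (the rate constants
    span five orders of magnitude) starting from the resting state.
    Returns an array (len(t_eval), n_states).
    """
    sch = system.scheme
    n = sch.n_states
    cf = interp1d(system.t_grid, system.conc, kind="linear",
                  bounds_error=False,
                  fill_value=(system.conc[0], system.conc[-1]))

    def rhs(t, p):
        q = sch.rate_matrix(float(cf(t)))
        return q.T @ p

    p0 = np.zeros(n)
    p0[sch.state_index(sch.resting_state.name)] = 1.0
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), p0, t_eval=t_eval,
                    method="LSODA", rtol=1e-8, atol=1e-10, max_step=1.0)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def gillespie_run(system: WellMixedSystem, rng: np.random.Generator,
                  t_end: float | None = None):
    """Exact stochastic path of one receptor under the piecewise-constant
    waveform.  Returns (event_times, state_indices) with the initial
    resting state at t = 0."""
    sch = system.scheme
    t_end = float(system.t_grid[-1]) if t_end is None else t_end
    # piecewise-constant concentration: left value on each interval
    knots = system.t_grid
    state = sch.state_index(sch.resting_state.name)
    names = [s.name for s in sch.states]
    t = 0.0
    times = [0.0]
    path = [state]
    while t < t_end:
        seg = int(np.searchsorted(knots, t, side="right") - 1)
        seg = min(max(seg, 0), len(knots) - 1)
        c = float(system.conc[seg])
        seg_end = float(knots[seg + 1]) if seg + 1 < len(knots) else t_end
        exits = []
        for tr in sch.transitions:
            if tr.source != names[state]:
                continue
            rate = tr.rate * c if tr.order == "bimolecular" else tr.rate
            if rate > 0:
                exits.append((rate, sch.state_index(tr.target)))
        if not exits:
            t = seg_end
            if seg + 1 >= len(knots):
                break
            continue
        total = sum(r for r, _ in exits)
        wait = rng.exponential(1.0 / total)
        if t + wait >= min(seg_end, t_end):
            # no event before the segment/horizon ends; rates change there
            t = min(seg_end, t_end)
            if t >= t_end:
                break
            continue
        t += wait
        u = rng.random() * total
        acc = 0.0
        for rate, tgt in exits:
            acc += rate
            if u <= acc:
                state = tgt
                break
        times.append(t)
        path.append(state)
    return np.array(times), np.array(path, dtype=int)


def gillespie_occupancy(system: WellMixedSystem, rng: np.random.Generator,
                        t_eval: np.ndarray, n_runs: int) -> np.ndarray:
    """Ensemble mean state occupancy over ``n_runs`` exact paths."""
    t_eval = np.asarray(t_eval, dtype=float)
    out = np.zeros((len(t_eval), system.scheme.n_states))
    for _ in range(n_runs):
        times, path = gillespie_run(system, rng, t_end=float(t_eval[-1]))
        idx = np.searchsorted(times, t_eval, side="right") - 1
        for j, k in enumerate(idx):
            out[j, path[k]] += 1
    return out / n_runs


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def _fixture_null_spine() -> dict:
    return {
        "name": "null_spine",
        "description": "default spine, no glutamate release; every receptor "
                       "must remain in its resting state",
        "geometry": {},
        "composition": {"AMPAR": 80, "NR2A": 20},
        "molecules": 0,
        "duration": 10.0,
        "seeds": [1, 2, 3],
    }


def _fixture_calibration_box() -> dict:
    return {
        "name": "calibration_box",
        "description": "closed 300 nm periodic box with one absorbing site; "
                       "recovered on-rate must match the requested k_on "
                       "within 5%",
        "box_nm": 300.0,
        "n_particles": 1000,
        "n_steps": 200_000,
        "dt": 0.01,
        "D_glu": 0.2,
    }


def _fixture_two_receptor_cleft() -> dict:
    return {
        "name": "two_receptor_cleft",
        "description": "two NR2A receptors 12 nm apart under the release "
                       "point; exercises nearest-receptor tie-breaking",
        "geometry": {},
        "positions": [[-6.0, 0.0, -10.0], [6.0, 0.0, -10.0]],
        "molecules": 200,
        "duration": 5.0,
    }


def _fixture_fig3_reduced() -> dict:
    return {
        "name": "fig3_reduced",
        "description": "dynamic-range scenario at reduced replication "
                       "(10 seeds, 100 ms window)",
        "composition": {"AMPAR": 80, "NR2A": 20},
        "molecules": 1500,
        "duration": 100.0,
        "seeds": list(range(10)),
    }


_FIXTURES: dict[str, Callable[[], dict]] = {
    "null_spine": _fixture_null_spine,
    "calibration_box": _fixture_calibration_box,
    "two_receptor_cleft": _fixture_two_receptor_cleft,
    "fig3_reduced": _fixture_fig3_reduced,
}


def make_fixture(name: str) -> dict:
    """Deterministic small scenario configurations for the test suite."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(_FIXTURES)}")
    return _FIXTURES[name]()
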