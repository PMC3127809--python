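"""Receptor gating kinetics.

Continuous-time Markov chains for the four glutamate-receptor species carried
by the model spine:

* ``AMPAR`` -- the Jonas scheme: two sequential glutamate bindings, a single
  conducting state and three desensitized states (one of which, D1->D2, is
  re-entered by binding a further glutamate molecule).
* ``NR2A`` / ``NR2B`` -- the Erreger diheteromeric NMDAR schemes: two
  equivalent glutamate sites (the first binding carries the statistical
  factor 2*k_on; dissociation uses the tabulated k_off), a slow and a fast
  gating step in series, and two desensitized states entered from the
  doubly-bound closed state.
* ``NR2A_NR2B`` -- the triheteromeric NMDAR: one NR2A-like and one NR2B-like
  glutamate site, each with its own on/off rates, gating and desensitization
  rates equal to the arithmetic mean of the two parent subtypes.

Rate conventions: unimolecular rates in ms^-1, bimolecular rates in
nm^3 ms^-1 (a volume rate; multiply by a concentration in molecules nm^-3 to
obtain a propensity in ms^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

SUBTYPES = ("AMPAR", "NR2A", "NR2B", "NR2A_NR2B")

#: Published rate constants for each receptor species.  Diheteromeric NMDAR
#: entries are the Erreger values, triheteromeric entries the site-resolved
#: NR2A/NR2B rates with averaged gating/desensitization, AMPAR entries the
#: Jonas values.  Units: *_on rates nm^3 ms^-1, everything else ms^-1.
RATE_TABLE: dict[str, dict[str, float]] = {
    "NR2A": {
        "k_on": 52456.0, "k_off": 1.010,
        "k_s+": 0.230, "k_s-": 0.178,
        "k_f+": 3.140, "k_f-": 0.174,
        "k_d1+": 0.0851, "k_d1-": 0.0297,
        "k_d2+": 0.230, "k_d2-": 0.00101,
    },
    "NR2B": {
        "k_on": 4698.0, "k_off": 0.0381,
        "k_s+": 0.048, "k_s-": 0.230,
        "k_f+": 2.836, "k_f-": 0.175,
        "k_d1+": 0.550, "k_d1-": 0.0814,
        "k_d2+": 0.112, "k_d2-": 0.00091,
    },
    "NR2A_NR2B": {
        "k_on-A": 52456.0, "k_off-A": 1.010,
        "k_on-B": 4698.0, "k_off-B": 0.0381,
        "k_s+": 0.139, "k_s-": 0.204,
        "k_f+": 2.988, "k_f-": 0.1745,
        "k_d1+": 0.318, "k_d1-": 0.0556,
        "k_d2+": 0.171, "k_d2-": 0.00096,
    },
    "AMPAR": {
        "k_R-RA": 7619.4, "k_RA-R": 4.260,
        "k_RA-RA2": 47144.0, "k_RA2-RA": 3.260,
        "k_RA2-O": 4.240, "k_O-RA2": 0.900,
        "k_RA-D1": 2.890, "k_D1-RA": 0.0392,
        "k_RA2-D2": 0.172, "k_D2-RA2": 0.000727,
        "k_O-D3": 0.0177, "k_D3-O": 0.004,
        "k_D1-D2": 2108.2, "k_D2-D1": 0.0457,
        "k_D2-D3": 0.0168, "k_D3-D2": 0.1904,
    },
}

#: Gating/desensitization symbols shared by the three NMDAR species; the
#: triheteromeric value of each is the mean of the NR2A and NR2B values.
NMDAR_SHARED_SYMBOLS = (
    "k_s+", "k_s-", "k_f+", "k_f-", "k_d1+", "k_d1-", "k_d2+", "k_d2-",
)

UNIMOLECULAR = "unimolecular"
BIMOLECULAR = "bimolecular"


@dataclass(frozen=True)
class State:
    """One receptor conformation.

    ``activated`` marks the conformations reached after the slow gating step
    (the gated intermediate and the open state for NMDARs; the open state
    alone for AMPARs); ``open`` marks the single conducting state.
    """

    name: str
    ligand_count: int
    open: bool = False
    desensitized: bool = False
    activated: bool = False


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate: float
    order: str  # UNIMOLECULAR or BIMOLECULAR
    symbol: str = ""


@dataclass
class ReceptorScheme:
    """A labelled CTMC for one receptor species."""

    subtype_id: str
    states: list[State]
    transitions: list[Transition]

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.states)}
        self.validate()

    # -- lookups ----------------------------------------------------------
    def state_index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def resting_state(self) -> State:
        return next(s for s in self.states if s.ligand_count == 0)

    @property
    def open_state(self) -> State:
        return next(s for s in self.states if s.open)

    def unimolecular_out(self, name: str) -> list[Transition]:
        return [t for t in self.transitions
                if t.source == name and t.order == UNIMOLECULAR]

    def bimolecular_out(self, name: str) -> list[Transition]:
        return [t for t in self.transitions
                if t.source == name and t.order == BIMOLECULAR]

    def open_exit_rate(self) -> float:
        return sum(t.rate for t in self.unimolecular_out(self.open_state.name))

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.subtype_id not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype_id!r}")
        unbound = [s for s in self.states if s.ligand_count == 0]
        if len(unbound) != 1:
            raise ValueError("scheme must have exactly one unbound resting state")
        if sum(s.open for s in self.states) != 1:
            raise ValueError("scheme must have exactly one conducting state")
        names = set(self._index)
        for t in self.transitions:
            if t.source not in names or t.target not in names:
                raise ValueError(f"transition {t} references unknown state")
            if t.rate <= 0:
                raise ValueError(f"non-positive rate in {t}")
            dlig = (self.states[self._index[t.target]].ligand_count
                    - self.states[self._index[t.source]].ligand_count)
            if t.order == BIMOLECULAR and dlig != 1:
                raise ValueError(f"bimolecular transition {t} must bind one ligand")
            if t.order == UNIMOLECULAR and dlig not in (0, -1):
                raise ValueError(f"unimolecular transition {t} may not bind ligand")

    # -- matrices ----------------------------------------------------------
    def rate_matrix(self, concentration: float = 0.0) -> np.ndarray:
        """Generator matrix Q (ms^-1) at a free-glutamate concentration.

        ``concentration`` is in molecules nm^-3.  Q[i, j] is the i->j rate;
        the diagonal holds minus the total exit rate, so the master equation
        is dP/dt = Q^T P.
        """
        n = self.n_states
        q = np.zeros((n, n))
        for t in self.transitions:
            rate = t.rate * concentration if t.order == BIMOLECULAR else t.rate
            q[self._index[t.source], self._index[t.target]] += rate
        np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        return q

    def stationary_distribution(self, concentration: float = 0.0,
                                keep: list[str] | None = None) -> np.ndarray:
        """Stationary distribution of the chain (optionally restricted to a
        subset of states, with transitions leaving the subset removed)."""
        if keep is None:
            q = self.rate_matrix(concentration)
            names = [s.name for s in self.states]
        else:
            names = keep
            idx = [self._index[n] for n in keep]
            full = np.zeros((self.n_states, self.n_states))
            for t in self.transitions:
                if t.source in keep and t.target in keep:
                    rate = (t.rate * concentration if t.order == BIMOLECULAR
                            else t.rate)
                    full[self._index[t.source], self._index[t.target]] += rate
            q = full[np.ix_(idx, idx)]
            np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
        # left null vector of Q
        w, v = np.linalg.eig(q.T)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        return pi

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "subtype_id": self.subtype_id,
            "states": [
                {"name": s.name, "ligand_count": s.ligand_count,
                 "open": s.open, "desensitized": s.desensitized,
                 "activated": s.activated}
                for s in self.states
            ],
            "transitions": [
                {"source": t.source, "target": t.target, "rate": t.rate,
                 "order": t.order, "symbol": t.symbol}
                for t in self.transitions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReceptorScheme":
        return cls(
            subtype_id=d["subtype_id"],
            states=[State(**s) for s in d["states"]],
            transitions=[Transition(**t) for t in d["transitions"]],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReceptorScheme":
        return cls.from_dict(yaml.safe_load(text))


def _build_nmdar(subtype: str, statistical_factors: bool = True) -> ReceptorScheme:
    r = RATE_TABLE[subtype]
    sf = 2.0 if statistical_factors else 1.0
    states = [
        State("R", 0),
        State("RA", 1),
        State("RA2", 2),
        State("RA2s", 2, activated=True),
        State("O", 2, open=True, activated=True),
        State("D1", 2, desensitized=True),
        State("D2", 2, desensitized=True),
    ]
    t = [
        # two equivalent glutamate sites: the first binding carries the
        # statistical factor 2 k_on; dissociation uses the tabulated k_off
        # for both steps (the table lists a single dissociation constant)
        Transition("R", "RA", sf * r["k_on"], BIMOLECULAR, "k_on1"),
        Transition("RA", "R", r["k_off"], UNIMOLECULAR, "k_off"),
        Transition("RA", "RA2", r["k_on"], BIMOLECULAR, "k_on"),
        Transition("RA2", "RA", r["k_off"], UNIMOLECULAR, "k_off"),
        Transition("RA2", "RA2s", r["k_s+"], UNIMOLECULAR, "k_s+"),
        Transition("RA2s", "RA2", r["k_s-"], UNIMOLECULAR, "k_s-"),
        Transition("RA2s", "O", r["k_f+"], UNIMOLECULAR, "k_f+"),
        Transition("O", "RA2s", r["k_f-"], UNIMOLECULAR, "k_f-"),
        Transition("RA2", "D1", r["k_d1+"], UNIMOLECULAR, "k_d1+"),
        Transition("D1", "RA2", r["k_d1-"], UNIMOLECULAR, "k_d1-"),
        Transition("RA2", "D2", r["k_d2+"], UNIMOLECULAR, "k_d2+"),
        Transition("D2", "RA2", r["k_d2-"], UNIMOLECULAR, "k_d2-"),
    ]
    return ReceptorScheme(subtype, states, t)


def _build_tri() -> ReceptorScheme:
    r = RATE_TABLE["NR2A_NR2B"]
    states = [
        State("R", 0),
        State("RA", 1),   # NR2A-type site bound
        State("RB", 1),   # NR2B-type site bound
        State("RAB", 2),
        State("RABs", 2, activated=True),
        State("O", 2, open=True, activated=True),
        State("D1", 2, desensitized=True),
        State("D2", 2, desensitized=True),
    ]
    t = [
        Transition("R", "RA", r["k_on-A"], BIMOLECULAR, "k_on-A"),
        Transition("RA", "R", r["k_off-A"], UNIMOLECULAR, "k_off-A"),
        Transition("R", "RB", r["k_on-B"], BIMOLECULAR, "k_on-B"),
        Transition("RB", "R", r["k_off-B"], UNIMOLECULAR, "k_off-B"),
        Transition("RA", "RAB", r["k_on-B"], BIMOLECULAR, "k_on-B"),
        Transition("RAB", "RA", r["k_off-B"], UNIMOLECULAR, "k_off-B"),
        Transition("RB", "RAB", r["k_on-A"], BIMOLECULAR, "k_on-A"),
        Transition("RAB", "RB", r["k_off-A"], UNIMOLECULAR, "k_off-A"),
        Transition("RAB", "RABs", r["k_s+"], UNIMOLECULAR, "k_s+"),
        Transition("RABs", "RAB", r["k_s-"], UNIMOLECULAR, "k_s-"),
        Transition("RABs", "O", r["k_f+"], UNIMOLECULAR, "k_f+"),
        Transition("O", "RABs", r["k_f-"], UNIMOLECULAR, "k_f-"),
        Transition("RAB", "D1", r["k_d1+"], UNIMOLECULAR, "k_d1+"),
        Transition("D1", "RAB", r["k_d1-"], UNIMOLECULAR, "k_d1-"),
        Transition("RAB", "D2", r["k_d2+"], UNIMOLECULAR, "k_d2+"),
        Transition("D2", "RAB", r["k_d2-"], UNIMOLECULAR, "k_d2-"),
    ]
    return ReceptorScheme("NR2A_NR2B", states, t)


def _build_ampar() -> ReceptorScheme:
    r = RATE_TABLE["AMPAR"]
    states = [
        State("R", 0),
        State("RA", 1),
        State("RA2", 2),
        State("O", 2, open=True, activated=True),
        State("D1", 1, desensitized=True),
        State("D2", 2, desensitized=True),
        State("D3", 2, desensitized=True),
    ]
    t = [
        Transition("R", "RA", r["k_R-RA"], BIMOLECULAR, "k_R-RA"),
        Transition("RA", "R", r["k_RA-R"], UNIMOLECULAR, "k_RA-R"),
        Transition("RA", "RA2", r["k_RA-RA2"], BIMOLECULAR, "k_RA-RA2"),
        Transition("RA2", "RA", r["k_RA2-RA"], UNIMOLECULAR, "k_RA2-RA"),
        Transition("RA2", "O", r["k_RA2-O"], UNIMOLECULAR, "k_RA2-O"),
        Transition("O", "RA2", r["k_O-RA2"], UNIMOLECULAR, "k_O-RA2"),
        Transition("RA", "D1", r["k_RA-D1"], UNIMOLECULAR, "k_RA-D1"),
        Transition("D1", "RA", r["k_D1-RA"], UNIMOLECULAR, "k_D1-RA"),
        Transition("RA2", "D2", r["k_RA2-D2"], UNIMOLECULAR, "k_RA2-D2"),
        Transition("D2", "RA2", r["k_D2-RA2"], UNIMOLECULAR, "k_D2-RA2"),
        Transition("O", "D3", r["k_O-D3"], UNIMOLECULAR, "k_O-D3"),
        Transition("D3", "O", r["k_D3-O"], UNIMOLECULAR, "k_D3-O"),
        # glutamate-dependent deep desensitization (volume-rate units)
        Transition("D1", "D2", r["k_D1-D2"], BIMOLECULAR, "k_D1-D2"),
        Transition("D2", "D1", r["k_D2-D1"], UNIMOLECULAR, "k_D2-D1"),
        Transition("D2", "D3", r["k_D2-D3"], UNIMOLECULAR, "k_D2-D3"),
        Transition("D3", "D2", r["k_D3-D2"], UNIMOLECULAR, "k_D3-D2"),
    ]
    return ReceptorScheme("AMPAR", states, t)


def build_scheme(subtype_id: str,
                 statistical_factors: bool = True) -> ReceptorScheme:
    """Construct the published kinetic scheme for one receptor species.

    ``statistical_factors`` applies the two-equivalent-site factor (2 k_on
    on the first binding) to the diheteromeric NMDAR schemes; the
    triheteromeric receptor has distinguishable sites and the AMPAR
    constants are per-transition fits, so neither carries factors.
    """
    if subtype_id == "AMPAR":
        return _build_ampar()
    if subtype_id in ("NR2A", "NR2B"):
        return _build_nmdar(subtype_id, statistical_factors)
    if subtype_id == "NR2A_NR2B":
        return _build_tri()
    raise ValueError(f"unknown subtype {subtype_id!r}; expected one of {SUBTYPES}")


# ---------------------------------------------------------------------------
# receptor instances and single-receptor stepping
# ---------------------------------------------------------------------------

@dataclass
class ReceptorInstance:
    """One receptor on the postsynaptic surface."""

    scheme: ReceptorScheme
    position: np.ndarray
    region: str = "synaptic"  # or "extrasynaptic"
    current_state: str = ""
    state_history: list[tuple[float, str]] = field(default_factory=list)
    time: float = 0.0

    def __post_init__(self) -> None:
        if not self.current_state:
            self.current_state = self.scheme.resting_state.name
        if not self.state_history:
            self.state_history = [(0.0, self.current_state)]

    def _move_to(self, state: str, time: float) -> None:
        self.current_state = state
        self.state_history.append((time, state))


def step_first_order(receptor: ReceptorInstance, dt: float,
                     rng: np.random.Generator) -> ReceptorInstance:
    """Advance one receptor through its unimolecular transitions over ``dt``.

    Competing exits are resolved by sampling one exponential waiting time per
    transition and taking the minimum if it falls inside the step, which is a
    Gillespie draw truncated at ``dt``: at most one transition fires, with
    total probability 1 - exp(-K dt) and branch weights proportional to the
    individual rates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    exits = receptor.scheme.unimolecular_out(receptor.current_state)
    if exits:
        waits = [rng.exponential(1.0 / t.rate) for t in exits]
        k = int(np.argmin(waits))
        if waits[k] < dt:
            receptor._move_to(exits[k].target, receptor.time + waits[k])
    receptor.time += dt
    return receptor


def open_time_distribution(scheme: ReceptorScheme, n_events: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Durations (ms) of contiguous residence in the conducting state.

    A flicker event ends at the first exit from the open state, so durations
    are exponential with mean 1 / (total unimolecular exit rate).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    k = scheme.open_exit_rate()
    return rng.exponential(1.0 / k, size=n_events)


def activation_period_distribution(scheme: ReceptorScheme, n_events: int,
                                   rng: np.random.Generator) -> np.ndarray:
    """Durations (ms) of contiguous residence in the activated conformations.

    An activation period starts when the receptor passes the slow gating step
    and ends when it drops back to the doubly-bound closed state; during the
    period the channel may flicker between the gated intermediate and the
    conducting state.  For AMPARs the activated set is the open state alone,
    so this coincides with :func:`open_time_distribution`.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    act = [s.name for s in scheme.states if s.activated]
    entry = act[0]  # gated intermediate (or open state for AMPAR)
    act_set = set(act)
    out = np.empty(n_events)
    for i in range(n_events):
        t, state = 0.0, entry
        while True:
            exits = scheme.unimolecular_out(state)
            rates = np.array([e.rate for e in exits])
            total = rates.sum()
            t += rng.exponential(1.0 / total)
            state = exits[rng.choice(len(exits), p=rates / total)].target
            if state not in act_set:
                break
        out[i] = t
    return out
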