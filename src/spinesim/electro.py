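"""Membrane potential, magnesium block and stochastic calcium entry.

The spine head is treated as a single isopotential compartment: open AMPARs
(12 pS, E = 0 mV) and conducting NMDARs (45 pS, E = 0 mV) depolarise it
against a 10 nS leak with E_leak = -60 mV; C_m comes from 1 uF/cm^2 over
the spine-head surface.  NMDAR conduction is gated by the voltage-dependent
Mg2+ block of Jahr & Stevens, sampled per receptor per step as an
independent Bernoulli trial (fast-block limit).  Calcium entry per open,
unblocked NMDAR is Poisson with mean gamma_Ca * |V_m - E_Ca| * dt / (z e),
with the calcium reversal E_Ca at its physiological ~+130 mV; the
net-current reversal E_NMDA = 0 mV is a separate quantity used only for
the voltage dynamics.  (With E_Ca set to 0 the calcium driving force would
vanish exactly where Mg unblock peaks, which suppresses the pairing
potentiation the spike-timing protocol measures.)

These standalone operations mirror the arithmetic embedded in the engine
kernel; the engine is the production path, these are its testable surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

E_CHARGE = 1.6e-19       # C
Z_CA = 2
#: ions per (pS * mV * ms): 1e-12 S * 1e-3 V * 1e-3 s / (2 * 1.6e-19 C)
ION_COEF = 1e-18 / (Z_CA * E_CHARGE)   # = 3.125


@dataclass
class MembraneState:
    """Electrical state of the spine-head compartment."""

    V_m: float = -60.0       # mV
    C_m: float = 1.24e-5     # nF (1 uF/cm^2 x ~1.24e6 nm^2 head surface)
    g_AMPA: float = 0.012    # nS (12 pS single channel)
    g_NMDA: float = 0.045    # nS (45 pS)
    E_AMPA: float = 0.0      # mV
    E_NMDA: float = 0.0      # mV
    g_leak: float = 10.0     # nS
    E_leak: float = -60.0    # mV
    Mg: float = 0.8          # mM


def mg_unblock_probability(V_m: float, Mg: float,
                           K0: float = 3.57, delta: float = 0.062) -> float:
    """Jahr-Stevens probability that an NMDAR pore is free of Mg2+ block.

    P = 1 / (1 + (Mg / K0) * exp(-delta * V_m)); strictly increasing in V_m,
    equal to 1 in Mg-free solution.
    """
    if Mg < 0:
        raise ValueError("Mg concentration must be >= 0")
    return 1.0 / (1.0 + (Mg / K0) * math.exp(-delta * V_m))


def steady_state_voltage(state: MembraneState, n_ampa_open: int,
                         n_nmda_conducting: int) -> float:
    """Conductance-weighted equilibrium potential with the given channels
    open: V* = (sum N g E + g_leak E_leak) / (sum N g + g_leak)."""
    g_r = n_ampa_open * state.g_AMPA + n_nmda_conducting * state.g_NMDA
    num = (n_ampa_open * state.g_AMPA * state.E_AMPA
           + n_nmda_conducting * state.g_NMDA * state.E_NMDA
           + state.g_leak * state.E_leak)
    return num / (g_r + state.g_leak)


def update_voltage(state: MembraneState, n_ampa_open: int,
                   n_nmda_conducting: int, dt: float) -> MembraneState:
    """Advance V_m by one step under the total ionic flux.

    The increment solves dV/dt = -(I_AMPA + I_NMDA + I_leak)/C_m with the
    conductances frozen over the step; because the membrane time constant
    C_m/g_total (~1 us) is far below the engine step, the update is applied
    as the exact exponential relaxation toward the steady-state voltage
    rather than a forward-Euler increment, which would be unstable at
    dt >> tau.
    """
    if n_ampa_open < 0 or n_nmda_conducting < 0:
        raise ValueError("channel counts must be >= 0")
    g_tot = (state.g_leak + n_ampa_open * state.g_AMPA
             + n_nmda_conducting * state.g_NMDA)
    v_star = steady_state_voltage(state, n_ampa_open, n_nmda_conducting)
    tau_ms = state.C_m / g_tot * 1e3     # nF / nS = s
    state.V_m = v_star + (state.V_m - v_star) * math.exp(-dt / tau_ms)
    return state


E_CA_DEFAULT = 130.0   # mV, calcium reversal potential


def calcium_mean(V_m: float, dt: float, gamma_ca: float = 4.5,
                 E_Ca: float = E_CA_DEFAULT) -> float:
    """Mean calcium ions per open, unblocked NMDAR in one step."""
    return ION_COEF * gamma_ca * abs(V_m - E_Ca) * dt


def calcium_step(n_open_unblocked: int, V_m: float, dt: float,
                 rng: np.random.Generator, gamma_ca: float = 4.5) -> int:
    """Stochastic calcium ions entering through the given receptors in one
    step: Poisson with mean n * N_Ca(V_m)."""
    if n_open_unblocked < 0:
        raise ValueError("receptor count must be >= 0")
    if n_open_unblocked == 0:
        return 0
    return int(rng.poisson(n_open_unblocked * calcium_mean(V_m, dt, gamma_ca)))


@dataclass
class SpikeWaveform:
    """Back-propagating-spike voltage command: instantaneous jump of
    ``peak`` mV above rest followed by a two-exponential decay (fast
    component plus slow hyperpolarizing tail)."""

    peak: float = 100.0      # mV above rest
    tau_fast: float = 3.0    # ms
    tau_slow: float = 25.0   # ms
    frac_fast: float = 0.75


def stdp_depolarization(delta_t: float, n_steps: int, dt: float,
                        t_release: float = 0.0,
                        waveform: SpikeWaveform | None = None,
                        enabled: bool = True) -> np.ndarray:
    """Voltage-command time series for an STDP pairing.

    The postsynaptic spike command is added to V_m at t_release + delta_t;
    with ``enabled=False`` (the unpaired control) the command is flat zero.
    Negative pre-spike portions of the waveform are clipped at the start of
    the simulation window.
    """
    v = np.zeros(n_steps)
    if not enabled:
        return v
    w = waveform or SpikeWaveform()
    t0 = t_release + delta_t
    t = np.arange(n_steps) * dt - t0
    m = t >= 0.0
    v[m] = w.peak * (w.frac_fast * np.exp(-t[m] / w.tau_fast)
                     + (1.0 - w.frac_fast) * np.exp(-t[m] / w.tau_slow))
    return v
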