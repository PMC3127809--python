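"""Particle-based stochastic reaction-diffusion engine.

Glutamate molecules perform Brownian dynamics (Gaussian displacements with
per-axis SD sqrt(2 D dt), specular reflection off every membrane); receptor
binding is detected by calibrated binding radii so that the well-mixed limit
of the particle simulation reproduces each published volume on-rate; gating
transitions fire as a continuous-time Markov chain discretised at the engine
time step.

Binding radii are obtained by root-finding on the steady-state capture rate
of an absorbing sphere probed with the engine's own displacement kernel (the
radial-distribution-function procedure of the Smoldyn algorithm family): a
radial profile is relaxed to steady state under alternating
Gaussian-propagation and absorption sweeps and the absorbed flux per step
gives the simulated rate for a trial radius.

Far from every receptor-bearing surface the engine aggregates Brownian steps
(one Gaussian move of K steps with SD sqrt(2 D K dt), K chosen so the move
stays several SDs away from any binding zone).  This is exact for free
diffusion and for specular reflection off planar walls and leaves binding
statistics untouched; it can be disabled per run (``adaptive=False``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from . import geometry as geo
from .kinetics import ReceptorScheme, build_scheme
from .presynaptic import ReleaseTrain

# ---------------------------------------------------------------------------
# fast gaussian sampler (ziggurat) for the kernel hot loop
# ---------------------------------------------------------------------------

def _build_ziggurat():
    r = 3.442619855899
    v = 9.91256303526217e-3
    x = np.zeros(129)
    x[0] = v / math.exp(-0.5 * r * r)   # pseudo-width of the base strip
    x[1] = r
    for i in range(2, 128):
        x[i] = math.sqrt(-2.0 * math.log(
            v / x[i - 1] + math.exp(-0.5 * x[i - 1] ** 2)))
    x[128] = 0.0
    f = np.exp(-0.5 * x ** 2)
    return x, f


_ZIG_X, _ZIG_F = _build_ziggurat()
_ZIG_R = 3.442619855899
_U64_MULT = np.uint64(2685821657736338717)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, fastmath=True)
def _randn(x):
    """Standard normal draw: 128-layer ziggurat over an xorshift64* stream.

    ``x`` is the uint64 generator state, threaded by value through the
    kernel; the tables are frozen module globals.  Returns (state, value).
    """
    while True:
        x ^= x >> np.uint64(12)
        x ^= x << np.uint64(25)
        x ^= x >> np.uint64(27)
        a = x * _U64_MULT
        i = int(a & np.uint64(127))                       # layer: low bits
        u = np.float64(a >> np.uint64(11)) * (2.0 * _INV_2_53) - 1.0
        xx = u * _ZIG_X[i]
        if abs(xx) < _ZIG_X[i + 1]:
            return x, xx
        if i == 0:
            # tail beyond r: Marsaglia exponential-rejection tail
            while True:
                x ^= x >> np.uint64(12)
                x ^= x << np.uint64(25)
                x ^= x >> np.uint64(27)
                e1 = np.float64((x * _U64_MULT) >> np.uint64(11)) * _INV_2_53
                x ^= x >> np.uint64(12)
                x ^= x << np.uint64(25)
                x ^= x >> np.uint64(27)
                e2 = np.float64((x * _U64_MULT) >> np.uint64(11)) * _INV_2_53
                ex = -math.log(1.0 - e1) / _ZIG_R
                ey = -math.log(1.0 - e2)
                if ey + ey >= ex * ex:
                    break
            return x, (_ZIG_R + ex if u > 0.0 else -(_ZIG_R + ex))
        x ^= x >> np.uint64(12)
        x ^= x << np.uint64(25)
        x ^= x >> np.uint64(27)
        yv = np.float64((x * _U64_MULT) >> np.uint64(11)) * _INV_2_53
        y = _ZIG_F[i] + yv * (_ZIG_F[i + 1] - _ZIG_F[i])
        if y < math.exp(-0.5 * xx * xx):
            return x, xx


# ---------------------------------------------------------------------------
# binding-radius calibration
# ---------------------------------------------------------------------------

_radius_cache: dict[tuple[float, float, float], float] = {}


def _capture_rate(rb_index: int, r: np.ndarray, w: np.ndarray,
                  kernel: np.ndarray, sigma: float, dt: float,
                  n_iter: int = 400) -> float:
    """Steady-state capture rate (nm^3/ms) of an absorbing sphere whose
    surface sits at grid index ``rb_index``, under the engine's per-step
    Gaussian displacement kernel."""
    bulk = 4.0 * math.pi * r ** 2          # radial mass density at unit conc
    m = bulk.copy()
    m[:rb_index] = 0.0
    outer = r > r[-1] - 4.0 * sigma        # band held at bulk concentration
    prev = -1.0
    absorbed = 0.0
    for _ in range(n_iter):
        m = kernel @ (w * m)
        absorbed = float(np.sum(w[:rb_index] * m[:rb_index]))
        m[:rb_index] = 0.0
        m[outer] = bulk[outer]
        if prev > 0 and abs(absorbed - prev) < 1e-8 * prev:
            break
        prev = absorbed
    return absorbed / dt


def _radial_kernel(r: np.ndarray, sigma: float) -> np.ndarray:
    """Transition density of |x + N(0, sigma^2 I_3)| between radial shells
    (the image-difference form of the 3-D Gaussian propagator in the radial
    coordinate): K[j, i] = p(r_i -> r_j)."""
    ri = r[None, :]
    rj = r[:, None]
    norm = rj / (ri * sigma * math.sqrt(2.0 * math.pi))
    return norm * (np.exp(-((ri - rj) ** 2) / (2 * sigma ** 2))
                   - np.exp(-((ri + rj) ** 2) / (2 * sigma ** 2)))


def binding_radius(k_on: float, D: float, dt: float) -> float:
    """Binding radius (nm) reproducing a volume on-rate in the engine.

    Parameters
    ----------
    k_on : volume rate, nm^3 ms^-1.
    D : relative diffusion coefficient, um^2 ms^-1.
    dt : engine time step, ms.
    """
    if k_on < 0 or D <= 0 or dt <= 0:
        raise ValueError("k_on must be >= 0 and D, dt > 0")
    if k_on == 0:
        return 0.0
    key = (round(k_on, 6), round(D, 9), round(dt, 9))
    if key in _radius_cache:
        return _radius_cache[key]

    d_nm = D * 1e6                       # nm^2 / ms
    sigma = math.sqrt(2.0 * d_nm * dt)   # per-axis rms step
    rb0 = (3.0 * k_on * dt / (4.0 * math.pi)) ** (1.0 / 3.0)
    # capture capacity check: even a radius far above the ballistic estimate
    # cannot exceed the diffusion-limited rate scale
    if k_on > 0.25 * 4.0 * math.pi * d_nm * (3.0 * rb0 + sigma):
        raise ValueError(
            f"k_on={k_on} nm^3/ms exceeds the diffusion-limited capture rate "
            f"achievable at D={D} um^2/ms, dt={dt} ms")

    # composite radial grid: fine inside ~2 rb0, coarse out to the kernel range
    r_in = np.arange(1, 301) * (2.0 * rb0 / 300.0)
    r_out = np.arange(1, 241) * (sigma / 40.0) + r_in[-1]
    r = np.concatenate([r_in, r_out])
    w = np.gradient(r)
    kern = _radial_kernel(r, sigma)

    # simulated rate at each candidate cutoff is monotone in the radius;
    # bracket the target then interpolate linearly in rb^3
    lo_i = int(np.searchsorted(r, 0.75 * rb0))
    hi_i = int(np.searchsorted(r, 1.35 * rb0))
    k_lo = _capture_rate(lo_i, r, w, kern, sigma, dt)
    k_hi = _capture_rate(hi_i, r, w, kern, sigma, dt)
    if not (k_lo <= k_on <= k_hi):
        lo_i, hi_i = max(2, lo_i // 2), min(len(r_in) - 1, 2 * hi_i)
        k_lo = _capture_rate(lo_i, r, w, kern, sigma, dt)
        k_hi = _capture_rate(hi_i, r, w, kern, sigma, dt)
        if not (k_lo <= k_on <= k_hi):
            raise ValueError("binding-radius bracket failure")
    while hi_i - lo_i > 1:
        mid = (lo_i + hi_i) // 2
        k_mid = _capture_rate(mid, r, w, kern, sigma, dt)
        if k_mid < k_on:
            lo_i, k_lo = mid, k_mid
        else:
            hi_i, k_hi = mid, k_mid
    f = (k_on - k_lo) / (k_hi - k_lo)
    rb = (r[lo_i] ** 3 + f * (r[hi_i] ** 3 - r[lo_i] ** 3)) ** (1.0 / 3.0)
    _radius_cache[key] = rb
    return rb


# ---------------------------------------------------------------------------
# scheme table compilation
# ---------------------------------------------------------------------------

S_MAX = 8  # largest number of states over all schemes


@dataclass
class CompiledSchemes:
    """Flat CSR tables driving the kernel's per-receptor state machine."""

    schemes: list[ReceptorScheme]
    base: np.ndarray          # (S,) slot base per scheme
    n_states: np.ndarray      # (S,)
    resting: np.ndarray       # (S,)
    is_ampa: np.ndarray       # (S,) u8
    sl_lig: np.ndarray        # (T,) ligand count per slot
    sl_open: np.ndarray       # (T,) u8
    sl_desens: np.ndarray     # (T,) u8
    sl_act: np.ndarray        # (T,) u8
    sl_pexit: np.ndarray      # (T,) exit probability per dt
    sl_ktot: np.ndarray       # (T,) total unimolecular exit rate
    uni_off: np.ndarray       # (T+1,)
    uni_rate: np.ndarray
    uni_tgt: np.ndarray
    uni_unb: np.ndarray       # u8: ligand-releasing transition
    uni_rrad: np.ndarray      # release radius for unbinding placement
    bim_off: np.ndarray       # (T+1,)
    bim_tgt: np.ndarray
    bim_r2: np.ndarray        # effective (concentric-corrected) radius^2
    rb_max: float


def compile_schemes(subtypes: list[str], D: float, dt: float,
                    surface_factor: float = 1.0,
                    statistical_factors: bool = True) -> CompiledSchemes:
    schemes = [build_scheme(s, statistical_factors) for s in subtypes]
    base = np.zeros(len(schemes), dtype=np.int32)
    n_states = np.array([s.n_states for s in schemes], dtype=np.int32)
    for i in range(1, len(schemes)):
        base[i] = base[i - 1] + n_states[i - 1]
    total = int(base[-1] + n_states[-1])

    sl_lig = np.zeros(total, dtype=np.int32)
    sl_open = np.zeros(total, dtype=np.uint8)
    sl_desens = np.zeros(total, dtype=np.uint8)
    sl_act = np.zeros(total, dtype=np.uint8)
    sl_ktot = np.zeros(total)
    resting = np.zeros(len(schemes), dtype=np.int32)
    is_ampa = np.zeros(len(schemes), dtype=np.uint8)

    uni_off = np.zeros(total + 1, dtype=np.int32)
    bim_off = np.zeros(total + 1, dtype=np.int32)
    uni_rate: list[float] = []
    uni_tgt: list[int] = []
    uni_unb: list[int] = []
    uni_rrad: list[float] = []
    bim_tgt: list[int] = []
    bim_r2: list[float] = []
    rb_max = 0.0

    for si, sch in enumerate(schemes):
        is_ampa[si] = sch.subtype_id == "AMPAR"
        resting[si] = sch.state_index(sch.resting_state.name)
        # receptors sit on reflecting membranes, so the capture region is a
        # hemisphere and the realized wall rate is surface_factor/2 times
        # the tabulated one; the default (1) mirrors a plain binding-radius
        # transcription of the published rates, surface_factor=2 would
        # restore the tabulated k_on exactly at the wall
        radii = {(t.source, t.target):
                 binding_radius(surface_factor * t.rate, D, dt)
                 for t in sch.transitions if t.order == "bimolecular"}
        for li, st in enumerate(sch.states):
            slot = int(base[si]) + li
            sl_lig[slot] = st.ligand_count
            sl_open[slot] = st.open
            sl_desens[slot] = st.desensitized
            sl_act[slot] = st.activated
            uni = sch.unimolecular_out(st.name)
            sl_ktot[slot] = sum(t.rate for t in uni)
            uni_off[slot + 1] = uni_off[slot] + len(uni)
            for t in uni:
                uni_rate.append(t.rate)
                uni_tgt.append(sch.state_index(t.target))
                releases = (sch.states[sch.state_index(t.target)].ligand_count
                            < st.ligand_count)
                uni_unb.append(int(releases))
                # released ligand placed at the reverse binding radius
                uni_rrad.append(radii.get((t.target, t.source), 1.0)
                                if releases else 0.0)
            bim = sorted(sch.bimolecular_out(st.name),
                         key=lambda t: radii[(t.source, t.target)])
            bim_off[slot + 1] = bim_off[slot] + len(bim)
            cum3 = 0.0
            for t in bim:
                # concentric correction: with the nearest-qualifying-radius
                # assignment rule, shell volumes (not sphere volumes) realise
                # each rate, so radii are made volume-cumulative
                cum3 += radii[(t.source, t.target)] ** 3
                r_eff = cum3 ** (1.0 / 3.0)
                bim_tgt.append(sch.state_index(t.target))
                bim_r2.append(r_eff ** 2)
                rb_max = max(rb_max, r_eff)

    sl_pexit = -np.expm1(-sl_ktot * dt)
    return CompiledSchemes(
        schemes=schemes, base=base, n_states=n_states, resting=resting,
        is_ampa=is_ampa, sl_lig=sl_lig, sl_open=sl_open, sl_desens=sl_desens,
        sl_act=sl_act, sl_pexit=sl_pexit, sl_ktot=sl_ktot,
        uni_off=uni_off, uni_rate=np.array(uni_rate),
        uni_tgt=np.array(uni_tgt, dtype=np.int32),
        uni_unb=np.array(uni_unb, dtype=np.uint8),
        uni_rrad=np.array(uni_rrad),
        bim_off=bim_off, bim_tgt=np.array(bim_tgt, dtype=np.int32),
        bim_r2=np.array(bim_r2), rb_max=rb_max,
    )


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Inputs fully determining one stochastic trajectory."""

    geometry: geo.SpineGeometry
    layout: geo.ReceptorLayout
    release: ReleaseTrain
    duration: float                 # ms
    dt: float = 0.01                # ms
    D_glu: float = 0.2              # um^2 / ms
    seed: int = 0
    record_stride: int = 10         # steps between recorded frames
    record_cleft: bool = True
    adaptive: bool = True
    electro: bool = False
    Mg: float = 0.8                 # mM
    mg_K0: float = 3.57             # mM
    mg_delta: float = 0.062         # mV^-1
    g_ampa: float = 0.012           # nS (12 pS)
    g_nmda: float = 0.045           # nS (45 pS)
    g_leak: float = 10.0            # nS
    E_leak: float = -60.0           # mV
    gamma_ca: float = 4.5           # pS
    E_Ca: float = 130.0             # mV, calcium reversal for the driving force
    v_command: Optional[np.ndarray] = None  # added to V_m, per step
    event_cap: int = 2_000_000
    surface_rate_factor: float = 1.0
    statistical_factors: bool = True

    def __post_init__(self) -> None:
        if not (0.001 <= self.dt <= 0.1):
            raise ValueError("dt must lie in [0.001, 0.1] ms")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.05 <= self.D_glu <= 1.0):
            raise ValueError("implausible glutamate diffusion coefficient")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def capacitance_nF(self) -> float:
        """Spine-head membrane capacitance from 1 uF/cm^2."""
        return self.geometry.head_surface_area() * 1e-11


@dataclass
class Trajectory:
    """Recorded output of one engine run."""

    times: np.ndarray               # (F,) ms
    counts: np.ndarray              # (F, P, S_MAX) receptors per pop x state
    pop_names: list[str]
    pop_schemes: dict[str, ReceptorScheme]
    pop_sizes: dict[str, int]
    free_count: np.ndarray          # (F,)
    cleft_count: np.ndarray         # (F,)
    released: np.ndarray            # (F,) cumulative molecules released
    vm: np.ndarray                  # (F,) mV (includes any command waveform)
    cum_ca: np.ndarray              # (F,) cumulative calcium ions
    events: dict[str, np.ndarray]   # time, receptor, from, to, kind
    rec_pop: np.ndarray             # (M,) population index per receptor
    rec_subtype: list[str]
    config: SimulationConfig
    final_positions: np.ndarray | None = None  # (n_free_end, 3) nm
    diagnostics: dict | None = None
    events_truncated: bool = False

    def _mask(self, pop: str, flag: str) -> np.ndarray:
        sch = self.pop_schemes[pop]
        m = np.zeros(S_MAX, dtype=bool)
        for i, s in enumerate(sch.states):
            m[i] = getattr(s, flag)
        return m

    def pop_index(self, pop: str) -> int:
        return self.pop_names.index(pop)

    def open_count(self, pop: str) -> np.ndarray:
        p = self.pop_index(pop)
        return self.counts[:, p, :] @ self._mask(pop, "open")

    def activated_count(self, pop: str) -> np.ndarray:
        p = self.pop_index(pop)
        return self.counts[:, p, :] @ self._mask(pop, "activated")

    def desensitized_count(self, pop: str) -> np.ndarray:
        p = self.pop_index(pop)
        return self.counts[:, p, :] @ self._mask(pop, "desensitized")

    def open_fraction(self, pop: str) -> np.ndarray:
        return self.open_count(pop) / self.pop_sizes[pop]

    def bound_ligands(self) -> np.ndarray:
        out = np.zeros(len(self.times))
        for pop in self.pop_names:
            p = self.pop_index(pop)
            lig = np.zeros(S_MAX)
            sch = self.pop_schemes[pop]
            for i, s in enumerate(sch.states):
                lig[i] = s.ligand_count
            out += self.counts[:, p, :] @ lig
        return out

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("states", data=self.counts)
            f.create_dataset("aggregates/free", data=self.free_count)
            f.create_dataset("aggregates/cleft", data=self.cleft_count)
            f.create_dataset("aggregates/released", data=self.released)
            f.create_dataset("vm", data=self.vm)
            f.create_dataset("calcium", data=self.cum_ca)
            for k, v in self.events.items():
                f.create_dataset(f"events/{k}", data=v)
            f.attrs["pop_names"] = ",".join(self.pop_names)
            f.attrs["seed"] = self.config.seed
            f.attrs["dt"] = self.config.dt

    def aggregates_dataframe(self):
        import pandas as pd

        data = {"time_ms": self.times, "free": self.free_count,
                "cleft": self.cleft_count, "vm_mV": self.vm,
                "cum_ca": self.cum_ca}
        for pop in self.pop_names:
            data[f"open_{pop}"] = self.open_count(pop)
            data[f"desens_{pop}"] = self.desensitized_count(pop)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# the kernel
# ---------------------------------------------------------------------------

EV_GATE, EV_BIND, EV_UNBIND = 0, 1, 2


@njit(cache=True, fastmath=True)
def _run_kernel(seed, n_steps, dt, d_nm, g, rst,
                rec_x, rec_y, rec_z, rec_nx, rec_ny, rec_nz,
                rec_scheme, rec_pop, rec_state, idx_syn, idx_ext,
                base, resting, is_ampa,
                sl_lig, sl_open, sl_pexit, sl_ktot,
                uni_off, uni_rate, uni_tgt, uni_unb, uni_rrad,
                bim_off, bim_tgt, bim_r2, rb_max,
                rel_step, rel_n, rel_x, rel_y, rel_z,
                pos, alive, nxt,
                stride, record_cleft, adaptive,
                electro, el, vext,
                counts, free_rec, cleft_rec, released_rec, vm_rec, ca_rec,
                ev_t, ev_rec, ev_from, ev_to, ev_kind, diag):
    np.random.seed(seed)
    rs = rst[0]
    sigma1 = math.sqrt(2.0 * d_nm * dt)
    # hoisted geometry bounds for the inline fast path
    bxw = g[geo.G_BX]
    byw = g[geo.G_BY]
    bzw = g[geo.G_BZ]
    sbx = g[geo.G_SA] if g[geo.G_SA] > g[geo.G_A] else g[geo.G_A]
    szt = g[geo.G_SZHI] if g[geo.G_SZHI] > g[geo.G_ZB_TOP] else g[geo.G_ZB_TOP]
    szb = g[geo.G_ZD_LO] if g[geo.G_ZD_LO] < g[geo.G_ZS_BOT] else g[geo.G_ZS_BOT]
    inv2ddt = 1.0 / (2.0 * d_nm * dt)
    kmax = 256

    # binding zones (broad phase)
    z1x = g[geo.G_PSD] + rb_max + 0.5
    z1lo = g[geo.G_ZS_TOP] - 0.5
    z1hi = g[geo.G_ZS_TOP] + rb_max + 0.5
    n_ext = idx_ext.shape[0]
    z2x = g[geo.G_A] + rb_max + 0.5
    z2lo = g[geo.G_ZS_BOT] - rb_max - 0.5
    z2hi = g[geo.G_ZS_TOP] + rb_max + 0.5

    # electro params
    g_ampa = el[0]
    g_nmda = el[1]
    g_leak = el[2]
    e_leak = el[3]
    c_nf = el[4]
    mg = el[5]
    mg_k0 = el[6]
    mg_delta = el[7]
    ion_coef = el[8]          # 3.125 * gamma_pS -> ions per (mV * ms)
    e_ca = el[9]

    # calendar queue: particles bucketed by wake-up step so each step only
    # touches active particles.  A slot lives in exactly one chain; dead
    # slots are recycled when their pending bucket entry is consumed.
    n_buckets = kmax + 4
    head = np.full(n_buckets, -1, dtype=np.int64)
    cap = pos.shape[0]
    freestk = np.empty(cap, dtype=np.int64)
    n_free_slots = 0
    hi_water = 0
    n_alive = 0

    released = 0
    rel_ptr = 0
    n_rel = rel_step.shape[0]
    m_rec = rec_state.shape[0]
    n_syn = idx_syn.shape[0]

    n_open_ampa = 0
    n_open_nmda = 0
    vdyn = e_leak
    cumca = 0.0
    nev = 0
    ev_cap = ev_t.shape[0]
    truncated = 0

    cand_cap = 4096
    cand_p = np.empty(cand_cap, dtype=np.int64)
    cand_r = np.empty(cand_cap, dtype=np.int64)
    cand_d2 = np.empty(cand_cap)

    # frame 0: initial state
    for rr in range(m_rec):
        counts[0, rec_pop[rr], rec_state[rr]] += 1
    vm_rec[0] = vdyn + vext[0]

    frame = 0
    for t in range(n_steps):
        tm = t * dt
        bkt = t % n_buckets
        # 1. scheduled vesicle releases (pushed into this step's bucket)
        while rel_ptr < n_rel and rel_step[rel_ptr] == t:
            for _ in range(rel_n[rel_ptr]):
                if n_free_slots > 0:
                    n_free_slots -= 1
                    i = freestk[n_free_slots]
                else:
                    i = hi_water
                    hi_water += 1
                    if hi_water > cap:
                        return nev, 2, frame, truncated, 0
                pos[i, 0] = rel_x[rel_ptr]
                pos[i, 1] = rel_y[rel_ptr]
                pos[i, 2] = rel_z[rel_ptr]
                alive[i] = 1
                nxt[i] = head[bkt]
                head[bkt] = i
                n_alive += 1
            released += rel_n[rel_ptr]
            rel_ptr += 1

        # 2-3. diffusion with reflection, then binding detection
        ncand = 0
        chain = head[bkt]
        head[bkt] = -1
        while chain != -1:
            i = chain
            chain = nxt[i]
            if alive[i] == 0:
                # lazy deletion: recycle the slot now its entry is consumed
                freestk[n_free_slots] = i
                n_free_slots += 1
                continue
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            k_steps = 1
            if adaptive == 1:
                # distance to the PSD binding zone box
                dx = abs(x) - z1x
                if dx < 0.0:
                    dx = 0.0
                dy = abs(y) - z1x
                if dy < 0.0:
                    dy = 0.0
                dz = z - z1hi
                if dz < 0.0:
                    dz = z1lo - z
                    if dz < 0.0:
                        dz = 0.0
                d2 = dx * dx + dy * dy + dz * dz
                if n_ext > 0:
                    ex = abs(x) - z2x
                    if ex < 0.0:
                        ex = 0.0
                    ey = abs(y) - z2x
                    if ey < 0.0:
                        ey = 0.0
                    ez = z - z2hi
                    if ez < 0.0:
                        ez = z2lo - z
                        if ez < 0.0:
                            ez = 0.0
                    e2 = ex * ex + ey * ey + ez * ez
                    if e2 < d2:
                        d2 = e2
                k_steps = int(d2 * inv2ddt / 9.0)  # 3-sigma margin
                if k_steps < 1:
                    k_steps = 1
                elif k_steps > kmax:
                    k_steps = kmax
                if k_steps > n_steps - t:
                    k_steps = n_steps - t
                    if k_steps < 1:
                        k_steps = 1
            if k_steps == 1:
                s = sigma1
            else:
                s = math.sqrt(2.0 * d_nm * dt * k_steps)
            # requeue at the wake-up step
            wb = (t + k_steps) % n_buckets
            nxt[i] = head[wb]
            head[wb] = i
            diag[0] += 1.0
            diag[1] += k_steps
            rs, v1 = _randn(rs)
            rs, v2 = _randn(rs)
            rs, v3 = _randn(rs)
            nx = x + s * v1
            ny = y + s * v2
            nz = z + s * v3
            # separating-plane fast path: both endpoints beyond one face of
            # the structure bounding box => the segment cannot touch any
            # interior surface; outer-wall overshoots fold exactly
            if ((x > sbx and nx > sbx) or (x < -sbx and nx < -sbx)
                    or (y > sbx and ny > sbx) or (y < -sbx and ny < -sbx)
                    or (z > szt and nz > szt) or (z < szb and nz < szb)):
                if not (-bxw <= nx <= bxw and -byw <= ny <= byw
                        and -bzw <= nz <= bzw):
                    fx = nx
                    fy = ny
                    fz = nz
                    for _ in range(4):
                        if fx > bxw:
                            fx = 2.0 * bxw - fx
                        elif fx < -bxw:
                            fx = -2.0 * bxw - fx
                        if fy > byw:
                            fy = 2.0 * byw - fy
                        elif fy < -byw:
                            fy = -2.0 * byw - fy
                        if fz > bzw:
                            fz = 2.0 * bzw - fz
                        elif fz < -bzw:
                            fz = -2.0 * bzw - fz
                        if (-bxw <= fx <= bxw and -byw <= fy <= byw
                                and -bzw <= fz <= bzw):
                            break
                    # folded endpoint must stay clear of the structures
                    if ((x > sbx and fx > sbx) or (x < -sbx and fx < -sbx)
                            or (y > sbx and fy > sbx)
                            or (y < -sbx and fy < -sbx)
                            or (z > szt and fz > szt)
                            or (z < szb and fz < szb)):
                        nx = fx
                        ny = fy
                        nz = fz
                    else:
                        nx, ny, nz = geo.move_with_reflection(
                            x, y, z, nx, ny, nz, s, g)
            else:
                nx, ny, nz = geo.move_with_reflection(x, y, z, nx, ny, nz,
                                                      s, g)
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz
            if k_steps > 1:
                continue
            # broad-phase binding eligibility
            if (nz < z1hi and abs(nx) < z1x and abs(ny) < z1x
                    and ncand < cand_cap):
                for jj in range(n_syn):
                    r = idx_syn[jj]
                    slot = base[rec_scheme[r]] + rec_state[r]
                    b0 = bim_off[slot]
                    b1 = bim_off[slot + 1]
                    if b1 == b0:
                        continue
                    ddx = nx - rec_x[r]
                    ddy = ny - rec_y[r]
                    ddz = nz - rec_z[r]
                    pd2 = ddx * ddx + ddy * ddy + ddz * ddz
                    if pd2 < bim_r2[b1 - 1]:
                        cand_p[ncand] = i
                        cand_r[ncand] = r
                        cand_d2[ncand] = pd2
                        ncand += 1
                        if ncand >= cand_cap:
                            break
            if (n_ext > 0 and z2lo < nz < z2hi and abs(nx) < z2x
                    and abs(ny) < z2x and ncand < cand_cap):
                for jj in range(n_ext):
                    r = idx_ext[jj]
                    slot = base[rec_scheme[r]] + rec_state[r]
                    b0 = bim_off[slot]
                    b1 = bim_off[slot + 1]
                    if b1 == b0:
                        continue
                    ddx = nx - rec_x[r]
                    ddy = ny - rec_y[r]
                    ddz = nz - rec_z[r]
                    pd2 = ddx * ddx + ddy * ddy + ddz * ddz
                    if pd2 < bim_r2[b1 - 1]:
                        cand_p[ncand] = i
                        cand_r[ncand] = r
                        cand_d2[ncand] = pd2
                        ncand += 1
                        if ncand >= cand_cap:
                            break

        # nearest-first greedy assignment of binding candidates
        if ncand > 0:
            order = np.argsort(cand_d2[:ncand])
            for oo in range(ncand):
                cc = order[oo]
                i = cand_p[cc]
                if alive[i] == 0:
                    continue
                r = cand_r[cc]
                slot = base[rec_scheme[r]] + rec_state[r]
                chosen = -1
                for b in range(bim_off[slot], bim_off[slot + 1]):
                    if cand_d2[cc] < bim_r2[b]:
                        chosen = b
                        break
                if chosen < 0:
                    continue
                old = rec_state[r]
                new = bim_tgt[chosen]
                rec_state[r] = new
                alive[i] = 0          # consumed; slot recycles at its wake
                n_alive -= 1
                oslot = base[rec_scheme[r]] + old
                nslot = base[rec_scheme[r]] + new
                if sl_open[oslot] != sl_open[nslot]:
                    if is_ampa[rec_scheme[r]] == 1:
                        n_open_ampa += sl_open[nslot] - sl_open[oslot]
                    else:
                        n_open_nmda += sl_open[nslot] - sl_open[oslot]
                if nev < ev_cap:
                    ev_t[nev] = tm
                    ev_rec[nev] = r
                    ev_from[nev] = old
                    ev_to[nev] = new
                    ev_kind[nev] = EV_BIND
                    nev += 1
                else:
                    truncated = 1

        # 4. unimolecular transitions (one Gillespie draw truncated at dt)
        for r in range(m_rec):
            slot = base[rec_scheme[r]] + rec_state[r]
            pe = sl_pexit[slot]
            if pe <= 0.0:
                continue
            if np.random.random() >= pe:
                continue
            v = np.random.random() * sl_ktot[slot]
            acc = 0.0
            chosen = uni_off[slot]
            for b in range(uni_off[slot], uni_off[slot + 1]):
                acc += uni_rate[b]
                if v <= acc:
                    chosen = b
                    break
            old = rec_state[r]
            new = uni_tgt[chosen]
            if uni_unb[chosen] == 1:
                # place the released ligand at the unbinding radius, in the
                # outward hemisphere of the receptor's surface
                rs, ux = _randn(rs)
                rs, uy = _randn(rs)
                rs, uz = _randn(rs)
                un = math.sqrt(ux * ux + uy * uy + uz * uz)
                if un < 1e-12:
                    ux, uy, uz, un = 0.0, 0.0, 1.0, 1.0
                ux /= un
                uy /= un
                uz /= un
                dot = ux * rec_nx[r] + uy * rec_ny[r] + uz * rec_nz[r]
                if dot < 0.0:
                    ux -= 2.0 * dot * rec_nx[r]
                    uy -= 2.0 * dot * rec_ny[r]
                    uz -= 2.0 * dot * rec_nz[r]
                rr = uni_rrad[chosen]
                qx = rec_x[r] + rr * ux
                qy = rec_y[r] + rr * uy
                qz = rec_z[r] + rr * uz
                if not geo.inside_domain(qx, qy, qz, g):
                    qx = rec_x[r] + 1.0 * rec_nx[r]
                    qy = rec_y[r] + 1.0 * rec_ny[r]
                    qz = rec_z[r] + 1.0 * rec_nz[r]
                if n_free_slots > 0:
                    n_free_slots -= 1
                    i = freestk[n_free_slots]
                else:
                    i = hi_water
                    hi_water += 1
                    if hi_water > cap:
                        return nev, 2, frame, truncated, 0
                pos[i, 0] = qx
                pos[i, 1] = qy
                pos[i, 2] = qz
                alive[i] = 1
                wb = (t + 1) % n_buckets
                nxt[i] = head[wb]
                head[wb] = i
                n_alive += 1
            rec_state[r] = new
            oslot = base[rec_scheme[r]] + old
            nslot = base[rec_scheme[r]] + new
            if sl_open[oslot] != sl_open[nslot]:
                if is_ampa[rec_scheme[r]] == 1:
                    n_open_ampa += sl_open[nslot] - sl_open[oslot]
                else:
                    n_open_nmda += sl_open[nslot] - sl_open[oslot]
            if nev < ev_cap:
                ev_t[nev] = tm
                ev_rec[nev] = r
                ev_from[nev] = old
                ev_to[nev] = new
                ev_kind[nev] = EV_UNBIND if uni_unb[chosen] == 1 else EV_GATE
                nev += 1
            else:
                truncated = 1

        # 5. membrane potential, Mg block, calcium entry
        veff = vdyn + vext[t]
        if electro == 1:
            p_unb = 1.0 / (1.0 + (mg / mg_k0) * math.exp(-mg_delta * veff))
            n_unb = 0
            for _ in range(n_open_nmda):
                if np.random.random() < p_unb:
                    n_unb += 1
            if n_unb > 0:
                mean_ions = ion_coef * abs(veff - e_ca) * dt * n_unb
                cumca += np.random.poisson(mean_ions)
            gtot = g_leak + n_open_ampa * g_ampa + n_unb * g_nmda
            vs = g_leak * e_leak / gtot
            vdyn = vs + (vdyn - vs) * math.exp(-gtot * dt * 1e-3 / c_nf)

        # 6. recording
        if (t + 1) % stride == 0:
            frame += 1
            bound_lig = 0
            for rr in range(m_rec):
                counts[frame, rec_pop[rr], rec_state[rr]] += 1
                bound_lig += sl_lig[base[rec_scheme[rr]] + rec_state[rr]]
            free_rec[frame] = n_alive
            released_rec[frame] = released
            if n_alive + bound_lig != released:
                return nev, 1, frame, truncated, 0  # conservation violated
            if record_cleft == 1:
                nc = 0
                for i in range(hi_water):
                    if (alive[i] == 1 and abs(pos[i, 0]) < g[geo.G_PSD]
                            and abs(pos[i, 1]) < g[geo.G_PSD]
                            and g[geo.G_ZS_TOP] < pos[i, 2] < g[geo.G_ZB_BOT]):
                        nc += 1
                cleft_rec[frame] = nc
            vm_rec[frame] = vdyn + vext[min(t + 1, n_steps - 1)]
            ca_rec[frame] = cumca

    # compact surviving particle positions into the array prefix
    j = 0
    for i in range(hi_water):
        if alive[i] == 1:
            pos[j, 0] = pos[i, 0]
            pos[j, 1] = pos[i, 1]
            pos[j, 2] = pos[i, 2]
            j += 1
    return nev, 0, frame, truncated, j


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one seeded stochastic trajectory of the full spine model."""
    layout = config.layout
    gobj = config.geometry
    g = gobj.params()
    subtype_list = sorted(set(layout.subtypes))
    tables = compile_schemes(subtype_list, config.D_glu, config.dt,
                             config.surface_rate_factor,
                             config.statistical_factors)
    if tables.rb_max >= gobj.cleft_width / 2.0:
        raise ValueError("a binding radius exceeds half the cleft width")
    scheme_of = {s: i for i, s in enumerate(subtype_list)}

    pop_names = layout.population_names()
    pop_of = {p: i for i, p in enumerate(pop_names)}
    m = layout.n_receptors
    rec_scheme = np.array([scheme_of[s] for s in layout.subtypes],
                          dtype=np.int32)
    rec_pop = np.array([pop_of[p] for p in layout.populations], dtype=np.int32)
    rec_state = np.array([tables.resting[rec_scheme[r]] for r in range(m)],
                         dtype=np.int32)
    idx_syn = np.array([r for r in range(m) if layout.regions[r] == "synaptic"],
                       dtype=np.int64)
    idx_ext = np.array(
        [r for r in range(m) if layout.regions[r] == "extrasynaptic"],
        dtype=np.int64)

    train = config.release
    n_steps = config.n_steps
    rel_step = np.array([int(round(e.time / config.dt)) for e in train.events],
                        dtype=np.int64)
    if np.any(rel_step >= n_steps):
        keep = rel_step < n_steps
    else:
        keep = np.ones(len(rel_step), dtype=bool)
    rel_n = np.array([e.molecules for e in train.events],
                     dtype=np.int64)[keep]
    rel_pos = np.array([e.position for e in train.events]).reshape(-1, 3)[keep]
    rel_step = rel_step[keep]
    order = np.argsort(rel_step, kind="stable")
    rel_step = rel_step[order]
    rel_n = rel_n[order]
    rel_pos = rel_pos[order]

    # slots are recycled; the margin covers dead slots awaiting their
    # pending calendar-bucket entry
    n_cap = int(rel_n.sum()) + 65_536
    pos = np.empty((n_cap, 4))     # x, y, z + padding to one cache line
    alive = np.zeros(n_cap, dtype=np.uint8)
    nxt = np.full(n_cap, -1, dtype=np.int64)

    stride = int(config.record_stride)
    n_frames = n_steps // stride + 1
    n_pop = len(pop_names)
    counts = np.zeros((n_frames, n_pop, S_MAX), dtype=np.int32)
    free_rec = np.zeros(n_frames, dtype=np.int32)
    cleft_rec = np.zeros(n_frames, dtype=np.int32)
    released_rec = np.zeros(n_frames, dtype=np.int32)
    vm_rec = np.zeros(n_frames)
    ca_rec = np.zeros(n_frames)

    cap = int(config.event_cap)
    ev_t = np.empty(cap)
    ev_rec = np.empty(cap, dtype=np.int32)
    ev_from = np.empty(cap, dtype=np.int8)
    ev_to = np.empty(cap, dtype=np.int8)
    ev_kind = np.empty(cap, dtype=np.int8)

    diag = np.zeros(4)
    # hot-loop RNG state: a distinct, fixed scramble of the run seed
    rstate = np.array([(config.seed * 6364136223846793005 + 1442695040888963407)
                       % (2 ** 64) or 88172645463325252], dtype=np.uint64)
    if config.v_command is not None:
        vext = np.asarray(config.v_command, dtype=float)
        if vext.shape[0] != n_steps:
            raise ValueError("v_command must have one value per step")
    else:
        vext = np.zeros(n_steps)

    el = np.array([
        config.g_ampa, config.g_nmda, config.g_leak, config.E_leak,
        config.capacitance_nF(), config.Mg, config.mg_K0, config.mg_delta,
        3.125 * config.gamma_ca, config.E_Ca,
    ])

    nev, err, frame, truncated, n_end = _run_kernel(
        np.uint32(config.seed % (2 ** 31)), n_steps, config.dt,
        config.D_glu * 1e6, g, rstate,
        np.ascontiguousarray(layout.positions[:, 0]),
        np.ascontiguousarray(layout.positions[:, 1]),
        np.ascontiguousarray(layout.positions[:, 2]),
        np.ascontiguousarray(layout.normals[:, 0]),
        np.ascontiguousarray(layout.normals[:, 1]),
        np.ascontiguousarray(layout.normals[:, 2]),
        rec_scheme, rec_pop, rec_state, idx_syn, idx_ext,
        tables.base, tables.resting, tables.is_ampa,
        tables.sl_lig, tables.sl_open, tables.sl_pexit, tables.sl_ktot,
        tables.uni_off, tables.uni_rate, tables.uni_tgt, tables.uni_unb,
        tables.uni_rrad,
        tables.bim_off, tables.bim_tgt, tables.bim_r2, tables.rb_max,
        rel_step, rel_n,
        np.ascontiguousarray(rel_pos[:, 0]),
        np.ascontiguousarray(rel_pos[:, 1]),
        np.ascontiguousarray(rel_pos[:, 2]),
        pos, alive, nxt,
        stride, np.uint8(config.record_cleft), np.uint8(config.adaptive),
        np.uint8(config.electro), el, vext,
        counts, free_rec, cleft_rec, released_rec, vm_rec, ca_rec,
        ev_t, ev_rec, ev_from, ev_to, ev_kind, diag)

    if err == 2:
        raise RuntimeError("particle slot capacity exceeded")
    if err != 0:
        raise RuntimeError(
            f"occupancy/ligand conservation violated at frame {frame} "
            f"(seed {config.seed}); frame dump: free={free_rec[frame]}, "
            f"released={released_rec[frame]}")

    pop_schemes = {}
    pop_sizes = {p: 0 for p in pop_names}
    for r in range(m):
        pop_schemes[pop_names[rec_pop[r]]] = tables.schemes[rec_scheme[r]]
        pop_sizes[pop_names[rec_pop[r]]] += 1

    return Trajectory(
        times=np.arange(n_frames) * stride * config.dt,
        counts=counts, pop_names=pop_names, pop_schemes=pop_schemes,
        pop_sizes=pop_sizes, free_count=free_rec, cleft_count=cleft_rec,
        released=released_rec, vm=vm_rec, cum_ca=ca_rec,
        events={"time": ev_t[:nev].copy(), "receptor": ev_rec[:nev].copy(),
                "from_state": ev_from[:nev].copy(),
                "to_state": ev_to[:nev].copy(), "kind": ev_kind[:nev].copy()},
        rec_pop=rec_pop, rec_subtype=list(layout.subtypes), config=config,
        final_positions=pos[:n_end, :3].copy(),
        diagnostics={"moves": diag[0], "k_sum": diag[1]},
        events_truncated=bool(truncated),
    )
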