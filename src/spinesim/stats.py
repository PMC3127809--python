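"""Summary statistics over replicate trajectories.

All statistics operate on lists of :class:`~spinesim.engine.Trajectory`
replicates of one scenario and report replicate dispersion as the standard
error over seeds.  "Activated time" is extensive (receptor * ms summed over
all receptors of a class), so that per-receptor averages scale linearly
when predicting a mixed synapse from single-subtype runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .engine import Trajectory


@dataclass
class MeanSE:
    mean: float
    se: float
    n: int

    def __iter__(self):
        yield self.mean
        yield self.se


def _mean_se(values) -> MeanSE:
    v = np.asarray(values, dtype=float)
    se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
    return MeanSE(float(v.mean()), se, len(v))


def _boxcar(trace: np.ndarray, times: np.ndarray, smooth_ms: float) -> np.ndarray:
    if smooth_ms <= 0 or len(times) < 2:
        return trace
    dt = times[1] - times[0]
    win = max(1, int(round(smooth_ms / dt)))
    if win <= 1:
        return trace
    return np.convolve(trace, np.ones(win) / win, mode="same")


def peak_open_pct(trajectories: list[Trajectory], pop: str,
                  smooth_ms: float = 1.0) -> MeanSE:
    """Mean +/- SE over replicates of the peak open percentage of one
    receptor population (max over time of open count / population size).

    Each replicate's open-count trace is boxcar-smoothed (default 1 ms,
    matching :func:`time_to_peak`) before taking the max, so that the peak
    reflects the population response rather than single-frame flicker
    coincidences; pass ``smooth_ms=0`` for the raw frame-wise maximum.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least two replicate trajectories")
    peaks = []
    for tr in trajectories:
        if tr.pop_sizes.get(pop, 0) == 0:
            raise ValueError(f"population {pop!r} is empty")
        trace = _boxcar(tr.open_count(pop).astype(float), tr.times, smooth_ms)
        peaks.append(100.0 * trace.max() / tr.pop_sizes[pop])
    return _mean_se(peaks)


def cv_of_peak(trajectories: list[Trajectory], pop: str,
               smooth_ms: float = 1.0) -> float:
    """Coefficient of variation (SD/mean) of peak open counts across
    replicates; NaN when the mean response is zero."""
    if len(trajectories) < 10:
        raise ValueError("CV needs at least 10 replicates")
    peaks = np.array(
        [_boxcar(tr.open_count(pop).astype(float), tr.times, smooth_ms).max()
         for tr in trajectories])
    if peaks.mean() == 0:
        return float("nan")
    return float(peaks.std(ddof=1) / peaks.mean())


def time_to_peak(trajectories: list[Trajectory], pop: str,
                 smooth_ms: float = 1.0) -> float:
    """Time (ms) of the maximum of the replicate-averaged open-count trace,
    after a boxcar smooth (default 1 ms)."""
    times = trajectories[0].times
    trace = np.mean([tr.open_count(pop) for tr in trajectories], axis=0)
    if trace.max() <= 0:
        raise ValueError("no activation; time to peak undefined")
    trace = _boxcar(trace, times, smooth_ms)
    return float(times[int(np.argmax(trace))])


def time_to_peak_per_replicate(trajectories: list[Trajectory], pop: str,
                               smooth_ms: float = 1.0) -> MeanSE:
    """Per-replicate smoothed argmax times, reported as mean +/- SE;
    replicates in which the population never opened are skipped."""
    vals = []
    for tr in trajectories:
        try:
            vals.append(time_to_peak([tr], pop, smooth_ms))
        except ValueError:
            continue
    if not vals:
        raise ValueError("no replicate showed any activation")
    return _mean_se(vals)


# ---------------------------------------------------------------------------
# flicker analysis from the event log
# ---------------------------------------------------------------------------

@dataclass
class FlickerStats:
    events_per_binding: np.ndarray    # openings within each binding epoch
    openings_per_bind_event: np.ndarray  # per epoch, openings / bindings
    event_durations: np.ndarray       # ms, contiguous open residences
    activation_periods: np.ndarray    # ms, contiguous activated residences


def flicker_stats(trajectories: list[Trajectory], pop: str) -> FlickerStats:
    """Per-binding-epoch opening counts and open/activated durations.

    A binding epoch runs from the first glutamate binding of an unbound
    receptor to the return to the fully unbound state; epochs still bound
    when the recording ends are counted with the openings observed so far
    (dropping them would select against slowly-unbinding receptors, whose
    epochs outlive any finite window).  Open events are contiguous
    residences in the conducting state; activation periods are contiguous
    residences in the activated conformations (gated intermediate + open),
    which is what prolongs the macroscopic response of NR2B-containing
    receptors.
    """
    epb: list[int] = []
    opb: list[float] = []
    durations: list[float] = []
    periods: list[float] = []
    for tr in trajectories:
        sch = tr.pop_schemes[pop]
        p = tr.pop_index(pop)
        lig = np.array([s.ligand_count for s in sch.states])
        is_open = np.array([s.open for s in sch.states])
        is_act = np.array([s.activated for s in sch.states])
        ev = tr.events
        end_time = tr.times[-1]
        for r in np.unique(ev["receptor"]):
            if tr.rec_pop[r] != p:
                continue
            sel = ev["receptor"] == r
            t = ev["time"][sel]
            to = ev["to_state"][sel]
            frm = ev["from_state"][sel]
            # binding epochs and opening counts
            openings = 0
            bindings = 0
            in_epoch = False
            open_since = -1.0
            act_since = -1.0
            for i in range(len(t)):
                if not in_epoch and lig[frm[i]] == 0 and lig[to[i]] > 0:
                    in_epoch = True
                    openings = 0
                    bindings = 0
                if in_epoch and lig[to[i]] > lig[frm[i]]:
                    bindings += 1
                if in_epoch and is_open[to[i]] and not is_open[frm[i]]:
                    openings += 1
                if is_open[to[i]] and open_since < 0:
                    open_since = t[i]
                if not is_open[to[i]] and open_since >= 0:
                    durations.append(t[i] - open_since)
                    open_since = -1.0
                if is_act[to[i]] and act_since < 0:
                    act_since = t[i]
                if not is_act[to[i]] and act_since >= 0:
                    periods.append(t[i] - act_since)
                    act_since = -1.0
                if in_epoch and lig[to[i]] == 0:
                    in_epoch = False
                    epb.append(openings)
                    opb.append(openings / max(bindings, 1))
            if in_epoch:
                epb.append(openings)   # right-censored epoch
                opb.append(openings / max(bindings, 1))
            # open events still in progress at run end are dropped
    return FlickerStats(np.array(epb, dtype=int), np.array(opb),
                        np.array(durations), np.array(periods))


def ks_compare(a: np.ndarray, b: np.ndarray):
    """Two-sample Kolmogorov-Smirnov comparison of two distributions."""
    return sps.ks_2samp(a, b)


def expected_events_per_binding(scheme, concentration: float = 0.0) -> float:
    """Absorbing-chain expectation of openings per binding epoch.

    Treats the fully unbound state as absorbing, starts from the state
    reached by the first binding, and counts expected entries into the open
    state via the fundamental matrix of the embedded jump chain.
    ``concentration`` sets the bimolecular rates inside the epoch (0 for a
    single isolated binding).
    """
    names = [s.name for s in scheme.states]
    rest = scheme.resting_state.name
    open_name = scheme.open_state.name
    q = scheme.rate_matrix(concentration)
    idx = {n: i for i, n in enumerate(names)}
    # embedded jump chain over transient (non-resting) states
    transient = [n for n in names if n != rest]
    ti = {n: k for k, n in enumerate(transient)}
    n_t = len(transient)
    p = np.zeros((n_t, n_t))
    # entries into `open_name` counted via a visit-count formulation
    for a in transient:
        ia = idx[a]
        total = -q[ia, ia]
        if total <= 0:
            continue
        for b in names:
            if b == a:
                continue
            rate = q[ia, idx[b]]
            if rate <= 0 or b == rest:
                continue
            p[ti[a], ti[b]] += rate / total
    fund = np.linalg.inv(np.eye(n_t) - p)
    # start distribution: transitions out of rest (first binding)
    starts = np.zeros(n_t)
    ir = idx[rest]
    tot = q[ir].copy()
    tot[ir] = 0.0
    if tot.sum() == 0:
        # isolated binding: first bound state(s) reached bimolecularly
        first = [t.target for t in scheme.transitions
                 if t.source == rest and t.order == "bimolecular"]
        w = np.array([t.rate for t in scheme.transitions
                      if t.source == rest and t.order == "bimolecular"])
        for f, wi in zip(first, w / w.sum()):
            starts[ti[f]] = wi
    else:
        for b in names:
            if b != rest and tot[idx[b]] > 0:
                starts[ti[b]] = tot[idx[b]] / tot.sum()
    visits = starts @ fund
    # expected entries into open = sum over predecessors of visits * P(->open)
    entries = 0.0
    for a in transient:
        if a == open_name:
            continue
        ia = idx[a]
        total = -q[ia, ia]
        if total <= 0:
            continue
        entries += visits[ti[a]] * (q[ia, idx[open_name]] / total)
    return float(entries)


# ---------------------------------------------------------------------------
# desensitization / activated time / mixed-synapse prediction
# ---------------------------------------------------------------------------

def desensitized_fraction(trajectories: list[Trajectory], t: float,
                          pop: str) -> float:
    """Fraction of a population occupying any desensitized state at time t,
    averaged over replicates."""
    out = []
    for tr in trajectories:
        if t < tr.times[0] or t > tr.times[-1]:
            raise ValueError("t outside the trajectory span")
        i = int(np.searchsorted(tr.times, t))
        i = min(i, len(tr.times) - 1)
        out.append(tr.desensitized_count(pop)[i] / tr.pop_sizes[pop])
    return float(np.mean(out))


def desensitization_recovery(trajectories: list[Trajectory], pop: str,
                             stim_end: float, t_recover: float) -> MeanSE:
    """Percent of the peak desensitized pool recovered ``t_recover`` ms
    after the end of stimulation, per replicate."""
    vals = []
    for tr in trajectories:
        d = tr.desensitized_count(pop).astype(float)
        upto = tr.times <= stim_end
        peak = d[upto].max()
        if peak <= 0:
            continue
        i = int(np.searchsorted(tr.times, stim_end + t_recover))
        i = min(i, len(tr.times) - 1)
        vals.append(100.0 * (peak - d[i]) / peak)
    if not vals:
        return MeanSE(float("nan"), float("nan"), 0)
    return _mean_se(vals)


def activated_time(trajectory: Trajectory, pop: str,
                   t_max: float | None = None) -> float:
    """Total open-state residence summed over all receptors of a population
    (receptor * ms), integrated from the recorded open-count trace."""
    times = trajectory.times
    oc = trajectory.open_count(pop).astype(float)
    if t_max is not None:
        sel = times <= t_max
        times, oc = times[sel], oc[sel]
    return float(np.trapezoid(oc, times))


def activated_time_and_contribution(trajectories: list[Trajectory],
                                    t_max: float | None = None):
    """Per-population total activated time (mean +/- SE over seeds) and the
    fractional contribution of each population to the grand total."""
    pops = trajectories[0].pop_names
    totals = {p: [activated_time(tr, p, t_max) for tr in trajectories]
              for p in pops}
    means = {p: _mean_se(v) for p, v in totals.items()}
    grand = sum(m.mean for m in means.values())
    contrib = {p: (means[p].mean / grand if grand > 0 else float("nan"))
               for p in pops}
    return means, contrib


def predict_mixed_response(per_subtype_mean_per_receptor: dict[str, float],
                           composition: dict[str, int]) -> float:
    """Proportional-scaling prediction of the total activated time of a
    mixed synapse: sum over subtypes of count * mean per-receptor time."""
    missing = [s for s in composition if s not in
               per_subtype_mean_per_receptor]
    if missing:
        raise ValueError(f"no per-receptor average for {missing}")
    return float(sum(composition[s] * per_subtype_mean_per_receptor[s]
                     for s in composition))


@dataclass
class SummaryStats:
    """Per-scenario scalar summaries keyed by population."""

    peak_open_pct: dict[str, MeanSE] = field(default_factory=dict)
    cv_peak: dict[str, float] = field(default_factory=dict)
    time_to_peak_ms: dict[str, float] = field(default_factory=dict)
    activated_time: dict[str, MeanSE] = field(default_factory=dict)
    contribution: dict[str, float] = field(default_factory=dict)
    calcium_total: MeanSE | None = None

    def to_dict(self) -> dict:
        def conv(d):
            return {k: ([v.mean, v.se] if isinstance(v, MeanSE) else v)
                    for k, v in d.items()}

        out = {
            "peak_open_pct": conv(self.peak_open_pct),
            "cv_peak": self.cv_peak,
            "time_to_peak_ms": self.time_to_peak_ms,
            "activated_time": conv(self.activated_time),
            "contribution": self.contribution,
        }
        if self.calcium_total is not None:
            out["calcium_total"] = [self.calcium_total.mean,
                                    self.calcium_total.se]
        return out


def summarize(trajectories: list[Trajectory],
              t_max: float | None = None) -> SummaryStats:
    """Compute the standard per-scenario summary over replicates."""
    s = SummaryStats()
    at, contrib = activated_time_and_contribution(trajectories, t_max)
    s.activated_time = at
    s.contribution = contrib
    for p in trajectories[0].pop_names:
        try:
            s.peak_open_pct[p] = peak_open_pct(trajectories, p)
        except ValueError:
            continue
        if len(trajectories) >= 10:
            s.cv_peak[p] = cv_of_peak(trajectories, p)
        try:
            s.time_to_peak_ms[p] = time_to_peak(trajectories, p)
        except ValueError:
            pass
    ca = [tr.cum_ca[-1] for tr in trajectories]
    if any(c > 0 for c in ca):
        s.calcium_total = _mean_se(ca)
    return s
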