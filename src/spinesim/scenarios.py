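"""Scenario registry reproducing the study's simulation experiments.

Each scenario composes geometry, receptor layout, release protocol, engine
and statistics to reproduce one figure-level experiment: diffusion-rate
sensitivity, dynamic range under uni/multivesicular release, activation
timing and flickering, frequency-train subtype shifts, desensitization and
recovery, chemical LTP, STDP pairing, and the maturation composition sweep.
Every scenario is fully determined by (scenario id, seed list, config
overrides); rerunning with identical seeds reproduces outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import replace

import numpy as np

from . import electro, geometry as geo, presynaptic as presyn, stats
from .engine import SimulationConfig, Trajectory, run_simulation

#: Synaptic NMDAR compositions used in the developmental comparisons
#: (AMPAR content held at 80 throughout).
COMPOSITIONS = {
    "young": {"AMPAR": 80, "NR2B": 20},
    "intermediate": {"AMPAR": 80, "NR2A": 8, "NR2A_NR2B": 8, "NR2B": 4},
    "mature": {"AMPAR": 80, "NR2A": 20},
}

SCENARIO_IDS = (
    "fig2_diffusion", "fig3_dynamic_range", "fig4_flicker", "fig5_frequency",
    "fig6_desensitization", "fig7_chemLTP", "fig8_stdp", "fig9_maturation",
)


def _seed_for(base: int, *parts) -> int:
    h = hashlib.sha256(("|".join(str(p) for p in parts)
                        + f"|{base}").encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31 - 1)


def make_layout(composition: dict[str, int], seed: int,
                geometry: geo.SpineGeometry | None = None,
                extrasynaptic: dict[str, int] | None = None
                ) -> geo.ReceptorLayout:
    g = geometry or geo.build_geometry()
    rng = np.random.default_rng(seed)
    return geo.place_receptors(g, composition, rng,
                               extrasynaptic=extrasynaptic)


def run_single_release(composition: dict[str, int], molecules: int,
                       duration: float, seeds: list[int],
                       base_seed: int = 0, D_glu: float = 0.2,
                       electro_on: bool = False,
                       extrasynaptic: dict[str, int] | None = None,
                       v_command=None, dt: float = 0.01,
                       record_stride: int = 10,
                       adaptive: bool = True) -> list[Trajectory]:
    """Replicated single point-release simulations of one composition."""
    g = geo.build_geometry()
    out = []
    for s in seeds:
        lseed = _seed_for(base_seed, "layout", s)
        layout = make_layout(composition, lseed, g, extrasynaptic)
        train = presyn.single_release(molecules, g)
        cfg = SimulationConfig(
            geometry=g, layout=layout, release=train, duration=duration,
            dt=dt, D_glu=D_glu, seed=_seed_for(base_seed, "engine", s),
            electro=electro_on, v_command=v_command,
            record_stride=record_stride, adaptive=adaptive)
        out.append(run_simulation(cfg))
    return out


def run_train(composition: dict[str, int], frequency: float,
              stim_duration: float, total_duration: float,
              seeds: list[int], base_seed: int = 0,
              electro_on: bool = False,
              extrasynaptic: dict[str, int] | None = None,
              params: presyn.PresynapticParams | None = None,
              record_cleft: bool = False,
              event_cap: int = 2_000_000) -> list[Trajectory]:
    """Replicated stochastic frequency-train simulations."""
    g = geo.build_geometry()
    out = []
    for s in seeds:
        rng = np.random.default_rng(_seed_for(base_seed, "train", s))
        train = presyn.frequency_train(frequency, stim_duration, g,
                                       params=params, rng=rng)
        layout = make_layout(composition, _seed_for(base_seed, "layout", s),
                             g, extrasynaptic)
        cfg = SimulationConfig(
            geometry=g, layout=layout, release=train,
            duration=total_duration, seed=_seed_for(base_seed, "engine", s),
            electro=electro_on, record_cleft=record_cleft,
            event_cap=event_cap)
        out.append(run_simulation(cfg))
    return out


def run_stdp(composition: dict[str, int], delta_t: float, paired: bool,
             seeds: list[int], base_seed: int = 0, duration: float = 150.0,
             molecules: int = 1500,
             waveform: electro.SpikeWaveform | None = None
             ) -> list[Trajectory]:
    """Single release paired (or not) with a postsynaptic spike command."""
    g = geo.build_geometry()
    dt = 0.01
    n_steps = int(round(duration / dt))
    v_cmd = electro.stdp_depolarization(delta_t, n_steps, dt,
                                        t_release=0.0, waveform=waveform,
                                        enabled=paired)
    return run_single_release(composition, molecules, duration, seeds,
                              base_seed=base_seed, electro_on=True,
                              v_command=v_cmd)


def stdp_fold_increase(composition: dict[str, int], delta_t: float,
                       seeds: list[int], base_seed: int = 0,
                       duration: float = 150.0):
    """Ratio of mean cumulative calcium, paired vs unpaired, with common
    random numbers (same seeds drive both arms)."""
    paired = run_stdp(composition, delta_t, True, seeds, base_seed, duration)
    unpaired = run_stdp(composition, delta_t, False, seeds, base_seed,
                        duration)
    ca_p = np.array([t.cum_ca[-1] for t in paired], dtype=float)
    ca_u = np.array([t.cum_ca[-1] for t in unpaired], dtype=float)
    fold = ca_p.mean() / ca_u.mean()
    # delta-method SE of the ratio of means
    n = len(seeds)
    se = fold * np.sqrt(ca_p.var(ddof=1) / n / ca_p.mean() ** 2
                        + ca_u.var(ddof=1) / n / ca_u.mean() ** 2)
    return fold, float(se), ca_p, ca_u


# ---------------------------------------------------------------------------
# figure-level scenario drivers
# ---------------------------------------------------------------------------

def _seeds(n_seeds: int) -> list[int]:
    if n_seeds <= 0:
        raise ValueError("n_seeds must be positive")
    return list(range(n_seeds))


def _scn_fig2(n_seeds, ov):
    res = {}
    for subtype in ("AMPAR", "NR2A", "NR2B", "NR2A_NR2B"):
        comp = ({"AMPAR": 80} if subtype == "AMPAR"
                else {"AMPAR": 80, subtype: 20})
        for d in ov.get("D_values", (0.2, 0.4)):
            trs = run_single_release(
                comp, ov.get("molecules", 3000), ov.get("duration", 100.0),
                _seeds(n_seeds), base_seed=ov.get("base_seed", 0), D_glu=d)
            res[f"{subtype}@D={d}"] = stats.peak_open_pct(trs, subtype)
    return res


def _scn_fig3(n_seeds, ov):
    res = {}
    molecules = ov.get("molecules_list", (500, 1500, 3000, 10000))
    for subtype in ov.get("subtypes", ("AMPAR", "NR2A", "NR2B", "NR2A_NR2B")):
        comp = ({"AMPAR": 80} if subtype == "AMPAR"
                else {"AMPAR": 80, subtype: 20})
        for m in molecules:
            trs = run_single_release(
                comp, m, ov.get("duration", 150.0), _seeds(n_seeds),
                base_seed=ov.get("base_seed", 0))
            key = f"{subtype}@{m}"
            res[key] = {
                "peak_open_pct": stats.peak_open_pct(trs, subtype),
                "cv_peak": (stats.cv_of_peak(trs, subtype)
                            if n_seeds >= 10 else None),
            }
    return res


def _scn_fig4(n_seeds, ov):
    res = {}
    for subtype in ("NR2A", "NR2A_NR2B", "NR2B"):
        trs = run_single_release(
            {"AMPAR": 80, subtype: 20}, ov.get("molecules", 1500),
            ov.get("duration", 200.0), _seeds(n_seeds),
            base_seed=ov.get("base_seed", 0))
        fl = stats.flicker_stats(trs, subtype)
        res[subtype] = {
            "time_to_peak_ms": stats.time_to_peak(trs, subtype),
            "events_per_binding_mean": float(fl.events_per_binding.mean())
            if len(fl.events_per_binding) else None,
            "open_duration_mean_ms": float(fl.event_durations.mean())
            if len(fl.event_durations) else None,
            "activation_period_mean_ms": float(fl.activation_periods.mean())
            if len(fl.activation_periods) else None,
        }
    return res


MIXED_EXTRA = {"NR2B": 10}


def _scn_fig5(n_seeds, ov):
    res = {}
    for f in ov.get("frequencies", (5, 10, 25, 50, 100)):
        trs = run_train(COMPOSITIONS["intermediate"], f, 1000.0,
                        ov.get("duration", 1000.0), _seeds(n_seeds),
                        base_seed=ov.get("base_seed", 0),
                        extrasynaptic=MIXED_EXTRA)
        at, contrib = stats.activated_time_and_contribution(trs)
        res[f"{f}Hz"] = {"activated_time": {k: list(v) for k, v in at.items()},
                         "contribution": contrib}
    return res


def _scn_fig6(n_seeds, ov):
    res = {}
    for f in ov.get("frequencies", (5, 50, 100)):
        trs = run_train(COMPOSITIONS["intermediate"], f, 1000.0,
                        ov.get("duration", 2000.0), _seeds(n_seeds),
                        base_seed=ov.get("base_seed", 0),
                        extrasynaptic=MIXED_EXTRA)
        frac = {p: stats.desensitized_fraction(trs, 1000.0, p)
                for p in trs[0].pop_names if p != "AMPAR"}
        rec = {p: list(stats.desensitization_recovery(trs, p, 1000.0, 1000.0))
               for p in trs[0].pop_names if p != "AMPAR"}
        res[f"{f}Hz"] = {"desensitized_fraction_at_stim_end": frac,
                         "recovery_pct_at_1s": rec}
    return res


def _scn_fig7(n_seeds, ov):
    res = {}
    for name, comp in COMPOSITIONS.items():
        trs = run_train(comp, ov.get("frequency", 5), 1000.0,
                        ov.get("duration", 1000.0), _seeds(n_seeds),
                        base_seed=ov.get("base_seed", 0),
                        electro_on=True, extrasynaptic=MIXED_EXTRA)
        nmdar_pops = [p for p in trs[0].pop_names if p != "AMPAR"]
        tot = [sum(stats.activated_time(t, p) for p in nmdar_pops)
               for t in trs]
        tot = np.array(tot)
        res[name] = {
            "activated_time_mean": float(tot.mean()),
            "activated_time_se": float(tot.std(ddof=1) / np.sqrt(len(tot))),
            "activated_time_cv": float(tot.std(ddof=1) / tot.mean())
            if tot.mean() > 0 else None,
            "calcium_mean": float(np.mean([t.cum_ca[-1] for t in trs])),
        }
    return res


def _scn_fig8(n_seeds, ov):
    res = {}
    for name in ov.get("compositions", ("young", "intermediate", "mature")):
        for dt_pair in ov.get("delta_ts", (0.0,)):
            fold, se, ca_p, ca_u = stdp_fold_increase(
                COMPOSITIONS[name], dt_pair, _seeds(n_seeds),
                base_seed=ov.get("base_seed", 0))
            res[f"{name}@dt={dt_pair}"] = {
                "fold_increase": fold, "fold_se": se,
                "ca_paired_mean": float(ca_p.mean()),
                "ca_unpaired_mean": float(ca_u.mean()),
            }
    return res


def _scn_fig9(n_seeds, ov):
    """Maturation sweep via proportional scaling of per-receptor responses.

    Per-receptor frequency responses of each subtype are measured on
    single-subtype synapses, then composition ratios from all-NR2B to
    either all-NR2A or all-triheteromeric are predicted by proportional
    scaling (as done for the published composition sweep)."""
    freqs = ov.get("frequencies", (5, 50, 100))
    per_rec: dict[int, dict[str, float]] = {f: {} for f in freqs}
    for subtype in ("NR2A", "NR2B", "NR2A_NR2B"):
        for f in freqs:
            trs = run_train({"AMPAR": 80, subtype: 20}, f, 1000.0,
                            ov.get("duration", 1000.0), _seeds(n_seeds),
                            base_seed=ov.get("base_seed", 0))
            vals = [stats.activated_time(t, subtype) / 20.0 for t in trs]
            per_rec[f][subtype] = float(np.mean(vals))
    res = {"per_receptor_activated_time": per_rec, "predictions": {}}
    for f in freqs:
        mature_a = stats.predict_mixed_response(per_rec[f], {"NR2A": 20})
        mature_t = stats.predict_mixed_response(per_rec[f], {"NR2A_NR2B": 20})
        res["predictions"][f"{f}Hz"] = {
            "all_NR2A": mature_a, "all_tri": mature_t,
            "ratio_NR2A_over_tri": (mature_a / mature_t
                                    if mature_t > 0 else float("nan")),
        }
    return res


_HANDLERS = {
    "fig2_diffusion": _scn_fig2,
    "fig3_dynamic_range": _scn_fig3,
    "fig4_flicker": _scn_fig4,
    "fig5_frequency": _scn_fig5,
    "fig6_desensitization": _scn_fig6,
    "fig7_chemLTP": _scn_fig7,
    "fig8_stdp": _scn_fig8,
    "fig9_maturation": _scn_fig9,
}

#: Replicate counts mirroring the published design.
DEFAULT_SEEDS = {
    "fig2_diffusion": 40, "fig3_dynamic_range": 40, "fig4_flicker": 40,
    "fig5_frequency": 100, "fig6_desensitization": 20, "fig7_chemLTP": 40,
    "fig8_stdp": 40, "fig9_maturation": 40,
}


def _jsonify(obj):
    if isinstance(obj, stats.MeanSE):
        return [obj.mean, obj.se]
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_scenario(scenario_id: str, n_seeds: int | None = None,
                 overrides: dict | None = None,
                 out_dir: str | None = None, fast: bool = False) -> dict:
    """Execute one registered scenario and return (and optionally write)
    its summary statistics."""
    if scenario_id not in _HANDLERS:
        raise KeyError(f"unknown scenario {scenario_id!r}; "
                       f"available: {SCENARIO_IDS}")
    ov = dict(overrides or {})
    if n_seeds is None:
        n_seeds = 10 if fast else DEFAULT_SEEDS[scenario_id]
    if n_seeds <= 0:
        raise ValueError("n_seeds must be positive")
    result = _HANDLERS[scenario_id](n_seeds, ov)
    payload = {"scenario": scenario_id, "n_seeds": n_seeds,
               "overrides": _jsonify(ov), "results": _jsonify(result)}
    if out_dir is not None:
        path = pathlib.Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / f"{scenario_id}.json", "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)
    return payload
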