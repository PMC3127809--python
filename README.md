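# spinesim

Stochastic reaction–diffusion simulation of glutamatergic signalling at a
single dendritic spine, for computational neuroscientists studying how
NMDA-receptor subunit composition shapes synaptic transmission and
plasticity.

Individual glutamate molecules released from the presynaptic bouton
diffuse by Brownian dynamics through a 20 nm synaptic cleft and the
surrounding extracellular space, bind AMPA receptors and NMDA receptor
subtypes (NR1/NR2A, NR1/NR2B, triheteromeric NR1/NR2A/NR2B) on the
postsynaptic membrane through calibrated binding radii, and gate each
receptor's published kinetic scheme as a continuous-time Markov chain.
A compartmental electrical model with the Jahr–Stevens Mg²⁺ block converts
conducting NMDARs into stochastic Ca²⁺ entry, enabling chemical-LTP and
spike-timing (STDP) protocols. Because NR2A- and NR2B-containing receptors
differ sharply in glutamate affinity, gating and desensitization, the model
resolves which subtypes respond to univesicular versus multivesicular
release and how their contributions shift across 5–100 Hz stimulus trains.

The model's core pieces:

* **Kinetics** — Jonas AMPAR scheme (two bindings, three desensitized
  states) and Erreger NMDAR schemes (two bindings, slow+fast series gating,
  two desensitized states); the triheteromeric receptor binds one NR2A-like
  and one NR2B-like site with averaged gating rates.
* **Binding radii** — each bimolecular rate k_on (nm³ ms⁻¹) is converted to
  a capture radius by root-finding on the steady-state capture rate of an
  absorbing sphere under the engine's own Gaussian displacement kernel, so
  the well-mixed particle simulation reproduces mass action.
* **Geometry** — octagonal spine head and bouton (500 nm across flats),
  300×300 nm PSD, 20 nm cleft, a perforated reflecting neuropil sleeve at
  20 nm clearance, and a closed outer box; all surfaces reflect and
  glutamate is conserved.
* **Electro** — V_m from open-channel currents against a 10 nS leak,
  P_unblocked = 1/(1 + (Mg/3.57 mM)·e^(−0.062 V_m)), Poisson ion counting
  with mean γ_Ca·|V_m − E_Ca|·Δt/(2e).

See `docs/methods.md` for the full model description, parameter tables and
design rationale.

## Worked example

Simulate a single 1,500-molecule vesicle onto a synapse bearing 80 AMPARs
and 20 NR1/NR2A-NMDARs, replicated over 8 seeds:

```python
import numpy as np
from spinesim import geometry as geo, presynaptic as presyn, stats
from spinesim.engine import SimulationConfig, run_simulation

g = geo.build_geometry()
runs = []
for seed in range(8):
    layout = geo.place_receptors(g, {"AMPAR": 80, "NR2A": 20},
                                 np.random.default_rng(100 + seed))
    cfg = SimulationConfig(geometry=g, layout=layout,
                           release=presyn.single_release(1500, g),
                           duration=150.0, seed=seed)
    runs.append(run_simulation(cfg))

peak = stats.peak_open_pct(runs, "NR2A")
print(f"NR2A peak open: {peak.mean:.1f} +/- {peak.se:.1f} %")
print(f"time to peak:   {stats.time_to_peak(runs, 'NR2A'):.1f} ms")
```

Output from this exact script:

```
NR2A peak open: 20.6 +/- 5.0 %
time to peak:   5.9 ms
```

Roughly a fifth to a third of the NR2A receptors conduct at the population
peak (replicate-to-replicate variation is large at 8 seeds; at 40 seeds the
mean settles near 25-30 %), reached a few milliseconds after release —
NR2A-NMDARs act as sensitive, fast detectors of single-vesicle release,
while an identical synapse built with NR2B receptors peaks an order of
magnitude lower and tens of milliseconds later (swap `"NR2A"` for
`"NR2B"` above to see it).

Figure-level experiments are packaged as scenarios:

```bash
spinesim reproduce --scenario fig3_dynamic_range --seeds 10 --out results/
spinesim list-scenarios
```

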