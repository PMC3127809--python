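# Methods

`spinesim` is a particle-based stochastic reaction–diffusion model of
glutamatergic transmission at a single dendritic spine. Glutamate molecules
released from the presynaptic bouton diffuse by Brownian dynamics through
the synaptic cleft and surrounding extracellular space, bind AMPA and NMDA
receptors on the postsynaptic membrane via calibrated binding radii, and
drive continuous-time Markov gating of each receptor. A compartmental
electrical model converts conducting NMDARs into stochastic calcium entry
under the voltage-dependent Mg²⁺ block.

## Receptor kinetics

Four receptor species are modelled as labelled CTMCs (module
`spinesim.kinetics`; all rates in `RATE_TABLE`):

* **AMPAR** (Jonas scheme): R ⇌ RA ⇌ RA₂ ⇌ O with desensitized states D1
  (from RA), D2 (from RA₂ and from D1 by binding another glutamate — the
  D1→D2 constant has volume-rate units) and D3 (from O and D2).
* **NR1/NR2A and NR1/NR2B** (Erreger schemes): two glutamate bindings, a
  slow (k_s±) then fast (k_f±) gating step in series to a single conducting
  state, and two desensitized states entered from the doubly-bound closed
  state only.
* **NR1/NR2A/NR2B** (triheteromeric): one NR2A-like and one NR2B-like
  glutamate site binding independently with their own on/off constants;
  gating and desensitization use the arithmetic mean of the parent
  subtypes' rates (verified exactly in the tests).

Unimolecular rates are in ms⁻¹; bimolecular rates are volume rates in
nm³ ms⁻¹ (1 nm³ ms⁻¹ ≈ 602 M⁻¹s⁻¹).

Two transcription conventions for the published constants are genuinely
underdetermined, and both are exposed as configuration:

* `statistical_factors` (default on): the diheteromeric schemes' first
  binding carries the two-equivalent-site factor (2·k_on); dissociation
  uses the tabulated k_off for both unbinding steps. The triheteromeric
  receptor's sites are distinguishable and the AMPAR constants are
  per-transition fits, so neither carries factors.
* `surface_rate_factor` (default 1): binding radii are computed for
  `factor × k_on`. A receptor mounted on a reflecting membrane captures
  from a hemisphere, so with the default the realized on-rate at the wall
  is ≈ k_on/2 — the behaviour of a plain binding-radius transcription of
  the tabulated rates. Setting 2 restores exactly k_on at the wall.

The defaults were selected because they reproduce the published
dynamic-range values (in particular the AMPAR range 0.8 % → 42 % across
500 → 10,000 released molecules) that the alternatives miss severalfold.

"Open" means the single conducting state. For event statistics we
distinguish **open events** (contiguous residence in the conducting state;
exponentially distributed with mean 1/(total exit rate), ≈ 5.7 ms for both
diheteromeric NMDARs and ≈ 1.1 ms for AMPARs) from **activation periods**
(contiguous residence in the activated conformations — gated intermediate
plus open — during which the channel flickers). Single-opening durations
are nearly identical between NR2A and NR2B because their k_f⁻ differ by
0.6 %; it is the activation periods that separate the subtypes
(≈ 107 ms NR2A vs ≈ 75 ms NR2B in closed form), and subtype duration
comparisons are therefore made on activation periods.

## Geometry

Coordinates: origin at the cleft centre, z normal to the PSD, lengths in
nm. The spine head and presynaptic bouton are regular octagonal prisms
(500 nm across flats) whose facing surfaces form a 20 nm cleft; the
300×300 nm PSD square is centred on the spine-head top face. Default prism
heights are 350 nm each (the head height is not constrained by the
morphology the model follows; see "Free parameters" below).

The surrounding neuropil membrane is modelled as a reflecting octagonal
sleeve at 20 nm clearance around the sides of bouton and spine head,
continuing 350 nm along the axon above the bouton, open at the axon end
and closed below by the parent dendritic shaft (an octagonal slab at the
sleeve scale). A closed outer box (4×4×4 µm) bounds the whole domain, so
glutamate is strictly conserved — there is no uptake in the model.

This composite was chosen over the two obvious alternatives after a
quantitative failure analysis: an open box without the sleeve clears the
cleft in ~0.2 ms, an order of magnitude faster than the multi-millisecond
cleft persistence the model is meant to exhibit, and collapses NMDAR
activation at univesicular release; a fully sealed 20 nm shell conserves
tens of µM to mM glutamate indefinitely, which (given the desensitization
rate constants) would prevent any post-train recovery of desensitized
receptors. The perforated sleeve reproduces both regimes: released
glutamate is retained near the synapse for several milliseconds (the cleft
content falls below 10 % of peak within ~1 ms and continues to decay), then
leaks through the axonal opening and dilutes into the box to ~0.2 µM per
1,500-molecule vesicle, low enough for receptors to unbind and recover
between and after stimulus trains.

Reflection is specular and exact for the planar surface set: the segment
from the previous to the proposed position is tested for its earliest
crossing of any surface (outer box, both prisms, dendrite slab, and the
two-sided sleeve), mirrored across the crossed plane, and iterated (up to
12 reflections, then the step is truncated at the last valid surface
point). Receptors are placed uniformly at random on the PSD
(synaptic) or on the spine-head side faces (extrasynaptic) with a 10 nm
minimum centre spacing so binding radii never overlap.

### Free parameters and sensitivity

Prism heights, sleeve extension and box size are not constrained by the
published morphology; they control the *duration* and *amplitude* of the
glutamate exposure after release. They were fixed once (350/350/350 nm,
4 µm box) by matching the published single-release dynamic range and
time-to-peak values over a small panel of candidate geometries, and are
not adjusted per scenario. Sensitivity: deeper prisms/longer sleeves
lengthen the exposure tail, which delays and (through NR2A desensitization)
depresses the NR2A peak while feeding the slowly integrating NR2B-containing
receptors; the residual misfits at 10,000 released molecules (AMPAR ≈ +13 %,
NR2B ≈ −20 %, triheteromeric ≈ −30 %) could not be removed by any geometry
in this family without breaking the NR2A anchors, because exposure scales
exactly linearly in released molecules while the published B-site dose
curves are steeper than that between 1,500 and 10,000 molecules.

## Engine

Time step 0.01 ms (configurable 0.001–0.1; peak activations at 0.01 and
0.002 ms agree within replicate error — tested). Per step: scheduled
vesicles are released as point sources 1 nm beneath the presynaptic face
centre; every particle takes an isotropic Gaussian step with per-axis SD
√(2 D Δt) (D = 0.2 µm²/ms by default) and is reflected; particles ending
within a receptor's binding radius are bound nearest-first (one particle to
the nearest receptor, the nearest particle to a contested receptor, ties by
index); unimolecular transitions fire as a single Gillespie draw truncated
at Δt (at most one transition per receptor per step, exit probability
1 − e^(−KΔt), branches proportional to rates); released ligands are placed
at the reverse-binding radius in the outward hemisphere and diffuse from
the next step.

Binding radii are calibrated by root-finding on the steady-state capture
rate of an absorbing sphere probed with the engine's own displacement
kernel: the radial profile around the sphere is relaxed under alternating
Gaussian-propagation/absorption sweeps (the radial-distribution-function
construction), the absorbed flux per step gives the simulated rate for a
trial radius, and the radius is bracketed and interpolated in r³. At
D = 0.2 µm²/ms and Δt = 0.01 ms the rms step (63 nm) far exceeds every
radius (1.7–6.3 nm), so capture is ballistic-limited and the radius is
within ~0.5 % of (3 k Δt / 4π)^{1/3}; the calibration is verified against
an independent well-mixed Monte-Carlo box to within 5 %. When one state
exposes several binding transitions (the triheteromeric resting state),
radii are made volume-cumulative and candidates take the smallest
qualifying radius, so each transition realizes its own rate exactly in the
ballistic limit.

**Far-field step aggregation.** Particles far from every receptor-bearing
zone take one Gaussian move of K steps (SD √(2 D K Δt)), with K chosen so
the move stays ≥ 3 SDs from any binding zone (K ≤ 256). This is exact for
free diffusion and for specular reflection off planar walls; only
corner-crossing statistics are approximated, far from receptors. It can be
disabled (`adaptive=False`). Particles are scheduled in a calendar queue
keyed by wake-up step (so a step touches only the particles moving in it),
normal deviates come from a 128-layer ziggurat over an xorshift64* stream
(validated against the normal distribution in moments, tails and KS), and
wall-only overshoots are resolved by exact coordinate folding. Together
these keep second-long 100 Hz train simulations at desk scale.

Invariants enforced or tested: exactly one state per receptor; free +
receptor-bound glutamate equals cumulative released at every frame (the
kernel aborts on violation); mean-squared displacement 6 D t within 2 %;
no particle outside the domain.

## Presynaptic release

Single (500–1,500 molecules) and multivesicular-equivalent (2,500–10,000)
releases are single point sources at t = 0. Frequency trains (5–100 Hz for
1 s, 1,500 molecules per vesicle) put spike opportunities on a regular
grid; each spike releases with probability Pr = min(1, Pr₀·F·A) gated by a
readily releasable pool (RRP). Facilitation F and augmentation A are
incremented per spike (0.3 and 0.01) and decay exponentially (τ = 100 ms
and 7 s); the RRP (16 vesicles) refills from a recycling pool (180) with
τ = 5 s. These short-term-plasticity constants are not published for the
hippocampal model the protocol follows; the defaults are plausible
literature-scale values, exposed entirely in `PresynapticParams`, and the
release-count statistics reduce exactly to Binomial(n_spikes, Pr₀) when the
dynamics are disabled (tested against that oracle).

## Membrane potential and calcium

The spine head is one isopotential compartment: open AMPARs (12 pS) and
conducting NMDARs (45 pS) with 0 mV reversal against a 10 nS leak at
−60 mV; C_m from 1 µF/cm² over the head surface (≈ 0.009 pF for the
default head). Because C_m/g_total ≈ 1 µs is far below the 10 µs step, the
voltage update uses the exact exponential relaxation toward the
conductance-weighted steady state (a forward-Euler increment would be
unstable at this step). Mg²⁺ block follows the Jahr–Stevens relation
P_unblocked = 1/(1 + (Mg/3.57 mM)·e^(−0.062 V_m)) at 0.8 mM Mg, sampled
per open NMDAR per step as an independent Bernoulli trial (fast-block
limit). Each open, unblocked NMDAR passes a Poisson number of calcium ions
with mean γ_Ca·|V_m − E_Ca|·Δt/(2e), γ_Ca = 4.5 pS, with the calcium
reversal E_Ca at its physiological +130 mV (configurable). E_Ca matters
structurally: with E_Ca = 0 the driving force vanishes exactly where Mg
unblock peaks, which suppresses the pairing potentiation that the
spike-timing protocol measures; the net-current reversal E_NMDA = 0 mV is
a separate quantity used only for the voltage dynamics. Cumulative calcium
for the pairing protocol is integrated over a 150 ms window containing the
single-release NMDAR response.

The STDP protocol adds a back-propagating-spike command to V_m at
t_release + Δt: an instantaneous 100 mV jump decaying with fast (3 ms,
75 %) and slow (25 ms) exponentials. The command drives Mg unblock and
driving force but not the leak dynamics.

## Statistics

Peak open percentage is the per-replicate maximum of the population
open-count trace after a 1 ms boxcar (the raw frame-wise maximum of a
small count is dominated by single-flicker coincidences; the window is
configurable and `smooth_ms=0` recovers the raw statistic), averaged over
seeds with SE. Time-to-peak is the argmax of the 1 ms-smoothed
replicate-averaged trace. CV is SD/mean of per-replicate peaks. Flicker
statistics (openings per binding epoch, open-event durations, activation
periods) are computed from the exact event log; the expected openings per
binding epoch has an absorbing-Markov-chain closed form used as a test
oracle. "Activated time" is extensive (receptor·ms summed over the
population), so mixed-synapse responses are predicted by proportional
scaling Σ count × mean-per-receptor and compared to direct mixed
simulations. Desensitization recovery is the fraction of the peak
desensitized pool recovered a fixed time after stimulation end.

## Independent references

`spinesim.oracle` provides a mean-field master-equation integrator
(LSODA, rtol 1e−8/atol 1e−10 — the rates span five orders of magnitude)
driven by an arbitrary concentration waveform, and an exact Gillespie
sampler for piecewise-constant waveforms. They share no code with the
engine and are used to validate it. Note that the engine's responses to a
point release legitimately exceed the oracle driven by the *mean* cleft
concentration for fast, supralinearly activating receptors, because the
release creates a radial concentration gradient and the response is convex
in local exposure; oracle agreement is therefore asserted for the slow
NR2B receptor, whose activation integrates past the sub-millisecond
spatial transient.

## Problem sizes

The replicate design follows the modelled study (40 seeds for
single-release and pairing statistics, 100 for frequency trains) in the
scenario registry defaults. The test suite and the reproduction script
(`scripts/acceptance.py`) run reduced replicates chosen as the package's
desk-scale defaults: 40 seeds for sub-2,000-molecule releases and the STDP
pairing, 16 for 10,000-molecule releases, 10 for the cleft transient, and
8 two-second 100 Hz trains; reduced sizes widen the replicate SE
correspondingly and are reported alongside each value.

## Known limitations

* The neuropil wrap is a single idealized perforated sleeve; real synapses
  have heterogeneous astrocytic coverage and active glutamate uptake,
  which the model omits entirely (clearance is purely diffusive).
* No glycine co-agonist site, conductance sublevels or modal gating.
* Calcium is counted, not localized: no buffering, extrusion or
  within-spine diffusion.
* The spine neck is closed to glutamate; extrasynaptic receptors live on
  the head sides only.
* Synthetic release trains use regular spike grids (no axonal jitter) and
  uniform vesicle content; real vesicle content varies severalfold, which
  would add presynaptic variance on top of the postsynaptic stochasticity
  quantified here, so passing CV tests bound only the postsynaptic
  component observed in real recordings.
* Residual quantitative misfits at multivesicular release are described in
  "Free parameters and sensitivity" above.
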