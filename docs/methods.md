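# Methods

## The model

`nociterm` simulates a single unmyelinated (C-fiber) nociceptive neuron as a
branched multicompartment cable. The morphology is a 25 µm soma-like
cylinder on a 100 µm stem axon that bifurcates at a T-junction into a
peripheral and a central axon (2,000 µm each — about ten electrotonic
length constants, so the boundaries are invisible and doubling the axons
changes nothing; 0.25 µm diameter throughout the fiber). The peripheral
axon fans out into `n_endings` terminal chains, each ordered

```
distal_axon (250 µm) → propagation (50 µm) → Na(v)less SIZ (25 µm) → free ending (32 / 26 µm)
```

The spike initiation zone (SIZ) compartment carries no sodium conductance;
the propagation compartment carries the full sodium complement and converts
transducer-driven depolarization into action potentials that travel through
the tree to the central terminal, where output spikes are counted.

Passive properties: membrane resistance 10,000 Ω·cm², capacitance
1 µF/cm², axial resistivity 150 Ω·cm, passive reversal −60 mV. Free endings
(and de novo branches, which are ending-like) have 4× the somatic membrane
resistance and 15× the axial resistivity, modeling organelle crowding in
the distal terminal.

Active currents (densities in S/cm²): Na_v1.8 (0.02), Na_v1.9 (0.00064),
TTX-sensitive fast Na (0.0017), persistent Na (5e-5), delayed-rectifier K
(0.00083), A-type K (0.0015, both gates shifted −20 mV), Kv7/M (0.00034),
h-current (0.00033), and L/H-voltage-activated Ca (0.003 / 0.001).
Reversals: E_Na = +60 mV, E_K = −85 mV, E_h = −20 mV, E_Ca fixed at
+120 mV (no internal calcium dynamics). Sodium densities are zero on the
SIZ, free endings, and de novo branches; every other conductance is
uniform over all compartments.

### Gating kinetics

The source literature for each channel family gives rate equations, not
this package; we parameterize every gate in one uniform form —
Boltzmann steady state `1/(1+exp(±(V½−V)/k))` and a bell-shaped time
constant `τ0 + τ1·exp(−((V−c)/w)²)` — and chose midpoints, slopes, and τ
profiles per family so the assembled neuron reproduces the behaviors the
model is used for: a stable, quiescent rest near −59 mV; no spontaneous
firing; tonic, adapting spike trains under sustained terminal
depolarization (carried by a TTX-sensitive current whose inactivation
midpoint, −44 mV, keeps it available at the −50…−40 mV plateau the
terminal drive produces, with Na_v1.8 supplying the spike body); and
complete silence when all sodium conductances are removed. Three choices
matter most and were set deliberately:

* **No subthreshold plateau attractor.** The persistent inward windows
  (persistent Na, Na_v1.9, T-type Ca) are placed so that the steady-state
  current below −30 mV stays net outward: without this the terminal
  latches onto a self-sustaining depolarized plateau and the spike count
  stops encoding the stimulus. The L-type Ca current carries an
  inactivation gate for the same reason.
* **Slow spike-frequency adaptation.** The Kv7/M time constant
  (τ ≈ 30–280 ms) accumulates across interspike intervals, which makes
  the firing rate grow with drive, terminates firing shortly after the
  puff ends, and sets the few-hertz rates seen in the traces.
* **Depolarization-tolerant sodium.** Na_v1.8 inactivates at −35 mV with
  fast recovery, so trains persist from depolarized holding potentials,
  as in sensory C-fibers.
* **Sodium-dependent propagation.** The L-type Ca current activates only
  above ~−20 mV with a several-millisecond time constant (true HVA
  behavior), so it shapes spikes that sodium initiates but cannot
  regenerate a propagating wave on its own: removing every sodium
  conductance abolishes all output at any drive, as a TTX-like null
  must.

## Nerve-ending stimulation

The capsaicin-like stimulus has a spatial and a temporal part, shared by a
distributed transducer conductance (reversal 0 mV, TRPV1-like) and a point
conductance drive at each ending tip.

**Spatial.** Each stimulated ending — free endings and de novo branches —
is the application site: its membrane carries the full transducer density
ḡ_Trans = 0.0025 S/cm². Beyond the endings the density decays as
`ḡ_Trans·e^(−x/y)` with y = 7.04 µm, where x is the axial distance to the
nearest stimulated ending (computed over the compartment tree). With this
anchoring, elongating an ending enlarges its transducer-bearing membrane
in proportion, and added branches add stimulated membrane — the two
structural manipulations translate directly into drive. Anchoring the
exponential at the ending *tip* instead makes elongation move the
conductance e²-fold away from the SIZ and inverts the structural
phenotype; we therefore read "distance from the nerve ending" as distance
from the ending as a whole.

**Temporal.** The gate is α(t)·β(t) inside the puff window and zero
outside, with β = exp(−(t−t_onset)/τ_β), τ_β = 6500 ms, and
α = α_max·(1−exp(−(t−t_onset)/τ_act)), τ_act = 50 ms. The amplitude
α_max is the one calibrated constant of the stimulus: the printed slow
activation constant τ_α = 1×10⁶ ms is stored (and available via
`literal_tau_alpha=True`, where the gate peaks near 2.4×10⁻³), but the
drive magnitude of the original point-process equations is not
recoverable in physical units, so α_max is fixed once per package version
by `nociterm.experiments.calibrate_drive`: a grid value whose
control-morphology response is a modest train (3–10 spikes at the central
terminal) with the structural contrast holding with headroom — the stated
purpose of the calibration. The shipped value is **α_max = 0.2** (both
classes), with a tip point drive ḡ_Cap = 7×10⁻⁴ S/cm² referenced to the
class-baseline ending area (an absolute ~0.18 nS per ending, independent
of mesh and condition). At full gate the terminal membrane would be
conductance-clamped toward 0 mV (drive ceiling); the calibrated amplitude
keeps the control response a modest, regular, adapting train. Note that
the count–drive relation of the model is not monotone: uniformly scaling
the gate amplitude up eventually *reduces* spike output
(depolarization-block-like saturation, as strong capsaicin produces in
real nociceptors), and stimulating a single ending of a tree can yield
more spikes than stimulating all of them. The structural manipulations
increase output through added stimulated membrane and its interaction
with the terminal architecture, not through uniform drive scaling.

## The structural-plasticity matrix

Conditions per class: control; branching (+100% de novo branches generic,
+200% peptidergic, attached one per ending round-robin at the
propagation/SIZ junction, Na(v)less, class-baseline length); elongation
(endings 32→46 µm generic, 26→44.6 µm peptidergic, propagation sections
scaled by the same ratio — `scale_propagation=False` disables this);
combined. The peptidergic class additionally removes Na_v1.9 everywhere
and uses 7 endings of 26 µm (versus 14 of 32 µm).

Protocol (test scale): 500 ms settling from V = −60 mV, stimulus onset
500 ms later, 2 s puff, 4 s simulated after settling; backward-Euler step
0.025 ms. Readout: upward 0 mV crossings at the distal end of the central
axon, 2 ms refractory, crossing times linearly interpolated.

With the shipped calibration the matrix gives (spike counts at the
central terminal, default sizes):

| class       | control | branching | elongation | combined |
|-------------|---------|-----------|------------|----------|
| generic     | 3       | 4         | 3          | 4        |
| peptidergic | 5       | 10        | 5          | 10       |

Branching carries the contrast: each de novo branch is new stimulated
membrane converging on the SIZ. Elongation is neutral here: the ending
behind its 15× axial resistivity operates as a voltage-source region, so
lengthening it adds little deliverable current; its count equals control
(and the inequalities of the ordinal claim hold with equality). The
ordinal claim — combined above control, single manipulations at least
control — holds for 4, 7, or 14 endings, at half the time step, and with
propagation scaling disabled. At the default sizes combined also matches
the stronger manipulation exactly; at reduced sizes (4 or 7 generic
endings) the combined count can sit one spike below branching-only,
because the elongated propagation sections add membrane load without
adding stimulated area.

## Numerics

Backward Euler on the voltage with staggered exact-exponential gate
updates; gate steady states and relaxation factors are pre-tabulated per
time step on a 0.05 mV grid over [−150, 80] mV and linearly interpolated
(the convention of compartmental simulators). The per-step linear system
is solved exactly in O(N) by Hines elimination over the compartment tree
(children into parents, back-substitution from the root). Integration is
fully deterministic — identical configurations give bit-identical traces.
Divergence (|V| > 200 mV) raises an error naming the first offending
compartment and time.

Discretization defaults: ≤2 µm segments in the free endings and the SIZ
(the stimulus gradient lives there and the effective length constant
under drive is ~23 µm), ≤5 µm in propagation sections, ≤10 µm in distal
axons, ≤25 µm in the long axons (passive length constant ≈ 204 µm). The
transducer conductance is quadratured on a 0.05 µm grid and assigned to
compartments with moment-preserving hat weights, and the point drive is
anchored at the true section end by a Thévenin series correction, so the
attached drive itself is mesh-independent.

Convergence is verified on two axes. At the production resolution,
halving dt (0.025→0.0125 ms) preserves every spike count in the full
condition matrix exactly. Spike-time convergence is assessed at a
dedicated study resolution (1.5 µm ending/SIZ and 12.5 µm axon segments,
dt 0.005 ms, four terminal chains): halving dt and the mesh together
preserves the count and moves the first spike by ~0.3 ms; the late spike
near the end of the puff moves by ~1 ms — timing errors accumulate along
the train and late rebound spikes are hair-trigger timed, so late-spike
times converge more slowly than counts. The spike count, the quantity
the model is used for, is exact everywhere tested; absolute late-spike
times carry a millisecond-scale discretization offset at any affordable
resolution.

Solver verification against closed forms: single-compartment RC charging
to within 0.1%, steady-state sealed-cable attenuation against
cosh((L−x)/λ)/cosh(L/λ) to within 0.5%, and an all-passive tree holding
−60 mV to 1×10⁻⁶ mV without stimulus.

## Calcium-trace analysis

Processing order: background-ROI subtraction → 1 s centered moving
average (edge-truncated) → ΔF/F₀ with F₀ the mean of the first 2 s,
denominator clamped at 1 (numerator keeps the true F₀) → detection.
Baseline statistics F_b (mean) and F_b-max (max) are taken over
[1 s, stimulus onset − 1 s]; a response is positive when the in-window
peak exceeds F_b + (F_b-max − F_b)·k and stays above threshold
contiguously for ≥0.5 s (response duration = longest contiguous
suprathreshold run). k defaults to 2.5, configurable in [2, 3]; the
per-recording choice "depending on baseline stability" in the source
procedure is judgment-based and is replaced here by the fixed default,
as is manual visual inspection — reproducibility over curation. Image
registration and ROI segmentation are out of scope; the module starts
from extracted ROI series.

## Synthetic data

The trace generator emulates GCaMP6s somatic transients:
difference-of-exponentials events (rise 0.2 s, decay 1.8 s — canonical
GCaMP6s scale), a flat baseline (F₀ = 50 a.u.) on top of a background
level, optional slow sinusoidal drift, and white noise; the background
channel is an independent noisy constant, so background subtraction
recovers the event signal exactly on the ΔF/F₀ scale. At 32 Hz and
peak/σ = 5, detection with k = 2.5 reaches ≥95% sensitivity with ≤5%
false positives on event-free traces. What passing these tests does not
show: performance under movement artifacts, correlated (photon/shot)
noise, overlapping events, or neuropil contamination — none of which the
generator emulates.

The morphometry generator draws ending lengths (log-normal, CV 0.25;
control location 32 µm, inflamed 46 µm) and branch counts (Poisson, rate
1 vs 2 per fiber) per condition, and maps samples onto buildable trees
(length → elongation, count → branching percentage). The distribution
families and parameters are configuration chosen to span the control vs.
inflamed geometry range — they exercise the pipeline and make no claim
about measured biological effect sizes.

## Known limitations

* Gating kinetics are behavior-constrained reconstructions, not fits to
  voltage-clamp data; quantities tied to precise rate constants (exact
  rheobase, AP width) should not be read off this model.
* No calcium accumulation or Nernst dynamics; E_Ca is fixed, and the
  L/T-type currents exist for their electrical roles only.
* The drive amplitude is calibrated, so absolute spike counts are
  meaningful only relative to each other across conditions — which is
  the claim the model tests.
* Single neuron, isopotential extracellular space, no temperature (Q10)
  scaling, no TRPV1 desensitization beyond the β inactivation factor.
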