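# Methods

## The single-cell model

The model describes an embryonic preBötC inspiratory pacemaker neuron
as a single electrical compartment with two coexisting slow processes
that can each rhythmically depolarize the cell.

**Membrane.** Currents (pA, outward positive) on a 21 pF membrane:

- spiking subsystem — fast sodium `I_Na = g_Na·m∞³(V)·(1−n)·(V−V_Na)`
  and delayed rectifier `I_K = g_K·n⁴·(V−V_K)` with
  `dn/dt = (n∞(V)−n)/τ_n(V)`, plus an ohmic leak
  `I_L = g_L·(V−V_L)`;
- persistent sodium `I_NaP = g_NaP·m∞(V)·h·(V−V_NaP)` whose
  inactivation gate `h` relaxes with a bell-shaped time constant
  peaking at `τ̄_h = 10 s` — the slow variable of the oscillatory
  bursting mechanism;
- calcium-activated nonspecific cation current
  `I_CAN = g_CAN·[Ca]_i/([Ca]_i+K_CAN)·(V−V_NaP)` — the readout of the
  calcium subsystem;
- a small non-inactivating voltage-gated calcium current `I_Ca`
  sharing the I_NaP activation curve, which couples spiking to
  calcium influx;
- an optional hyperpolarization-related current `I_h` (zero
  conductance by default; no published parameter values exist for it).

All steady-state gates are sigmoids `x∞ = 1/(1+exp((V−V_x)/s_x))`;
negative slope = activation. Time constants are
`τ_x = τ̄_x/cosh((V−V_x)/(2 s_x))`.

**Calcium.** A two-pool model: cytosol and ER exchange through
IP3-receptor-gated release (open probability
`[IP3]·Ca·l/(([IP3]+K_I)(Ca+K_a))` cubed, with slow Ca-dependent
inactivation gate `l`) plus an ER leak, against SERCA re-uptake
(Hill 2). The plasma membrane carries voltage-gated influx
`J_PM_in = −α·I_Ca` and PMCA extrusion (Hill 2), scaled by `1/λ`
(ER-to-plasma-membrane surface ratio). Total calcium
`[Ca]_tot = [Ca]_i + σ·[Ca]_ER` changes only through the plasma
membrane, so with `α = 0` and `V_PMCA = 0` it is exactly conserved —
a standing regression test.

The cytosolic balance is implemented with ER release *raising*
cytosolic calcium (`+(J_ER_in − J_ER_out)`): the release flux is
defined as ER→cytosol, so any other sign would invert the physics and
preclude ER-driven oscillation.

### Parameter provenance and the two reconciliations

All rate constants, conductances and affinities are the published
values for this cell type (defaults in `ModelParameters`; `to_dict`
round-trips them through flat config files). Two points required
reconciliation, resolved against the antecedent respiratory-neuron
model this one derives from:

1. **Fast-Na activation.** Re-using the I_NaP activation midpoint
   (−40 mV, slope −6) for the spike-generating sodium current creates
   a window current so large that the membrane locks at a stable
   depolarized fixed point near −23 mV and never spikes. The fast
   sodium activation therefore defaults to the antecedent spiking
   pair's values (−34 mV, slope −5); I_NaP and I_Ca keep −40/−6.
   Both are configurable (`vm_na`, `sm_na`).
2. **τ_n.** With a voltage-independent `τ_n = 10 ms` the spike
   downstroke is so slow that every "burst" collapses into a single
   ~50 ms spike. The delayed rectifier uses the antecedent model's
   voltage-dependent `τ_n(V) = τ̄_n/cosh((V−v_n)/(2 s_n))`
   (`n_tau_voltage_dependent=False` restores the constant).

An `as_printed` spiking mode (ohmic K-dominated leak, no fast Na, no
separate leak) is retained for comparison; it cannot produce action
potentials and is not used by any default pipeline.

### Calcium flux units and the single calibration constant

The flux constants are given in amount-per-time units (aMol/s for the
pumps, pL/s permeabilities × µM concentrations) over an effective
volume `V_i` in µm³; since 1 aMol/µm³ = 1 µM·ms⁻¹·s, a single global
conversion factor `flux_scale` maps them onto the µM/ms of the
integrator. The dimensionally natural value is of order one; it is
calibrated **once** to `0.6` — the value at which the three discharge
regimes fall at the published conductance balances
((g_NaP, g_CAN) = (2.5, 2.5) plateau, (2.5, 1) mixed, (2.5, 0)
oscillatory, robust to ±2% perturbation of every conductance) — and
never revisited per experiment.

## Numerics

LSODA (stiff/non-stiff switching) with `rtol 1e−8`, `atol 1e−10`,
50 ms maximum step (so quiescent phases cannot step over a burst),
0.5 ms output sampling (resolving ~2 ms spikes), and a 6 s discarded
initial transient. Halving the tolerances moves the mean burst period
by well under 1% (tested). The default initial state rests at −60 mV
with gates at their fixed points, 0.05 µM cytosolic calcium and a
loaded ER (10 µM); the transient discard makes analyses insensitive
to it. Simulations are deterministic bit-for-bit on one platform.

## Drive-potential measurement

1. **Spikes** are upward crossings of a 15 mV *prominence* threshold
   (excursion of the raw trace above its 50 ms running median),
   2 ms refractory. An absolute voltage threshold fails here because
   strong plateau DPs themselves reach −20 mV.
2. **Envelope**: detected spikes are blanked (±8 ms, linear
   interpolation) and a 50 ms running median removes any residue.
3. **Segmentation**: events are envelope local maxima with ≥ 2 mV
   topographic prominence. A global fractional threshold would either
   miss the small mode of a bimodal (mixed) discharge or trigger on
   the slow subthreshold depolarizing ramp between bursts; prominence
   does neither. Boundaries are walked outward from each peak at
   **half of the event's own amplitude** above the inter-burst
   baseline; events closer than 0.2 s merge, and events truncated by
   the window edges are discarded as unmeasurable.
4. **Baseline** is estimated provisionally as the 15th percentile of
   the envelope (for detection) and finalized as the histogram mode
   of the envelope *outside* the detected events.
5. **Amplitude** is the median of the envelope over the event's top
   region (within 20% of its peak) minus baseline — a robust "plateau
   level" that a single noisy sample cannot inflate. **Duration** is
   the width at half amplitude; measuring lower (e.g. at 20%) runs
   into the pacemaker's inter-burst depolarizing ramp and absorbs it
   into the duration. The generator places its ground-truth
   onsets/offsets at the same half-amplitude level, so recovery is
   unbiased by construction rather than by cancellation.

**Per-event class**: plateau-like if duration ≥ 1.2 s *or* the
depolarization-block signature is present (first spike within the
first 30% of the event and a spike-free depolarized stretch covering
≥ 30% of it — brief rebound spikes on the terminal repolarization do
not defeat the flag); else oscillatory-like. The 1.2 s split sits
> 3 SD above the oscillatory per-cycle duration spread
(0.79 ± 0.12 s) and below every plateau-class duration the model or
generator produces; the model's calcium-driven plateaus shorten to
≈ 1.3–1.5 s (at half-amplitude) near the mixed regime, which is why
the split is below the midpoint of the two published means.

**Trace label**: silent (no spikes, no events), tonic (spiking with
no ≥ 0.5 s quiescent gap), plateau or oscillatory (≥ 80% of events in
one class), mixed otherwise; fewer than 3 events sets an
`indeterminate` flag that the regime map keeps as its own category.

## Regime map and sweeps

Each grid point is an independent 46 s simulation (40 s analyzed)
classified as above; the default grid is g_NaP 0–3 nS × g_CAN
0–4.5 nS at 0.25 nS. At the calibrated flux scale the g_CAN sweep at
g_NaP = 2.5 nS reproduces the full oscillatory → mixed → plateau
ordering. The g_NaP sweep at g_CAN = 1.5 nS reproduces the
plateau → mixed portion, with two honest deviations, both documented
by a deliberately failing test:

- at g_NaP ≤ 0.5 nS the cell is not strictly silent: the ER oscillator
  still fires ~1 burst per 70 s (sparse, flagged indeterminate);
- by g_NaP = 5 nS the discharge remains mixed rather than purely
  oscillatory. In this open-cell formulation the ER refills from
  spike-driven calcium influx, so raising g_NaP *accelerates* plateau
  recurrence; no global flux scale both preserves the three anchor
  regimes and starves the plateau mechanism at high g_NaP.

## Synthetic data

Templates encode the published phenotype statistics: plateau DPs
N(30.5, 6.6) mV × N(2.9, 0.35) s at −52.7 mV baseline; oscillatory
DPs N(12.8, 3.8) mV × N(0.79, 0.12) s at −49.2 mV; the mixed template
draws each cycle from the plateau component with probability 0.45
(the weight that solves 0.45·2.9 + 0.55·0.79 ≈ 1.74 s, the reported
mixed-phenotype mean). The published "±" values for durations are
standard errors over hundreds of cycles, so per-cycle SDs (0.35 s and
0.12 s) are design values consistent with per-cycle histogram spread;
amplitude "±" values are used directly as per-cycle SDs. Cycle
periods are not published; 8 / 4 / 5 s (plateau / oscillatory /
mixed, 10% CV) are free choices in the physiological range. Traces
are smoothed-square DPs (80 ms raised-cosine edges, half-amplitude
width = drawn duration) carrying stereotyped ~2 ms spikes at 25 Hz —
confined to the first 40% of plateau-like events, spread across
oscillatory ones — plus 1.5 mV white noise, a typical patch-recording
noise floor. Population fixtures build exact subtype counts
(E18.5: 3 plateau / 9 mixed / 23 oscillatory of 35; E16.5:
13 / 1 / 13 of 27, an interpolation of "near-equal" plateau and
oscillatory prevalence at the reported total). ΔF/F traces are
burst-onset impulse trains convolved with a 1 s exponential kernel at
a 0.1 s frame interval; drive-current traces are zero-baseline
deflection trains. Every artifact ships its exact ground truth and
all randomness flows from explicit seeds.

What the generator does **not** emulate: spike-shape diversity,
slow baseline drift, seal/access artifacts, bleaching or motion in
imaging, and correlated (pink) noise. Passing round trips therefore
demonstrate correctness of the measurement pipeline under clean,
stationary recording conditions, not robustness to every artifact of
real data.

## In-silico pharmacology

Drugs scale maximal conductances ((1−efficacy)·g; no kinetics or
off-target action): riluzole → g_NaP, FFA and 9-phenanthrol → g_CAN;
the synaptic-blockade cocktail has no single-cell target and is a
documented no-op. At full block, riluzole silences the pure-NaP
configuration and FFA the pure-CAN one; on the mixed configuration
FFA leaves pure oscillatory discharge while riluzole leaves only
rare calcium-driven plateau-like events (the fast rhythm collapses by
more than an order of magnitude in event rate). The chi-square
comparison of stage compositions uses the Pearson statistic without
continuity correction; expected counts below 5 are tolerated with the
usual asymptotic caveat.

## Imaging classification

Rhythmicity is the height of the best non-zero-lag autocorrelation
peak of the detrended ΔF/F trace within a 2–20 s period band
(threshold 0.3); phase locking is peak normalized cross-correlation
with the population trace within ±0.5 s (threshold 0.3). The decision
tree — inspiratory iff rhythmic + locked in control; pacemaker iff
still rhythmic under synaptic blockade (locking no longer required,
as isolated pacemakers run at unrelated frequencies);
riluzole-sensitive vs -resistant by the final condition — is a
transparent stand-in for the original undescribed analysis software;
its thresholds live in `ImagingConfig`.

## Problem sizes

Default analyses use 46 s simulations per conductance point, sweeps
at 0.25 nS resolution, and synthetic samples at the published cycle
counts (343 plateau / 1296 oscillatory cycles); these reproduce the
reported statistics comfortably on a single CPU.

## Known limitations

- The flux-scale calibration targets the three anchor regimes; burst
  *periods* of the model (≈ 7–8 s) are slower than typical reported
  inspiratory rates, and plateau durations at half-amplitude are
  shorter than the 2.9 s measured in real cells.
- The model is bistable in places (a depolarized quiescent state
  coexists with bursting), so extreme initial conditions can reach a
  non-bursting attractor; the default initial state and transient
  discard avoid it across the mapped grid.
- No synaptic coupling or network simulation: network-level
  developmental findings are treated as measurement protocols on
  synthetic traces only.
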