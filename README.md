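# prebotc-pacemaker

Modeling and analysis of **embryonic preBötzinger-complex (preBötC)
inspiratory pacemaker neurons** — the brainstem cells whose intrinsic
bursting helps drive the respiratory rhythm before birth.

Late-gestation preBötC pacemakers come in three electrophysiological
flavors: *plateau* bursters (long square-wave drive potentials with
early spikes followed by depolarization block), *oscillatory* bursters
(short, faster-repeating bursts with spikes throughout), and a *mixed*
phenotype emitting both burst classes. The two burst-generating
mechanisms are the persistent sodium current I_NaP (riluzole-sensitive)
and the calcium-activated nonspecific cation current I_CAN
(FFA/9-phenanthrol-sensitive), and the balance of their maximal
conductances g_NaP and g_CAN determines the phenotype.

This package provides, for computational neuroscientists and
electrophysiologists:

- **`prebotc.model_core` / `prebotc.simulator`** — a conductance-based
  single-cell model combining a Hodgkin–Huxley-style spiking membrane
  with two-pool (cytosol/ER) calcium handling:

  ```
  Cm dV/dt = −I_Na − I_K − I_L − I_NaP − I_Ca − I_CAN − I_h + I_app
  I_NaP = g_NaP · m∞(V) · h · (V − V_NaP)        (slow inactivation h, τ̄_h = 10 s)
  I_CAN = g_CAN · [Ca]_i/([Ca]_i + K_CAN) · (V − V_NaP)
  d[Ca]_i/dt  = f_i/V_i · ( (J_PM_in − J_PM_out)/λ + (J_ER_in − J_ER_out) )
  d[Ca]_tot/dt = f_i/V_i · (J_PM_in − J_PM_out)/λ
  ```

  with IP3-receptor-gated ER release, SERCA re-uptake, voltage-gated
  Ca entry and PMCA extrusion. Slow NaP inactivation yields short
  oscillatory bursts; slow ER calcium cycling through I_CAN yields
  long plateaus; intermediate balances yield both.

- **`prebotc.burst_metrics`** — spike detection, spike-stripped
  drive-potential (DP) envelope extraction, per-burst measurement
  (amplitude, duration at half-amplitude, depolarization-block flag),
  and five-way discharge classification
  (silent / tonic / oscillatory / plateau / mixed).

- **`prebotc.regime`** — the (g_NaP, g_CAN) regime map and the two
  canonical one-dimensional sweeps.

- **`prebotc.pharmacology`** — in-silico riluzole / FFA /
  9-phenanthrol block, current–frequency and I–V protocols, and the
  chi-square comparison of phenotype proportions across developmental
  stages (E16.5 vs E18.5).

- **`prebotc.imaging`** — pacemaker identification from ΔF/F
  calcium-imaging traces (rhythmicity via autocorrelation, phase
  locking to the population rhythm, and the
  control → synaptic-blockade → riluzole decision tree).

- **`prebotc.synthetic`** — a ground-truthed generator of voltage,
  ΔF/F and synaptic drive-current traces with the statistical
  structure reported for embryonic pacemakers (plateau DPs
  30.5 ± 6.6 mV / 2.9 s, oscillatory DPs 12.8 ± 3.8 mV / 0.79 s,
  bimodal mixed discharge, stage-specific population compositions),
  so every analysis stage is testable without recording data.

## Worked example

Reproduce the conductance-balance experiment — hold g_NaP at 2.5 nS
and vary g_CAN:

```python
from prebotc import ModelParameters, simulate
from prebotc.burst_metrics import classify_trace, burst_statistics

for gcan in (2.5, 1.0, 0.0):
    p = ModelParameters(gNaP=2.5, gCAN=gcan)
    tr = simulate(p, duration=46.0)          # 6 s transient discarded
    c = classify_trace(tr)
    s = burst_statistics(c.events)
    print(f"gCAN = {gcan:3.1f} nS -> {c.label:11s} "
          f"({s['n_events']} bursts, {s['duration_mean']:.2f} s, "
          f"{s['amplitude_mean']:.1f} mV, {s['frequency_hz']:.3f} Hz)")
```

prints

```
gCAN = 2.5 nS -> plateau     (5 bursts, 1.44 s, 34.2 mV, 0.120 Hz)
gCAN = 1.0 nS -> mixed       (5 bursts, 1.16 s, 17.1 mV, 0.122 Hz)
gCAN = 0.0 nS -> oscillatory (5 bursts, 0.53 s, 11.9 mV, 0.123 Hz)
```

i.e. the same cell model switches from plateau bursting through a
mixed pattern to pure oscillatory bursting as the I_CAN conductance is
withdrawn — the conductance-balance account of the three biological
phenotypes. (`mean_dp_duration` for the mixed point averages long and
short events; inspect `c.per_event_labels` for the bimodal census.)

The same experiments are available from a shell:

```sh
prebotc simulate --set model.gCAN=1.0 --out out_sim
prebotc regime-map --set grid.gnap=0:3:0.25 --set grid.gcan=0:4.5:0.25 --out out_map
prebotc synth --stage E18.5 --out out_fix
prebotc virtual --out out_dev       # E16.5 vs E18.5 + chi-square
```

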