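"""Ground-truthed synthetic data emulating embryonic pacemaker recordings.

Generates voltage traces with the statistical structure reported for
the three embryonic inspiratory pacemaker phenotypes, plus ΔF/F
calcium-imaging traces and synaptic drive-current traces, so that
every stage of the analysis pipeline can be validated against exact
ground truth without any recording data.

Per-phenotype drive-potential statistics (amplitude, duration,
inter-burst membrane potential) follow the published embryonic-stage
measurements: plateau bursters 30.5 ± 6.6 mV / 2.9 s at −52.7 mV,
oscillatory bursters 12.8 ± 3.8 mV / 0.79 s at −49.2 mV, and a mixed
phenotype drawing each cycle from one of the two templates with a
plateau weight of 0.45 (which reproduces the reported overall mixed
means of ≈14.5 mV and ≈1.74 s).  Cycle periods are not reported and
default to 8 / 4 / 5 s.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .burst_metrics import BurstEvent
from .simulator import Trace

__all__ = [
    "SubtypeTemplate",
    "VirtualPopulation",
    "VirtualCell",
    "DffTrace",
    "default_templates",
    "generate_trace",
    "generate_population",
    "generate_dff",
    "generate_drive_current",
    "E18_5_COMPOSITION",
    "E16_5_COMPOSITION",
]

SUBTYPES = ("plateau", "oscillatory", "mixed")

# published per-stage subtype counts (plateau, mixed, oscillatory);
# the E16.5 breakdown interpolates "almost equally present" over the
# reported total of 27 cells
E18_5_COMPOSITION = {"plateau": 3, "mixed": 9, "oscillatory": 23}
E16_5_COMPOSITION = {"plateau": 13, "mixed": 1, "oscillatory": 13}


@dataclass(frozen=True)
class SubtypeTemplate:
    """Statistical template for one discharge phenotype.

    dp_amplitude / dp_duration / cycle_period : per-cycle normal draws
        (mean, SD) in mV / s / s.
    baseline_vm : inter-burst membrane potential, mV.
    plateau_fraction : probability that a cycle of a *mixed* cell is
        drawn from the plateau component (0 for pure oscillatory,
        1 for pure plateau).
    spike_height : spike peak above the local DP envelope, mV.
    spike_width_ms : Gaussian spike half-width, ms.
    spike_rate_hz : intra-burst firing rate.
    spike_early_frac : fraction of the DP over which plateau-like
        cycles spike before depolarization block (oscillatory-like
        cycles spike throughout).
    noise_sd : additive Gaussian noise, mV.
    """

    subtype: str
    dp_amplitude: Tuple[float, float]
    dp_duration: Tuple[float, float]
    cycle_period: Tuple[float, float]
    baseline_vm: float
    plateau_fraction: float = 0.0
    spike_height: float = 55.0
    spike_width_ms: float = 1.5
    spike_rate_hz: float = 25.0
    spike_early_frac: float = 0.4
    noise_sd: float = 1.5
    edge_ms: float = 80.0

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        for name in ("dp_amplitude", "dp_duration", "cycle_period"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")
            if mean <= 0:
                raise ValueError(f"{name} mean must be > 0")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_templates() -> Dict[str, SubtypeTemplate]:
    """Templates reproducing the published phenotype statistics.

    The printed ± values for DP amplitude are used as per-cycle SDs
    (consistent with the spread of the published per-cycle
    histograms); duration SDs of 0.35 s (plateau) and 0.12 s
    (oscillatory) are design values because the printed ± values are
    SEMs over hundreds of cycles.  The mixed template draws each cycle
    from the plateau component with probability 0.45, which solves the
    two-point mixture equation 0.45·2.9 + 0.55·0.79 ≈ 1.74 s for the
    reported mixed-phenotype mean duration.
    """
    plateau = SubtypeTemplate(
        subtype="plateau",
        dp_amplitude=(30.5, 6.6),
        dp_duration=(2.9, 0.35),
        cycle_period=(8.0, 0.8),
        baseline_vm=-52.7,
    )
    oscillatory = SubtypeTemplate(
        subtype="oscillatory",
        dp_amplitude=(12.8, 3.8),
        dp_duration=(0.79, 0.12),
        cycle_period=(4.0, 0.4),
        baseline_vm=-49.2,
    )
    mixed = SubtypeTemplate(
        subtype="mixed",
        dp_amplitude=(30.5, 6.6),       # plateau component; oscillatory
        dp_duration=(2.9, 0.35),        # component values are taken from
        cycle_period=(5.0, 0.5),        # the oscillatory template
        baseline_vm=-49.1,
        plateau_fraction=0.45,
    )
    return {"plateau": plateau, "oscillatory": oscillatory, "mixed": mixed}


def _smoothed_pulse(t: np.ndarray, onset: float, dur: float,
                    amp: float, edge_s: float) -> np.ndarray:
    """Smoothed square DP pulse whose width at half amplitude is ``dur``.

    Raised-cosine rising and falling edges of length ``edge_s``; the
    half-amplitude crossing points (the level at which DP duration is
    measured) are placed exactly at onset and onset+dur.
    """
    # a raised-cosine edge passes half amplitude at mid-edge
    rise_start = onset - 0.5 * edge_s
    fall_end = onset + dur + 0.5 * edge_s
    y = np.zeros_like(t)
    up = (t >= rise_start) & (t < rise_start + edge_s)
    y[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - rise_start) / edge_s))
    top = (t >= rise_start + edge_s) & (t <= fall_end - edge_s)
    y[top] = 1.0
    dn = (t > fall_end - edge_s) & (t <= fall_end)
    y[dn] = 0.5 * (1.0 - np.cos(np.pi * (fall_end - t[dn]) / edge_s))
    return amp * y


def generate_trace(tpl: SubtypeTemplate, n_cycles: int,
                   dt_ms: float = 0.5,
                   seed: int | np.random.SeedSequence = 0,
                   ) -> Tuple[Trace, List[BurstEvent]]:
    """Synthesize a voltage trace of ``n_cycles`` bursts plus exact
    ground-truth events.

    Each cycle draws amplitude, duration and period from the template;
    a smoothed-square DP carries stereotyped spikes (confined to the
    early phase for plateau-like cycles, spread across the burst for
    oscillatory-like ones) and Gaussian noise is added throughout.
    Ground-truth ``BurstEvent`` onsets/offsets mark the half-amplitude
    points of each DP (the analysis measurement level); reproducible
    per seed.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    amps, durs, periods, kinds = [], [], [], []
    for _ in range(n_cycles):
        if tpl.subtype == "mixed" and rng.random() >= tpl.plateau_fraction:
            osc = default_templates()["oscillatory"]
            a_mu, a_sd = osc.dp_amplitude
            d_mu, d_sd = osc.dp_duration
            kind = "oscillatory-like"
        else:
            a_mu, a_sd = tpl.dp_amplitude
            d_mu, d_sd = tpl.dp_duration
            kind = ("plateau-like" if tpl.subtype in ("plateau", "mixed")
                    else "oscillatory-like")
        p_mu, p_sd = tpl.cycle_period
        amp = max(3.0, rng.normal(a_mu, a_sd))
        dur = max(0.1, rng.normal(d_mu, d_sd))
        period = max(rng.normal(p_mu, p_sd), dur + 1.0)
        amps.append(amp); durs.append(dur); periods.append(period)
        kinds.append(kind)
    dt = dt_ms / 1000.0
    lead = 2.0
    total = lead + float(np.sum(periods)) + lead
    t = np.arange(0.0, total, dt)
    V = np.full_like(t, tpl.baseline_vm)
    events: List[BurstEvent] = []
    onset = lead
    for amp, dur, period, kind in zip(amps, durs, periods, kinds):
        V += _smoothed_pulse(t, onset, dur, amp, tpl.edge_ms / 1000.0)
        spike_times = _spike_train(rng, onset, dur, kind, tpl)
        for s in spike_times:
            V += tpl.spike_height * np.exp(
                -0.5 * ((t - s) / (tpl.spike_width_ms / 1000.0)) ** 2)
        events.append(BurstEvent(
            onset=onset, offset=onset + dur, dp_amplitude=amp,
            dp_duration=dur, spike_times=list(spike_times),
            depol_block=(kind == "plateau-like")))
        onset += period
    if tpl.noise_sd > 0:
        V += rng.normal(0.0, tpl.noise_sd, size=t.shape)
    meta = {"subtype": tpl.subtype, "n_cycles": n_cycles,
            "noise_sd": tpl.noise_sd, "synthetic": True}
    return Trace(t=t, V=V, meta=meta), events


def _spike_train(rng: np.random.Generator, onset: float, dur: float,
                 kind: str, tpl: SubtypeTemplate) -> np.ndarray:
    """Regular intra-burst spike times with small jitter."""
    window = dur * (tpl.spike_early_frac if kind == "plateau-like" else 0.92)
    base = onset + 0.04 * dur + np.arange(
        max(1, int(window * tpl.spike_rate_hz))) / tpl.spike_rate_hz
    jitter = rng.normal(0.0, 2e-3, size=base.shape)
    s = base + jitter
    s = s[(s >= onset + 0.01) & (s <= onset + window)]
    if s.size == 0:
        s = np.array([onset + 0.5 * window])
    return np.sort(s)


@dataclass(frozen=True)
class VirtualCell:
    cell_id: str
    subtype: str
    template: SubtypeTemplate
    seed: int


@dataclass
class VirtualPopulation:
    """A developmental-stage population of virtual pacemaker cells."""

    stage: str
    cells: List[VirtualCell]

    def counts(self) -> Dict[str, int]:
        out = {s: 0 for s in SUBTYPES}
        for c in self.cells:
            out[c.subtype] += 1
        return out

    def generate_traces(self, n_cycles: int = 15, dt_ms: float = 0.5
                        ) -> List[Tuple[VirtualCell, Trace, List[BurstEvent]]]:
        return [(c, *generate_trace(c.template, n_cycles, dt_ms, c.seed))
                for c in self.cells]


def generate_population(stage: str, composition: Dict[str, int],
                        seed: int = 0,
                        templates: Dict[str, SubtypeTemplate] | None = None,
                        ) -> VirtualPopulation:
    """Build a virtual population with exactly the requested subtype
    counts; per-cell seeds are spawned deterministically from ``seed``."""
    templates = templates or default_templates()
    cells: List[VirtualCell] = []
    for sub in SUBTYPES:
        n = int(composition.get(sub, 0))
        if n < 0:
            raise ValueError(f"negative count for {sub}")
        for i in range(n):
            cells.append(VirtualCell(
                cell_id=f"{stage}_{sub}_{i:03d}", subtype=sub,
                template=templates[sub],
                seed=_cell_seed(seed, sub, i)))
    return VirtualPopulation(stage=stage, cells=cells)


def _cell_seed(seed: int, sub: str, i: int) -> int:
    ss = np.random.SeedSequence([seed, SUBTYPES.index(sub), i])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ------------------------------------------------------------- ΔF/F

@dataclass
class DffTrace:
    """Fractional-fluorescence (ΔF/F) trace at the imaging frame rate."""

    t: np.ndarray
    dff: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.t.shape != self.dff.shape or self.t.ndim != 1:
            raise ValueError("t and dff must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.dff))):
            raise ValueError("samples must be finite")


def generate_dff(burst_onsets: Sequence[float], duration: float,
                 kernel_tau: float = 1.0, amplitude: float = 1.0,
                 frame_interval: float = 0.1, noise_sd: float = 0.05,
                 seed: int | np.random.SeedSequence = 0) -> DffTrace:
    """Calcium-indicator trace: burst-onset impulses convolved with a
    single-exponential decay kernel, sampled at the imaging frame
    interval, plus Gaussian noise.

    The default 0.1 s frame interval matches a 100 ms exposure time.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, frame_interval)
    dff = np.zeros_like(t)
    for onset in burst_onsets:
        m = t >= onset
        dff[m] += amplitude * np.exp(-(t[m] - onset) / kernel_tau)
    if noise_sd > 0:
        dff += rng.normal(0.0, noise_sd, size=t.shape)
    return DffTrace(t=t, dff=dff, frame_interval=frame_interval)


def generate_drive_current(n_bursts: int, amplitude_mean: float,
                           amplitude_sd: float = 0.0,
                           period: float = 4.0, width: float = 0.8,
                           dt_ms: float = 2.0,
                           seed: int | np.random.SeedSequence = 0,
                           ) -> Tuple[Trace, np.ndarray]:
    """Zero-baseline synaptic drive-current trace with ``n_bursts``
    envelope deflections; returns the trace and the exact per-burst
    amplitudes (pA)."""
    rng = np.random.default_rng(seed)
    amps = rng.normal(amplitude_mean, amplitude_sd, size=n_bursts)
    dt = dt_ms / 1000.0
    total = 2.0 + max(n_bursts, 1) * period
    t = np.arange(0.0, total, dt)
    I = np.zeros_like(t)
    for i, a in enumerate(amps):
        I += _smoothed_pulse(t, 1.0 + i * period, width, a, 0.1)
    meta = {"kind": "drive_current", "n_bursts": n_bursts}
    return Trace(t=t, V=I, meta=meta), amps
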