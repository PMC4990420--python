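"""Reproduction protocols: canned experiments combining the generator
and the measurement pipeline at the published sample sizes.

These are the procedures behind the headline numbers: drive-potential
statistics recovered from synthetic phenotype traces at the reported
cycle counts (343 plateau cycles from 12 cells; 1296 oscillatory
bursts from 23 cells), and the end-to-end classification of the
packaged developmental-stage population fixture.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .burst_metrics import MetricsConfig, classify_trace
from .synthetic import (E18_5_COMPOSITION, default_templates,
                        generate_population, generate_trace)

__all__ = [
    "dp_recovery_experiment",
    "population_fixture_experiment",
    "E18_5_FIXTURE_SEED",
]

# the packaged developmental fixture is built with a fixed seed so that
# it is one concrete, reproducible population
E18_5_FIXTURE_SEED = 185

PUBLISHED_SAMPLE_SIZES = {
    "plateau": dict(total_cycles=343, n_cells=12),
    "oscillatory": dict(total_cycles=1296, n_cells=23),
    "mixed": dict(total_cycles=739, n_cells=15),
}


def _split_cycles(total: int, cells: int) -> List[int]:
    base = total // cells
    extra = total - base * cells
    return [base + 1] * extra + [base] * (cells - extra)


def dp_recovery_experiment(subtype: str, total_cycles: int, n_cells: int,
                           seed: int,
                           metrics: MetricsConfig | None = None) -> Dict:
    """Generate ``total_cycles`` bursts of one phenotype spread over
    ``n_cells`` synthetic cells, run the full DP-measurement pipeline,
    and summarize measured vs ground-truth statistics.

    Returns a dict with the measured and ground-truth mean amplitude
    (mV) and duration (s), the matched per-event measurement errors,
    and the ground-truth standard errors of the mean.
    """
    tpl = default_templates()[subtype]
    metrics = metrics or MetricsConfig()
    ss = np.random.SeedSequence(seed)
    cell_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in ss.spawn(n_cells)]
    meas_amp, meas_dur = [], []
    gt_amp, gt_dur = [], []
    matched_amp_err, matched_dur_err = [], []
    for n_cycles, cs in zip(_split_cycles(total_cycles, n_cells), cell_seeds):
        tr, gt = generate_trace(tpl, n_cycles, seed=cs)
        c = classify_trace(tr, metrics)
        for e in c.events:
            meas_amp.append(e.dp_amplitude)
            meas_dur.append(e.dp_duration)
            g = min(gt, key=lambda g: abs(g.onset - e.onset))
            matched_amp_err.append(e.dp_amplitude - g.dp_amplitude)
            matched_dur_err.append(e.dp_duration - g.dp_duration)
        gt_amp.extend(g.dp_amplitude for g in gt)
        gt_dur.extend(g.dp_duration for g in gt)
    n = len(gt_amp)
    return {
        "subtype": subtype,
        "n_true": n,
        "n_measured": len(meas_amp),
        "amp_mean": float(np.mean(meas_amp)),
        "dur_mean": float(np.mean(meas_dur)),
        "gt_amp_mean": float(np.mean(gt_amp)),
        "gt_dur_mean": float(np.mean(gt_dur)),
        "gt_amp_sem": float(np.std(gt_amp, ddof=1) / np.sqrt(n)),
        "gt_dur_sem": float(np.std(gt_dur, ddof=1) / np.sqrt(n)),
        "matched_amp_bias": float(np.mean(matched_amp_err)),
        "matched_dur_bias": float(np.mean(matched_dur_err)),
    }


def population_fixture_experiment(seed: int = E18_5_FIXTURE_SEED,
                                  n_cycles: int = 15,
                                  metrics: MetricsConfig | None = None
                                  ) -> Dict:
    """Classify every cell of the packaged late-stage (35-cell)
    population fixture end-to-end and report the label census."""
    pop = generate_population("E18.5", E18_5_COMPOSITION, seed=seed)
    counts: Dict[str, int] = {}
    correct = 0
    for cell, tr, _ in pop.generate_traces(n_cycles=n_cycles):
        label = classify_trace(tr, metrics).label
        counts[label] = counts.get(label, 0) + 1
        correct += label == cell.subtype
    total = len(pop.cells)
    return {
        "counts": counts,
        "total": total,
        "accuracy": correct / total,
        "percent_oscillatory": 100.0 * counts.get("oscillatory", 0) / total,
    }
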