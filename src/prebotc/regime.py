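"""Discharge-regime mapping over the (g_NaP, g_CAN) conductance plane.

The balance between the persistent-sodium and calcium-activated
cation conductances determines whether the model cell is silent,
fires short oscillatory bursts, long plateau bursts, or a mixture.
This module classifies single points, runs the two canonical
one-dimensional sweeps (g_CAN variable at g_NaP = 2.5 nS; g_NaP
variable at g_CAN = 1.5 nS), and evaluates the full two-parameter
regime map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .burst_metrics import (DischargeClassification, MetricsConfig,
                            classify_trace)
from .model_core import ModelParameters
from .simulator import SimulationError, SolverSettings, simulate

__all__ = [
    "RegimeMap",
    "classify_point",
    "sweep_gcan",
    "sweep_gnap",
    "compute_regime_map",
    "write_regime_tsv",
]


@dataclass
class RegimeMap:
    """Grid of phenotype labels over (g_NaP, g_CAN).

    labels[i, j] is the phenotype at gnap_values[i], gcan_values[j];
    ``indeterminate`` marks sparse discharges (too few events for a
    confident call) and per-point simulation failures.
    """

    gnap_values: np.ndarray
    gcan_values: np.ndarray
    labels: np.ndarray               # dtype=object, shape (n_gnap, n_gcan)
    frequency: np.ndarray            # Hz, NaN where undefined
    mean_dp_duration: np.ndarray     # s, NaN where undefined

    def __post_init__(self) -> None:
        shape = (len(self.gnap_values), len(self.gcan_values))
        if self.labels.shape != shape:
            raise ValueError("label matrix shape must match the grid")

    def label_at(self, gnap: float, gcan: float) -> str:
        i = int(np.argmin(np.abs(self.gnap_values - gnap)))
        j = int(np.argmin(np.abs(self.gcan_values - gcan)))
        return str(self.labels[i, j])


def classify_point(gnap: float, gcan: float,
                   base: ModelParameters | None = None,
                   duration: float = 46.0,
                   settings: SolverSettings | None = None,
                   metrics: MetricsConfig | None = None,
                   ) -> DischargeClassification:
    """Simulate one (g_NaP, g_CAN) configuration and classify its
    discharge.  Deterministic."""
    if gnap < 0 or gcan < 0:
        raise ValueError("conductances must be >= 0")
    base = base or ModelParameters()
    p = base.with_updates(gNaP=gnap, gCAN=gcan)
    tr = simulate(p, duration=duration, settings=settings)
    return classify_trace(tr, metrics)


def _label(c: DischargeClassification) -> str:
    return "indeterminate" if c.indeterminate else c.label


def sweep_gcan(gnap: float = 2.5,
               gcan_values: Optional[np.ndarray] = None,
               base: ModelParameters | None = None,
               duration: float = 46.0,
               settings: SolverSettings | None = None,
               metrics: MetricsConfig | None = None) -> List[str]:
    """Labels along g_CAN (default 0–4.5 nS) at fixed g_NaP.

    With rising g_CAN the discharge passes from oscillatory through
    mixed to plateau bursting.
    """
    if gcan_values is None:
        gcan_values = np.arange(0.0, 4.5 + 1e-9, 0.25)
    return [
        _label(classify_point(gnap, float(g), base, duration,
                              settings, metrics))
        for g in gcan_values
    ]


def sweep_gnap(gcan: float = 1.5,
               gnap_values: Optional[np.ndarray] = None,
               base: ModelParameters | None = None,
               duration: float = 46.0,
               settings: SolverSettings | None = None,
               metrics: MetricsConfig | None = None) -> List[str]:
    """Labels along g_NaP (default 0–5 nS) at fixed g_CAN."""
    if gnap_values is None:
        gnap_values = np.arange(0.0, 5.0 + 1e-9, 0.25)
    return [
        _label(classify_point(float(g), gcan, base, duration,
                              settings, metrics))
        for g in gnap_values
    ]


def compute_regime_map(gnap_values: Optional[np.ndarray] = None,
                       gcan_values: Optional[np.ndarray] = None,
                       base: ModelParameters | None = None,
                       duration: float = 46.0,
                       settings: SolverSettings | None = None,
                       metrics: MetricsConfig | None = None) -> RegimeMap:
    """Evaluate the full grid (default g_NaP 0–3 nS × g_CAN 0–4.5 nS,
    0.25 nS steps).

    Points are independent, so the result does not depend on
    evaluation order; per-point solver failures are recorded as
    ``indeterminate`` rather than aborting the map.
    """
    if gnap_values is None:
        gnap_values = np.arange(0.0, 3.0 + 1e-9, 0.25)
    if gcan_values is None:
        gcan_values = np.arange(0.0, 4.5 + 1e-9, 0.25)
    gnap_values = np.asarray(gnap_values, dtype=float)
    gcan_values = np.asarray(gcan_values, dtype=float)
    if gnap_values.size == 0 or gcan_values.size == 0:
        raise ValueError("empty conductance grid")
    shape = (len(gnap_values), len(gcan_values))
    labels = np.empty(shape, dtype=object)
    freq = np.full(shape, np.nan)
    dur = np.full(shape, np.nan)
    for i, gnap in enumerate(gnap_values):
        for j, gcan in enumerate(gcan_values):
            try:
                c = classify_point(float(gnap), float(gcan), base,
                                   duration, settings, metrics)
            except SimulationError:
                labels[i, j] = "indeterminate"
                continue
            labels[i, j] = _label(c)
            if c.burst_frequency is not None:
                freq[i, j] = c.burst_frequency
            if c.mean_dp_duration is not None:
                dur[i, j] = c.mean_dp_duration
    return RegimeMap(gnap_values=gnap_values, gcan_values=gcan_values,
                     labels=labels, frequency=freq, mean_dp_duration=dur)


def write_regime_tsv(rm: RegimeMap, path: str | Path) -> None:
    """Long-format TSV: one row per (gnap, gcan) grid point."""
    rows = []
    for i, gnap in enumerate(rm.gnap_values):
        for j, gcan in enumerate(rm.gcan_values):
            rows.append({
                "gnap_nS": gnap,
                "gcan_nS": gcan,
                "label": rm.labels[i, j],
                "frequency_hz": rm.frequency[i, j],
                "mean_dp_duration_s": rm.mean_dp_duration[i, j],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
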