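"""Pacemaker identification from calcium-imaging (ΔF/F) traces.

Re-creates, as a transparent algorithm, the decision pipeline used to
identify inspiratory pacemaker neurons in population imaging:

1. a cell is *inspiratory* if its ΔF/F signal is rhythmic in control
   conditions and phase-locked to the simultaneously recorded
   population rhythm;
2. an inspiratory cell is a *pacemaker* if it remains rhythmic after
   chemical synapses are blocked (a cocktail of glutamatergic /
   glycinergic / GABAergic antagonists) — phase-locking is no longer
   required, because isolated pacemakers run at their own frequencies;
3. a pacemaker is *riluzole-sensitive* (persistent-sodium dependent)
   if additional riluzole silences its rhythm, and
   *riluzole-resistant* (presumed I_CAN-dependent) otherwise.

Rhythmicity is scored by the first non-zero-lag peak of the
autocorrelation of the detrended trace; phase locking by the peak
normalized cross-correlation with the population trace within a
short lag window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .synthetic import DffTrace

__all__ = [
    "ImagingConfig",
    "CellConditionRecord",
    "CellClassification",
    "rhythmicity_score",
    "phase_locked",
    "classify_cell",
    "read_dff_csv",
    "write_cell_classifications",
    "CELL_LABELS",
]

CELL_LABELS = ("non_inspiratory", "non_pacemaker",
               "pacemaker_ril_sensitive", "pacemaker_ril_resistant")

CONDITIONS = ("control", "cocktail", "cocktail_ril")


class MissingConditionError(ValueError):
    """A condition trace required by the decision tree is absent."""


@dataclass(frozen=True)
class ImagingConfig:
    """Thresholds for the imaging decision tree.

    rhythm_threshold : minimum autocorrelation-peak score to call a
        trace rhythmic.
    lock_threshold : minimum normalized cross-correlation to call a
        trace phase-locked to the population rhythm.
    min_period_s / max_period_s : physiological band searched for the
        burst period.
    max_lag_s : lag window for phase locking.
    use_abs_correlation : apply the lock threshold to |r| (sign-
        inverted indicators still count as locked) — off by default.
    """

    rhythm_threshold: float = 0.3
    lock_threshold: float = 0.3
    min_period_s: float = 2.0
    max_period_s: float = 20.0
    max_lag_s: float = 0.5
    use_abs_correlation: bool = False


@dataclass
class CellConditionRecord:
    """Per-cell ΔF/F traces across pharmacological conditions plus the
    control-condition population trace."""

    cell_id: str
    traces: Dict[str, DffTrace]
    population_trace: DffTrace

    def __post_init__(self) -> None:
        if "control" not in self.traces:
            raise MissingConditionError(
                f"cell {self.cell_id}: control trace is required")
        unknown = set(self.traces) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")


@dataclass
class CellClassification:
    label: str
    scores: Dict[str, float] = field(default_factory=dict)
    periods: Dict[str, Optional[float]] = field(default_factory=dict)
    locked: Optional[bool] = None


def _detrend(x: np.ndarray) -> np.ndarray:
    t = np.arange(len(x), dtype=float)
    a, b = np.polyfit(t, x, 1)
    return x - (a * t + b)


def rhythmicity_score(d: DffTrace, min_period: float = 2.0,
                      max_period: float = 20.0
                      ) -> Tuple[float, Optional[float]]:
    """Score periodicity of a ΔF/F trace in [0, 1] and estimate the
    period.

    The score is the height of the highest autocorrelation peak of the
    detrended, variance-normalized trace at lags within
    [min_period, max_period].  Scale-invariant; white noise scores
    near zero, a noiseless periodic transient train near one.  The
    trace must span at least three times the maximum period searched.
    """
    n = len(d.dff)
    dt = d.frame_interval
    if n * dt < 3.0 * max_period:
        raise ValueError(
            f"trace ({n * dt:.1f} s) shorter than 3x max_period "
            f"({3 * max_period:.1f} s)")
    x = _detrend(d.dff.astype(float))
    var = float(np.dot(x, x))
    if var <= 0:
        return 0.0, None
    ac = np.correlate(x, x, mode="full")[n - 1:] / var
    lo = max(1, int(round(min_period / dt)))
    hi = min(n - 2, int(round(max_period / dt)))
    if hi <= lo:
        raise ValueError("period band too narrow for the frame interval")
    window = ac[lo:hi + 1]
    # highest local maximum in the band (not a monotone shoulder)
    best_score, best_lag = 0.0, None
    for k in range(1, len(window) - 1):
        if window[k] >= window[k - 1] and window[k] >= window[k + 1]:
            if window[k] > best_score:
                best_score, best_lag = float(window[k]), lo + k
    if best_lag is None:
        k = int(np.argmax(window))
        best_score, best_lag = float(window[k]), lo + k
    return max(0.0, best_score), best_lag * dt


def phase_locked(d: DffTrace, pop: DffTrace, max_lag: float = 0.5,
                 threshold: float = 0.3,
                 use_abs: bool = False) -> Tuple[bool, float]:
    """Is the cell's signal synchronized to the population rhythm?

    Computes the normalized cross-correlation between the detrended
    cell and population traces over the overlapping time support and
    returns (peak correlation within ±max_lag ≥ threshold, peak value).
    """
    t0 = max(d.t[0], pop.t[0])
    t1 = min(d.t[-1], pop.t[-1])
    if t1 - t0 <= max(d.frame_interval, pop.frame_interval) * 10:
        raise ValueError("cell and population traces do not overlap")
    # resample the population trace onto the cell's time base
    m = (d.t >= t0) & (d.t <= t1)
    tc = d.t[m]
    x = _detrend(d.dff[m])
    y = _detrend(np.interp(tc, pop.t, pop.dff))
    sx = float(np.sqrt(np.dot(x, x)))
    sy = float(np.sqrt(np.dot(y, y)))
    if sx == 0 or sy == 0:
        return False, 0.0
    n = len(x)
    lags = int(round(max_lag / d.frame_interval))
    cc = np.correlate(x, y, mode="full") / (sx * sy)
    center = n - 1
    window = cc[center - lags:center + lags + 1]
    if use_abs:
        peak = float(np.max(np.abs(window)))
    else:
        peak = float(np.max(window))
    return peak >= threshold, peak


def classify_cell(rec: CellConditionRecord,
                  cfg: ImagingConfig | None = None) -> CellClassification:
    """Run the control → synaptic-blockade → riluzole decision tree.

    Raises :class:`MissingConditionError` if a condition trace needed
    at the reached depth of the tree is absent (a silent control cell
    needs no further conditions; a cocktail-rhythmic cell needs the
    riluzole condition to be subclassified).
    """
    cfg = cfg or ImagingConfig()
    out = CellClassification(label="", scores={}, periods={})

    def rhythmic(cond: str) -> bool:
        if cond not in rec.traces:
            raise MissingConditionError(
                f"cell {rec.cell_id}: condition {cond!r} required")
        score, period = rhythmicity_score(
            rec.traces[cond], cfg.min_period_s, cfg.max_period_s)
        out.scores[cond] = score
        out.periods[cond] = period
        return score >= cfg.rhythm_threshold

    if not rhythmic("control"):
        out.label = "non_inspiratory"
        return out
    locked, r = phase_locked(rec.traces["control"], rec.population_trace,
                             cfg.max_lag_s, cfg.lock_threshold,
                             cfg.use_abs_correlation)
    out.locked = locked
    out.scores["lock"] = r
    if not locked:
        out.label = "non_inspiratory"
        return out
    if not rhythmic("cocktail"):
        out.label = "non_pacemaker"
        return out
    if not rhythmic("cocktail_ril"):
        out.label = "pacemaker_ril_sensitive"
    else:
        out.label = "pacemaker_ril_resistant"
    return out


# ---------------------------------------------------------------- I/O

def read_dff_csv(path) -> Dict[str, DffTrace]:
    """Read per-cell ΔF/F traces from a CSV with a ``t_s`` column and
    one column per cell."""
    import pandas as pd

    df = pd.read_csv(path)
    if "t_s" not in df.columns:
        raise ValueError(f"{path}: expected a t_s column")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: too few samples")
    dt = float(t[1] - t[0])
    return {col: DffTrace(t=t, dff=df[col].to_numpy(dtype=float),
                          frame_interval=dt)
            for col in df.columns if col != "t_s"}


def write_cell_classifications(results: Dict[str, CellClassification],
                               path) -> None:
    """One CSV row per cell: label, rhythmicity scores, periods, and
    the phase-lock correlation."""
    import pandas as pd

    rows = []
    for cell_id, c in results.items():
        rows.append({
            "cell_id": cell_id,
            "label": c.label,
            "locked": c.locked,
            "lock_r": c.scores.get("lock"),
            **{f"score_{k}": v for k, v in c.scores.items() if k != "lock"},
            **{f"period_{k}_s": v for k, v in c.periods.items()},
        })
    pd.DataFrame(rows).to_csv(path, index=False)
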