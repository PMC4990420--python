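"""In-silico pharmacology, stimulation protocols, and population
proportion statistics.

Drug action is modeled purely as maximal-conductance scaling:
riluzole blocks the persistent sodium conductance, flufenamic acid
(FFA) and 9-phenanthrol block the calcium-activated cation
conductance.  The synaptic-blockade cocktail (CNQX/AP5/strychnine/
bicuculline) targets chemical synapses and is therefore a no-op on
the isolated single-cell model — it is represented so that protocol
descriptions remain faithful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.stats import chi2_contingency

from .burst_metrics import MetricsConfig, classify_trace
from .model_core import ModelParameters
from .simulator import SolverSettings, simulate, voltage_clamp_current

__all__ = [
    "BlockerSpec",
    "PopulationResult",
    "apply_blocker",
    "current_frequency_curve",
    "iv_curve",
    "population_proportions",
    "compare_stages",
]

_TARGETS = {
    "riluzole": ("gNaP",),
    "FFA": ("gCAN",),
    "phenanthrol9": ("gCAN",),
    "cocktail": (),          # synaptic agents: no single-cell target
}


@dataclass(frozen=True)
class BlockerSpec:
    """A pharmacological block: drug identity and blocked fraction."""

    drug: str
    efficacy: float = 1.0

    def __post_init__(self) -> None:
        if self.drug not in _TARGETS:
            raise ValueError(
                f"unknown drug {self.drug!r}; choose from {sorted(_TARGETS)}")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError("efficacy must lie in [0, 1]")


def apply_blocker(p: ModelParameters, b: BlockerSpec) -> ModelParameters:
    """Return parameters with the drug's target conductance scaled by
    (1 − efficacy); all other fields untouched."""
    updates = {g: getattr(p, g) * (1.0 - b.efficacy)
               for g in _TARGETS[b.drug]}
    return p.with_updates(**updates) if updates else p


def current_frequency_curve(p: ModelParameters,
                            i_app_values: Sequence[float],
                            duration: float = 46.0,
                            settings: SolverSettings | None = None,
                            metrics: MetricsConfig | None = None,
                            ) -> List[Tuple[float, float]]:
    """Burst frequency (Hz) as a function of injected current.

    Pacemaker bursting is voltage-dependent: within the bursting range
    the cycle frequency rises with depolarizing current.  Silent
    points are reported as 0 Hz.
    """
    out = []
    for i_app in i_app_values:
        c = classify_trace(simulate(p, duration=duration, I_app=float(i_app),
                                    settings=settings), metrics)
        f = c.burst_frequency
        out.append((float(i_app),
                    float(f) if f is not None and np.isfinite(f) else 0.0))
    return out


def iv_curve(p: ModelParameters, v_steps: Sequence[float],
             t_step: float = 500.0, t_measure: float = 400.0,
             settings: SolverSettings | None = None,
             ) -> List[Tuple[float, float]]:
    """Steady-state I–V relationship under voltage steps.

    Each step holds the command potential for ``t_step`` ms and reads
    the total membrane current at ``t_measure`` ms (the standard
    0.5 s step / 400 ms read-out protocol).
    """
    return [(float(v), voltage_clamp_current(p, float(v), t_step, t_measure,
                                             settings=settings))
            for v in v_steps]


@dataclass
class PopulationResult:
    """Phenotype composition of one developmental stage."""

    stage: str
    counts: Dict[str, int]
    proportions: Dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def population_proportions(stage: str, labels: Sequence[str]
                           ) -> PopulationResult:
    """Counts and proportions of phenotype labels for one stage."""
    if len(labels) == 0:
        raise ValueError(f"stage {stage!r} has no classified cells")
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    n = len(labels)
    props = {k: v / n for k, v in counts.items()}
    return PopulationResult(stage=stage, counts=counts, proportions=props)


def compare_stages(a: PopulationResult, b: PopulationResult,
                   ) -> Tuple[float, float]:
    """Pearson chi-square test on the stage × phenotype contingency
    table (no continuity correction).

    Returns (statistic, p-value).  Categories absent from one stage
    count as zero there; expected counts below 5 are tolerated but
    make the asymptotic p-value approximate.
    """
    cats = sorted(set(a.counts) | set(b.counts))
    if len(cats) < 2:
        raise ValueError("need at least two phenotype categories")
    table = np.array([[a.counts.get(c, 0) for c in cats],
                      [b.counts.get(c, 0) for c in cats]], dtype=float)
    nonzero = table.sum(axis=0) > 0
    table = table[:, nonzero]
    if table.shape[1] < 2:
        raise ValueError("need at least two populated categories")
    stat, pval, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(pval)
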