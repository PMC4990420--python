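"""Shared fixtures.

Anchor-point simulations (the three reference conductance balances)
are expensive stiff-ODE runs; they are computed once per session and
shared across the tests that inspect them.
"""

from __future__ import annotations

import numpy as np
import pytest

from prebotc import ModelParameters, simulate
from prebotc.burst_metrics import MetricsConfig, classify_trace


ANCHORS = {
    "plateau": dict(gNaP=2.5, gCAN=2.5),
    "mixed": dict(gNaP=2.5, gCAN=1.0),
    "oscillatory": dict(gNaP=2.5, gCAN=0.0),
}


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def metrics_cfg():
    return MetricsConfig()


@pytest.fixture(scope="session")
def anchor_traces():
    """46 s simulations at the three reference (g_NaP, g_CAN) points."""
    out = {}
    for name, kw in ANCHORS.items():
        p = ModelParameters(**kw)
        out[name] = simulate(p, duration=46.0)
    return out


@pytest.fixture(scope="session")
def anchor_classifications(anchor_traces, metrics_cfg):
    return {name: classify_trace(tr, metrics_cfg)
            for name, tr in anchor_traces.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
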