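"""Shared fixtures: expensive paced simulations are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from epicard.params import ModelParameters
from epicard.simulate import paced_last_ap, run_paced
from epicard.traces import ap_features


@pytest.fixture(scope="session")
def baseline_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_train(baseline_params):
    """Baseline 5 s, 5 Hz train from the quiescent state (native dt)."""
    return run_paced(baseline_params, 5.0, 5.0)


@pytest.fixture(scope="session")
def baseline_last_ap(baseline_params):
    """Steady-state baseline last AP at 1 ms (rate-adapted protocol)."""
    return paced_last_ap(baseline_params)


@pytest.fixture(scope="session")
def baseline_features(baseline_last_ap):
    return ap_features(baseline_last_ap)


@pytest.fixture(scope="session")
def endpoint_features(baseline_params, baseline_features):
    """Steady-state AP features at the scan endpoints used by the study."""
    out = {"control": baseline_features}
    cases = {
        "Ktof_0.5": baseline_params.with_scale("Ktof", 0.5),
        "Kur_0.5": baseline_params.with_scale("Kur", 0.5),
        "Kss_0.5": baseline_params.with_scale("Kss", 0.5),
        "Kss_1.5": baseline_params.with_scale("Kss", 1.5),
        "NaL_1.5": baseline_params.with_k_reopen(1.5),
    }
    for name, p in cases.items():
        out[name] = ap_features(paced_last_ap(p))
    return out
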