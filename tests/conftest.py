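"""Shared fixtures: calibrated model runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from navdissect.neuron_model import build_model
from navdissect import protocols as pr


@pytest.fixture()
def model():
    """Fresh calibrated model (cheap to build; heavy runs are session-scoped)."""
    return build_model()


@pytest.fixture(scope="session")
def tuned_amp():
    m = build_model()
    return pr.tune_baseline_amplitude(m)


@pytest.fixture(scope="session")
def density_sweeps(tuned_amp):
    """(nav16_table, nav12_table) from the calibrated model."""
    m = build_model()
    s16 = pr.run_density_sweep(m, "nav16", amp_na=tuned_amp)
    s12 = pr.run_density_sweep(m, "nav12", amp_na=tuned_amp)
    return s16, s12


@pytest.fixture(scope="session")
def crossover_table(tuned_amp):
    m = build_model()
    return pr.run_crossover_sweep(m, amp_na=tuned_amp)


@pytest.fixture(scope="session")
def onboarding_results(tuned_amp):
    """Recovery summaries per condition: no_drug, sr_sr, block16, block12."""
    conditions = {
        "no_drug": (0.0, "YW", "YW"),
        "sr_sr": (200.0, "SR", "SR"),
        "block16": (200.0, "SR", "YW"),   # only NaV1.6 carries the YW site
        "block12": (200.0, "YW", "SR"),
    }
    out = {}
    for name, (conc, g12, g16) in conditions.items():
        m = build_model()
        table, summary = pr.run_onboarding_recovery(
            m, conc, g12, g16, amp_na=tuned_amp, recovery_s=50.0,
        )
        out[name] = {"table": table, "summary": summary}
    return out


@pytest.fixture(scope="session")
def long_train_results():
    """Long-train delta tables: no_drug, sr_sr, wt_drug."""
    conditions = {
        "no_drug": (0.0, "YW", "YW"),
        "sr_sr": (200.0, "SR", "SR"),
        "wt_drug": (200.0, "YW", "YW"),
    }
    out = {}
    for name, (conc, g12, g16) in conditions.items():
        m = build_model()
        out[name] = pr.run_long_train(m, 0.3, 10.0, conc, g12, g16)
    return out
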