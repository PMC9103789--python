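"""Shared fixtures: packaged configs, physiology, and the (expensive)
calibrated victim baseline, computed once per session."""

from __future__ import annotations

import pytest

from szddi import (
    PhysiologyParams,
    calibrate_baseline,
    default_scenarios,
    load_compound,
    load_interaction,
    packaged_config,
)


@pytest.fixture(scope="session")
def phys():
    return PhysiologyParams()


@pytest.fixture(scope="session")
def sza():
    return load_compound(packaged_config("sza.yaml"))


@pytest.fixture(scope="session")
def szb():
    return load_compound(packaged_config("szb.yaml"))


@pytest.fixture(scope="session")
def sza_interaction():
    return load_interaction(packaged_config("sza.yaml"))


@pytest.fixture(scope="session")
def szb_interaction():
    return load_interaction(packaged_config("szb.yaml"))


@pytest.fixture(scope="session")
def victim_raw():
    return load_compound(packaged_config("tacrolimus_synthetic.yaml"))


@pytest.fixture(scope="session")
def calibrated(victim_raw, phys):
    """(calibrated victim, [non_expresser, expresser] scenarios, diagnostics)."""
    return calibrate_baseline(victim_raw, phys, default_scenarios())


@pytest.fixture(scope="session")
def victim(calibrated):
    return calibrated[0]


@pytest.fixture(scope="session")
def scenario_ne(calibrated):
    return next(s for s in calibrated[1] if s.label == "non_expresser")


@pytest.fixture(scope="session")
def scenario_ex(calibrated):
    return next(s for s in calibrated[1] if s.label == "expresser")
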