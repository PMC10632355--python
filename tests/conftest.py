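"""Shared fixtures: one default synthetic bundle plus its calibration."""

import pytest

from cadchart.occupancy import binarize_states, calibrate_threshold, stage_means
from cadchart.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def calibration(bundle):
    """Threshold, stage-level signal and binary states of the default bundle."""
    cfg = bundle.config
    threshold, curve = calibrate_threshold(bundle.atac, bundle.background, target_fdr=0.01)
    signal = stage_means(bundle.atac, cfg.stage_design, cfg.stage_labels)
    states = binarize_states(signal, threshold)
    return {"threshold": threshold, "curve": curve, "stage_signal": signal, "states": states}
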