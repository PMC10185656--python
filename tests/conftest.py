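"""Shared fixtures: seeded synthetic cohorts and calibrated thresholds.

Cohorts are session-scoped because rendering dominates test time; every
fixture is deterministic (fixed seeds), so test outcomes are reproducible
run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from aisquant import aismorph as am
from aisquant import imgcore as ic
from aisquant import synthgen as sg

#: channels the morphometry pipeline consumes
MORPH_CHANNELS = ("map2", "tuj1", "ankg", "pnf", "pannav")


@pytest.fixture(scope="session")
def render_cfg() -> sg.RenderConfig:
    """Default-noise rendering restricted to the morphometry channels."""
    return sg.RenderConfig(channels=MORPH_CHANNELS, z_slices=3)


@pytest.fixture(scope="session")
def full_cfg() -> sg.RenderConfig:
    """All seven channels at default noise."""
    return sg.RenderConfig(z_slices=3)


@pytest.fixture(scope="session")
def noiseless_cfg() -> sg.RenderConfig:
    """Noise- and PSF-free rendering for conservation checks."""
    return sg.RenderConfig(
        z_slices=3, psf_sigma=0.0, noise_gaussian_sd=0.0
    )


@pytest.fixture(scope="session")
def control_cohort(full_cfg):
    """Six control cells with all channels, default noise."""
    return list(
        sg.generate_cohort(6, sg.control_params(), full_cfg, seed=11)
    )


@pytest.fixture(scope="session")
def thresholds(full_cfg):
    """Channel thresholds calibrated on pathology-free control cells."""
    cohort = list(
        sg.generate_cohort(6, sg.calibration_params(), full_cfg, seed=911)
    )
    mips = {
        ch: [
            ic.max_intensity_projection(stack, ch)
            for _, stack, _, _ in cohort
        ]
        for ch in ("ankg", "pnf", "nfl", "tuj1")
    }
    return am.calibrate_thresholds(mips)


@pytest.fixture(scope="session")
def recovery_cohort(render_cfg, thresholds):
    """100 measured cells spanning GAP 0-15 µm and AIS 15-45 µm.

    Returns a list of (ground_truth, measurement) pairs at default noise.
    """
    params = sg.NeuronParams(
        gap_length=(0.0, 15.0), ais_length=(15.0, 45.0), p_accumulation=0.0
    )
    pairs = []
    for gt, stack, _, ann in sg.generate_cohort(
        100, params, render_cfg, seed=5
    ):
        pairs.append((gt, am.measure_cell(stack, ann, thresholds)))
    return pairs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
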